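"""Covariate specification and design-matrix construction.

The mean model regresses log NO2 on a configurable set of terms:

* an intercept (always present),
* the natural log of the modelled-PCM background concentration,
* a monitor/tube indicator (reference: tube),
* local-environment dummies (reference: kerbside),
* spatially varying slope terms ``log_modelled x easting`` and
  ``log_modelled x northing``, with coordinates centred at the site
  centroid and scaled to units of 10 km so the design stays well
  conditioned.

A fitted :class:`DesignMatrix` remembers the factor levels it saw and the
coordinate centering constants, so the identical transform is applied at
prediction locations; an unseen factor level at prediction time raises
:class:`UnseenLevelError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import ENVIRONMENTS, SOURCES

COORD_SCALE_M = 10_000.0  # interaction coordinates in units of 10 km

#: term names accepted by :meth:`CovariateSpec.from_terms`
TERM_NAMES = ("log_modelled", "monitor_tube", "environment",
              "log_modelled:easting", "log_modelled:northing")


class DesignError(ValueError):
    pass


class UnseenLevelError(DesignError):
    """A factor level at prediction time was absent from the training data."""


@dataclass(frozen=True)
class CovariateSpec:
    """Declarative covariate choice for the mean model."""

    include_log_modelled: bool = True
    include_source: bool = False
    include_environment: bool = True
    include_spatial_interaction: bool = False
    reference_source: str = "tube"
    reference_environment: str = "kerbside"

    def __post_init__(self):
        if self.reference_source not in SOURCES:
            raise DesignError(f"unknown reference source {self.reference_source!r}")
        if self.reference_environment not in ENVIRONMENTS:
            raise DesignError(
                f"unknown reference environment {self.reference_environment!r}")
        if self.include_spatial_interaction and not self.include_log_modelled:
            raise DesignError("spatial interaction requires the log_modelled term")

    @classmethod
    def from_terms(cls, terms) -> "CovariateSpec":
        """Build a spec from a list of term names (see ``TERM_NAMES``)."""
        terms = list(terms)
        unknown = [t for t in terms if t not in TERM_NAMES]
        if unknown:
            raise DesignError(f"unknown terms {unknown}; valid: {TERM_NAMES}")
        inter = ("log_modelled:easting" in terms) or ("log_modelled:northing" in terms)
        return cls(
            include_log_modelled="log_modelled" in terms or inter,
            include_source="monitor_tube" in terms,
            include_environment="environment" in terms,
            include_spatial_interaction=inter,
        )

    @property
    def terms(self) -> tuple:
        out = []
        if self.include_log_modelled:
            out.append("log_modelled")
        if self.include_source:
            out.append("monitor_tube")
        if self.include_environment:
            out.append("environment")
        if self.include_spatial_interaction:
            out += ["log_modelled:easting", "log_modelled:northing"]
        return tuple(out)


@dataclass
class DesignMatrix:
    """A fitted design matrix plus everything needed to rebuild rows at new
    locations (factor levels, coordinate centering constants)."""

    values: np.ndarray
    column_names: list
    spec: CovariateSpec
    source_levels: tuple = ()
    environment_levels: tuple = ()
    center_easting_m: float = 0.0
    center_northing_m: float = 0.0
    coord_scale_m: float = COORD_SCALE_M

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def transform(self, sites: pd.DataFrame) -> np.ndarray:
        """Design rows for new locations under the stored transform."""
        values, _ = _rows(sites, self.spec, self.source_levels,
                          self.environment_levels, self.center_easting_m,
                          self.center_northing_m, self.coord_scale_m,
                          training=False)
        return values


def _log_modelled(sites: pd.DataFrame) -> np.ndarray:
    pcm = sites["pcm_no2_ugm3"].to_numpy(dtype=float)
    if (pcm <= 0).any():
        raise DesignError("modelled-PCM values must be strictly positive")
    return np.log(pcm)


def _rows(sites, spec, source_levels, env_levels, ce, cn, scale, *, training):
    m = len(sites)
    cols = [np.ones(m)]
    names = ["intercept"]
    if spec.include_log_modelled:
        logm = _log_modelled(sites)
        cols.append(logm)
        names.append("log_modelled")
    if spec.include_source:
        for lev in source_levels:
            cols.append((sites["source"].to_numpy() == lev).astype(float))
            names.append(lev)
        if not training:
            seen = set(sites["source"]) - {spec.reference_source} - set(source_levels)
            if seen:
                raise UnseenLevelError(f"source level(s) {sorted(seen)} not in training data")
    if spec.include_environment:
        for lev in env_levels:
            cols.append((sites["environment"].to_numpy() == lev).astype(float))
            names.append(lev)
        if not training:
            seen = (set(sites["environment"]) - {spec.reference_environment}
                    - set(env_levels))
            if seen:
                raise UnseenLevelError(
                    f"environment level(s) {sorted(seen)} not in training data")
    if spec.include_spatial_interaction:
        e = (sites["easting_m"].to_numpy(dtype=float) - ce) / scale
        n = (sites["northing_m"].to_numpy(dtype=float) - cn) / scale
        cols.append(logm * e)
        names.append("log_modelled:easting")
        cols.append(logm * n)
        names.append("log_modelled:northing")
    return np.column_stack(cols), names


def build_design_matrix(sites: pd.DataFrame, spec: CovariateSpec) -> DesignMatrix:
    """Fit a design matrix on a site table.

    Dummy columns are created for every non-reference factor level observed in
    ``sites`` (in vocabulary order), so no column is constant other than the
    intercept.  Interaction coordinates are centred at the site centroid.
    """
    source_levels = tuple(
        lev for lev in SOURCES
        if lev != spec.reference_source and (sites["source"] == lev).any()
    ) if spec.include_source else ()
    env_levels = tuple(
        lev for lev in ENVIRONMENTS
        if lev != spec.reference_environment and (sites["environment"] == lev).any()
    ) if spec.include_environment else ()
    ce = float(sites["easting_m"].mean())
    cn = float(sites["northing_m"].mean())
    values, names = _rows(sites, spec, source_levels, env_levels, ce, cn,
                          COORD_SCALE_M, training=True)
    dm = DesignMatrix(values=values, column_names=names, spec=spec,
                      source_levels=source_levels, environment_levels=env_levels,
                      center_easting_m=ce, center_northing_m=cn)
    (values2, names2) = (dm.transform(sites), names)
    assert np.array_equal(values, values2), "stored transform must reproduce training rows"
    return dm
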