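"""Synthetic study-region generator.

Emulates the structure of the motivating dataset — a West-of-Scotland-like
region with a 1 km modelled-background NO2 grid, a monitoring network of
abundant diffusion tubes and sparse automatic monitors (some co-located with
tubes), preferential siting towards polluted cells, and the five-level local
environment classification — and draws observations exactly from the
geostatistical fusion model the package fits:

    log Y = Z alpha + phi + eps,   phi ~ MVN(0, sigma2 * exp(-rho D)),
    eps ~ N(0, nu2 * sigma2 * I).

Defaults mirror the study conditions: 246 sites (230 tubes, 16 monitors),
environment frequencies 142/34/8/60/2 out of 246, a ~20 km x 20 km extent at
1 km grid resolution, and generative parameters set to the fitted study's
posterior medians (sigma2 = 0.057, nu2 = 0.232, rho = 12.852 per km, and the
reported covariate coefficients).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .covariance import (M_PER_KM, distance_matrix, exp_correlation,
                         jitter_duplicates)
from .design import CovariateSpec, build_design_matrix
from .tables import ENVIRONMENTS, validate_grid, validate_sites

#: generative coefficients on the log-concentration scale, keyed by design
#: column name; entries are looked up for whichever columns a covariate spec
#: actually produces.
DEFAULT_ALPHA = {
    "intercept": 1.900,
    "log_modelled": 0.594,
    "monitor": 0.125,
    "roadside": -0.150,
    "rural": -1.021,
    "special": -0.390,
    "urban_background": -0.531,
    "log_modelled:easting": 0.0,
    "log_modelled:northing": 0.0,
}

DEFAULT_ENVIRONMENT_PROPORTIONS = {
    "roadside": 142 / 246,
    "kerbside": 34 / 246,
    "special": 8 / 246,
    "urban_background": 60 / 246,
    "rural": 2 / 246,
}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class TrueParams:
    """Generative parameters of the fusion model."""

    alpha: dict = field(default_factory=lambda: dict(DEFAULT_ALPHA))
    sigma2: float = 0.057
    nu2: float = 0.232
    rho: float = 12.852  # decay per km; effective range ~ 3/rho ~ 0.23 km

    def __post_init__(self):
        if self.sigma2 <= 0:
            raise ConfigError("sigma2 must be positive")
        if not 0 < self.nu2 < 1:
            raise ConfigError("nu2 must lie in (0, 1)")
        if self.rho <= 0:
            raise ConfigError("rho must be positive")

    def alpha_for(self, column_names) -> np.ndarray:
        """Coefficient vector matching a design matrix's columns."""
        try:
            return np.array([self.alpha[c] for c in column_names], dtype=float)
        except KeyError as exc:
            raise ConfigError(f"no generative coefficient for column {exc}") from exc


@dataclass(frozen=True)
class SyntheticConfig:
    """Shape of the synthetic study region and monitoring network."""

    extent_m: tuple = (0.0, 20_000.0, 0.0, 20_000.0)  # (e_min, e_max, n_min, n_max)
    grid_resolution_m: float = 1000.0
    n_tubes: int = 230
    n_monitors: int = 16
    n_colocated: int = 8
    environment_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_ENVIRONMENT_PROPORTIONS))
    true_params: TrueParams = field(default_factory=TrueParams)
    seed: int = 0
    urban_radius_m: float | None = None  # default: 35% of the shorter extent side
    pcm_range_m: float = 5000.0      # smoothness of the log modelled surface
    pcm_sd_log: float = 0.25         # small-scale log-variability of the surface
    urban_bump_log: float = 0.9      # log-scale elevation of the city centre

    def __post_init__(self):
        e0, e1, n0, n1 = self.extent_m
        if not (e1 > e0 and n1 > n0):
            raise ConfigError("degenerate extent")
        if self.grid_resolution_m <= 0:
            raise ConfigError("grid_resolution_m must be positive")
        tot = sum(self.environment_proportions.values())
        if abs(tot - 1.0) > 1e-9:
            raise ConfigError(f"environment proportions sum to {tot}, not 1")
        unknown = set(self.environment_proportions) - set(ENVIRONMENTS)
        if unknown:
            raise ConfigError(f"unknown environment(s) {sorted(unknown)}")
        if self.n_colocated > min(self.n_tubes, self.n_monitors):
            raise ConfigError("n_colocated exceeds min(n_tubes, n_monitors)")
        if min(self.n_tubes, self.n_monitors, self.n_colocated) < 0:
            raise ConfigError("counts must be non-negative")

    @property
    def city_centre_m(self) -> tuple:
        e0, e1, n0, n1 = self.extent_m
        return (0.5 * (e0 + e1), 0.5 * (n0 + n1))

    @property
    def effective_urban_radius_m(self) -> float:
        if self.urban_radius_m is not None:
            return self.urban_radius_m
        e0, e1, n0, n1 = self.extent_m
        return 0.35 * min(e1 - e0, n1 - n0)


def generate_grid(config: SyntheticConfig) -> pd.DataFrame:
    """Generate a regular modelled-background grid over the extent.

    The log surface is a smooth Gaussian random field (squared-exponential
    kernel, range ``pcm_range_m``) around a rural baseline, plus a Gaussian
    "urban bump" centred on the synthetic city, so urban cells carry higher
    modelled values; cells within ``urban_radius_m`` of the centre are
    flagged urban.
    """
    rng = np.random.default_rng(config.seed)
    e0, e1, n0, n1 = config.extent_m
    res = config.grid_resolution_m
    e_centres = np.arange(e0 + res / 2, e1, res)
    n_centres = np.arange(n0 + res / 2, n1, res)
    ee, nn = np.meshgrid(e_centres, n_centres, indexing="ij")
    coords = np.column_stack([ee.ravel(), nn.ravel()])
    n_cells = coords.shape[0]
    if n_cells < 1:
        raise ConfigError("extent too small for the grid resolution")

    d = cdist(coords, coords) / config.pcm_range_m
    K = config.pcm_sd_log ** 2 * np.exp(-0.5 * d ** 2)
    K[np.diag_indices_from(K)] += 1e-8
    field_log = np.linalg.cholesky(K) @ rng.standard_normal(n_cells)

    cc = np.array(config.city_centre_m)
    dist_centre = np.hypot(coords[:, 0] - cc[0], coords[:, 1] - cc[1])
    radius = config.effective_urban_radius_m
    bump = config.urban_bump_log * np.exp(-0.5 * (dist_centre / radius) ** 2)
    rural_baseline_log = np.log(4.8)  # ug/m3, typical rural background
    pcm = np.exp(rural_baseline_log + bump + field_log)
    urban = dist_centre <= radius

    grid = pd.DataFrame({
        "cell_id": np.arange(n_cells),
        "easting_m": coords[:, 0],
        "northing_m": coords[:, 1],
        "pcm_no2_ugm3": pcm,
        "urban": urban,
    })
    return validate_grid(grid)


def generate_sites(config: SyntheticConfig, grid: pd.DataFrame) -> pd.DataFrame:
    """Place tubes and monitors on the region.

    Sites are assigned to grid cells with probability proportional to the
    cell's modelled value (emulating preferential siting where pollution is
    expected to be high), then uniformly within the cell.  ``n_colocated``
    monitors are placed at exactly the coordinates of a tube.  Environments
    are a multinomial draw from ``environment_proportions``.  The returned
    table has a placeholder concentration column (the modelled value) until
    :func:`simulate_observations` overwrites it.
    """
    rng = np.random.default_rng(config.seed + 1)
    n_sites = config.n_tubes + config.n_monitors
    if n_sites < 2:
        raise ConfigError("need at least two sites")
    n_free = n_sites - config.n_colocated
    if n_free > 50 * len(grid):
        raise ConfigError("requested site count exceeds what the extent can hold")
    res = config.grid_resolution_m
    w = grid["pcm_no2_ugm3"].to_numpy()
    cells = rng.choice(len(grid), size=n_free, replace=True, p=w / w.sum())
    offs = rng.uniform(-res / 2, res / 2, size=(n_free, 2))
    east = grid["easting_m"].to_numpy()[cells] + offs[:, 0]
    north = grid["northing_m"].to_numpy()[cells] + offs[:, 1]

    # layout: tubes first, then monitors; the last n_colocated monitors copy
    # the coordinates of the first n_colocated tubes.
    source = np.array(["tube"] * config.n_tubes + ["monitor"] * config.n_monitors)
    east = np.concatenate([east, east[:config.n_colocated]])
    north = np.concatenate([north, north[:config.n_colocated]])

    levels = list(config.environment_proportions)
    probs = np.array([config.environment_proportions[k] for k in levels])
    env = rng.choice(levels, size=n_sites, p=probs)

    # attach the containing cell's modelled value (co-located monitors share
    # their tube's cell)
    all_cells = np.concatenate([cells, cells[:config.n_colocated]])
    pcm = grid["pcm_no2_ugm3"].to_numpy()[all_cells]

    sites = pd.DataFrame({
        "site_id": [f"s{i:04d}" for i in range(n_sites)],
        "easting_m": east,
        "northing_m": north,
        "source": source,
        "environment": env,
        "pcm_no2_ugm3": pcm,
        "no2_ugm3": pcm,  # placeholder until observations are simulated
    })
    return validate_sites(sites)


def simulate_observations(sites: pd.DataFrame, spec: CovariateSpec,
                          params: TrueParams, seed: int) -> pd.DataFrame:
    """Draw NO2 observations from the generative model at the site locations.

    Returns a copy of ``sites`` with ``no2_ugm3`` set to ``exp(Z alpha + phi
    + eps)`` and two extra columns retained for oracle checks:
    ``phi_true`` (the realized spatial effect) and ``log_no2_true``
    (``Z alpha + phi``, the noiseless log mean).  Duplicated coordinates are
    deterministically jittered before the correlation matrix is formed.
    """
    rng = np.random.default_rng(seed)
    dm = build_design_matrix(sites, spec)
    alpha = params.alpha_for(dm.column_names)
    coords = jitter_duplicates(
        sites[["easting_m", "northing_m"]].to_numpy(dtype=float))
    D = distance_matrix(coords)
    S = exp_correlation(D, params.rho)
    try:
        L = np.linalg.cholesky(S + 1e-12 * np.eye(len(S)))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "correlation matrix singular even after jittering duplicated "
            f"coordinates (m={len(S)}, rho={params.rho}): {exc}") from exc
    phi = np.sqrt(params.sigma2) * (L @ rng.standard_normal(len(S)))
    eps = np.sqrt(params.nu2 * params.sigma2) * rng.standard_normal(len(S))
    mean_log = dm.values @ alpha
    y_log = mean_log + phi + eps
    out = sites.copy()
    out["no2_ugm3"] = np.exp(y_log)
    out["phi_true"] = phi
    out["log_no2_true"] = mean_log + phi
    return out


def generate_dataset(config: SyntheticConfig, spec: CovariateSpec | None = None):
    """Convenience wrapper: grid + sites + simulated observations.

    Returns ``(sites, grid)``; observation noise uses ``config.seed + 2``.
    """
    if spec is None:
        spec = CovariateSpec(include_log_modelled=True, include_source=True,
                             include_environment=True)
    grid = generate_grid(config)
    sites = generate_sites(config, grid)
    sites = simulate_observations(sites, spec, config.true_params,
                                  seed=config.seed + 2)
    return sites, grid
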