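"""Leave-one-out cross-validation and the model/data-source comparison
studies, with bias / RMSPE / coverage metrics.

All metrics are computed on the log scale (the modelling scale): bias is the
mean of (prediction - observation), RMSPE the root mean square of those
differences, and coverage the percentage of central 95% prediction intervals
(closed at both ends) containing the held-out log observation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .covariance import (CorrelationCache, cross_distance, default_rho_grid,
                         distance_matrix, exp_correlation, jitter_duplicates)
from .design import CovariateSpec, UnseenLevelError, build_design_matrix
from .inference import PriorSpec, ols_fit, reml_fit, run_mcmc
from .prediction import FusionFit, predict_points

logger = logging.getLogger(__name__)

FIT_METHODS = ("mcmc", "reml", "ols")


class ValidationError(RuntimeError):
    pass


@dataclass
class ValidationSummary:
    """LOOCV performance of one (model, data source) combination."""

    bias: float
    rmspe: float
    coverage_pct: float
    n_sites: int
    model: str = ""
    data_source: str = ""
    n_skipped: int = 0

    def as_dict(self) -> dict:
        return {"model": self.model, "data_source": self.data_source,
                "bias": self.bias, "rmspe": self.rmspe,
                "coverage_pct": self.coverage_pct, "n_sites": self.n_sites,
                "n_skipped": self.n_skipped}


def bias(predicted, observed) -> float:
    """Mean of (prediction - observation); positive means over-prediction."""
    p, o = _paired(predicted, observed)
    return float(np.mean(p - o))


def rmspe(predicted, observed) -> float:
    """Root mean square prediction error."""
    p, o = _paired(predicted, observed)
    return float(np.sqrt(np.mean((p - o) ** 2)))


def coverage(lower, upper, observed) -> float:
    """Percentage of closed intervals [lower, upper] containing the value."""
    lo = np.asarray(lower, dtype=float)
    hi = np.asarray(upper, dtype=float)
    o = np.asarray(observed, dtype=float)
    if not (lo.shape == hi.shape == o.shape):
        raise ValueError("interval and observation lengths differ")
    if (lo > hi).any():
        raise ValueError("malformed interval: lower > upper")
    return float(100.0 * np.mean((lo <= o) & (o <= hi)))


def _paired(predicted, observed):
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {o.shape}")
    if not (np.isfinite(p).all() and np.isfinite(o).all()):
        raise ValueError("non-finite values in metric inputs")
    return p, o


@dataclass
class MCMCSettings:
    """Scaled-down per-fold MCMC defaults for cross-validation runs."""

    n_burn: int = 500
    n_keep: int = 1000
    priors: PriorSpec | None = None


def _predict_one_mcmc(train, test_row, spec, settings, rho_grid, seed):
    dm = build_design_matrix(train, spec)
    z_star = dm.transform(test_row)[0]
    coords = jitter_duplicates(
        train[["easting_m", "northing_m"]].to_numpy(dtype=float))
    D = distance_matrix(coords)
    cache = CorrelationCache(D, rho_grid if rho_grid is not None
                             else default_rho_grid(D))
    y = np.log(train["no2_ugm3"].to_numpy(dtype=float))
    post = run_mcmc(y, dm.values, cache, priors=settings.priors,
                    n_burn=settings.n_burn, n_keep=settings.n_keep, seed=seed)
    fit = FusionFit(posterior=post, design=dm, cache=cache, coords_m=coords,
                    y_log=y)
    c = test_row[["easting_m", "northing_m"]].to_numpy(dtype=float)
    draws = predict_points(fit, c, z_star[None, :], seed=seed + 1)[:, 0]
    lo, med, hi = np.percentile(draws, [2.5, 50.0, 97.5])
    return med, lo, hi


def _predict_one_reml(train, test_row, spec, rho_grid):
    dm = build_design_matrix(train, spec)
    z_star = dm.transform(test_row)[0]
    coords = jitter_duplicates(
        train[["easting_m", "northing_m"]].to_numpy(dtype=float))
    D = distance_matrix(coords)
    cache = CorrelationCache(D, rho_grid if rho_grid is not None
                             else default_rho_grid(D))
    y = np.log(train["no2_ugm3"].to_numpy(dtype=float))
    fit = reml_fit(y, dm.values, cache)
    d = cross_distance(test_row[["easting_m", "northing_m"]].to_numpy(dtype=float),
                       coords)[0]
    c_star = exp_correlation(d, fit.rho)
    mean, sd = fit.predict(z_star, c_star)
    q = norm.ppf(0.975)
    return mean, mean - q * sd, mean + q * sd


def _predict_one_ols(train, test_row, spec):
    dm = build_design_matrix(train, spec)
    z_star = dm.transform(test_row)[0]
    y = np.log(train["no2_ugm3"].to_numpy(dtype=float))
    fit = ols_fit(y, dm.values)
    mean, _ = fit.predict(z_star)
    lo, hi = fit.interval(z_star)
    return mean, lo, hi


def _predict_batch(sites, targets, spec, fit_method, settings, rho_grid, seed):
    """Fit once on ``sites`` and predict every row of ``targets``.

    Returns ``(median, lo, hi, ok)`` with one entry per target whose design
    row could be built; ``ok`` marks which targets those are.
    """
    dm = build_design_matrix(sites, spec)
    ok = np.ones(len(targets), dtype=bool)
    rows = []
    for j, idx in enumerate(targets.index):
        try:
            rows.append(dm.transform(targets.loc[[idx]])[0])
        except UnseenLevelError as exc:
            logger.warning("skipping site %s: %s", idx, exc)
            ok[j] = False
    if not rows:
        return np.array([]), np.array([]), np.array([]), ok
    Z_star = np.vstack(rows)
    kept = targets.loc[ok]
    coords_t = kept[["easting_m", "northing_m"]].to_numpy(dtype=float)
    y = np.log(sites["no2_ugm3"].to_numpy(dtype=float))
    if fit_method == "ols":
        fit = ols_fit(y, dm.values)
        out = np.array([(fit.predict(z)[0], *fit.interval(z)) for z in Z_star])
        return out[:, 0], out[:, 1], out[:, 2], ok
    coords = jitter_duplicates(
        sites[["easting_m", "northing_m"]].to_numpy(dtype=float))
    D = distance_matrix(coords)
    cache = CorrelationCache(D, rho_grid if rho_grid is not None
                             else default_rho_grid(D))
    if fit_method == "reml":
        fit = reml_fit(y, dm.values, cache)
        q = norm.ppf(0.975)
        out = []
        for z, c in zip(Z_star, exp_correlation(
                cross_distance(coords_t, coords), fit.rho)):
            mean, sd = fit.predict(z, c)
            out.append((mean, mean - q * sd, mean + q * sd))
        out = np.array(out)
        return out[:, 0], out[:, 1], out[:, 2], ok
    post = run_mcmc(y, dm.values, cache, priors=settings.priors,
                    n_burn=settings.n_burn, n_keep=settings.n_keep, seed=seed)
    fit = FusionFit(posterior=post, design=dm, cache=cache, coords_m=coords,
                    y_log=y)
    draws = predict_points(fit, coords_t, Z_star, seed=seed + 1)
    lo, med, hi = np.percentile(draws, [2.5, 50.0, 97.5], axis=0)
    return med, lo, hi, ok


def loocv(sites: pd.DataFrame, spec: CovariateSpec, fit_method: str = "mcmc",
          settings: MCMCSettings | None = None, rho_grid=None, seed: int = 0,
          label: str = "", predict_sites: pd.DataFrame | None = None,
          max_skip_frac: float = 0.05) -> ValidationSummary:
    """Leave-one-out cross-validation of spatial prediction.

    Each site in ``predict_sites`` (default: all of ``sites``) is predicted
    in turn.  If the site belongs to the fitting set it is removed before
    refitting (its co-located twin, if any, stays — sharing coordinates is
    not leakage of the held-out measurement); otherwise the model is fitted
    on all of ``sites``.  Folds whose design cannot be built (e.g. the held
    out site carries a factor level absent from the remaining data) are
    skipped with a warning; more than ``max_skip_frac`` skipped folds aborts.
    """
    if fit_method not in FIT_METHODS:
        raise ValueError(f"fit_method must be one of {FIT_METHODS}")
    if len(sites) < 10:
        raise ValidationError("need at least 10 sites for cross-validation")
    settings = settings or MCMCSettings()
    if predict_sites is None:
        predict_sites = sites
    if rho_grid is None and fit_method in ("mcmc", "reml"):
        coords_all = jitter_duplicates(
            sites[["easting_m", "northing_m"]].to_numpy(dtype=float))
        rho_grid = default_rho_grid(distance_matrix(coords_all))

    in_fit = predict_sites.index.isin(sites.index)
    preds, los, his, obs = [], [], [], []
    skipped = 0
    for j, idx in enumerate(predict_sites.index):
        if not in_fit[j]:
            continue
        train = sites.drop(idx)
        test_row = predict_sites.loc[[idx]]
        try:
            if fit_method == "mcmc":
                med, lo, hi = _predict_one_mcmc(train, test_row, spec, settings,
                                                rho_grid, seed + 7919 * j)
            elif fit_method == "reml":
                med, lo, hi = _predict_one_reml(train, test_row, spec, rho_grid)
            else:
                med, lo, hi = _predict_one_ols(train, test_row, spec)
        except (UnseenLevelError, np.linalg.LinAlgError) as exc:
            logger.warning("skipping fold %s: %s", idx, exc)
            skipped += 1
            continue
        preds.append(med)
        los.append(lo)
        his.append(hi)
        obs.append(np.log(float(test_row["no2_ugm3"].iloc[0])))

    # sites outside the fitting set: one fit on all of `sites`, batch predict
    outside = predict_sites.loc[~in_fit]
    if len(outside):
        med, lo, hi, ok = _predict_batch(sites, outside, spec, fit_method,
                                         settings, rho_grid, seed + 104729)
        skipped += int((~ok).sum())
        preds += list(med)
        los += list(lo)
        his += list(hi)
        obs += list(np.log(outside["no2_ugm3"].to_numpy(dtype=float)[ok]))
    n_total = len(predict_sites)
    if skipped > max_skip_frac * n_total:
        raise ValidationError(
            f"{skipped}/{n_total} folds failed; cross-validation aborted")
    return ValidationSummary(
        bias=bias(preds, obs), rmspe=rmspe(preds, obs),
        coverage_pct=coverage(los, his, obs), n_sites=len(preds),
        model=label or fit_method, data_source="all", n_skipped=skipped)


def compare_models(sites: pd.DataFrame, specs, fit_methods=None,
                   settings: MCMCSettings | None = None, seed: int = 0,
                   rho_grid=None) -> pd.DataFrame:
    """LOOCV one covariate spec / estimation method per row.

    ``specs`` is a list of ``(label, CovariateSpec)``; ``fit_methods``
    defaults to MCMC for every spec.
    """
    specs = list(specs)
    if fit_methods is None:
        fit_methods = ["mcmc"] * len(specs)
    rows = []
    for (label, spec), method in zip(specs, fit_methods):
        s = loocv(sites, spec, fit_method=method, settings=settings,
                  seed=seed, label=label, rho_grid=rho_grid)
        rows.append(s.as_dict())
    return pd.DataFrame(rows)


def compare_data_sources(sites: pd.DataFrame, spec: CovariateSpec,
                         settings: MCMCSettings | None = None, seed: int = 0,
                         rho_grid=None, subsets=("monitors", "tubes", "both"),
                         max_skip_frac: float = 0.15) -> pd.DataFrame:
    """Fit on monitors only / tubes only / both; predict every site.

    For each subset the model is fitted to that subset's sites and all sites
    are predicted: subset members by leave-one-out refitting, the rest from
    the full subset fit.
    """
    frames = {"monitors": sites[sites["source"] == "monitor"],
              "tubes": sites[sites["source"] == "tube"],
              "both": sites}
    rows = []
    for name in subsets:
        sub = frames[name]
        if len(sub) < 10:
            raise ValidationError(
                f"subset {name!r} has only {len(sub)} sites; too few to fit")
        s = loocv(sub, spec, fit_method="mcmc", settings=settings, seed=seed,
                  label="fusion", predict_sites=sites, rho_grid=rho_grid,
                  max_skip_frac=max_skip_frac)
        s.data_source = name
        rows.append(s.as_dict())
    return pd.DataFrame(rows)


def pcm_baseline(sites: pd.DataFrame, label: str = "pcm_adjusted") -> ValidationSummary:
    """Dispersion-model baseline: log modelled value plus a fitted additive
    adjustment for roadside/kerbside sites, evaluated by LOOCV.

    The model is ``log Y = log PCM + b0 + b1 * 1(roadside or kerbside)``,
    i.e. an intercept-and-indicator regression of the log ratio; no spatial
    component.
    """
    y = np.log(sites["no2_ugm3"].to_numpy(dtype=float))
    logpcm = np.log(sites["pcm_no2_ugm3"].to_numpy(dtype=float))
    road = sites["environment"].isin(["roadside", "kerbside"]).to_numpy().astype(float)
    ratio = y - logpcm
    Z = np.column_stack([np.ones(len(y)), road])
    preds, los, his = [], [], []
    for i in range(len(y)):
        keep = np.arange(len(y)) != i
        fit = ols_fit(ratio[keep], Z[keep])
        mean, _ = fit.predict(Z[i])
        lo, hi = fit.interval(Z[i])
        preds.append(logpcm[i] + mean)
        los.append(logpcm[i] + lo)
        his.append(logpcm[i] + hi)
    return ValidationSummary(
        bias=bias(preds, y), rmspe=rmspe(preds, y),
        coverage_pct=coverage(los, his, y), n_sites=len(y),
        model=label, data_source="all")
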