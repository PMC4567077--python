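"""Model fitting: Gibbs/Metropolis MCMC for the Bayesian geostatistical
fusion model, plus REML and OLS comparators.

The model for the m log-scale observations Y at sites s_1..s_m is

    Y | alpha, phi, sigma2, nu2        ~ N(Z alpha + phi, nu2 sigma2 I)
    phi | sigma2, rho                  ~ N(0, sigma2 Sigma(rho)),
                                         Sigma(rho) = exp(-rho D)
    alpha ~ N(0, v I),   sigma2 ~ InvGamma(a, b),
    nu2 ~ Uniform(0, 1), rho ~ DiscreteUniform(rho_1..rho_r)

nu2 is the noise-to-signal ratio (the nugget is nu2*sigma2), rho the spatial
decay per km.  alpha, phi, sigma2 and rho have conjugate/enumerable full
conditionals and are Gibbs-updated exactly; nu2 is updated by a random-walk
Metropolis step on the logit scale.  Because rho has a discrete prior, every
correlation matrix the chain can visit is factorized exactly once, up front
(:class:`airfusion.covariance.CorrelationCache`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize_scalar
from scipy.special import expit, logit
import statsmodels.api as sm

from .covariance import CorrelationCache


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the weakly informative priors."""

    alpha_prior_var: float = 1000.0
    ig_a: float = 0.001
    ig_b: float = 0.001

    def __post_init__(self):
        if min(self.alpha_prior_var, self.ig_a, self.ig_b) <= 0:
            raise ValueError("prior hyperparameters must be positive")


@dataclass
class ModelState:
    """One MCMC state."""

    alpha: np.ndarray
    phi: np.ndarray
    sigma2: float
    nu2: float
    rho_index: int

    def validate(self, r: int) -> None:
        if self.sigma2 <= 0 or not (0 < self.nu2 < 1):
            raise ValueError(f"invalid state: sigma2={self.sigma2}, nu2={self.nu2}")
        if not 0 <= self.rho_index < r:
            raise ValueError(f"rho_index {self.rho_index} out of range")


@dataclass
class PosteriorSamples:
    """Retained MCMC draws plus bookkeeping."""

    alpha: np.ndarray      # (M, p)
    phi: np.ndarray        # (M, m)
    sigma2: np.ndarray     # (M,)
    nu2: np.ndarray        # (M,)
    rho_index: np.ndarray  # (M,) integer indices into rho_values
    rho_values: np.ndarray
    column_names: list = field(default_factory=list)
    n_burn: int = 0
    accept_rate_nu2: float = np.nan
    n_factorizations: int = 0
    nu2_step: float = np.nan
    geweke_z: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.sigma2.shape[0]

    @property
    def rho(self) -> np.ndarray:
        return self.rho_values[self.rho_index]

    @property
    def stationary(self) -> bool:
        """Geweke-style stationarity flag: |z| < 2 for sigma2 and nu2 traces."""
        return all(abs(z) < 2 for z in self.geweke_z.values())

    def summary(self) -> dict:
        """Posterior medians and central 95% intervals per parameter."""
        out = {}
        for i, name in enumerate(self.column_names or
                                 [f"alpha_{i}" for i in range(self.alpha.shape[1])]):
            out[name] = _msummary(self.alpha[:, i])
        out["sigma2"] = _msummary(self.sigma2)
        out["nu2"] = _msummary(self.nu2)
        out["rho"] = _msummary(self.rho)
        return out


def _msummary(x):
    lo, med, hi = np.percentile(x, [2.5, 50, 97.5])
    return {"median": med, "lo95": lo, "hi95": hi}


# ---------------------------------------------------------------------------
# full-conditional updates

def sample_alpha(Y, Z, phi, sigma2, nu2, prior_var, rng, ZtZ=None):
    """Exact Gibbs draw of the regression coefficients.

    Conjugate Gaussian: precision Z'Z/(nu2 sigma2) + I/prior_var, mean the
    precision-weighted regression of (Y - phi) on Z.
    """
    p = Z.shape[1]
    tau2 = nu2 * sigma2
    if ZtZ is None:
        ZtZ = Z.T @ Z
    A = ZtZ / tau2 + np.eye(p) / prior_var
    b = Z.T @ (Y - phi) / tau2
    L = np.linalg.cholesky(A)
    mean = cho_solve((L, True), b, check_finite=False)
    z = rng.standard_normal(p)
    return mean + solve_triangular(L, z, lower=True, trans="T",
                                   check_finite=False)


def alpha_full_conditional(Y, Z, phi, sigma2, nu2, prior_var):
    """Mean and covariance of the alpha full conditional (for oracle checks)."""
    p = Z.shape[1]
    tau2 = nu2 * sigma2
    A = Z.T @ Z / tau2 + np.eye(p) / prior_var
    cov = np.linalg.inv(A)
    return cov @ (Z.T @ (Y - phi)) / tau2, cov


def sample_phi(Y, Z, alpha, sigma2, nu2, sigma_inv, rng):
    """Exact Gibbs draw of the spatial random effects.

    Full conditional is Gaussian with precision (Sigma^-1 + I/nu2)/sigma2 and
    mean solving that precision against (Y - Z alpha)/(nu2 sigma2).
    """
    m = Y.shape[0]
    B = sigma_inv + np.eye(m) / nu2
    L = np.linalg.cholesky(B)
    resid = Y - Z @ alpha
    mean = cho_solve((L, True), resid / nu2, check_finite=False)
    z = rng.standard_normal(m)
    return mean + np.sqrt(sigma2) * solve_triangular(L, z, lower=True, trans="T",
                                                     check_finite=False)


def phi_full_conditional(Y, Z, alpha, sigma2, nu2, sigma):
    """Mean and covariance of the phi full conditional (for oracle checks)."""
    m = Y.shape[0]
    prec = (np.linalg.inv(sigma) + np.eye(m) / nu2) / sigma2
    cov = np.linalg.inv(prec)
    return cov @ (Y - Z @ alpha) / (nu2 * sigma2), cov


def sigma2_shape_scale(Y, Z, alpha, phi, nu2, quad_phi, priors: PriorSpec):
    """Inverse-gamma full-conditional shape and scale for sigma2.

    Both the nugget likelihood and the spatial prior have variances
    proportional to sigma2, so each contributes m/2 to the shape: the
    posterior shape is a + m, and the scale is
    b + [phi' Sigma^-1 phi + ||Y - Z alpha - phi||^2 / nu2] / 2.
    """
    m = Y.shape[0]
    resid = Y - Z @ alpha - phi
    shape = priors.ig_a + m
    scale = priors.ig_b + 0.5 * (quad_phi + resid @ resid / nu2)
    return shape, scale


def sample_sigma2(Y, Z, alpha, phi, nu2, quad_phi, priors, rng):
    shape, scale = sigma2_shape_scale(Y, Z, alpha, phi, nu2, quad_phi, priors)
    return scale / rng.gamma(shape)


def nu2_log_density(nu2, ss, m, sigma2):
    """Unnormalized log full conditional of nu2 on (0, 1)."""
    if not 0 < nu2 < 1:
        return -np.inf
    return -0.5 * m * np.log(nu2) - ss / (2.0 * nu2 * sigma2)


def sample_nu2(Y, Z, alpha, phi, sigma2, nu2, step, rng):
    """Metropolis-Hastings update of nu2 via a logit-scale random walk.

    Returns ``(new_nu2, accepted)``; the logit Jacobian nu2(1-nu2) is
    included so the walk targets the stated density on (0, 1).
    """
    resid = Y - Z @ alpha - phi
    ss = resid @ resid
    m = Y.shape[0]
    theta = logit(nu2)
    prop = float(expit(theta + step * rng.standard_normal()))
    # expit can saturate to exactly 0/1 in float; reject those proposals
    if not 0.0 < prop < 1.0:
        return nu2, False
    log_ratio = (nu2_log_density(prop, ss, m, sigma2)
                 - nu2_log_density(nu2, ss, m, sigma2)
                 + np.log(prop * (1 - prop)) - np.log(nu2 * (1 - nu2)))
    if np.log(rng.uniform()) < log_ratio:
        return prop, True
    return nu2, False


def rho_log_probs(phi, sigma2, cache: CorrelationCache):
    """Unnormalized log full-conditional mass for every decay candidate."""
    return -0.5 * cache.logdet - cache.quad_forms(phi) / (2.0 * sigma2)


def sample_rho(phi, sigma2, cache, rng):
    """Exact draw from the discrete full conditional of the decay index."""
    logp = rho_log_probs(phi, sigma2, cache)
    mx = np.max(logp)
    if not np.isfinite(mx):
        raise FloatingPointError("all decay candidates have zero posterior mass")
    w = np.exp(logp - mx)
    cum = np.cumsum(w)
    return int(np.searchsorted(cum, rng.uniform() * cum[-1]))


# ---------------------------------------------------------------------------
# the chain

def run_mcmc(Y, Z, cache: CorrelationCache, priors: PriorSpec | None = None,
             n_burn: int = 500, n_keep: int = 1000, seed: int = 0,
             column_names=None, nu2_step: float = 1.0,
             adapt_interval: int = 25) -> PosteriorSamples:
    """Fit the fusion model by MCMC.

    One systematic scan per iteration in the order alpha, phi, sigma2, nu2,
    rho; the nu2 proposal step is adapted toward a 20-50% acceptance rate
    during burn-in only and frozen afterwards.  Deterministic for a given
    seed.  Raises on divergence (non-finite or exploding sigma2).
    """
    Y = np.asarray(Y, dtype=float)
    Z = np.asarray(Z, dtype=float)
    priors = priors or PriorSpec()
    if n_keep <= 0 or n_burn < 0:
        raise ValueError("need n_keep > 0 and n_burn >= 0")
    m, p = Z.shape
    if Y.shape != (m,) or cache.m != m:
        raise ValueError("Y, Z and cache dimensions disagree")
    rng = np.random.default_rng(seed)
    ZtZ = Z.T @ Z

    # moment-based initialization
    alpha, *_ = np.linalg.lstsq(Z, Y, rcond=None)
    resid0 = Y - Z @ alpha
    sigma2 = max(float(resid0 @ resid0) / max(m - p, 1), 1e-6)
    nu2 = 0.5
    phi = np.zeros(m)
    rho_index = cache.r // 2

    keep_alpha = np.empty((n_keep, p))
    keep_phi = np.empty((n_keep, m))
    keep_sigma2 = np.empty(n_keep)
    keep_nu2 = np.empty(n_keep)
    keep_rho = np.empty(n_keep, dtype=int)
    step = float(nu2_step)
    acc_window = 0
    acc_kept = 0

    for it in range(n_burn + n_keep):
        alpha = sample_alpha(Y, Z, phi, sigma2, nu2, priors.alpha_prior_var,
                             rng, ZtZ=ZtZ)
        phi = sample_phi(Y, Z, alpha, sigma2, nu2, cache.sigma_inv[rho_index], rng)
        quad_phi = float(phi @ cache.sigma_inv[rho_index] @ phi)
        sigma2 = sample_sigma2(Y, Z, alpha, phi, nu2, quad_phi, priors, rng)
        if not np.isfinite(sigma2) or sigma2 > 1e12:
            raise RuntimeError(
                f"chain diverged at iteration {it}: sigma2={sigma2!r}, "
                f"nu2={nu2!r}, rho={cache.rho_grid[rho_index]!r}")
        nu2, accepted = sample_nu2(Y, Z, alpha, phi, sigma2, nu2, step, rng)
        rho_index = sample_rho(phi, sigma2, cache, rng)

        if it < n_burn:
            acc_window += accepted
            if (it + 1) % adapt_interval == 0:
                rate = acc_window / adapt_interval
                # multiplicative nudge toward a ~35% acceptance rate
                step *= float(np.exp(rate - 0.35))
                acc_window = 0
        else:
            j = it - n_burn
            acc_kept += accepted
            keep_alpha[j] = alpha
            keep_phi[j] = phi
            keep_sigma2[j] = sigma2
            keep_nu2[j] = nu2
            keep_rho[j] = rho_index

    geweke = {"sigma2": geweke_z(keep_sigma2), "nu2": geweke_z(keep_nu2)}
    return PosteriorSamples(
        alpha=keep_alpha, phi=keep_phi, sigma2=keep_sigma2, nu2=keep_nu2,
        rho_index=keep_rho, rho_values=np.asarray(cache.rho_grid),
        column_names=list(column_names or []), n_burn=n_burn,
        accept_rate_nu2=acc_kept / n_keep,
        n_factorizations=cache.n_factorizations, nu2_step=step,
        geweke_z=geweke)


def geweke_z(trace, first: float = 0.1, last: float = 0.5):
    """Crude Geweke-style z-score comparing early and late segment means.

    Uses naive (iid) standard errors; intended as a red flag for a clearly
    non-stationary trace, not a calibrated test.
    """
    n = len(trace)
    a = trace[: max(int(first * n), 2)]
    b = trace[-max(int(last * n), 2):]
    se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
    if se == 0:
        return 0.0
    return float((a.mean() - b.mean()) / se)


# ---------------------------------------------------------------------------
# comparators

def restricted_loglik_profile(Y, Z, V):
    """Profiled restricted log-likelihood of Y ~ N(Z alpha, sigma2 V).

    Returns ``(loglik, sigma2_hat, alpha_hat, cov_alpha_unit)`` where sigma2
    is profiled out at its REML estimate r'V^-1 r/(m-p) and ``cov_alpha_unit``
    is (Z'V^-1 Z)^-1 (multiply by sigma2_hat for the GLS covariance).
    """
    m, p = Z.shape
    cv = cho_factor(V, lower=True)
    Vi_Z = cho_solve(cv, Z)
    Vi_Y = cho_solve(cv, Y)
    ZtViZ = Z.T @ Vi_Z
    cz = cho_factor(ZtViZ, lower=True)
    alpha_hat = cho_solve(cz, Z.T @ Vi_Y)
    r = Y - Z @ alpha_hat
    sigma2_hat = float(r @ cho_solve(cv, r)) / (m - p)
    logdet_V = 2.0 * np.sum(np.log(np.diag(cv[0])))
    logdet_ZtViZ = 2.0 * np.sum(np.log(np.diag(cz[0])))
    ll = -0.5 * ((m - p) * (1.0 + np.log(2 * np.pi * sigma2_hat))
                 + logdet_V + logdet_ZtViZ)
    return ll, sigma2_hat, alpha_hat, np.linalg.inv(ZtViZ)


@dataclass
class REMLFit:
    """Plug-in spatial fit: REML variance components with a profile search
    over the discrete decay grid, GLS coefficients at the optimum.

    Predictions are universal kriging with the estimated (sigma2, nu2, rho)
    treated as fixed and known, so its intervals carry no parameter
    uncertainty beyond the GLS coefficient covariance.
    """

    alpha: np.ndarray
    cov_alpha: np.ndarray
    sigma2: float
    nu2: float
    rho: float
    rho_index: int
    loglik: float
    column_names: list
    _Vi_resid: np.ndarray = None   # V^-1 (Y - Z alpha_hat)
    _Vi_Z: np.ndarray = None
    _Z: np.ndarray = None

    def predict(self, z_star: np.ndarray, c_star: np.ndarray):
        """Plug-in predictive mean and sd (log scale) at one location.

        ``c_star`` is the exponential correlation between the location and
        the m observation sites at the fitted rho.
        """
        mean = float(z_star @ self.alpha + c_star @ self._Vi_resid)
        u = z_star - c_star @ self._Vi_Z
        var = self.sigma2 * (1.0 + self.nu2
                             - float(c_star @ self._krige_Vi(c_star))
                             + float(u @ self.cov_alpha @ u) / self.sigma2)
        return mean, np.sqrt(max(var, 0.0))

    def _krige_Vi(self, c_star):
        return cho_solve(self._cv, c_star)


def reml_fit(Y, Z, cache: CorrelationCache, column_names=None) -> REMLFit:
    """Fit the spatial model by restricted maximum likelihood.

    For each decay candidate the noise-to-signal ratio nu2 is optimized on a
    log scale (sigma2 profiled in closed form); the candidate with the best
    restricted likelihood wins and GLS coefficients are computed there.
    """
    Y = np.asarray(Y, dtype=float)
    Z = np.asarray(Z, dtype=float)
    m = Y.shape[0]
    eye = np.eye(m)
    best = None
    for k in range(cache.r):
        S = cache.sigma[k]

        def neg_ll(log_nu2, S=S):
            return -restricted_loglik_profile(Y, Z, S + np.exp(log_nu2) * eye)[0]

        res = minimize_scalar(neg_ll, bounds=(-12.0, 5.0), method="bounded",
                              options={"xatol": 1e-4})
        if best is None or -res.fun > best[0]:
            best = (-res.fun, k, float(np.exp(res.x)))
    ll, k, nu2 = best
    V = cache.sigma[k] + nu2 * eye
    ll, sigma2, alpha, cov_unit = restricted_loglik_profile(Y, Z, V)
    cv = cho_factor(V, lower=True)
    fit = REMLFit(alpha=alpha, cov_alpha=sigma2 * cov_unit, sigma2=sigma2,
                  nu2=nu2, rho=float(cache.rho_grid[k]), rho_index=k,
                  loglik=ll, column_names=list(column_names or []),
                  _Vi_resid=cho_solve(cv, Y - Z @ alpha),
                  _Vi_Z=cho_solve(cv, Z), _Z=Z)
    fit._cv = cv
    return fit


@dataclass
class OLSFit:
    """Non-spatial comparator: ordinary least squares on the log scale with
    iid-Gaussian (t-based) prediction intervals."""

    result: object
    column_names: list

    @property
    def alpha(self) -> np.ndarray:
        return np.asarray(self.result.params)

    def predict(self, z_star: np.ndarray):
        """Predictive mean and sd (log scale) at design row(s) z_star."""
        pred = self.result.get_prediction(np.atleast_2d(z_star))
        return float(pred.predicted_mean[0]), float(pred.se_obs[0])

    def interval(self, z_star, level=0.95):
        pred = self.result.get_prediction(np.atleast_2d(z_star))
        lo, hi = pred.conf_int(obs=True, alpha=1 - level)[0]
        return float(lo), float(hi)


def ols_fit(Y, Z, column_names=None) -> OLSFit:
    """Ordinary least squares on the log scale, ignoring spatial correlation."""
    Z = np.asarray(Z, dtype=float)
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    res = sm.OLS(np.asarray(Y, dtype=float), Z).fit()
    return OLSFit(result=res, column_names=list(column_names or []))
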