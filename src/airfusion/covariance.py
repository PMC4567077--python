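"""Spatial covariance machinery: distances, the exponential kernel and the
per-candidate correlation cache.

The spatial random effects carry an isotropic exponential correlation,
``Sigma(rho) = exp(-rho * D)``, with ``D`` the matrix of pairwise Euclidean
distances.  The decay parameter ``rho`` has a discrete prior over ``r``
candidate values, so each correlation matrix, its inverse and its
log-determinant are factorized once and cached; the MCMC then never touches
a dense factorization of ``Sigma`` again.  The cache counts factorizations
so this economy is testable.

Distances are in kilometres; coordinates enter in metres and are divided by
1000 here, at the single unit boundary.  ``rho`` is therefore a decay per
kilometre (effective correlation range ~ 3/rho km).
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist

M_PER_KM = 1000.0

#: deterministic offset (metres) applied to duplicated coordinates before any
#: distance matrix is formed; exp(-rho*D) is singular at zero distances.
JITTER_M = 1.0


def jitter_duplicates(coords_m: np.ndarray, step_m: float = JITTER_M) -> np.ndarray:
    """Return a copy of ``coords_m`` (n x 2, metres) with duplicated points
    displaced deterministically.

    Within each group of identical coordinates the first point is untouched
    and the k-th subsequent duplicate is moved ``k * step_m`` metres along a
    fixed direction that cycles E, N, W, S.  Deterministic, so a rebuilt
    distance matrix is bit-identical.
    """
    coords = np.asarray(coords_m, dtype=float).copy()
    directions = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0], [0.0, -1.0]])
    seen: dict[tuple, int] = {}
    for i in range(coords.shape[0]):
        key = (coords[i, 0], coords[i, 1])
        k = seen.get(key, 0)
        seen[key] = k + 1
        if k > 0:
            d = directions[(k - 1) % 4]
            coords[i] += d * step_m * (1 + (k - 1) // 4)
    return coords


def distance_matrix(coords_m: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distance matrix in km from metre coordinates.

    Duplicated coordinates must already have been jittered
    (:func:`jitter_duplicates`); off-diagonal zeros raise.
    """
    coords = np.asarray(coords_m, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] < 2:
        raise ValueError("expected an (n>=2) x 2 coordinate array")
    D = cdist(coords, coords) / M_PER_KM
    off = ~np.eye(D.shape[0], dtype=bool)
    if (D[off] <= 0).any():
        raise ValueError("zero off-diagonal distance: jitter duplicates first")
    return D


def cross_distance(coords_pred_m: np.ndarray, coords_obs_m: np.ndarray) -> np.ndarray:
    """N x m distance matrix (km) between prediction and observation points."""
    a = np.atleast_2d(np.asarray(coords_pred_m, dtype=float))
    b = np.atleast_2d(np.asarray(coords_obs_m, dtype=float))
    return cdist(a, b) / M_PER_KM


def exp_correlation(D: np.ndarray, rho: float) -> np.ndarray:
    """Exponential correlation ``exp(-rho * D)``; ``rho`` must be > 0."""
    if rho <= 0:
        raise ValueError(f"rho must be positive, got {rho}")
    return np.exp(-rho * np.asarray(D, dtype=float))


def default_rho_grid(D: np.ndarray, r: int = 50) -> np.ndarray:
    """Default decay-candidate grid: ``r`` geometrically spaced values whose
    effective range 3/rho spans 0.005x to 2x the maximum inter-site distance.

    The wide lower end lets the model represent correlation that is only
    appreciable between near-coincident sites (co-located instrument pairs),
    which is the regime the study's short-range decay lives in.
    """
    d_max = float(np.max(D))
    if d_max <= 0:
        raise ValueError("degenerate distance matrix")
    lo = 3.0 / (2.0 * d_max)
    hi = 3.0 / (0.005 * d_max)
    return np.geomspace(lo, hi, int(r))


class CorrelationCache:
    """Precomputed exponential-correlation factorizations on a fixed site set.

    For each candidate decay ``rho_k`` the cache holds ``Sigma(rho_k)``, its
    inverse and its log-determinant, computed via one Cholesky factorization
    per candidate.  ``n_factorizations`` records how many factorizations were
    ever performed (exactly ``r`` per fitted dataset).

    Parameters
    ----------
    D : (m, m) array
        Symmetric distance matrix in km, zero diagonal, positive off-diagonal.
    rho_grid : (r,) array
        Strictly increasing candidate decays.
    """

    def __init__(self, D: np.ndarray, rho_grid: np.ndarray):
        D = np.asarray(D, dtype=float)
        rho_grid = np.asarray(rho_grid, dtype=float)
        if rho_grid.ndim != 1 or len(rho_grid) == 0:
            raise ValueError("rho_grid must be a nonempty 1-d array")
        if len(rho_grid) > 1 and not np.all(np.diff(rho_grid) > 0):
            raise ValueError("rho_grid must be strictly increasing")
        if (rho_grid <= 0).any():
            raise ValueError("rho candidates must be positive")
        if not np.allclose(D, D.T) or np.abs(np.diag(D)).max() > 0:
            raise ValueError("D must be symmetric with a zero diagonal")
        self.D = D
        self.rho_grid = rho_grid
        m, r = D.shape[0], len(rho_grid)
        self.m = m
        self.r = r
        self.sigma = np.empty((r, m, m))
        self.sigma_inv = np.empty((r, m, m))
        self.logdet = np.empty(r)
        self.n_factorizations = 0
        eye = np.eye(m)
        for k, rho in enumerate(rho_grid):
            S = exp_correlation(D, rho)
            try:
                c, low = cho_factor(S, lower=True)
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise np.linalg.LinAlgError(
                    f"Sigma(rho={rho:g}) not positive definite: {exc}") from exc
            self.n_factorizations += 1
            self.sigma[k] = S
            self.sigma_inv[k] = cho_solve((c, low), eye)
            self.logdet[k] = 2.0 * np.sum(np.log(np.diag(c)))

    def quad_forms(self, phi: np.ndarray) -> np.ndarray:
        """``phi^T Sigma(rho_k)^{-1} phi`` for every candidate k, as an (r,) array."""
        tmp = self.sigma_inv @ phi            # (r, m)
        return tmp @ phi
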