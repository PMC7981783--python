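"""Sparse canonical correlation analysis by penalized matrix decomposition.

The solver finds sparse unit weight vectors wx, wy maximizing the
cross-block covariance

    maximize  wxᵀ (XᵀY) wy
    subject to ‖wx‖₂ ≤ 1, ‖wy‖₂ ≤ 1,
               ‖wx‖₁ ≤ penalty_x·√p, ‖wy‖₁ ≤ penalty_y·√q,

by alternating soft-threshold updates: with wy fixed, wx is the
L2-normalized soft-thresholding of XᵀY·wy, the threshold found by
bisection so the L1 bound binds (zero threshold when the bound is
slack); symmetrically for wy.  The penalty parameters live on
(1/√dim, 1], so penalty = 1 imposes no sparsity (any unit vector has
L1 ≤ √dim) and penalty = 1/√dim forces a single nonzero weight.

The canonical correlation r of a mode is the Pearson correlation of the
two variates X·wx and Y·wy (the covariance objective is a surrogate for
it, exact when within-block feature correlations vanish).  Successive
modes are obtained by Hotelling deflation of the cross-covariance
matrix.  The proportion of covariance a mode accounts for is r².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SCCAMode",
    "SCCAModel",
    "soft_threshold",
    "fit_first_mode",
    "fit_modes",
    "cross_loadings",
    "covariance_explained",
    "filter_by_effect",
]

MAX_ITER = 1000
WEIGHT_TOL = 1e-6
L1_BISECT_TOL = 1e-8


def soft_threshold(v: np.ndarray, delta: float) -> np.ndarray:
    """Elementwise sign(v)·max(|v| − delta, 0)."""
    if delta < 0:
        raise ValueError("delta must be non-negative")
    v = np.asarray(v, dtype=float)
    return np.sign(v) * np.maximum(np.abs(v) - delta, 0.0)


def _unit(v: np.ndarray) -> np.ndarray:
    nrm = np.sqrt(v @ v)
    return v / nrm if nrm > 0 else v


def _threshold_for_l1(abs_a: np.ndarray, c: float) -> float | None:
    """Exact soft threshold Δ with ‖S(a,Δ)‖₁/‖S(a,Δ)‖₂ = c, or None.

    With the active set fixed to the k largest |a| and partial sums
    s = Σ|a|, ss = Σa², the bound binds where
    (s − kΔ)² = c²(ss − 2sΔ + kΔ²), a quadratic in Δ solved on the
    interval [t_(k+1), t_(k)) of sorted magnitudes.  Returns None when
    ties at the boundary leave no root (degenerate active set).
    """
    t = np.sort(abs_a)[::-1]
    s = np.cumsum(t)
    ss = np.cumsum(t**2)
    d = t.size
    k_range = np.arange(1, d + 1)
    # L1/L2 ratio at each interval's lower endpoint Δ = t_(k+1) (0 for k=d)
    lows = np.empty(d)
    lows[:-1] = t[1:]
    lows[-1] = 0.0
    l2 = np.sqrt(np.maximum(ss - 2 * lows * s + k_range * lows**2, 0.0))
    ratio = (s - k_range * lows) / (l2 + 1e-300)
    crossing = np.flatnonzero(ratio >= c)
    if crossing.size == 0:
        return None
    t_max = t[0]
    k_first = int(crossing[0]) + 1
    for k in (k_first, min(k_first + 1, d)):
        sk, ssk = s[k - 1], ss[k - 1]
        km = k - c * c
        if abs(km) < 1e-12:  # c^2 == k: the equation loses its Δ dependence
            continue
        disc = c * c * km * (k * ssk - sk * sk)
        if disc < 0:
            continue
        root = np.sqrt(disc)
        # "−" branch lies on the decreasing side of the ratio; try it first
        for delta in ((sk * km - root) / (k * km), (sk * km + root) / (k * km)):
            if not 0.0 <= delta <= t_max:
                continue
            # accept the root whose achieved ratio actually meets the bound
            v = np.maximum(abs_a - delta, 0.0)
            l2v = np.sqrt(v @ v)
            if l2v > 0 and abs(v.sum() / l2v - c) < 1e-9 * max(1.0, c):
                return float(delta)
    return None


def _penalized_unit_vector(a: np.ndarray, c: float) -> np.ndarray:
    """argmax_u aᵀu  s.t. ‖u‖₂ ≤ 1, ‖u‖₁ ≤ c.

    The unconstrained maximizer is a/‖a‖₂; when its L1 norm already
    satisfies the bound the threshold is zero (fast path).  Otherwise the
    soft threshold Δ making the L1 bound bind is computed in closed form
    per active set, with a bisection fallback (tolerance L1_BISECT_TOL)
    for degenerate configurations.
    """
    abs_a = np.abs(a)
    u = _unit(a)
    if np.abs(u).sum() <= c:
        return u
    delta = _threshold_for_l1(abs_a, c)
    if delta is not None:
        u = _unit(soft_threshold(a, delta))
        if np.any(u) and np.abs(u).sum() <= c * (1 + L1_BISECT_TOL):
            return u
    lo, hi = 0.0, float(abs_a.max())
    while hi - lo > L1_BISECT_TOL * max(1.0, hi):
        mid = 0.5 * (lo + hi)
        u = _unit(soft_threshold(a, mid))
        if np.abs(u).sum() > c:
            lo = mid
        else:
            hi = mid
    u = _unit(soft_threshold(a, hi))
    if not np.any(u):
        # exact ties at max|a| make the thresholded family jump from
        # infeasible straight to zero; the optimum then spreads the L1
        # budget equally over the tied entries
        tied = abs_a >= hi * (1.0 - 1e-12)
        k = int(tied.sum())
        u = np.zeros_like(a)
        u[tied] = np.sign(a[tied]) * min(c / k, 1.0 / np.sqrt(k))
    return u


@dataclass
class SCCAMode:
    """One canonical mode: sparse weights, variates, r, cross-loadings."""

    weights_x: np.ndarray
    weights_y: np.ndarray
    variate_x: np.ndarray
    variate_y: np.ndarray
    r: float
    cross_loadings_x: np.ndarray
    cross_loadings_y: np.ndarray
    covariance_explained: float
    n_iter: int
    converged: bool
    objective: float


@dataclass
class SCCAModel:
    """Ordered modes from successive deflations, with the shared penalties."""

    modes: list[SCCAMode]
    penalty_x: float
    penalty_y: float

    @property
    def first(self) -> SCCAMode:
        return self.modes[0]


def _as_matrix(M, name: str) -> np.ndarray:
    A = np.asarray(getattr(M, "to_numpy", lambda: M)(), dtype=float)
    if A.ndim != 2:
        raise ValueError(f"{name} must be 2-D")
    if not np.all(np.isfinite(A)):
        raise ValueError(f"{name} contains non-finite values")
    return A


def _check_penalty(penalty: float, dim: int, name: str) -> float:
    if not 0.0 < penalty <= 1.0:
        raise ValueError(f"{name} must lie in (0, 1]")
    c = penalty * np.sqrt(dim)
    if c < 1.0 - 1e-9:
        raise ValueError(f"{name}={penalty} is below the feasible floor 1/sqrt(dim)")
    return max(c, 1.0)  # c = 1 exactly at the grid's lower endpoint


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def _fit_mode_on_cross(
    Z: np.ndarray, cx: float, cy: float
) -> tuple[np.ndarray, np.ndarray, int, bool, float]:
    """Alternating maximization of uᵀZv on the constrained ball pair.

    Initialized at the leading right singular vector of Z (deterministic).
    The objective is non-decreasing across iterations; a decrease beyond
    round-off is flagged as a convergence failure.
    """
    v = np.linalg.svd(Z, full_matrices=False)[2][0]
    v = _penalized_unit_vector(v, cy)
    u = _penalized_unit_vector(Z @ v, cx)
    obj = float(u @ Z @ v)
    converged = False
    ascent_ok = True
    it = 0
    for it in range(1, MAX_ITER + 1):
        u_new = _penalized_unit_vector(Z @ v, cx)
        v_new = _penalized_unit_vector(Z.T @ u_new, cy)
        obj_new = float(u_new @ Z @ v_new)
        # slack covers round-off from the approximate L1 bisection
        if obj_new < obj - 1e-6 * max(1.0, abs(obj)):
            ascent_ok = False
        delta = max(np.abs(u_new - u).max(), np.abs(v_new - v).max())
        u, v, obj = u_new, v_new, obj_new
        if delta < WEIGHT_TOL:
            converged = True
            break
    if not converged:
        warnings.warn("sCCA alternating updates did not converge; returning best iterate")
    return u, v, it, converged and ascent_ok, obj


def _canonical_sign(u: np.ndarray, v: np.ndarray) -> float:
    """Joint sign making the largest-magnitude weight positive.

    The solution pair is only defined up to (u, v) -> (-u, -v); pinning
    the representative by a value-based rule keeps fits equivariant
    under feature permutation and independent of SVD sign conventions.
    """
    for w in (u, v):
        if np.any(w != 0):
            return float(np.sign(w[np.argmax(np.abs(w))]))
    return 1.0


def _populate_mode(
    X: np.ndarray,
    Y: np.ndarray,
    u: np.ndarray,
    v: np.ndarray,
    it: int,
    conv: bool,
    obj: float,
    loadings: bool = True,
) -> SCCAMode:
    r = _pearson(X @ u, Y @ v)
    if r < 0:  # sign convention: report r >= 0, flipping both weight vectors
        u, v, r = -u, -v, -r
    r = min(r, 1.0)  # guard against round-off beyond the exact bound
    s = _canonical_sign(u, v)
    u, v = s * u, s * v
    ax, ay = X @ u, Y @ v
    if loadings:
        clx, cly = _cross_loadings_arrays(X, Y, ax, ay)
    else:  # refit-heavy resampling paths only need r
        clx = cly = np.empty(0)
    return SCCAMode(
        weights_x=u,
        weights_y=v,
        variate_x=ax,
        variate_y=ay,
        r=r,
        cross_loadings_x=clx,
        cross_loadings_y=cly,
        covariance_explained=covariance_explained(r),
        n_iter=it,
        converged=conv,
        objective=obj,
    )


def fit_first_mode(X, Y, penalty_x: float, penalty_y: float, loadings: bool = True) -> SCCAMode:
    """Fit the leading sparse canonical mode of two standardized blocks.

    ``loadings=False`` skips the cross-loading computation (used by
    resampling loops that only consume r).
    """
    Xa, Ya = _as_matrix(X, "X"), _as_matrix(Y, "Y")
    if Xa.shape[0] != Ya.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    cx = _check_penalty(penalty_x, Xa.shape[1], "penalty_x")
    cy = _check_penalty(penalty_y, Ya.shape[1], "penalty_y")
    Z = Xa.T @ Ya
    u, v, it, conv, obj = _fit_mode_on_cross(Z, cx, cy)
    return _populate_mode(Xa, Ya, u, v, it, conv, obj, loadings=loadings)


def fit_modes(X, Y, penalty_x: float, penalty_y: float, n_modes: int = 1) -> SCCAModel:
    """Fit successive modes by Hotelling deflation of the cross-covariance.

    After each mode, Z ← Z − (uᵀZv)·u·vᵀ removes the found rank-one
    structure; variates and correlations are always evaluated against
    the original data.
    """
    Xa, Ya = _as_matrix(X, "X"), _as_matrix(Y, "Y")
    p, q = Xa.shape[1], Ya.shape[1]
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    if n_modes > min(p, q):
        raise ValueError(f"n_modes={n_modes} exceeds min(p, q)={min(p, q)}")
    cx = _check_penalty(penalty_x, p, "penalty_x")
    cy = _check_penalty(penalty_y, q, "penalty_y")
    Z = Xa.T @ Ya
    modes: list[SCCAMode] = []
    for _ in range(n_modes):
        u, v, it, conv, obj = _fit_mode_on_cross(Z, cx, cy)
        modes.append(_populate_mode(Xa, Ya, u, v, it, conv, obj))
        d = float(u @ Z @ v)
        Z = Z - d * np.outer(u, v)
    return SCCAModel(modes=modes, penalty_x=penalty_x, penalty_y=penalty_y)


def _corr_with_vector(M: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column of M with y (vectorized)."""
    Mc = M - M.mean(axis=0)
    yc = y - y.mean()
    denom = np.linalg.norm(Mc, axis=0) * np.linalg.norm(yc)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, Mc.T @ yc / np.where(denom > 0, denom, 1.0), 0.0)
    return out


def _cross_loadings_arrays(
    X: np.ndarray, Y: np.ndarray, variate_x: np.ndarray, variate_y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    if variate_x.std() == 0 or variate_y.std() == 0:
        raise ValueError("zero-variance canonical variate; cross-loadings undefined")
    return _corr_with_vector(X, variate_y), _corr_with_vector(Y, variate_x)


def cross_loadings(mode: SCCAMode, X, Y) -> tuple[np.ndarray, np.ndarray]:
    """Correlation of each original variable with the opposite block's variate."""
    Xa, Ya = _as_matrix(X, "X"), _as_matrix(Y, "Y")
    return _cross_loadings_arrays(Xa, Ya, mode.variate_x, mode.variate_y)


def covariance_explained(r: float) -> float:
    """Proportion of cross-block covariance a mode accounts for: r².

    Reporting rounds 100·r² to the nearest integer percent.
    """
    if abs(r) > 1:
        raise ValueError("|r| must not exceed 1")
    return float(r) ** 2


def filter_by_effect(loadings: np.ndarray, threshold: float = 0.1) -> np.ndarray:
    """Indices of loadings of at least small effect: strictly |loading| > threshold."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    loadings = np.asarray(loadings, dtype=float)
    return np.flatnonzero(np.abs(loadings) > threshold)
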