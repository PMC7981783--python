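"""Data conditioning for the two-block analysis.

Stage order contract: impute -> multivariate outlier filter ->
empirical-Bayes site harmonization -> (change scores, if longitudinal)
-> standardization.  Each stage's output satisfies the next stage's
preconditions; every function is pure (returns new tables).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PreprocessConfig",
    "ChangeScoreTable",
    "impute_missing",
    "mahalanobis_filter",
    "empirical_bayes_harmonize",
    "standardize",
    "compute_change_scores",
    "regress_out_covariates",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunables of the conditioning stages.

    ``mahalanobis_quantile`` is the chi-square quantile (df = number of
    imaging features) above which a subject's squared Mahalanobis
    distance marks it an outlier.  ``impute_tol`` is the relative change
    in imputed values below which the iterative imputation stops.
    """

    mahalanobis_quantile: float = 0.999
    impute_max_iter: int = 10
    impute_tol: float = 1e-3
    rf_n_estimators: int = 100
    harmonize: bool = True
    standardize: bool = True
    covariates_to_remove: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 < self.mahalanobis_quantile < 1.0:
            raise ValueError("mahalanobis_quantile must lie strictly in (0, 1)")


# ---------------------------------------------------------------------------
# Iterative random-forest imputation (missForest-style)

def impute_missing(
    block: pd.DataFrame,
    config: PreprocessConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Impute missing cells by iterated random-forest regression.

    Missing cells are initialized with column means, then columns are
    revisited (most complete first), fitting a random forest of that
    column on all others over the originally observed rows and
    predicting the missing rows.  Iteration stops when the relative
    change of the imputed values falls below ``impute_tol``, when it
    stops decreasing, or at ``impute_max_iter``.  Deterministic given
    the seed.
    """
    from sklearn.ensemble import RandomForestRegressor

    config = config or PreprocessConfig()
    if block.isna().all(axis=0).any():
        bad = block.columns[block.isna().all(axis=0)].tolist()
        raise ValueError(f"columns entirely missing, cannot impute: {bad}")
    if not block.isna().any().any():
        return block.copy()

    out = block.astype(float).copy()
    na = block.isna()
    out = out.fillna(out.mean())
    cols = na.sum().sort_values(kind="stable").index  # most complete first
    cols = [c for c in cols if na[c].any()]

    prev_change = np.inf
    for it in range(config.impute_max_iter):
        previous = out.copy()
        for j, col in enumerate(cols):
            obs = ~na[col]
            others = out.drop(columns=[col])
            rf = RandomForestRegressor(
                n_estimators=config.rf_n_estimators,
                random_state=(seed * 1009 + j) % (2**31 - 1),
                n_jobs=1,
            )
            rf.fit(others.loc[obs], out.loc[obs, col])
            out.loc[na[col], col] = rf.predict(others.loc[na[col]])
        num = float(((out - previous).to_numpy() ** 2).sum())
        den = float((out.to_numpy() ** 2).sum())
        change = num / den if den > 0 else 0.0
        if change < config.impute_tol or change > prev_change:
            break
        prev_change = change
    return out


# ---------------------------------------------------------------------------
# Multivariate outlier exclusion

def mahalanobis_filter(
    block: pd.DataFrame,
    quantile: float = 0.999,
    shrinkage: bool = False,
    robust: bool = False,
) -> tuple[pd.Index, pd.Index, pd.Series]:
    """Flag rows whose squared Mahalanobis distance exceeds a chi-square quantile.

    Distances are computed from the column means under the sample
    covariance (classical by default; Ledoit-Wolf shrinkage or minimum
    covariance determinant on request).  The cut-off is the chi-square
    quantile with df equal to the number of features.

    Returns (kept ids, excluded ids, squared distances).
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie strictly in (0, 1)")
    X = block.to_numpy(dtype=float)
    n, p = X.shape
    if robust:
        from sklearn.covariance import MinCovDet

        est = MinCovDet(random_state=0).fit(X)
        center, cov = est.location_, est.covariance_
    elif shrinkage:
        from sklearn.covariance import LedoitWolf

        est = LedoitWolf().fit(X)
        center, cov = est.location_, est.covariance_
    else:
        center = X.mean(axis=0)
        cov = np.cov(X, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "sample covariance is singular; rerun with shrinkage=True "
            "(Ledoit-Wolf) or reduce the feature count"
        ) from exc
    centred = X - center
    d2 = np.einsum("ij,jk,ik->i", centred, cov_inv, centred)
    d2 = pd.Series(d2, index=block.index, name="mahalanobis_sq")
    cutoff = stats.chi2.ppf(quantile, df=p)
    excluded = block.index[d2 > cutoff]
    kept = block.index[d2 <= cutoff]
    return kept, excluded, d2


# ---------------------------------------------------------------------------
# Empirical-Bayes site harmonization (parametric ComBat)

def _combat_priors(gamma_hat: np.ndarray, delta_hat: np.ndarray):
    gamma_bar = gamma_hat.mean()
    t2 = gamma_hat.var(ddof=1)
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    a_prior = (2 * s2 + m**2) / s2
    b_prior = (m * s2 + m**3) / s2
    return gamma_bar, t2, a_prior, b_prior


def _combat_it_sol(
    z: np.ndarray,
    gamma_hat: np.ndarray,
    delta_hat: np.ndarray,
    gamma_bar: float,
    t2: float,
    a: float,
    b: float,
    conv: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative solution of the EB posterior means (per site)."""
    n = np.sum(~np.isnan(z), axis=0)
    gamma, delta = gamma_hat.copy(), delta_hat.copy()
    change = 1.0
    while change > conv:
        gamma_new = (n * t2 * gamma_hat + delta * gamma_bar) / (n * t2 + delta)
        ssq = np.nansum((z - gamma_new) ** 2, axis=0)
        delta_new = (0.5 * ssq + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.max(np.abs(gamma_new - gamma) / (np.abs(gamma) + 1e-12)).item(),
            np.max(np.abs(delta_new - delta) / delta).item(),
        )
        gamma, delta = gamma_new, delta_new
    return gamma, delta


def empirical_bayes_harmonize(
    block: pd.DataFrame,
    sites: pd.Series,
    preserve: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Remove additive and multiplicative site effects, feature by feature.

    Location-scale batch model with parametric empirical-Bayes shrinkage
    of per-site shift and scale estimates toward pooled priors
    (ComBat).  Covariates passed via ``preserve`` are protected: their
    fitted effects are removed before estimating site parameters and
    restored afterwards.  With a single site the operation is the
    identity; constant features pass through unchanged with a warning.
    """
    sites = sites.loc[block.index]
    levels = sites.unique()
    if len(levels) < 2:
        return block.copy()
    counts = sites.value_counts()
    if (counts < 2).any():
        singletons = counts.index[counts < 2].tolist()
        raise ValueError(f"each site needs >= 2 subjects; singleton sites: {singletons}")

    X = block.to_numpy(dtype=float)  # n x p
    n, p = X.shape
    col_sd = X.std(axis=0, ddof=1)
    constant = col_sd == 0
    if constant.any():
        warnings.warn(
            f"constant features passed through unharmonized: "
            f"{block.columns[constant].tolist()}"
        )

    batch = pd.get_dummies(sites).to_numpy(dtype=float)  # n x B
    n_batches = batch.shape[1]
    batch_sizes = batch.sum(axis=0)

    design = batch
    if preserve is not None:
        C = preserve.loc[block.index].to_numpy(dtype=float)
        C = C - C.mean(axis=0)  # center so batch means absorb the intercept
        design = np.hstack([batch, C])

    work = X[:, ~constant]
    beta, *_ = np.linalg.lstsq(design, work, rcond=None)
    grand_mean = (batch_sizes / n) @ beta[:n_batches]  # weighted batch means
    stand_mean = np.tile(grand_mean, (n, 1))
    cov_effect = design[:, n_batches:] @ beta[n_batches:] if design.shape[1] > n_batches else 0.0

    resid = work - batch @ beta[:n_batches] - cov_effect
    var_pooled = (resid**2).mean(axis=0)
    sd_pooled = np.sqrt(var_pooled)
    Z = (work - stand_mean - cov_effect) / sd_pooled

    adjusted = np.empty_like(Z)
    for b_idx in range(n_batches):
        members = batch[:, b_idx] == 1
        zb = Z[members]
        gamma_hat = zb.mean(axis=0)
        delta_hat = zb.var(axis=0, ddof=1)
        gamma_bar, t2, a_prior, b_prior = _combat_priors(gamma_hat, delta_hat)
        gamma_star, delta_star = _combat_it_sol(
            zb, gamma_hat, delta_hat, gamma_bar, t2, a_prior, b_prior
        )
        adjusted[members] = (zb - gamma_star) / np.sqrt(delta_star)

    out_work = adjusted * sd_pooled + stand_mean + cov_effect
    out = X.copy()
    out[:, ~constant] = out_work
    return pd.DataFrame(out, index=block.index, columns=block.columns)


# ---------------------------------------------------------------------------
# Standardization, change scores, covariate removal

def standardize(block: pd.DataFrame) -> pd.DataFrame:
    """Z-score each column to mean 0, SD 1 (denominator n-1)."""
    if block.isna().any().any():
        raise ValueError("block contains missing entries; impute first")
    sd = block.std(ddof=1)
    zero = sd[sd == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-variance columns cannot be standardized: {zero}")
    return (block - block.mean()) / sd


@dataclass
class ChangeScoreTable:
    """Residualized change scores plus the per-variable fit coefficients."""

    residuals: pd.DataFrame
    coefficients: pd.DataFrame = field(repr=False)  # columns: intercept, slope


def compute_change_scores(baseline: pd.DataFrame, followup: pd.DataFrame) -> ChangeScoreTable:
    """Follow-up minus baseline, residualized on baseline per variable.

    Simple OLS with intercept per variable removes the
    regression-to-the-mean coupling of raw change with baseline; the
    residuals are exactly uncorrelated with baseline.
    """
    if not baseline.index.equals(followup.index):
        missing = baseline.index.symmetric_difference(followup.index).tolist()
        raise ValueError(f"subject sets differ between timepoints: {missing[:10]}")
    if list(baseline.columns) != list(followup.columns):
        raise ValueError("variable sets differ between timepoints")
    delta = followup - baseline
    resid = {}
    coefs = {}
    for col in baseline.columns:
        x = baseline[col].to_numpy(dtype=float)
        d = delta[col].to_numpy(dtype=float)
        A = np.column_stack([np.ones_like(x), x])
        (b0, b1), *_ = np.linalg.lstsq(A, d, rcond=None)
        resid[col] = d - (b0 + b1 * x)
        coefs[col] = (b0, b1)
    residuals = pd.DataFrame(resid, index=baseline.index)
    coefficients = pd.DataFrame(coefs, index=["intercept", "slope"]).T
    return ChangeScoreTable(residuals=residuals, coefficients=coefficients)


def regress_out_covariates(block: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Replace each column by its OLS residual on the covariates (with intercept)."""
    C = covariates.loc[block.index].to_numpy(dtype=float)
    design = np.column_stack([np.ones(len(block)), C])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    X = block.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(design, X, rcond=None)
    return pd.DataFrame(X - design @ beta, index=block.index, columns=block.columns)
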