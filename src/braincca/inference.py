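"""Sparsity tuning, permutation significance, and FDR adjustment.

Tuning follows the reported procedure: a 10-point ladder of penalty
candidates per block, linearly spaced from 1/√dim to 1, all 100
combinations fitted, and the pair maximizing the first-mode canonical
correlation selected.  Significance of the tuned model comes from an
exact permutation P value: the rows of Y are permuted (breaking the
subject link while preserving each block's internal structure), the
first mode is refitted with the tuned penalties held fixed, and P is
the fraction of permutations with r at least as large as observed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .scca import fit_first_mode

__all__ = [
    "SparsityGrid",
    "PermutationResult",
    "TuningResult",
    "build_grid",
    "tune_sparsity",
    "permutation_test",
    "fdr_adjust",
]


@dataclass(frozen=True)
class SparsityGrid:
    """Ten penalty candidates per block on [1/√dim, 1], endpoints inclusive."""

    candidates_x: tuple[float, ...]
    candidates_y: tuple[float, ...]

    def __post_init__(self) -> None:
        for cand in (self.candidates_x, self.candidates_y):
            if len(cand) != 10:
                raise ValueError("each block needs exactly 10 candidates")
            if any(b < a for a, b in zip(cand, cand[1:])):
                raise ValueError("candidates must be non-decreasing")


def build_grid(p: int, q: int) -> SparsityGrid:
    """Linearly spaced candidates from 1/√dim to 1, 10 values per block."""
    if p < 2 or q < 2:
        raise ValueError("p and q must be >= 2")
    gx = np.linspace(1.0 / np.sqrt(p), 1.0, 10)
    gy = np.linspace(1.0 / np.sqrt(q), 1.0, 10)
    return SparsityGrid(candidates_x=tuple(gx), candidates_y=tuple(gy))


@dataclass
class TuningResult:
    penalty_x: float
    penalty_y: float
    table: pd.DataFrame  # columns: penalty_x, penalty_y, r, converged


def tune_sparsity(X, Y, grid: SparsityGrid) -> TuningResult:
    """Fit every penalty combination; keep the pair maximizing first-mode r.

    Exact ties resolve to the lexicographically smallest
    (penalty_x, penalty_y) — the sparser model.  Non-converged cells are
    recorded in the table; if every cell fails an error is raised.
    """
    rows = []
    best_r = -np.inf
    best: tuple[float, float] | None = None
    for px in grid.candidates_x:  # lexicographic order => strict '>' keeps sparser ties
        for py in grid.candidates_y:
            mode = fit_first_mode(X, Y, px, py, loadings=False)
            rows.append(
                {"penalty_x": px, "penalty_y": py, "r": mode.r, "converged": mode.converged}
            )
            if mode.r > best_r:
                best_r = mode.r
                best = (px, py)
    table = pd.DataFrame(rows)
    if best is None or not np.isfinite(best_r):
        raise RuntimeError("all tuning cells failed to produce a fit")
    return TuningResult(penalty_x=best[0], penalty_y=best[1], table=table)


@dataclass
class PermutationResult:
    observed_r: float
    permuted_r: np.ndarray
    exact_p: float
    mean_permuted: float
    sd_permuted: float
    n_perm: int


def permutation_test(
    X,
    Y,
    penalty_x: float,
    penalty_y: float,
    n_perm: int = 1000,
    seed: int = 0,
    conservative: bool = False,
) -> PermutationResult:
    """Exact permutation P for the first canonical mode.

    Rows of Y are permuted uniformly at random (X fixed) and the first
    mode refitted with the tuned penalties each time.  The exact P is
    the count of permuted r values >= the observed r divided by
    ``n_perm`` — it may be exactly 0.  ``conservative`` switches to
    (count + 1)/(n_perm + 1) for users needing strictly positive P.
    """
    Xa = np.asarray(getattr(X, "to_numpy", lambda: X)(), dtype=float)
    Ya = np.asarray(getattr(Y, "to_numpy", lambda: Y)(), dtype=float)
    if Xa.shape[0] < 3:
        raise ValueError("permutation test needs at least 3 subjects")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = fit_first_mode(Xa, Ya, penalty_x, penalty_y, loadings=False).r
    rng = np.random.default_rng(seed)
    permuted = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(Xa.shape[0])
        permuted[b] = fit_first_mode(Xa, Ya[perm], penalty_x, penalty_y, loadings=False).r
    count = int((permuted >= observed).sum())
    exact_p = (count + 1) / (n_perm + 1) if conservative else count / n_perm
    return PermutationResult(
        observed_r=observed,
        permuted_r=permuted,
        exact_p=float(exact_p),
        mean_permuted=float(permuted.mean()),
        sd_permuted=float(permuted.std(ddof=1)) if n_perm > 1 else 0.0,
        n_perm=n_perm,
    )


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
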