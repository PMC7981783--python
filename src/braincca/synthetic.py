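"""Synthetic two-block cohorts with known sparse canonical structure.

The generator emulates the structure of a multi-site adolescent imaging
cohort: an imaging block of continuous morphometric features (regional
thickness/area/volume plus global measures), a non-imaging block of mixed
demographic/behavioural features, site labels with additive and
multiplicative batch effects on the imaging block, missing-at-random
entries in the non-imaging block, and an optional follow-up timepoint in
which thickness-like features systematically decrease.

The two blocks share latent canonical modes (an inter-battery factor
model): for mode k a standard-normal latent score z_k is drawn per
subject and projected onto sparse unit weight vectors u_k (imaging) and
v_k (non-imaging).  With signal amplitude a_k and independent Gaussian
feature noise of standard deviation sigma, the population correlation of
the true variates X·u_k and Y·v_k is

    r_k = a_k^2 / (a_k^2 + sigma^2),

because ‖u_k‖₂ = 1 makes the noise projected onto u_k again N(0, sigma²).
Inverting gives the amplitude used here: a_k = sigma·sqrt(r_k/(1−r_k)).

Nonzero true weights have equal magnitude 1/sqrt(support) with random
signs — the standard design in sparse-recovery simulations — so the
L1/L2 ratio of each true vector is exactly sqrt(support).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InvalidSpecError",
    "SyntheticSpec",
    "GroundTruth",
    "TwoBlockDataset",
    "generate_linked_blocks",
    "inject_site_effects",
    "inject_missingness",
    "generate_longitudinal_pair",
    "weight_recovery_score",
    "write_dataset",
    "read_dataset",
]


class InvalidSpecError(ValueError):
    """Raised when a SyntheticSpec violates its invariants."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic cohort.

    ``support_x``/``support_y`` give, per mode, how many true weights are
    nonzero; ``target_r`` the population canonical correlation of each
    mode (strictly decreasing across modes so ordering is identifiable).
    ``site_scale_range`` is the (lo, hi) interval of multiplicative site
    scales; ``site_shift_sd`` the SD of additive site offsets.
    ``thinning_mean``/``thinning_sd`` describe the per-subject decrement
    applied to thickness-like (here: all imaging) columns at follow-up,
    in the units of the imaging features.
    """

    n_subjects: int = 600
    p_imaging: int = 40
    q_nonimaging: int = 30
    n_modes: int = 1
    support_x: tuple[int, ...] = (5,)
    support_y: tuple[int, ...] = (5,)
    target_r: tuple[float, ...] = (0.7,)
    noise_sd: float = 1.0
    n_sites: int = 4
    site_shift_sd: float = 0.4
    site_scale_range: tuple[float, float] = (0.8, 1.25)
    missing_rate: float = 0.0
    longitudinal: bool = False
    thinning_mean: float = -0.12
    thinning_sd: float = 0.06
    q_binary: int = 0
    q_ordinal: int = 0
    ordinal_levels: int = 7
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_subjects, self.p_imaging, self.q_nonimaging) < 1:
            raise InvalidSpecError("n_subjects, p_imaging, q_nonimaging must be positive")
        if self.n_modes < 0:
            raise InvalidSpecError("n_modes must be non-negative")
        if self.n_modes > min(self.p_imaging, self.q_nonimaging):
            raise InvalidSpecError(
                f"n_modes={self.n_modes} exceeds min(p, q)="
                f"{min(self.p_imaging, self.q_nonimaging)}"
            )
        for name, sup, dim in (
            ("support_x", self.support_x, self.p_imaging),
            ("support_y", self.support_y, self.q_nonimaging),
        ):
            if len(sup) < self.n_modes:
                raise InvalidSpecError(f"{name} must give one count per mode")
            if any(s < 1 or s > dim for s in sup[: self.n_modes]):
                raise InvalidSpecError(f"{name} entries must lie in [1, {dim}]")
        if len(self.target_r) < self.n_modes:
            raise InvalidSpecError("target_r must give one value per mode")
        rs = self.target_r[: self.n_modes]
        if any(not 0.0 <= r <= 1.0 for r in rs):
            raise InvalidSpecError("target_r values must lie in [0, 1]")
        if any(rs[i] <= rs[i + 1] for i in range(len(rs) - 1)):
            raise InvalidSpecError("target_r must be strictly decreasing across modes")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be non-negative")
        if self.noise_sd > 0 and any(r >= 1.0 for r in rs):
            raise InvalidSpecError("target_r = 1 requires noise_sd = 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise InvalidSpecError("missing_rate must lie in [0, 1)")
        if self.n_sites < 1:
            raise InvalidSpecError("n_sites must be positive")
        lo, hi = self.site_scale_range
        if lo <= 0 or hi < lo:
            raise InvalidSpecError("site_scale_range must satisfy 0 < lo <= hi")
        if self.q_binary + self.q_ordinal > self.q_nonimaging:
            raise InvalidSpecError("q_binary + q_ordinal exceeds q_nonimaging")


@dataclass
class TwoBlockDataset:
    """Subject-aligned imaging and non-imaging blocks.

    Both blocks are DataFrames indexed by ``subject_id``; ``sites`` is a
    Series of site labels on the same index, ``quality`` an optional
    per-subject scan-quality scalar.
    """

    imaging: pd.DataFrame
    nonimaging: pd.DataFrame
    sites: pd.Series
    quality: pd.Series | None = None
    missing_mask: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.imaging.index.equals(self.nonimaging.index):
            raise ValueError("imaging and nonimaging blocks must share subject index")
        if not self.imaging.index.equals(self.sites.index):
            raise ValueError("sites must share the subject index")

    @property
    def subject_ids(self) -> pd.Index:
        return self.imaging.index

    def copy(self) -> "TwoBlockDataset":
        return TwoBlockDataset(
            imaging=self.imaging.copy(),
            nonimaging=self.nonimaging.copy(),
            sites=self.sites.copy(),
            quality=None if self.quality is None else self.quality.copy(),
            missing_mask=None if self.missing_mask is None else self.missing_mask.copy(),
        )


@dataclass
class GroundTruth:
    """True generative parameters recorded alongside a synthetic cohort."""

    true_weights_x: np.ndarray  # (n_modes, p), unit rows
    true_weights_y: np.ndarray  # (n_modes, q), unit rows
    true_r: np.ndarray  # (n_modes,)
    site_shift: pd.DataFrame | None = None  # site x imaging feature
    site_scale: pd.DataFrame | None = None
    missing_mask: pd.DataFrame | None = None
    latent: np.ndarray | None = None  # (n, n_modes) latent scores
    spec: SyntheticSpec | None = None


def _sparse_unit_weights(rng: np.random.Generator, dim: int, supports: Sequence[int]) -> np.ndarray:
    """Per-mode sparse unit vectors with equal-magnitude ±1/sqrt(s) entries.

    Supports are drawn disjointly across modes when the feature budget
    allows, so planted modes are exactly orthogonal in weight space.
    """
    k = len(supports)
    W = np.zeros((k, dim))
    disjoint = sum(supports) <= dim
    available = list(rng.permutation(dim))
    for m, s in enumerate(supports):
        if disjoint:
            idx = np.array([available.pop() for _ in range(s)])
        else:
            idx = rng.choice(dim, size=s, replace=False)
        W[m, idx] = rng.choice([-1.0, 1.0], size=s) / np.sqrt(s)
    return W


def _signal_amplitudes(spec: SyntheticSpec) -> np.ndarray:
    rs = np.asarray(spec.target_r[: spec.n_modes], dtype=float)
    if spec.noise_sd == 0:
        return np.ones_like(rs)
    return spec.noise_sd * np.sqrt(rs / (1.0 - rs))


def _discretize_nonimaging(Y: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Threshold trailing latent-Gaussian columns into binary/ordinal codes.

    Mirrors cohorts where most non-imaging variables are ordinal
    questionnaire codes or binary indicators; the pipeline treats them as
    numeric before standardization.
    """
    Y = Y.copy()
    q = Y.shape[1]
    ord_cols = range(q - spec.q_ordinal - spec.q_binary, q - spec.q_binary)
    bin_cols = range(q - spec.q_binary, q)
    for j in ord_cols:
        col = Y[:, j]
        # equal-probability bins of the column's own distribution
        edges = np.quantile(col, np.linspace(0, 1, spec.ordinal_levels + 1)[1:-1])
        Y[:, j] = np.digitize(col, edges).astype(float)
    for j in bin_cols:
        Y[:, j] = (Y[:, j] > np.median(Y[:, j])).astype(float)
    return Y


def generate_linked_blocks(spec: SyntheticSpec) -> tuple[TwoBlockDataset, GroundTruth]:
    """Generate subject-aligned blocks sharing latent sparse canonical modes.

    Deterministic: the same spec (including seed) yields bit-identical
    output.  Site effects are *not* applied here; see
    :func:`inject_site_effects`.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, p, q, k = spec.n_subjects, spec.p_imaging, spec.q_nonimaging, spec.n_modes

    Wx = _sparse_unit_weights(rng, p, spec.support_x[:k])
    Wy = _sparse_unit_weights(rng, q, spec.support_y[:k])
    amps = _signal_amplitudes(spec)
    Z = rng.standard_normal((n, k))

    X = rng.standard_normal((n, p)) * spec.noise_sd
    Y = rng.standard_normal((n, q)) * spec.noise_sd
    if k:
        X += (Z * amps) @ Wx
        Y += (Z * amps) @ Wy
    if spec.q_binary or spec.q_ordinal:
        Y = _discretize_nonimaging(Y, spec, rng)

    ids = pd.Index([f"sub-{i:05d}" for i in range(n)], name="subject_id")
    sites = pd.Series(
        [f"site{(i % spec.n_sites) + 1}" for i in rng.permutation(n)], index=ids, name="site"
    )
    quality = pd.Series(rng.beta(8.0, 2.0, size=n), index=ids, name="quality")

    imaging = pd.DataFrame(X, index=ids, columns=[f"roi_{j:03d}" for j in range(p)])
    nonimaging = pd.DataFrame(Y, index=ids, columns=[f"var_{j:03d}" for j in range(q)])

    data = TwoBlockDataset(imaging=imaging, nonimaging=nonimaging, sites=sites, quality=quality)

    shift = pd.DataFrame(
        rng.normal(0.0, spec.site_shift_sd, size=(spec.n_sites, p)),
        index=[f"site{s + 1}" for s in range(spec.n_sites)],
        columns=imaging.columns,
    )
    lo, hi = spec.site_scale_range
    scale = pd.DataFrame(
        rng.uniform(lo, hi, size=(spec.n_sites, p)),
        index=shift.index,
        columns=imaging.columns,
    )
    truth = GroundTruth(
        true_weights_x=Wx,
        true_weights_y=Wy,
        true_r=np.asarray(spec.target_r[:k], dtype=float),
        site_shift=shift,
        site_scale=scale,
        latent=Z,
        spec=spec,
    )
    return data, truth


def inject_site_effects(data: TwoBlockDataset, truth: GroundTruth) -> TwoBlockDataset:
    """Apply the recorded per-site location/scale effects to the imaging block.

    Each imaging cell becomes ``x*scale[site, feature] + shift[site, feature]``.
    Only the imaging block is perturbed (only imaging is harmonized
    downstream).
    """
    if truth.site_shift is None or truth.site_scale is None:
        raise ValueError("ground truth carries no site-effect parameters")
    out = data.copy()
    known = set(truth.site_shift.index)
    unknown = sorted(set(data.sites.unique()) - known)
    if unknown:
        raise ValueError(f"unknown site labels: {unknown}")
    shift = truth.site_shift.loc[data.sites].to_numpy()
    scale = truth.site_scale.loc[data.sites].to_numpy()
    out.imaging = data.imaging * scale + shift
    return out


def inject_missingness(data: TwoBlockDataset, rate: float, seed: int) -> TwoBlockDataset:
    """Set non-imaging entries missing completely at random at ``rate``.

    The imaging block is never touched.  The Boolean mask is recorded on
    the returned dataset (``missing_mask``).
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("missing rate must lie in [0, 1)")
    out = data.copy()
    rng = np.random.default_rng(seed)
    mask = rng.random(out.nonimaging.shape) < rate
    mask_df = pd.DataFrame(mask, index=out.nonimaging.index, columns=out.nonimaging.columns)
    nonimaging = out.nonimaging.astype(float)
    nonimaging[mask_df] = np.nan
    out.nonimaging = nonimaging
    out.missing_mask = mask_df
    return out


def generate_longitudinal_pair(
    spec: SyntheticSpec,
) -> tuple[TwoBlockDataset, TwoBlockDataset, GroundTruth]:
    """Baseline plus follow-up cohort with systematic thinning.

    The follow-up imaging block equals baseline plus a per-subject
    decrement drawn N(thinning_mean, thinning_sd) applied to every
    thickness-like (imaging) column, plus a fresh draw of the linked-mode
    signal and feature noise so that change scores carry their own
    canonical structure with the same true weights.
    """
    if not spec.longitudinal:
        raise InvalidSpecError("spec.longitudinal must be set")
    base, truth = generate_linked_blocks(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    n, k = spec.n_subjects, spec.n_modes

    decrement = rng.normal(spec.thinning_mean, spec.thinning_sd, size=n)
    dX = np.tile(decrement[:, None], (1, spec.p_imaging)).astype(float)
    dY = np.zeros((n, spec.q_nonimaging))
    dX += rng.standard_normal(dX.shape) * spec.noise_sd
    dY += rng.standard_normal(dY.shape) * spec.noise_sd
    if k:
        amps = _signal_amplitudes(spec)
        Z2 = rng.standard_normal((n, k))
        dX += (Z2 * amps) @ truth.true_weights_x
        dY += (Z2 * amps) @ truth.true_weights_y

    follow = base.copy()
    follow.imaging = base.imaging + dX
    follow.nonimaging = base.nonimaging + dY
    return base, follow, truth


def weight_recovery_score(estimated: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """Sign-invariant cosine and support-F1 between a fitted and true weight vector."""
    est = np.asarray(estimated, dtype=float).ravel()
    tru = np.asarray(truth, dtype=float).ravel()
    if est.shape != tru.shape:
        raise ValueError("weight vectors must have equal length")
    ne, nt = np.linalg.norm(est), np.linalg.norm(tru)
    if ne == 0 or nt == 0:
        raise ValueError("weight vectors must be nonzero")
    cosine = float(abs(est @ tru) / (ne * nt))
    e, t = est != 0, tru != 0
    tp = int((e & t).sum())
    if e.sum() == 0 or tp == 0:
        return cosine, 0.0
    precision = tp / e.sum()
    recall = tp / t.sum()
    return cosine, float(2 * precision * recall / (precision + recall))


# ---------------------------------------------------------------------------
# Standard on-disk layout: TSVs with a header and leading subject_id column,
# plus truth.json for the generative parameters.

def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=True, na_rep="NA")


def write_dataset(
    data: TwoBlockDataset,
    outdir: str | Path,
    truth: GroundTruth | None = None,
    followup: TwoBlockDataset | None = None,
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_tsv(data.imaging, outdir / "imaging.tsv")
    _write_tsv(data.nonimaging, outdir / "nonimaging.tsv")
    site_tbl = data.sites.to_frame()
    if data.quality is not None:
        site_tbl = site_tbl.join(data.quality)
    _write_tsv(site_tbl, outdir / "sites.tsv")
    if followup is not None:
        _write_tsv(followup.imaging, outdir / "imaging_followup.tsv")
        _write_tsv(followup.nonimaging, outdir / "nonimaging_followup.tsv")
    if truth is not None:
        payload = {
            "true_weights_x": truth.true_weights_x.tolist(),
            "true_weights_y": truth.true_weights_y.tolist(),
            "true_r": truth.true_r.tolist(),
            "seed": None if truth.spec is None else truth.spec.seed,
            "supports_x": None if truth.spec is None else list(truth.spec.support_x),
            "supports_y": None if truth.spec is None else list(truth.spec.support_y),
        }
        (outdir / "truth.json").write_text(json.dumps(payload, indent=1))


def read_dataset(indir: str | Path) -> TwoBlockDataset:
    indir = Path(indir)
    imaging = pd.read_csv(indir / "imaging.tsv", sep="\t", index_col="subject_id", na_values=["NA"])
    nonimaging = pd.read_csv(
        indir / "nonimaging.tsv", sep="\t", index_col="subject_id", na_values=["NA"]
    )
    site_tbl = pd.read_csv(indir / "sites.tsv", sep="\t", index_col="subject_id")
    quality = site_tbl["quality"] if "quality" in site_tbl else None
    return TwoBlockDataset(
        imaging=imaging,
        nonimaging=nonimaging,
        sites=site_tbl["site"],
        quality=quality,
    )
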