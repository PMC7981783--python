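"""End-to-end orchestration: I/O, configuration, the full analysis, reports.

The pipeline mirrors the stated analysis order: impute the non-imaging
block, exclude multivariate outliers on the imaging block, harmonize
imaging features across sites, compute residualized change scores when
analysing a longitudinal pair, standardize both blocks, tune the
sparsity grid, fit the first mode, assess significance by permutation
with FDR adjustment, and run the robustness battery.  ``report.json``
is the machine-readable source of truth; the TSVs are views of it.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import preprocess as pp
from .inference import build_grid, fdr_adjust, permutation_test, tune_sparsity
from .robustness import run_robustness
from .scca import fit_first_mode
from .synthetic import TwoBlockDataset

__all__ = [
    "RunConfig",
    "RunReport",
    "read_block_table",
    "run_pipeline",
    "write_report",
    "REPORT_SCHEMA",
]

logger = logging.getLogger("braincca")

# Minimal structural schema for report.json: required keys and their types.
REPORT_SCHEMA: dict[str, type] = {
    "observed_r": float,
    "exact_p": float,
    "fdr_p": float,
    "covariance_explained_percent": int,
    "penalty_x": float,
    "penalty_y": float,
    "mean_permuted_r": float,
    "sd_permuted_r": float,
    "rr_median": float,
    "test_train_ratio": float,
    "pass_fdr": bool,
    "pass_rr": bool,
    "pass_split": bool,
    "reported": bool,
    "seed": int,
    "n_subjects": int,
    "analysis": str,
}


@dataclass
class RunConfig:
    """Everything one analysis run needs; every tunable default matches
    the reference analysis (1000 permutations, 10-point grid, 0.999
    Mahalanobis quantile, 500 resamples/splits, 0.1 effect threshold,
    FDR gate 0.001)."""

    imaging: str | Path | None = None
    nonimaging: str | Path | None = None
    sites: str | Path | None = None
    imaging_followup: str | Path | None = None
    nonimaging_followup: str | Path | None = None
    analysis: str = "baseline"  # baseline | change
    penalty_x: float | None = None  # None => auto-tune on the grid
    penalty_y: float | None = None
    n_perm: int = 1000
    n_resample: int = 500
    n_splits: int = 500
    stability_reps: int = 100
    mahalanobis_quantile: float = 0.999
    fdr_alpha: float = 0.001
    effect_threshold: float = 0.1
    harmonize: bool = True
    seed: int = 0
    outdir: str | Path | None = None
    extra_p_values: tuple[float, ...] = ()  # other models in the FDR family

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_alpha < 1.0:
            raise ValueError("fdr_alpha must lie in (0, 1)")
        if self.effect_threshold < 0:
            raise ValueError("effect_threshold must be non-negative")
        if self.analysis not in ("baseline", "change"):
            raise ValueError("analysis must be 'baseline' or 'change'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)


@dataclass
class RunReport:
    observed_r: float
    exact_p: float
    fdr_p: float
    covariance_explained_percent: int
    penalty_x: float
    penalty_y: float
    mean_permuted_r: float
    sd_permuted_r: float
    rr_median: float
    test_train_ratio: float
    quality_rho: float
    pass_fdr: bool
    pass_rr: bool
    pass_split: bool
    reported: bool
    seed: int
    n_subjects: int
    analysis: str
    excluded_subjects: list[str] = field(default_factory=list)
    weights: pd.DataFrame | None = field(default=None, repr=False)
    cross_loadings_table: pd.DataFrame | None = field(default=None, repr=False)
    permuted_r: np.ndarray | None = field(default=None, repr=False)
    tuning_table: pd.DataFrame | None = field(default=None, repr=False)

    def to_json_dict(self) -> dict:
        return {
            k: (v if not isinstance(v, (np.floating, np.integer, np.bool_)) else v.item())
            for k, v in asdict(self).items()
            if k in REPORT_SCHEMA or k in ("quality_rho", "excluded_subjects")
        }


def validate_report_dict(payload: dict) -> None:
    """Check report.json against the shipped structural schema."""
    for key, typ in REPORT_SCHEMA.items():
        if key not in payload:
            raise ValueError(f"report missing required key: {key}")
        value = payload[key]
        if typ is float and isinstance(value, int):
            continue
        if not isinstance(value, typ):
            raise ValueError(f"report key {key} has type {type(value).__name__}, wants {typ.__name__}")


def read_block_table(path: str | Path, role: str = "imaging") -> pd.DataFrame | pd.Series:
    """Read a TSV/CSV block table keyed by a leading subject_id column.

    ``role`` is one of imaging / nonimaging / sites / quality.  Missing
    values are the empty string or "NA".  Duplicate subject IDs and
    non-numeric cells in numeric roles raise descriptive errors.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    table = pd.read_csv(path, sep=sep, na_values=["NA", ""], keep_default_na=False)
    if table.columns[0] != "subject_id":
        raise ValueError(f"{path.name}: first column must be subject_id")
    table = table.set_index("subject_id")
    dup = table.index[table.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"{path.name}: duplicated subject_id values: {dup}")
    if role in ("imaging", "nonimaging", "quality"):
        bad = [c for c in table.columns if not pd.api.types.is_numeric_dtype(table[c])]
        if bad:
            raise ValueError(f"{path.name}: non-numeric cells in numeric columns: {bad}")
    if role == "sites":
        return table.iloc[:, 0]
    if role == "quality":
        return table.iloc[:, 0].astype(float)
    return table.astype(float)


def _load_dataset(config: RunConfig) -> tuple[TwoBlockDataset, pd.DataFrame | None, pd.DataFrame | None]:
    imaging = read_block_table(config.imaging, "imaging")
    nonimaging = read_block_table(config.nonimaging, "nonimaging")
    site_tbl = pd.read_csv(config.sites, sep="\t", na_values=["NA", ""], keep_default_na=False)
    site_tbl = site_tbl.set_index("subject_id")
    mismatch = imaging.index.symmetric_difference(nonimaging.index).tolist()
    if mismatch:
        raise ValueError(f"subject IDs differ between blocks: {mismatch[:10]}")
    sites = site_tbl["site"].loc[imaging.index]
    quality = site_tbl["quality"].loc[imaging.index] if "quality" in site_tbl else None
    data = TwoBlockDataset(imaging=imaging, nonimaging=nonimaging, sites=sites, quality=quality)
    follow_img = follow_non = None
    if config.analysis == "change":
        if config.imaging_followup is None or config.nonimaging_followup is None:
            raise ValueError("change analysis requires follow-up tables")
        follow_img = read_block_table(config.imaging_followup, "imaging")
        follow_non = read_block_table(config.nonimaging_followup, "nonimaging")
    return data, follow_img, follow_non


def _stage(name: str):
    start = time.perf_counter()

    def done(rows: int, cols: int) -> None:
        logger.info("%s: %d rows x %d cols (%.2fs)", name, rows, cols, time.perf_counter() - start)

    return done


def run_pipeline(config: RunConfig, data: TwoBlockDataset | None = None,
                 followup: TwoBlockDataset | None = None) -> RunReport:
    """Execute the full analysis; reproducible given ``config.seed``.

    Inputs come either from the configured file paths or from an
    in-memory dataset (``data`` and, for change analyses, ``followup``).
    """
    follow_img = follow_non = None
    if data is None:
        data, follow_img, follow_non = _load_dataset(config)
    elif followup is not None:
        follow_img, follow_non = followup.imaging, followup.nonimaging

    ss = np.random.SeedSequence(config.seed)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3)]
    s_impute, s_perm, s_robust = seeds

    # 1. impute the non-imaging block
    done = _stage("impute")
    Y = pp.impute_missing(data.nonimaging, pp.PreprocessConfig(), seed=s_impute)
    done(*Y.shape)

    # 2. multivariate outlier exclusion on the imaging block
    done = _stage("outlier-filter")
    shrink = data.imaging.shape[1] >= data.imaging.shape[0] // 2
    kept, excluded, _ = pp.mahalanobis_filter(
        data.imaging, quantile=config.mahalanobis_quantile, shrinkage=shrink
    )
    X = data.imaging.loc[kept]
    Y = Y.loc[kept]
    sites = data.sites.loc[kept]
    quality = None if data.quality is None else data.quality.loc[kept]
    done(*X.shape)

    # 3. harmonize imaging features across sites
    if config.harmonize and sites.nunique() > 1:
        done = _stage("harmonize")
        X = pp.empirical_bayes_harmonize(X, sites)
        done(*X.shape)

    # 4. change scores for longitudinal analyses
    if config.analysis == "change":
        done = _stage("change-scores")
        X = pp.compute_change_scores(X, follow_img.loc[kept]).residuals
        follow_non_imputed = pp.impute_missing(
            follow_non.loc[kept], pp.PreprocessConfig(), seed=s_impute + 1
        )
        Y = pp.compute_change_scores(Y, follow_non_imputed).residuals
        done(*X.shape)

    # 5. standardize both blocks
    X = pp.standardize(X)
    Y = pp.standardize(Y)

    # 6. tune sparsity on the 10x10 grid (unless penalties are pinned)
    tuning_table = None
    if config.penalty_x is None or config.penalty_y is None:
        done = _stage("tune")
        tuned = tune_sparsity(X, Y, build_grid(X.shape[1], Y.shape[1]))
        px, py, tuning_table = tuned.penalty_x, tuned.penalty_y, tuned.table
        done(*X.shape)
    else:
        px, py = config.penalty_x, config.penalty_y

    # 7. fit, permute, FDR
    mode = fit_first_mode(X, Y, px, py)
    done = _stage("permute")
    perm = permutation_test(X, Y, px, py, n_perm=config.n_perm, seed=s_perm)
    done(config.n_perm, 1)
    family = np.concatenate([[perm.exact_p], np.asarray(config.extra_p_values, dtype=float)])
    fdr_p = float(fdr_adjust(family)[0])

    # 8. robustness battery
    done = _stage("robustness")
    robust = run_robustness(
        X,
        Y,
        px,
        py,
        fdr_p=fdr_p,
        quality=quality,
        n_resample=config.n_resample,
        n_splits=config.n_splits,
        stability_reps=config.stability_reps,
        seed=s_robust,
    )
    done(config.n_resample, config.n_splits)

    weights = pd.concat(
        [
            pd.DataFrame(
                {
                    "variable": X.columns,
                    "block": "imaging",
                    "weight": mode.weights_x,
                    "cross_loading": mode.cross_loadings_x,
                }
            ),
            pd.DataFrame(
                {
                    "variable": Y.columns,
                    "block": "nonimaging",
                    "weight": mode.weights_y,
                    "cross_loading": mode.cross_loadings_y,
                }
            ),
        ],
        ignore_index=True,
    )
    weights["reported"] = weights["cross_loading"].abs() > config.effect_threshold

    return RunReport(
        observed_r=float(mode.r),
        exact_p=float(perm.exact_p),
        fdr_p=fdr_p,
        covariance_explained_percent=int(round(100.0 * mode.r**2)),
        penalty_x=float(px),
        penalty_y=float(py),
        mean_permuted_r=float(perm.mean_permuted),
        sd_permuted_r=float(perm.sd_permuted),
        rr_median=float(robust.rr_median),
        test_train_ratio=float(robust.test_train_ratio),
        quality_rho=float(robust.quality_rho),
        pass_fdr=bool(robust.pass_fdr),
        pass_rr=bool(robust.pass_rr),
        pass_split=bool(robust.pass_split),
        reported=bool(robust.reported),
        seed=int(config.seed),
        n_subjects=int(X.shape[0]),
        analysis=config.analysis,
        excluded_subjects=[str(s) for s in excluded],
        weights=weights,
        cross_loadings_table=weights[["variable", "block", "cross_loading", "reported"]],
        permuted_r=perm.permuted_r,
        tuning_table=tuning_table,
    )


def write_report(report: RunReport, outdir: str | Path) -> None:
    """Emit report.json plus the TSV views and a run log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = report.to_json_dict()
    payload["quality_rho"] = (
        None if np.isnan(report.quality_rho) else float(report.quality_rho)
    )
    validate_report_dict(payload)
    (outdir / "report.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    if report.weights is not None:
        report.weights.to_csv(outdir / "weights.tsv", sep="\t", index=False)
        report.weights.loc[
            report.weights["reported"], ["variable", "block", "weight", "cross_loading"]
        ].to_csv(outdir / "cross_loadings.tsv", sep="\t", index=False)
    if report.permuted_r is not None:
        pd.DataFrame({"permuted_r": report.permuted_r}).to_csv(
            outdir / "permutations.tsv", sep="\t", index=False
        )
    if report.tuning_table is not None:
        report.tuning_table.to_csv(outdir / "tuning_grid.tsv", sep="\t", index=False)
    (outdir / "inference.json").write_text(
        json.dumps(
            {
                "observed_r": report.observed_r,
                "exact_p": report.exact_p,
                "fdr_p": report.fdr_p,
                "mean_permuted_r": report.mean_permuted_r,
                "sd_permuted_r": report.sd_permuted_r,
            },
            indent=1,
        )
    )
    (outdir / "robustness_report.json").write_text(
        json.dumps(
            {
                "rr_median": report.rr_median,
                "test_train_ratio": report.test_train_ratio,
                "quality_rho": payload["quality_rho"],
                "pass_fdr": report.pass_fdr,
                "pass_rr": report.pass_rr,
                "pass_split": report.pass_split,
                "reported": report.reported,
            },
            indent=1,
        )
    )
    import braincca

    (outdir / "run_log.txt").write_text(
        "\n".join(
            [
                f"braincca version: {braincca.__version__}",
                f"numpy version: {np.__version__}",
                f"pandas version: {pd.__version__}",
                f"seed: {report.seed}",
                f"analysis: {report.analysis}",
                f"n_subjects: {report.n_subjects}",
                f"excluded_subjects: {','.join(report.excluded_subjects) or 'none'}",
            ]
        )
        + "\n"
    )
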