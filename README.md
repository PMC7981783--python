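# braincca

Sparse canonical correlation analysis (sCCA) for linking brain
morphometry to non-imaging phenotypes, built for multi-site
adolescent-cohort studies where an imaging block (regional cortical
thickness, surface area, or subcortical volumes plus global measures)
and a non-imaging block (demographics, anthropometrics, cognition,
personality, substance use, life events, …) are measured on the same
subjects, possibly at two timepoints.

The package is aimed at researchers who want the full analysis chain —
not just a solver — with every stage reproducible and testable:

1. **Preprocessing**: random-forest imputation of missing non-imaging
   values, multivariate outlier exclusion by Mahalanobis distance
   (chi-square 0.999 quantile), empirical-Bayes site harmonization
   (ComBat), baseline-residualized change scores for longitudinal
   analyses, z-standardization.
2. **sCCA**: penalized matrix decomposition finding sparse weight
   vectors wx, wy maximizing wxᵀ(XᵀY)wy subject to ‖w‖₂ ≤ 1 and
   ‖w‖₁ ≤ c·√dim with c ∈ (1/√dim, 1]; the canonical correlation r is
   the Pearson correlation of the variates X·wx and Y·wy, and a mode
   accounts for r² of the cross-block covariance.
3. **Inference**: sparsity tuned on a 10×10 grid from 1/√dim to 1 by
   maximizing r; exact permutation P from 1000 row permutations of Y
   (P = #{permuted r ≥ observed r}/1000); Benjamini–Hochberg FDR across
   models.
4. **Robustness battery**: redundancy-reliability (RR) scores over 500
   half-resamples, a 10–150% stability curve, 500× split-half
   train/test generalization, and a scan-quality association. A mode is
   *reported* only if FDR P < 0.001, median RR > 0.80, and the
   test/train correlation ratio is ≥ 0.80.
5. **Synthetic cohorts**: a generator with known sparse canonical
   structure, site effects, missingness, and longitudinal thinning, so
   every stage can be validated against ground truth.

See `docs/methods.md` for the model, assumptions, and numerical
choices.

## Worked example

Generate a synthetic cohort with one planted mode (population r = 0.6,
5 true nonzero weights per block among 40 imaging and 30 non-imaging
features), batter it with site effects and 2% missingness, and run the
full pipeline:

```python
from braincca import (RunConfig, SyntheticSpec, generate_linked_blocks,
                      inject_site_effects, inject_missingness, run_pipeline)

spec = SyntheticSpec(n_subjects=600, p_imaging=40, q_nonimaging=30,
                     n_modes=1, support_x=(5,), support_y=(5,),
                     target_r=(0.6,), seed=2024)
data, truth = generate_linked_blocks(spec)
data = inject_site_effects(data, truth)
data = inject_missingness(data, 0.02, seed=2025)

report = run_pipeline(RunConfig(n_perm=1000, seed=7), data=data)
print(report.observed_r, report.exact_p, report.covariance_explained_percent)
```

Output of this exact configuration:

```
r = 0.628
exact P = 0.0  FDR P = 0.0
permuted r mean(SD) = 0.36 0.03
covariance explained = 39 %
penalties = 0.532 0.637
rr_median = 0.923  test/train = 0.842
reported = True
```

Reading it: the tuned model recovers the planted association (fitted
r = 0.628 against a planted 0.6; the in-sample value sits slightly above
because tuning is optimistic), none of 1000 permutations reached the
observed correlation (exact P = 0, FDR-adjusted P = 0 < 0.001), the
mode accounts for 39% of the cross-block covariance (r² rounded to
integer percent), and all three robustness gates pass — median RR score
0.923 > 0.80 and test-half correlations at 84% of training-half ones —
so the mode is flagged `reported`. Permuted correlations average 0.36
rather than 0 because the permutation null preserves each block's
internal structure and the maximal sparse correlation between unlinked
blocks of this size is substantial — exactly why inference is by
permutation rather than against zero.

A command-line interface mirrors the library:

```bash
braincca simulate --n-subjects 600 --seed 1 --outdir cohort/
braincca preprocess --indir cohort/ --outdir clean/ --seed 1
braincca fit --indir clean/
braincca run --indir cohort/ --seed 1 --outdir results/
```

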