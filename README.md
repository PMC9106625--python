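# metabodcv

Double cross-validated PLS-DA for untargeted LC–MS metabolomics
diet-discrimination studies.

In a parallel-arm dietary intervention profiled by untargeted LC–MS, the
question is which serum metabolites change differently between the two
diets, and whether that diet-specific metabolic profile relates to clinical
risk markers. `metabodcv` implements the full analysis chain for this
design, exercised end-to-end on synthetic data with known ground truth:

1. **Feature-table cleanup** — removal of blank-borne features, retention-time
   windowing, an early-eluting mass-defect plausibility filter,
   isotope/duplicate removal, ratio-based inter-batch correction, QC-pool
   LOWESS drift correction, correlated-feature grouping, ionization-mode
   concatenation, and per-subject baseline subtraction (week 8 − baseline).
2. **Discrimination with honest error control** — repeated double
   cross-validation: for each of *R* stratified 80/20 train/test splits,
   backward elimination discards low-VIP variables and a nested inner CV
   chooses the panel size; the refitted model is scored once on the
   untouched test subjects (misclassification rate ER, ROC AUC). Features
   selected in > 70 % of the repeats form the stability panel.
3. **Clinical interpretation** — PCA profile scores on the panel, Pearson
   correlations with clinical changes (Fisher-z 95 % CIs), bootstrap
   product-of-coefficients causal mediation (ACME/ADE), and
   Spearman-correlation hierarchical clustering of the panel.
4. **Annotation support** — per-class OLS retention-time calibration for
   homologous phospholipid series (RT increases with acyl carbons,
   decreases with double bonds), with prediction intervals for candidate
   annotations.

## The statistics at the core

PLS-DA is fitted by NIPALS PLS1 on autoscaled X against the arm label
y ∈ {−1, +1}. Variable importance in projection for variable *j* is

    VIP_j = sqrt( p · Σ_a SSY_a (w_ja / ‖w_a‖)² / Σ_a SSY_a ),

with SSY_a = q_a² t_aᵀt_a the y-variance captured by component *a* and *p*
the variable count (so mean VIP² = 1). Held-out AUC is the Mann–Whitney
probability that a random experimental-arm subject outscores a random
control-arm subject, ties counted ½.

The elimination step estimates the error-versus-panel-size curve *nested*:
each inner fold runs its own VIP-elimination path and scores every size on
the fold's held-out samples, which removes the optimism that makes
chance-correlated variables look useful. The selected size is the largest
one contiguously within 3 standard errors of the curve minimum — for
biomarker recovery, omitting a true marker costs more than carrying a
spurious one, and the stability threshold across repeats removes the
spurious ones. See `docs/methods.md` for the full rationale.

## Worked example

```python
import numpy as np
from metabodcv import (SimConfig, generate_study, inject_batch_and_drift,
                       DCVConfig, run_repeated_dcv, stability_select,
                       pca_profile, associate_outcomes)
from metabodcv.pipeline import RunConfig, preprocess_table
from metabodcv.tables import clinical_changes

cfg = SimConfig(n_subjects_per_arm=25, n_features_per_mode=(75, 75),
                n_discriminating=10, n_blank_features=5, n_isotope_pairs=5,
                rng_seed=1)
table, clinical, truth = generate_study(cfg)
table = inject_batch_and_drift(table, cfg)
change, reports = preprocess_table(table, RunConfig())
print(f"{len(table.features)} features -> {len(change.features)} after cleanup")

X = change.intensities.T
y = np.where(change.samples.loc[X.index, "arm"] == "Ex", 1.0, -1.0)
res = run_repeated_dcv(X.to_numpy(float), y, DCVConfig(n_repeats=30, rng_seed=2),
                       subject_ids=list(X.index), variable_ids=list(X.columns))
panel = stability_select(res)
hits = len(set(panel) & set(truth.discriminating_ids))
print(f"mean test AUC {res.mean_auc:.2f}, mean test ER {res.mean_er:.2f}")
print(f"stability panel: {len(panel)} features ({hits} of {len(truth.discriminating_ids)} planted)")

profile = pca_profile(X[panel])
print(f"PC1+PC2 explain {100*profile.explained_variance_ratio[:2].sum():.1f}% of panel variance")
assoc = associate_outcomes(profile, clinical_changes(clinical))
row = assoc[(assoc.outcome == "ldl_c") & (assoc.component == "PC1")].iloc[0]
print(f"LDL-C change vs PC1: r = {row['r']:.2f} "
      f"(95% CI {row['ci_low']:.2f} to {row['ci_high']:.2f})")
```

prints

```
155 features -> 145 after cleanup
mean test AUC 0.89, mean test ER 0.24
stability panel: 22 features (10 of 10 planted)
PC1+PC2 explain 49.3% of panel variance
LDL-C change vs PC1: r = -0.44 (95% CI -0.64 to -0.19)
```

The cleanup removed exactly the 10 planted blank/isotope artifacts; the
double-CV panel recovered all 10 planted discriminating features (plus 12
unstable extras at this small scale); and the profile score built from the
panel correlates with the simulated LDL-cholesterol change, as planted.

Every stage is also available from the shell:

```sh
metabodcv simulate  --outdir run/sim --seed 1
metabodcv preprocess --features run/sim/features.tsv --meta run/sim/samples.tsv --outdir run/pre
metabodcv dcv       --matrix run/pre/change_matrix.tsv --meta run/pre/change_samples.tsv \
                    --repeats 100 --seed 2 --outdir run/dcv
metabodcv downstream --matrix run/pre/change_matrix.tsv --meta run/pre/change_samples.tsv \
                    --panel run/dcv/panel.tsv --clinical run/sim/clinical.tsv --outdir run/down
metabodcv annotate-rt --outdir run/rt
metabodcv run-all   --outdir run/all --seed 3   # everything + hashed manifest
```

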