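# Methods

This note documents the models, numerical choices, and known limitations of
`metabodcv`. It states design rationale only; every empirical claim here is
recomputed by the test suite or by `scripts/acceptance.py`.

## Study design being modelled

The package targets a two-arm, parallel, baseline/week-8 dietary
intervention profiled by untargeted LC–MS in positive and negative
ionization modes: a control arm ("C") and an experimental arm ("Ex") whose
diet shifts a subset of serum metabolites (phospholipids, acylcarnitines
and related polar lipids in the motivating application). The analysis
surface is the per-subject *change* profile (week 8 − baseline), which
cancels stable inter-individual differences.

## Synthetic data generator

`synthetic.generate_study` emits a feature table (features × injections),
sample metadata, a clinical table and a ground-truth record.

**Intensity model.** Intensities are generated on the natural-log scale and
exponentiated, since LC–MS peak intensities are positive and approximately
log-normal. For subject *s*, feature *f*, visit *v*:

    log I = mu_f + u_{f,s} + delta_{f,s,v} + eps,   eps ~ N(0, noise_sd²)

- `mu_f ~ N(10, 1)`: feature base abundance (arbitrary units).
- `u_{f,s} ~ N(0, subject_sd²)`, default 0.5: persistent subject deviation,
  shared between visits — exactly the "individuality" that baseline
  subtraction removes.
- `delta`: the planted diet effect, nonzero only for discriminating
  features at week 8 in the Ex arm:
  `delta = sign_f · effect_size · √2 · noise_sd · c_s`. The √2 makes
  `effect_size` the standardized mean difference on the *baseline-corrected*
  log scale, whose residual SD is √2·noise_sd. Signs are random per feature
  (some metabolites rise on the experimental diet, some fall).
- `c_s ~ N(1, compliance_sd²)`, default 0.25: per-subject response
  heterogeneity (dietary compliance and metabolic idiosyncrasy). This is a
  deliberate realism choice: with negligible heterogeneity the two arms
  become almost perfectly separable (AUC → 1) and the inner-CV error floors
  at zero, which no real dietary study exhibits; 0.25 keeps the held-out
  AUC high but imperfect while leaving each planted feature's marginal
  effect at the configured size.

**Artifacts.** Blank-borne features receive blank-injection intensities at
sample level (all other features sit ~5 log units lower in blanks, a noise
floor). Isotope satellites are appended at +1.00336 Da (¹³C−¹²C), same RT,
intensity 0.3× the parent with correlation ≈ 1. `inject_batch_and_drift`
multiplies each intensity by exp(g), g ~ N(0, batch_sd²) per
(feature, batch) — batch effects in LC–MS are feature-specific — and by a
monotone drift function of within-batch injection rank rising from 1 to
1 + drift_amplitude (linear by default, quadratic optional). QC pools and
blanks receive the same distortions. Two blanks open each batch and a QC
pool is injected every 10 study samples and at the batch end.

**Clinical outcomes.** Baselines are drawn per outcome at values typical of
a moderately hypercholesterolemic adult cohort (e.g. LDL-C 4.15 ± 0.6
mmol/L); the week-8 change is `beta_o · latent + noise`, where `latent` is
the same compliance factor `c_s` that scales the metabolite shift (0 in the
control arm). Default betas lower LDL-C (−0.4), total cholesterol (−0.6)
and slightly HDL-C/TG in the experimental arm and leave glycaemia
untouched. Because metabolite shift and outcome change share the latent
factor, profile scores and clinical changes are genuinely associated — the
structure the downstream association and mediation analyses assume.

**What the generator does not emulate:** raw spectra, peak-picking
artifacts (missing values, gap filling), adducts/in-source fragments beyond
isotope pairs, heavy-tailed intensity distributions, correlated metabolite
modules beyond the single diet-response factor, and dropout. Passing tests
therefore demonstrate correctness of the *procedures*, not performance
guarantees on any real cohort.

## Preprocessing

Filters run in the order blank → RT window → mass defect →
isotopes/duplicates; each is idempotent.

- **Blank filter**: "present in blanks" is operationalized as mean blank
  intensity > 0.5 × mean study-sample intensity (configurable); absolute
  presence is meaningless above a noise floor.
- **RT window**: closed interval [0.3, 9.42] min — inclusive bounds are the
  conservative reading given identified compounds at the window edges.
- **Mass defect**: in the 0.3–0.8 min dead-volume region, features whose
  m/z fractional part is in [0.4, 1.0) ("first decimal 4–9") are
  implausible for small polar metabolites and removed.
- **Isotopes/duplicates**: within 0.01 min, a feature +k·1.00336 Da
  (k = 1, 2; tolerance 0.01 Da) above a more intense feature with Pearson
  r ≥ 0.7 across study samples is an isotope; features agreeing in both m/z
  and RT are duplicates (most intense kept). The tolerances are package
  defaults; peak-picking software does not report them.
- **Batch correction**: per feature, `corrected = I · overall/batch` mean
  ratio (means over study samples; the factor applied to every injection of
  the batch). This equalizes per-feature batch means exactly and preserves
  the per-feature grand mean. A `verbatim` mode implementing the inverse
  ratio (× batch/overall) is preserved for audits; that direction amplifies
  rather than removes batch differences and is assumed to be a
  transcription slip in the protocol it mirrors.
- **Drift correction**: per feature and batch, LOWESS (span 0.75) of
  QC-pool intensity on injection order, interpolated to all injections,
  normalized to its batch mean, and divided out. Batches with < 3 QC pools
  and features with non-positive fitted trends are left uncorrected with a
  warning rather than guessing.
- **Grouping**: single-linkage groups of features within 0.01 min with
  Pearson r > 0.7 over study samples (blanks/QCs excluded — grouping should
  reflect biological covariation), collapsed to the most intense member.
  Pearson is used here; the Spearman correlations of the downstream
  clustering serve a different purpose (monotone association among selected
  metabolites).
- **Baseline subtraction** produces one signed column per subject
  (week 8 − baseline raw intensity); unpaired subjects are an error, not a
  silent drop.

## PLS-DA kernel

NIPALS PLS1 with y ∈ {−1, +1}, mean-centering mandatory, unit-variance
scaling on by default (metabolomics convention). For a single response the
NIPALS weight step is closed-form, so fits are exact and deterministic.
Constant variables are kept at unit scale — centering zeroes them, giving
exactly zero weight, which is equivalent to dropping them while keeping
variable indices stable (a warning is emitted). Coefficients for any
leading subset of components derive from (W, P, q) without refitting, which
the cross-validation exploits (one fit per fold serves all component
counts). Classification threshold: midpoint of the training class-mean
scores; a score exactly at the threshold goes to the positive class.
Model-complexity selection returns the *smallest* component count achieving
the minimal CV error. AUC uses the rank-based Mann–Whitney form with ties
counted ½, so it is invariant to monotone transforms of the scores.

## Double cross-validation and stability selection

Outer loop: `n_repeats` (default 100) stratified-by-arm random 80/20
subject splits, each repeat seeded from a `SeedSequence` spawn of the
global seed, so results are reproducible and independent of execution
order. Scaling parameters are always estimated on training subjects only.

**Variable elimination.** Within a training set, backward elimination
repeatedly drops the 20 % lowest-VIP variables (VIP from a 2-component fit;
floor of one variable per round), producing a nested path of candidate
sets. The error-versus-size curve that chooses the returned set is
estimated by *nested* cross-validation: in each of 3 replicate stratified
5-fold splits, every fold runs its own elimination path on the fold's
training portion and scores each size on the fold's held-out portion.
Estimating this curve with the same samples that ranked the variables — the
naive reading of "CV error after elimination" — is systematically
optimistic for large sets, because variables chance-correlated with the
label in the training data look predictive in-sample; in our simulations
that bias inflates the error-minimizing size several-fold and floods the
stability panel with false discoveries.

**Size rule.** From the debiased curve, the chosen size is the largest one
*contiguously* within 3 standard errors (SE = √(ER·(1−ER)/n_evaluations))
of the curve minimum. The asymmetric direction is deliberate: the held-out
prediction optimum is typically smaller than the full planted support
(a handful of correlated markers predict nearly as well as all of them), so
minimizing error alone silently drops true markers. Walking toward larger
sizes within statistical slack protects sensitivity, while the stability
threshold across repeats (a variable must recur in > 70 % of repeats —
strict inequality) removes the spurious variables that individual repeats
carry. The contiguity constraint keeps a noisy flat tail of the curve from
dragging the choice to the full set.

**Aggregation.** Mean test ER and AUC are arithmetic means over successful
repeats; degenerate repeats (e.g. an inner fold losing a class) are
excluded with a warning and the selection-frequency denominator is the
number of successful repeats.

## Downstream analyses

- **Profile scores**: centered PCA (SVD) of the subjects × panel matrix;
  deterministic sign convention (largest-magnitude loading positive).
  Scores enter later models raw (unstandardized).
- **Associations**: Pearson r of each clinical change score against PC1 and
  PC2, Fisher-z 95 % CI, two-sided p, unadjusted — this is an exploratory
  table; a Benjamini–Hochberg switch is available in principle via
  `statsmodels` on the returned frame. Clinical outcomes are analyzed as
  week-8 − baseline changes to match the baseline-corrected metabolome.
- **Mediation**: OLS mediator model (mediator ~ treatment) and outcome
  model (outcome ~ treatment + mediator); ACME = a·b, ADE = c′, so
  total = ACME + ADE holds exactly for the point estimates. CIs are
  case-resampling percentile bootstrap (default 2000 draws, seeded).
  Percentile CIs for a product statistic undercover mildly near the null
  (measured ≈ 0.84–0.90 actual at 0.90 nominal in our simulations);
  bias-corrected variants performed worse at the null in the same
  simulations and were not adopted. Insulin is excluded from the mediation
  outcome list: the profile scores summarize a lipid-driven contrast and
  glycaemic mediation hypotheses were limited to glucose.
- **Clustering**: Spearman ρ over subjects, asymptotic p-values, p < 0.05
  significance mask (unadjusted, mirroring exploratory heatmap practice),
  average-linkage tree on 1 − ρ with deterministic leaf order. Constant
  metabolite columns are dropped with a warning.

## Retention-time calibration

Per lipid class (PC, lysoPC, PC-plasmalogen), OLS of observed RT on total
acyl carbons and double bonds. The additive linear form is a deliberately
minimal realization of homologous-series behaviour — adequate over the
narrow carbon/double-bond ranges of a serum phospholipid panel, not a
general lipophilicity model. Calibrations need ≥ 3 species spanning ≥ 2
carbon counts; fitted slopes with unexpected signs (carbons ≤ 0 or double
bonds ≥ 0) are flagged, not rejected. Predictions carry OLS prediction
intervals; candidates outside the calibrated covariate range are flagged as
extrapolations. Features with signal area below 100 counts are flagged
ineligible for MS/MS identification (an eligibility flag, not a data
filter). The packaged `data/reference_lipids.tsv` holds identified serum
phosphatidylcholines and related species with observed RT/m/z used as the
default calibration set.

## Reproducibility and problem sizes

All randomness flows from one global seed through `SeedSequence`-derived
per-stage seeds (< 2³¹); no stage consults ambient entropy. Every artifact
is delimited text written with 6-significant-digit float formatting, and
the run manifest records a SHA-256 per output (line endings normalized), so
a rerun with the same configuration reproduces every hash. The default
`RunConfig` demonstration scale (25 subjects/arm, 150 features, 30 repeats)
runs in under a minute; the reference scale used by `scripts/acceptance.py`
(50/arm, 500 features, 50 repeats) completes in a few seconds per stage.
These sizes were chosen so that the full analysis, including the nested
elimination, remains interactive on a laptop while keeping the planted
effects within the regimes the procedures are designed for.

## Known limitations

- The stability panel's false-discovery control is empirical, not a formal
  guarantee; variables chance-correlated with the diet response at the
  cohort level are indistinguishable from true markers at n ≈ 100.
- The drift corrector assumes a smooth trend expressible by LOWESS of ≥ 3
  QC pools; step changes within a batch are not modelled.
- Mediation assumes linear models with no treatment–mediator interaction
  and no unmeasured confounding of the mediator–outcome path; the CIs
  quantify sampling noise, not identification assumptions.
- The RT model ignores sn-position isomerism and class-specific curvature;
  it supports annotation plausibility, not identification.
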