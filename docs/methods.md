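# Methods

## Scope and data model

The pipeline starts from an *aligned feature table* — the product of
vendor peak picking and alignment — with per-feature m/z and retention
time and per-injection sequence metadata (order, batch, role ∈ {study,
qc, dqc, blank, conditioning}, sample id, class labels). Raw spectra,
chromatographic peak shapes, isotope patterns and MS/MS identification
are out of scope. All tables are plain pandas objects; matrix-level
steps (scaling, PQN, PLS/OPLS, MCUVE) are sklearn-style estimators so
they compose with sklearn model selection, while table-level stages
(dilution filter, drift corrector) follow the same fit/transform idiom
on the `FeatureTable` container because they need injection metadata a
bare matrix lacks.

## Synthetic-data generator

The generator emulates the design of the cohort study the pipeline
re-implements; its defaults are the study conditions where stated and a
realistic choice where not.

**Cohort.** Eight CASA semen parameters driven by four latent factors:
a global motility factor loading positively on SP, QP, NP, HY and
negatively on static sperm (ST); a count factor shared by concentration
(CO) and total sperm count (TS) with corr(CO, TS) = 0.9 by construction
(configurable); a second motility contrast; and an independent
morphology factor (MO). Parameter means/scales (e.g. TS 180 ± 60
million, CO 60 ± 20 million/mL, MO 40 ± 14%) are chosen so that
clipping at physiological bounds (≥ 0, MO ≤ 100) is a ≲ 0.2% tail
event and does not distort the factor structure. PCA of a large
generated cohort reproduces the qualitative component pattern of the
real cohort: a motility axis opposing ST, a CO/TS axis, a second
motility contrast, and a morphology-dominated axis.

**Sequence.** Each batch: optional blanks, 5 conditioning injections
(excluded from all statistics), a leading QC/dQC pair, then blocks of
≤ 8 study samples each closed by a QC/dQC pair; the pair after the last
block anchors the batch end. Anchoring both batch ends is a declared
convention — drift interpolation needs support at the extremes; the
study design only fixes the 8-sample interval.

**Intensities.** Expected intensity = per-feature log-normal baseline ×
smooth per-batch drift (cosine ramp of relative amplitude
`drift_amplitude`, default 0.3) × per-batch offset × class effect
(2^effect on planted features for high-TS study samples) × role factor
(dQC: `dilution_factor` = 0.5; blanks: 1e-4). Noise is multiplicative
mean-one log-normal with coefficient of variation `noise_cv`; the
pipeline default is 0.10, a typical pooled-QC technical CV for
untargeted LC-MS (note that the dQC/QC *ratio* RSD is then ≈ √2 × 10% ≈
14%, comfortably under the 20% filter). Missing values are injected at
a configurable rate (default 0) as NaN. With `noise_cv = 0` every
oracle is exact: QC rows identical, dQC/QC ratio exactly 0.5, planted
fold changes exact.

What the generator does **not** emulate: correlated feature blocks from
shared metabolite origin (adducts/isotopes of one compound), intensity-
dependent (heteroscedastic-in-mean) noise floors, retention-time drift,
or censoring of low-abundance peaks. Passing tests therefore establish
correctness of the algorithms under the stated generative model, not
performance on real seminal-fluid data.

## Preprocessing

**Dilution filter.** Per adjacent QC/dQC pair, ratio = dQC/QC; pairs
with missing or zero QC (or missing dQC) are skipped. Center = mean of
pair ratios (median available), RSD = 100 × sd(n−1)/mean; a feature
needs ≥ 2 valid pairs for defined statistics. Retained iff defined,
center ∈ [0.2, 0.8] (closed — the conservative reading of "between"),
and RSD ≤ 20. The reject reason records the first failed rule in the
order undefined → range → RSD. The filter is monotone in both
thresholds and idempotent.

**Drift correction.** Degree-1 LOESS (tricube weights, window =
⌈span·n⌉ ≥ 2 nearest neighbours) of QC intensity vs injection order,
per feature × batch; implemented as a linear smoother whose weights
depend only on the shared injection orders, so one pass serves every
feature simultaneously. The span is chosen per feature from
{0.3, 0.45, 0.6, 0.75, 0.9, 1.0} (0.75 is the conventional initial
value; smaller spans are degenerate with few QCs) by leave-one-QC-out
cross-validation, ties resolved toward the larger (smoother) span.
Corrected intensity = raw × (reference / curve), with the reference the
feature's median QC intensity over *all* batches — a single
multiplicative map that removes within-batch drift and between-batch
offsets jointly. Batches with < 4 valid QCs, or curves that become ≤ 0
anywhere, leave the feature uncorrected and flagged in the audit.
Degenerate windows (zero weighted x-variance) fall back to the weighted
mean; window-edge weight collapse (all neighbours at the tricube zero)
falls back to uniform weights. Missingness and signs are preserved.

**PQN.** Reference = per-feature median of corrected QC injections.
Quotients are taken over features positive and present in both sample
and reference; each non-blank injection (study, QC, dQC, conditioning)
is divided by its median quotient. Samples sharing no positive feature
with the reference are flagged and left unnormalized. With a fixed
reference the operation is idempotent and scale-equivariant.

**UV scaling** mean-centers and divides by the sample (n−1) standard
deviation, erroring on zero-variance columns by index. Scaling is
refit inside every cross-validation fold and every MCUVE draw — no
leakage.

## Modelling

**PLS1** is the one-step NIPALS sequence (w ∝ Xᵀy, t = Xw, deflation by
t pᵀ), coefficients b = W(PᵀW)⁻¹q; with univariate y each component is
exact, so no iteration tolerance is exercised. **OPLS-DA** strips
`n_orth` y-orthogonal components (w_o ∝ p − (wᵀp)w) before a single
predictive PLS component; its training predictions coincide with PLS
using n_orth+1 components (verified numerically), and every orthogonal
score has zero covariance with y by construction. Classes are coded
−1/+1 in sorted label order so the decision threshold is 0; a
prediction of exactly 0 counts as wrong.

**DQ²** zeroes residuals of predictions beyond their class label, so
DQ² ≥ Q² always, and equals 1 under perfect or over-confident correct
prediction. **LOO-CV** refits scaler + model per fold; accuracy is the
percentage of sign-correct left-out predictions. The orthogonal count
is grown sequentially and stops at the first component whose LOO DQ²
gain is ≤ 0.05: under LOO an extra orthogonal component yields a small
chance-level gain (~0.02–0.03) even on data with no structured
y-orthogonal variation, so a plain argmax systematically overfits the
component count; 0.05 is the usual significance margin for adding a
latent variable. Setting `min_gain=0` restores the greedy argmax.

**MCUVE-PLS.** Stratified training draws of 0.7 of the rows, with
replacement (bootstrap) by default. With subsampling *without*
replacement at ratio f, draws share most of their rows and the ensemble
spread understates sampling variability by ≈ √(f/(1−f)) (≈ 1.53 at
f = 0.7); the null reliability index then behaves like 1.53·|Z| and the
conventional 1.5 cutoff retains roughly a third of purely uninformative
variables. Bootstrap draws make the ensemble spread match sampling
variability, so RI > 1.5 behaves like a ~1.8σ rule (measured false
selection ≈ 0.1 at the reference conditions, sensitivity 1.0 for
d = 1.5 effects). `replace=False` restores plain subsampling. RI uses
the (n_models − 1) sd; sd = 0 with nonzero mean gives infinite RI
(retained); selection is strict (RI > 1.5). The ensemble's PLS
component count defaults to the count selected by cross-validation on
the full data (1 + n_orth), capped at 3.

## Study-level conventions

**Stratification.** TS and MO are converted to quantile ranks; the MO
median splits abnormal (below) from normal strata; within each stratum
the n lowest and n highest TS-quantile subjects form the low/high-TS
groups (G1 low/abnormal, G2 low/normal, G3 high/abnormal, G4
high/normal). Extremeness is the TS-quantile distance from the median
within the required MO stratum — the joint criterion is under-
determined by the study description, so this rule is declared,
deterministic (ties broken by subject id) and configurable.
**Contingency**: round-half-away-from-zero of fraction × size (5% of
200 = 10), spread evenly over groups with the remainder going to the
groups whose next candidate is most extreme.

**Annotation** uses fixed adduct offsets (+1.007276, +22.989218,
−17.003289, −35.013854 Da), reporting every library entry within both
the ppm and RT tolerances, ranked by |ppm error|. Isotopic-pattern
scoring is not implemented: it requires raw isotopologue intensities
that the aligned-feature-table abstraction does not carry.

**Volcano.** log2(mean_high/mean_low) (positive = higher in the
high-count class), two-sided Welch t-test on the supplied (normalized)
intensities, Benjamini–Hochberg q-values; the adjustment method is an
interpretation — raw p-values are always reported alongside. Zero-
variance ties are assigned p = 1 when means are equal.

## Problem sizes

The test suite and the acceptance script use deliberately compact
problem sizes chosen to exercise every code path with tight oracles: a
2731-subject cohort for design arithmetic, two-batch tables of 24–32
study samples per batch and 60–300 features for preprocessing, ensembles
of 1000 models over 120 × 200 matrices for MCUVE recovery, and 100
label permutations for the null calibration. The headline discriminant
statistics of the original cohort (e.g. DQ²Y = 0.457 for the count
model) depend on undeposited biological data and are not reproduction
targets; the pipeline instead verifies the *contrast pattern* (count
model ≫ morphology model when effects are planted on the count classes,
refinement never hurting accuracy) and every in-study arithmetic
identity.

## Known limitations

- Two-class OPLS-DA only; no multi-class extension, O2PLS or kernels.
- No imputation: missing entries are excluded from fits and quotients.
- No blank-based background subtraction or adduct de-duplication.
- The drift model assumes multiplicative, smooth-in-order drift; abrupt
  mid-batch jumps are absorbed only as far as the LOESS span allows.
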