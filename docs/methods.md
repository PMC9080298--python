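# Methods

`moaprofile` implements a cell-metabolic-profiling pipeline that predicts the
mechanism-of-action (MoA) class of an anticancer compound from untargeted
LC-MS peak tables of drug-treated tumor cells. This note documents the
models, the synthetic study the package is exercised on, the numerical
choices, and the known limitations.

## Study design being modeled

The pipeline targets a design with 12 adherent tumor cell lines treated with
drugs from four MoA classes — antimetabolites, direct DNA-acting agents,
microtubule-dynamics disruptors and RNA-interfering (transcription-blocking)
agents — three drugs per class, each with a paired vehicle control and three
profiling replicates, giving 12 x 4 x 3 x 2 x 3 = 864 biological samples.
Metabolites are profiled in two complementary chromatographic blocks
(reversed-phase and HILIC) that are fused ("RP + HI") before modeling.
A pooled QC sample (equal aliquots of all study samples) is injected at the
head of the run and after every 6 analytical samples to monitor instrument
stability. A fourth replicate flask supplies a hemocytometer cell count used
to normalize intensities to biomass.

## Synthetic data generator

No public data accompany this design, so `synthetic.generate_study` emulates
it. For feature f and biological sample i,

    log10 I_fi = mu_f + line_f(cell line of i) + delta_fi + drug_fi + eps_fi

* `mu_f ~ U(3, 6)` — baseline log10 intensity;
* `line ~ N(0, cell_line_sd)` per (cell line, feature) — a cell-line random
  effect (default sd 0.2);
* `eps ~ N(0, noise_sd)` — multiplicative technical noise (default sd 0.1 on
  the log scale);
* `delta` — the planted class effect: each class owns `markers_per_class`
  (default 12) disjoint marker features, shifted by `+-effect_size` (default
  0.5, i.e. ~3.2-fold, inside the printed fold-change range 0.004–6.8 of the
  study's marker tables) in treated samples of that class only;
* `drug ~ N(0, effect_size/5)` per (drug, marker) — drugs of a class cluster
  together but are not identical.

Linear intensities are multiplied by the sample's cell count relative to the
nominal seeding density (counts ~ N(1e6, 10% CV)), zeros are injected at
`missing_rate` (default 5%), and intensities below a detection floor (the 1%
quantile of baseline abundance) are censored to zero — both mechanisms
produce the "ion intensity = 0" signature that the missingness filter
removes. QC samples are the feature-wise mean of all biological samples with
N(0, noise_sd/2) log-noise.

Two generator choices are deliberate design decisions:

* **Markers sit on reliably detected features.** Marker features are drawn
  from the upper 70% of baseline abundance. A down-shifted marker planted at
  the detection limit would be censored to zero and removed by the 20%
  missingness filter, making its own ground truth unrecoverable by
  construction; the printed marker tables contain no detection-limit ions.
* **Class effects are sparse.** Only the planted markers move; there is no
  diffuse class effect across the remaining features. A consequence worth
  knowing: at the default cell-line heterogeneity the leading *unsupervised*
  components capture cell-line variation (every feature carries the sd-0.2
  line effect, versus 12 shifted markers per class), so PCA shows modest
  class clustering — mirroring the situation that motivates a supervised
  discriminant model in the first place. The PCA class-clustering property
  is therefore demonstrated at reduced `cell_line_sd`, while the supervised
  pipeline separates the classes under full defaults.

`generate_new_drug_set` draws held-out treatment sets in the same feature
space: one named class applies that class's full marker shifts (the
GEM/BCNU/MIT/VDS-style evaluation sets); `"mixed"` applies half-magnitude
shifts of two classes simultaneously (default microtubule + DNA-acting),
emulating a compound with a dual mechanism whose projection falls *between*
two class regions.

A single integer seed drives every stochastic element through dedicated
`numpy` generator substreams, so identical configs produce byte-identical
tables and new-drug sets line up with the training study's planted truth.
What the generator does **not** emulate: retention-time drift, batch
effects, correlated metabolite modules, peak-shape artifacts and
heavy-tailed intensity noise. Passing tests demonstrate the pipeline's
statistical machinery, not performance on real spectra.

## Preprocessing

Fixed stage order, asserted by the runner:
align -> filter -> normalize -> log10 -> Pareto scale -> fuse.

* **Alignment** (for raw peak lists): greedy binning in descending intensity
  order with a 0.05 Da mass window and 0.5 min RT tolerance; peaks below 5%
  of their sample's base-peak intensity are discarded. The proprietary
  "noise elimination level" of vendor software is approximated by this
  intensity floor alone.
* **Missingness filter**: features with strictly more than 20% zeros across
  all samples are removed (a feature at exactly 20% is kept).
* **Cell-count normalization**: intensities are rescaled to the median cell
  count; QC samples pass through. Normalization happens after alignment;
  the provenance records this ordering.
* **log10**: remaining zeros are filled with half the feature's smallest
  positive intensity — the most common metabolomics convention; the policy
  is a parameter. For small projection sets a feature that is all-zero
  (the filter was fit on training data) can be filled with half the
  table-wide minimum instead.
* **Pareto scaling**: center by the mean, divide by the square root of the
  sample standard deviation (n−1). Zero-variance features are centered and
  left unscaled. The stored center/scale project new samples into the
  training space exactly. Because Pareto scaling is a per-feature operation,
  scaling each block before fusion and scaling the fused matrix are
  numerically identical; blocks are scaled before fusion and the provenance
  keeps per-block state.

## The OPLS-DA model

The class structure is coded as an n x K indicator ("dummy") matrix Y,
column-centered for fitting (no Y scaling). The backbone is NIPALS PLS2: per
component, iterate u -> w = X'u/||X'u||, t = Xw, c = Y't/(t't), u = Yc/(c'c)
to convergence of t, then p = X't/(t't) and deflation X := X − tp',
Y := Y − tc'. The alternating iteration converges linearly at the ratio of
the top two eigenvalues of X'YY'X, which is close to 1 for balanced
multi-class designs; the iteration is therefore warm-started at its own
fixed point (the dominant left singular vector of the p x K matrix X'Y),
after which a few polishing steps reach the 1e-10 tolerance.

Orthogonal ("Y-uncorrelated") variation is removed in the Trygg–Wold sense
before the predictive fit: for each orthogonal component, one PLS round
supplies a loading p; the part of p outside the span of the Y-predictive
weight basis (orthonormalized X'Y, rank-deficient directions dropped) is
normalized into w_o, and X is deflated by t_o p_o' with t_o = X w_o. The
predictive part then consists of K − 1 = 3 PLS2 components on the filtered
matrix. With zero orthogonal components the model reduces exactly to PLS2.

* **Component counts**: predictive A_p = K − 1 by default; orthogonal A_o
  either fixed or chosen automatically by growing while cross-validated Q2
  improves by more than 0.01, capped at 5. The search runs once on the full
  data; per-fold refits inside cross-validation and the permutation test
  reuse the chosen architecture (switchable).
* **Prediction**: new samples are transformed with the training
  center/scale, orthogonal components are stripped sequentially, and
  Y-hat = X_filtered B + y-bar with B = W (P'W)^-1 C'. Class = argmax of
  the raw membership vector; exact ties go to the smallest class index.
* **Fit metrics**: R2X is the predictive components' share of the scaled
  matrix's total sum of squares; R2Y = 1 − ||Y − Y-hat||²/||Yc||²;
  Q2 = 1 − PRESS/SSY from sevenfold stratified cross-validation in which
  Pareto scaling is refit inside each training fold (no leakage of held-out
  samples into the scaling). Q2 is reported at the final component count,
  not as a per-component product (a flagged alternative in commercial
  software).
* **VIP**: VIP_j = sqrt( p · Σ_a SSY_a w_ja² / Σ_a SSY_a ) over the
  predictive components, SSY_a = (t_a't_a)(c_a'c_a). With unit-norm weight
  columns, mean VIP² = 1 exactly, so VIP > 1 marks above-average
  contributors.

## Model validation

* **Permutation test** (default 999 permutations; the bundled analysis and
  acceptance runs use 99, which is ample for the sign of the intercepts at
  this effect size): class labels are permuted jointly (rows of Y, never
  within a column), the model is refit with the fixed architecture, and
  R2Y and cross-validated Q2 are recorded. Each permutation's similarity to
  the original labeling is r = mean |Pearson correlation| across paired
  dummy columns. Least-squares lines through all (r, R2) and (r, Q2) points
  — including the unpermuted model at r = 1 — give the intercepts at r = 0.
  Validity requires every permuted metric below the original and a negative
  Q2 intercept. If the r values are degenerate the intercept falls back to
  the mean of the permuted metrics.
* **CV-ANOVA**: an F test of the cross-validated residuals. SS_total = SSY
  with N·K − K df, SS_reg = SSY − PRESS with df equal to the total fitted
  component count, SS_res = PRESS with the remaining df. PRESS ≥ SSY floors
  F at 0 with p = 1. The df bookkeeping of the commercial implementation is
  proprietary; this df convention is documented as approximate.

## Marker selection

Per class: features with VIP > 1 in the four-class model form the candidate
family; each candidate is tested treated-vs-control *within the class* by
one-way ANOVA (for two groups F = t² of the pooled-variance t test) with
Bonferroni correction over the family size; survivors are retained when
p_adj < 0.05 and the oriented AUC exceeds 0.50, and ranked by AUC. Choices
where the workflow description is ambiguous:

* ANOVA grouping is treated-vs-control within the drug class (matching the
  per-class marker tables); an all-classes grouping is available.
* Bonferroni multiplicity = VIP survivors of that class (per-class family).
* AUC is the Mann–Whitney U statistic with midrank ties; the *oriented*
  AUC max(AUC, 1 − AUC) is used for the gate (the printed tables report
  down-regulated markers with AUC > 0.5, so their AUCs are
  direction-oriented); the raw treated-as-positive AUC is reported
  alongside.
* Fold change = mean(treated)/mean(control) on cell-count-normalized
  pre-log intensities; trend "up" iff FC > 1 strictly (FC = 1 counts as
  "down"); ratio semantics are used throughout (FC < 1 with a downward
  trend), a zero control mean drops the candidate with a logged reason.

The marker x class fold-change matrix is clustered by average-linkage
agglomeration on Euclidean distances of the actual FC values and cut into
four row clusters; ordering is the deterministic dendrogram leaf order. A
constant matrix yields a single cluster with a warning.

## Classification of new sets and the mixed-mechanism call

A new set's log10 matrix is projected through the frozen model. Per-sample
class = argmax Y-hat; the set call is the majority vote (exact ties are
reported as "unresolved", never silently broken). R2_pred measures how well
the projected memberships match the called class against the training
spread; Q2_ext accumulates the same residuals over a sevenfold re-blocking
of the set with the model frozen. A set whose two largest mean memberships
differ by less than `margin_threshold` (default 0.2 — the printed account
decides "between regions" visually, so the threshold is a package choice
exposed in config) raises the mixed-mechanism flag; a set whose largest
mean membership falls below 0.4 is additionally marked weak-signal with a
warning. The region report draws convex hulls of each training class in the
first two predictive score dimensions and reports the fraction of new
points inside each hull; a genuinely blended set typically falls inside no
hull, between the two involved regions, while a set pooling two pure
mechanisms lands in both.

## QC drift rule

PCA (SVD of the scaled matrix; sign fixed by making each component's
largest-magnitude loading positive) summarizes the fused matrix. A pooled
QC sample passes when each of its first-two-component scores lies within
k = 2 standard deviations of that component's score distribution over all
samples (the reference population is a parameter; all-samples is the
default).

## Problem sizes used by the bundled runs

The analysis drivers and the acceptance script run the full default study
(864 biological samples + 145 QCs, 500 features) for fitting, marker
recovery, permutation testing (99 permutations) and new-set classification.
Replicated checks (the 20-seed mixed-mechanism rate and the 20-seed null Q2)
use a reduced design — 3 cell lines, 2 drugs per class, 90 features — which
keeps the replicate loops cheap while preserving the full study structure;
the same reduced design backs most of the test suite.

## Known limitations

* The orthogonal-filter weight basis and the CV-ANOVA df convention follow
  the published descriptions of these methods as closely as they allow;
  commercial implementations differ in undocumented details, so absolute
  R2/Q2/p values are comparable in behavior, not digit-for-digit.
* The per-set R2_pred/Q2_ext of a projected set measure agreement with the
  *called* class, not an externally validated truth; a refit-based variant
  is available behind a flag.
* Marker records carry free-text name/pathway fields only for the packaged
  tables; the package does no metabolite identification or pathway
  enrichment.
* The generator's within-class biological variance across cell lines is a
  plausible choice, not a fitted one; no public raw data exist to calibrate
  it.
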