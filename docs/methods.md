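# Methods

## The procedure

`connectoml` implements a discovery framework for classifying two clinical
groups from MEG functional connectomes. The feature space is the set of all
unordered region pairs ("edges") of a 90-region AAL parcellation — 4005
edges — each carrying a weighted phase lag index (wPLI) synchrony value in
[0, 1], computed separately per frequency band (Theta 4–7 Hz, Alpha 8–14 Hz,
Beta 15–30 Hz, low gamma 30–80 Hz, high gamma 80–150 Hz). Per band the
funnel is:

1. **Univariate screen.** Welch two-sample t-test per edge, two-sided,
   significance on the raw p-value at α = 0.01. No multiple-testing
   correction by default: the screen is a variance-preserving filter, not an
   inference step (a Benjamini–Hochberg switch exists for reuse).
2. **Unsupervised structure checks.** Two-way hierarchical clustering
   (Ward linkage, Euclidean distance, z-scored columns) with the k = 2
   participant cut cross-tabulated against diagnosis, plus PCA score /
   explained-variance summaries, at three stages: all edges, significant
   edges, selected edges.
3. **Participant split.** Stratified 80/20 train/test split by participant;
   the total test count is round(0.2·n) apportioned to classes by largest
   fractional remainder (23 + 21 subjects → 5 cases + 4 controls held out).
   Nothing downstream ever sees the test subjects until the final ROC.
4. **CV-SVM-rRF-FS.** The univariate filter is recomputed on the training
   set alone, then recursive random-forest feature selection runs inside
   each of 10 stratified CV folds: fit a forest on the fold-training
   portion, record out-of-bag (OOB) error, drop the lowest-importance 20% of
   features, repeat to a floor of 2, and keep the path point with minimal
   OOB error (ties → fewest features). Edges selected in a majority of
   folds (≥ 5 of 10) form the consensus list.
5. **Final SVM.** RBF-kernel SVM on the consensus edges, features
   z-standardised with training statistics, C and γ from a small inner grid
   (C ∈ {0.1, 1, 10}, γ ∈ {1/p, 0.01, 0.1}); reported as stratified 10-fold
   CV accuracy (mean ± SD) and support-vector count.
6. **Permutation test.** Training labels shuffled B = 99 times, the fixed
   model configuration refit each time, internal CV accuracy recomputed;
   p = (1 + #{null ≥ observed}) / (B + 1), so the attainable floor is
   exactly 0.01.
7. **External evaluation.** Decision values on the held-out subjects;
   ROC at the distinct decision thresholds and AUC by the Mann–Whitney
   concordance formulation with ties counted ½ (identical to the
   trapezoidal integral of the ROC).
8. **PLS-DA verification.** Two-component NIPALS PLS-DA on the consensus
   edges (X standardised; class coded ±1, centred; prediction by sign),
   cumulative VIP scores
   VIP_j = √( p · Σ_a SSY_a (w_aj/‖w_a‖)² / Σ_a SSY_a ) with
   SSY_a = b_a²·t_aᵀt_a, flagged at the 0.8 importance threshold, plus its
   own stratified-CV accuracy as an SVM-independent check on the selected
   features. Σ_j VIP_j² = p is an algebraic identity of the formula and is
   asserted in tests.

Each band is processed fully independently. All randomness flows from one
top-level seed through named per-stage streams
(`SeedSequence(seed, crc32(label))`), so any stage can be reproduced in
isolation and full runs are byte-identical for a fixed seed and config.

## wPLI estimator

For two channels, epochs e and in-band FFT bins k, with cross-spectrum
S_xy = X(f)·conj(Y(f)):

    wPLI = | Σ_{e,k} Im S_xy | / Σ_{e,k} |Im S_xy|

pooled over epochs and bins in one ratio. Values lie in [0, 1]; the
estimator is invariant to per-channel amplitude scaling and to channel
order, and blind to zero-lag coupling. Two numerical decisions: (i) a
vanishing denominator (no imaginary cross-spectral mass, e.g. identical
signals) is defined as wPLI = 0 — no lagged synchrony; (ii) imaginary mass
below 1e-10 of the largest cross-spectral magnitude is treated as zero, so
floating-point residue of a purely real cross-spectrum cannot masquerade as
synchrony. Plain rectangular-window rfft per epoch; the source recordings'
epoch length and spectral estimator are free choices here (2 s epochs at
600 Hz by default, which keeps 150 Hz inside Nyquist).

## Synthetic data: what it emulates and what it does not

The generator reproduces the *design* of the emulated study — 23 cases vs
21 controls, 90 regions → 4005 edges, five bands, a few dozen genuinely
discriminative edges per band of mixed direction — with known ground truth.

Direct-edge mode (default test bed): edge weights are inverse-logit of
Gaussian draws centred at logit(0.2) with SD 0.5 on the logit scale; a
baseline wPLI around 0.2 is typical of resting-state synchrony, and the
logistic transform keeps [0, 1] support without truncation artefacts.
Planted edges shift the case-group centre by ±d·SD on the logit scale, so
"increase"/"decrease" are monotone on the observed scale and the group
difference can never be clipped to zero at the boundary. Default planting:
40 edges per band (the across-band mean of the significant-edge counts the
screen is expected to find), half increasing and half decreasing, at
d = 1.2 — a moderate effect giving per-edge Welch power near 0.9 at these
group sizes.

Timeseries mode exists to validate the wPLI estimator physically: unit
variance band-limited FIR-filtered noise per region, and for each planted
pair a shared carrier at the band centre (snapped to an FFT bin) with a
π/2 phase lag and per-epoch random phase, mixed as √(1−s²)·noise +
s·carrier so coupling strength s = 1 is a pure oscillation. The control
group couples at s; cases at s ± 0.3·d (clipped to [0, 1]).

What the synthetic data does **not** have: spatial correlation structure
among edges, 1/f spectra, volume-conduction artefacts, subject-level
covariates, or site/medication effects. Passing tests therefore demonstrate
that the *procedure* is correct, calibrated and leakage-free under the
stated design — not that real MEG cohorts will reach any particular
accuracy.

## Numerical and design choices

- **Welch, not pooled-variance, t-tests** (unequal group sizes, no variance
  homogeneity assumption). Edges constant in both groups get t = 0, p = 1;
  constant-but-different edges get p = 0. Exact zero mean differences are
  labelled "increase" with a tie flag for determinism.
- **Across-band summary** uses the sample SD (n−1): the five reference
  counts 30/40/49/22/59 then summarise to mean 40, SD 15 (population SD
  would give 13).
- **Forest size 300** in the recursive elimination: at ~30 fold-training
  subjects every sample is out-of-bag in roughly a third of the trees,
  which is ample for a stable OOB ranking; 1000 trees triples the cost of
  the dominant loop for no measurable change in selections. Importance is
  impurity-based (Gini) by default — one forest fit per elimination round;
  permutation importance is available via `rf_importance="permutation"` at
  features × repeats extra prediction passes per round.
- **The consensus list is a minimal signature, not a complete recovery.**
  Because the elimination stops at the smallest set with minimal OOB error,
  planted-edge recall is deliberately partial (a handful of strong edges
  already separates the groups) while precision is near 1; tests assert
  exactly this, plus monotone recall in effect size.
- **Consensus threshold** defaults to a fold majority (⌈k/2⌉ = 5 of 10).
- **SVM kernel RBF**; with ~30 training subjects and a dozen features a
  support-vector count near n is expected and not a pathology.
- **Permutation metric** is the same internal CV accuracy as the observed
  statistic, with fold structure re-drawn per permutation; the add-one
  formula keeps p in (0, 1].
- **Degenerate paths** are explicit: an empty univariate filter or empty
  consensus produces a "no-signal" result that evaluates at chance
  (AUC 0.5) instead of crashing; single-class folds are prevented by
  stratification; PCA components are sign-fixed (largest-magnitude loading
  positive).
- **Edge order** is the upper triangle read row-major over the packaged
  region list (0-based, i < j); the AAL-90 labels use the dotted left/right
  convention ("Frontal.Mid.R").

## Problem sizes used by the test suite

Distribution-level properties that are invariant to problem size run at
reduced scale so the suite stays fast: the 50-seed leakage guard and the
consensus-monotonicity check use 20 regions (190 edges), 12 + 12 subjects,
100-tree forests and 5 folds; the permutation-calibration check uses B = 19
at 3 folds. The headline end-to-end checks (permutation floor at d = 2;
median external AUC over 5 seeds at d = 1.2) run at the full study scale of
23 + 21 subjects and 4005 edges with the default configuration.

## Known limitations

- The univariate screen's descriptive arm (full-sample Table-style counts)
  intentionally differs from the leakage-safe arm (training-set-only
  filter); only the latter feeds the classifier.
- Hierarchical-clustering distance/linkage and the PLS-DA VIP weighting
  (cumulative over both components) are conventions chosen here; both are
  stated knobs rather than universal standards.
- The coupled-oscillator generator models one carrier per planted pair;
  regions participating in several pairs are renormalised only
  approximately.
- rRF-FS hyperparameters (tree count, drop fraction, importance metric)
  trade compute for ranking stability; all are config knobs and the
  defaults are documented above.
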