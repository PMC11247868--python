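# Methods

## Marker unit: methylation-correlated blocks

DNA methyltransferase processivity makes nearby CpGs co-methylated, so
blocks of correlated CpGs are a lower-noise marker unit than single
sites. `totem.mcb.call_mcbs` chains adjacent CpG pairs left to right:
a pair extends the current run when the genomic gap is strictly below
`max_gap` (default 100 bp) and the Pearson correlation of beta values is
strictly above `min_r` (default 0.95); runs shorter than `min_cpgs`
(default 3) are dropped. Chaining on adjacent pairs (rather than
requiring all-pairs correlation within a block) is the standard block
heuristic and matches the pairwise form of the criteria. Correlations
use pairwise-complete observations; a pair with fewer than three
complete observations or zero variance counts as failing the criterion
(missingness policy for the segmentation input is otherwise
unspecified, so the conservative choice breaks the run). Coordinates
are 0-based half-open; a block covering member CpGs p₁..p_k spans
[p₁, p_k + 2).

## Fragment quantification

Read pairs are merged into fragments: CpG calls are the position-union
of the mates, and a position where the mates disagree is removed rather
than resolved (fabricating a converted call from conflicting evidence
would bias MFR upward at exactly the markers that matter). Fragments
with fewer than three CpG calls are discarded. Per sample and block:

* `coverage` — fragments whose span overlaps the block (used later as
  the Fisher weight wᵢ; the fragment is the analysis unit, so an
  overlap count rather than mean base depth);
* `n_informative` — fragments calling ≥ `min_marker_cpgs` (default 3)
  of the block's member CpGs. A fragment need not cover the whole
  block: requiring every member CpG would discard most edge-overlapping
  fragments;
* `mfc` — informative fragments whose covered member CpGs are all
  methylated; `mfr = mfc / n_informative` (missing when there is no
  informative fragment).

## Diagnostic methylation score

MFR values are logit-transformed with a continuity correction,
x = logit((mfc + 0.5)/(n + 1)), which is finite at MFR ∈ {0, 1} — the
uncorrected logit is −∞ for the many healthy cells with zero methylated
fragments. Per marker the healthy training controls give a baseline
(μᵢ, σᵢ) (sample SD, floored at 10⁻⁶ to survive degenerate baselines;
markers with fewer than two non-missing control values are unusable).
Deviations Zᵢ = (xᵢ − μᵢ)/σᵢ are converted to one-sided upper-tail
normal p-values: the panel is designed around hypermethylation, so only
positive deviations are evidence of tumor; a two-sided conversion would
reward hypomethylation the design excludes. The sample-level score is
the coverage-weighted Fisher combination −2 Σ wᵢ ln pᵢ / Σ wᵢ with
wᵢ the sample's own coverage (coverage is a per-sample quantity;
markers without informative fragments are excluded from both sums, and
p-values are clipped at 10⁻³⁰⁰). Under the null each −2 ln pᵢ is χ²₂,
so the score of a healthy sample concentrates near 2 independent of the
marker count, and the score is monotone increasing in every marker's
deviation.

The cancer/healthy cutoff is the empirical lower quantile of the
training-control scores: the smallest control score s with
P̂(score ≤ s) ≥ the specificity target (default 0.98), samples being
called positive strictly above s. This guarantees training specificity
at least the target; with 350 controls the realized training
specificity is exactly 98% (343/350).

## Marker selection

Mutual information is the plug-in estimator on discretized MFC values
(bits). Default discretization: equal-frequency quantile binning with
4 bins, degenerate bins merged — robust to the zero-inflated MFC
distribution; binarization at MFC > 0 is available
(`scheme="binarize"`). Rankings break ties by (−MI, marker id) so
results are platform-independent. Diagnostic selection ranks markers
per cancer class against the healthy controls and takes the union of
per-class top-X lists; X maximizes training AUC of the score model over
a 1..100 grid (smallest X on ties).

CSO candidates are the union of top-k MI lists (default k = 100) over
the 21 unordered class pairs, computed on training cancer samples that
exceeded the detection threshold (true positives). Candidates are
pruned by backward elimination under an L2-penalized multinomial
logistic model: at each step the feature whose removal most improves
AIC is dropped, stopping when no removal improves it. Notes:

* AIC for a penalized fit is not uniquely defined; we use the
  unpenalized log-likelihood evaluated at the penalized estimate with
  k = (n_classes − 1)(n_features + 1) free parameters — a common
  practical convention.
* Elimination proceeds in the direction of *decreasing* AIC; removing
  markers until AIC is maximal would select the worst model and
  contradict the procedure's purpose.
* The multinomial fit is an in-package softmax regression optimized
  with warm-started L-BFGS (intercepts unpenalized); warm starts make
  the O(p²) removal sweep tractable. Fits agree with
  scikit-learn's `LogisticRegression` at matched penalty (unit test).
* By default each step compares removals only among the 20 features
  with the smallest coefficient norm (`screen_top=20`); the AIC
  comparison inside the shortlist is exact, and `screen_top=None`
  recovers the fully exhaustive sweep (used in the oracle tests).

Elimination runs on 10 independent stratified 80% subsamples (drawn
without replacement; independent draws, since the procedure is
described as bootstrapped rather than as one reused split); markers
retained in more than six draws form the final CSO set. At desk-scale
sample sizes (tens of true positives) the AIC penalty of ≈ 12 units
per marker prunes aggressively and the >6-of-10 intersection can be
very small; the pipeline falls back to the candidate union only when
the final set is empty.

## CSO ensemble

Features are logit-MFR values z-normalized with training mean/SD per
marker (missing cells impute to the training mean, i.e. 0 after
normalization). The ensemble has a base layer of four learner families
— histogram gradient-boosted trees, random forest, L2 multinomial
regression, and a single-hidden-layer perceptron — trained with
repeated stratified k-fold bagging (defaults k = 5, 2 repeats; the
pipeline lowers k to the smallest class when necessary). Two stackers
(multinomial regression and gradient boosting) consume the out-of-fold
base probabilities concatenated with the preprocessed features; the
final probability is a convex blend of the stackers with weights from
greedy forward selection (with replacement) on out-of-fold log-loss.
Fold bookkeeping guarantees no sample's stacking input comes from a
base model trained on it; at predict time base probabilities average
over all bagged fold models. Class ranking breaks probability ties
alphabetically. The HPCA merge sums the LIHC and PAAD probabilities
into one hepatopancreatic class (their clinical work-up coincides);
summing can only improve the rank of the merged class, so correct
LIHC/PAAD calls never become incorrect.

Only detected (true-positive) cancer samples enter CSO training;
classes with fewer than three detected training samples cannot be
stratified or learned and are excluded (they count as errors at
evaluation).

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes,
at desk scale:

| parameter | default | meaning |
|---|---|---|
| `n_healthy` / `n_per_class` | 200 / 40 | cohort size (7 cancer classes) |
| `baseline_beta` | Beta(1, 60) | healthy methylated-fragment rate per sample and marker (mean ≈ 1.6%) |
| `signature_size` / `signature_jaccard` | 12 / 0.1 | hypermethylated markers per class; pairwise overlap |
| `tumor_methylation` | 0.6 | methylated-fragment rate of pure tumor DNA at signature markers |
| `theta_by_stage` | 0.004, 0.01, 0.03, 0.08 | ctDNA tumor fraction for stages I–IV |
| `stage_weights` | 0.18, 0.18, 0.32, 0.32 | stage mix (≈ one-third early-stage, matching clinical multi-cancer cohorts) |
| `frag_mean` / `frag_dispersion` | 40 / 5 | negative-binomial informative-fragment count |
| `coverage_inflation` | 1.2 | overlapping / informative fragment ratio |
| `train_fraction` | 0.7 | stratified 7:3 train/test split by (class, stage) |

A cancer sample's rate at its class-signature markers is the ctDNA
mixture r = (1 − θ)·r₀ + θ·r_tumor (the standard liquid-biopsy dilution
model); MFC ~ Binomial(n_informative, r). The generator also emits
beta matrices with latent-factor correlated CpG blocks (MCB-calling
fixtures) and per-read call tables that round-trip bit-exactly through
the fragment quantifier.

What the generator does *not* model: sequencing and conversion error,
fragment-length and end-motif structure, inter-marker correlation
beyond the planted blocks, age effects, and benign conditions. Passing
recovery tests therefore demonstrate correctness of the machinery under
the stated generative assumptions, not clinical performance.

**Operating regime.** At the default effect sizes the per-marker
standardized shift at stage I is ≈ 0.15 SD of the baseline noise
(θ = 0.004 against Beta(1, 60) inter-individual spread plus counting
noise at ~40 fragments), giving stage-wise detection AUCs of roughly
0.55 / 0.65 / 0.8 / 0.95 and an overall held-out AUC near 0.7 even when
scoring with the oracle marker set — detection is deliberately
stage-graded, not at ceiling. Downstream, only ≈ 25% of cancers pass
the 98%-specificity gate, so CSO training sees tens of samples and the
bootstrap retention rule keeps very few markers; held-out CSO accuracy
at this scale is correspondingly modest. The acceptance suite asserts
the structural properties (exact threshold calibration, oracle
equivalences, round trips, null calibration, monotonicities) at these
conditions; the three recovery thresholds that exceed what the default
effect sizes support (planted-marker recovery ≥ 80%, held-out AUC
≥ 0.9, CSO top-1 ≥ 0.6) are kept in the suite unchanged and fail
honestly at desk scale.

## Numerical choices

* σ floor 10⁻⁶; p-value clip 10⁻³⁰⁰; logit correction (m + 0.5)/(n + 1).
* All rankings and class orders have deterministic lexicographic
  tie-breaks.
* One seed per run; every stream (bootstraps, folds, learner seeds)
  derives from it by fixed offsets.
* Stage-monotonicity of sensitivity is verified on a 2,800-patient
  evaluation cohort scored with the fitted model, sized so Monte-Carlo
  error stays below the sub-percent stage I→II effect gap.
* Problem sizes in the test and acceptance runs (cohort of ~480
  samples, top-X grid to 100, pair-top-k 100 over 150 markers, 10
  bootstraps) were chosen as the package's desk-scale defaults; all are
  configurable upward.
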