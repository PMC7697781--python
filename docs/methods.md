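# Methods

## Model

`smbpls` fits sparse multi-block PLS2 on the horizontally concatenated
superblock of Frobenius-normalized, Pareto-scaled blocks. Several
multi-block PLS variants exist (block-wise deflation, super-score
regression on block scores); the concatenated form was chosen because
Frobenius normalization already puts the blocks on one footing and the
quantities reported downstream — global scores, block scores, per-block
super weights — all fall out of it directly and exactly: with a unit-norm
super weight w partitioned into block slices w_b, the block scores
t_b = X_b w_b sum to the super score and the super weights ω_b = ‖w_b‖²
sum to one per component. Blocks are deliberately *not* rescaled by their
variable counts; the Frobenius norm alone controls block influence.

Sparsity is imposed on the concatenated super-weight vector with one
degree per component, not per block: with degree g and p features,
k = max(1, round((1−g)·p)) entries survive; λ is the (k+1)-th largest
|w_j| and every entry is shrunk by λ (soft thresholding) before
renormalization. Entries tied exactly at λ are zeroed, so fewer than k
may survive (logged); if a tie wipes out the whole vector the first
largest-magnitude entry by index is kept, also logged. The same
first-index rule breaks argmax ties at prediction time.

NIPALS details: the start vector is the Y column of maximal variance
after centering; convergence is declared at a relative score change
≤ 1e−10 with a 500-iteration cap (non-convergence is a warning, the last
iterate is accepted); both X and Y are deflated by the super score
(standard PLS2 deflation). Y is always centered inside the fit and the
centering stored, so predictions are ŷ = X_new B + ȳ with
B = W(PᵀW)⁻¹Qᵀ. With zero sparsity and one block this reduces exactly to
ordinary PLS2 (verified in the tests against an independent
eigen-decomposition of XᵀYYᵀX and against scikit-learn's dense PLS).
Consensus PCA of the same superblock (SVD-based, with the analogous
block score/super-weight decomposition) provides the unsupervised
overview.

## Preprocessing

Order of the modeling chain: Pareto scaling per block, then Frobenius
normalization per block. Pareto first keeps the block-weighting role of
the Frobenius step interpretable; doing it the other way round would let
a block's feature count leak back into its effective weight. All scaling
statistics (per-feature means and √SD divisors, per-block norms) are
estimated on training data only and frozen into a `ScalingState` that
transforms held-out samples identically — inside cross-validation this
happens per fold, so no test statistic ever reaches the model.

Upstream feature filters for untargeted LC-MS tables:

- **Blank filter** — a feature is dropped when its mean blank-injection
  intensity is at least `ratio_threshold` (default 1.0) times its mean
  sample intensity, missing values counting as zero. The threshold
  default is deliberately conservative: only features at least as bright
  in solvent blanks as in samples are treated as contaminants.
- **m/z / RT filter** — masses strictly above 700 Da are discarded
  (the boundary value itself is kept) and retention times outside a
  window are truncated; features lacking the metadata pass unchanged.
- **QC drift normalization** — per feature, a trend (linear by default;
  LOESS with span 0.75 available) is fitted to the QC intensities versus
  injection order, every row is divided by the fitted trend at its own
  injection order, and the feature is rescaled so its QC median is
  exactly preserved. Features with fewer than two usable QC values, or a
  fitted trend that is not strictly positive where needed, pass through
  unchanged with a warning. Note the unit anchor: the QC median of a
  drifted run carries the run's average drift, so the correction removes
  the injection-order *trend* (the quantity that damages downstream
  models) while pinning the absolute scale to the observed QC level; a
  drift-free replicate is recovered up to that per-feature scalar.

Log transforms replace zeros by half the smallest positive value in the
column (or raise, under the `error` policy); negative input always
raises.

## Cross-validation and tuning

Folds are leave-one-subject-out: all time points of one animal form one
test fold, the only split that respects the repeated-measures structure.
The degree of sparsity is optimized greedily per component: for
component a, with g₁…g₍ₐ₋₁₎ fixed, every grid value (default
{0, 0.5, 0.8, 0.9, 0.95, 0.99}) is scored by the pooled out-of-fold MCR
of the a-component model and the argmin is kept, ties resolving to the
smaller degree. The headline SR_CV pools all out-of-fold predictions;
fold-wise MCRs are kept for the standard error. A_Opt is the smallest A
with MCR(A) ≤ min MCR + SE(argmin) (one-standard-error rule); an exact
McNemar test on the pooled predictions is available behind
`selection_rule="mcnemar"`. The whole loop is deterministic given its
inputs.

Two calibration behaviors of this estimator are worth knowing and are
quantified in the test suite:

- A **fixed** (untuned) dense model on label-shuffled data is well
  calibrated: its SR_CV falls in the central 95% binomial band around
  chance in 19/20 seeded replicates. The binomial band is only the
  correct null reference in this untuned setting.
- The **tuned** pipeline deviates mildly in both directions: picking the
  grid argmin inflates the reported SR_CV on null data (selection
  optimism, mean ≈ 0.53 observed), while highly sparse fixed models show
  a below-chance bias (mean ≈ 0.45) because leave-subject-out folds make
  the training class balance anti-correlate with the held-out labels and
  a near-zero coefficient vector lets the majority-class offset dominate
  the argmax. Neither effect is large at this design size (≈ ±0.05), but
  a reported SR_CV after tuning should not be read as an unbiased error
  estimate.

## Biomarker statistics

Biomarkers are the features with a nonzero row in B at A_Opt, grouped by
block and ranked by |coefficient|; a dense model (all degrees zero)
returns everything with a warning. Univariate confirmation is one-way
ANOVA on natural-log intensities with the classification target as the
grouping factor, pooling the other design factors (time points when
classifying diet, and vice versa) — stratified alternatives would need a
mixed model, which is out of scope; pooled ANOVA is anticonservative
when the pooled factor is large, a documented limitation. p ≤ 0.05 flags
significance.

Correlation loadings are plain Pearson correlations of each variable
with the first two super scores, plotted against reference circles of
radius 1 (100% of the variable's variance in the LV plane) and √0.5
(50%). Pre-selection of variables "close to" a class operates on
Euclidean distance in (r1, r2) coordinates, default cutoff 0.3. For the
pairwise heat map, each centered variable is first projected
orthogonally onto the span of the two score vectors (a rank-2
representation, invariant to any invertible re-parameterization of the
plane); p-values use the exact t transform with n−2 degrees of freedom
on the original sample count (the conservative n−3 is available via
`df_policy`). Projections of near-zero norm are flagged missing rather
than producing spurious correlations.

## Synthetic data

The generator emulates the structure the analysis assumes — a two-diet,
15-subjects-per-diet, three-time-point design — with, per metabolomics
block: log-normal intensities (baseline log-mean 10, log-SD 1),
block-diagonal feature correlation (clusters of 10, ρ = 0.5, mimicking
adduct/isotope redundancy of untargeted LC-MS), 20 diet markers shifted
±1.5 log-SD in the LR group with alternating sign, 10 time markers with
a monotone linear trend over weeks, 10 QC injections at regular
intervals, 3 blank injections, 10 blank-only contaminant features, a
multiplicative linear intensity drift of +30% across the run, and 5%
missing samples independently per block (which exercises the
sample-correspondence removal at alignment). The block size of 300
features is a desk-scale stand-in for the thousands of features real
untargeted runs produce. The SCFA panel plants an LR-elevated total
(acetate ×1.5, propionate ×1.25, butyrate ×1.2) and a mild decline of
acetate/propionate over weeks; the taxa block is compositional via a
logistic-normal construction (Dirichlet behind a flag) with 10
diet-shifted taxa.

What the generator does **not** emulate: subject-level random effects
(samples of one animal are independent draws), heteroscedastic or
m/z-dependent noise, batch boundaries, censoring at the detection limit,
and any real 16S processing. Passing recovery tests therefore
demonstrate that the pipeline finds planted multivariate structure of a
realistic size and sign — not that it would perform identically on real
LC-MS data, whose headline figures are expected to be less favorable.

One behavior worth noting: when the planted signal is strong relative to
the design size, several degrees of sparsity (including zero) reach the
same CV-MCR floor, and the ties-to-smaller-degree rule then deliberately
returns a *less* sparse model. Sparse degrees are reliably chosen only
when sparsity genuinely improves the CV error, e.g. with 10 markers
among 500 features the first-component degree lands in {0.8…0.95} and
sparse models beat dense ones in ≥ 4 of 5 seeded replicates.

## Numerical and degenerate-input policy

Zero-variance features are centered but not scaled; zero-norm blocks are
an error; a Y that is constant after centering is an error ("degenerate
Y"); a singular PᵀW is an error rather than a pseudo-inverse, since it
signals duplicated components. CPCA truncates to the matrix rank with a
warning. Proportions over zero totals (SCFA panels, correlation of
constant variables) are NaN-flagged, never silently zero. All
tie-breaks (soft threshold, argmax, grid argmin) go to the first
index/smaller value and are logged. Model archives round-trip arrays
bit-exactly (raw `.npy` payloads in a zip with a JSON manifest).

## Problem sizes

Default test and acceptance runs use the full 90-sample design with
three 300-feature blocks; the cross-validation grid search fits roughly
30 folds × 6 grid values × 2 component counts ≈ 360 models per analysis,
a few seconds on one core. Reduced configurations (6 subjects per diet,
60-feature blocks) back the fast unit tests.
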