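# Methods

## The generative model

Each simulated experiment is a two-class alternating block design
(ABAB…). The defaults are TR = 2 s, 32-s blocks of 16 volumes, and 5,
10 or 15 repetitions per class (160, 320 or 480 acquired volumes).
"Neural" activity is iid N(0, 1) per voxel per volume — by construction
unrelated to the class labels. With signal strength *s* > 0, one
activation pattern per class is drawn with per-voxel sd *s* and added
to every volume of that class **at the neural stage**, before
haemodynamics.

BOLD responses are the neural series convolved per voxel (causal,
discrete, truncated to the input length) with a gamma-family HRF

    h(t) = (t/w)^a exp(-(t/w)/b),   a = 8.6, b = 0.547 s,

sampled at TR multiples. The width scale *w* stretches the time axis
(`h_w(t) = h(t/w)`), moving the peak to `w·a·b ≈ 4.70·w` s and scaling
the FWHM proportionally; this is the cleanest single-parameter notion
of a "shorter" or "longer" haemodynamic response. A rectangular boxcar
kernel (duration `16·w` s) is available to confirm that conclusions do
not hinge on the gamma shape.

Two amplitude conventions are fixed once:

* **Unit-peak kernel.** The raw gamma form spans absurd magnitudes
  (`t^8.6`), and no physical amplitude convention is implied by the
  model, so the sampled kernel is normalised to unit peak. Signal
  strength *s* is then comparable across widths: width changes affect
  temporal integration, not raw gain.
* **Kernel support.** The kernel is truncated where it falls below
  10⁻⁴ of its peak, but never shorter than 32 s. An explicitly given
  support must contain the peak time, otherwise configuration fails.

After convolution the first `trim_volumes` (default 8 = 16 s) volumes
of every block are discarded, removing the transition period in which
the previous block's response dominates. All per-experiment volume
counts quoted anywhere in the package refer to *acquired* volumes,
before trimming.

### Spatial signal correlations

Spatially correlated signal is modelled by convolving each class
pattern with a Gaussian kernel of sd `spatial_sigma` (voxel units) on a
1-D circular voxel lattice, truncated at ±4σ. The kernel has **unit
peak, not unit sum**, and the smoothed pattern is not rescaled: each
voxel then pools signal from its neighbours, so the per-voxel signal
variance grows with σ along with the correlation — a crude model of
spatially unspecific vasculature spreading activation. (A sum-one
kernel without rescaling would instead *shrink* the signal with σ and
reverse the direction of the spatial-correlation effect.) The lag-d
autocorrelation of the smoothed pattern is `exp(-d²/(4σ²))` under
either scaling. `SignalSpec(renormalize=True)` restores the per-voxel
sd to *s* after smoothing, isolating the pure correlation effect.

## Classifiers

* **Linear SVM** (`C = 1`, no class weighting): canonical defaults; the
  effects under study are driven by the correlation structure of the
  data, not by the regulariser. Voxels are standardised with
  training-fold statistics only (switchable via `standardize=False`);
  using anything else would add a leakage channel of its own.
* **Pearson template classifier**: a test pattern joins the class whose
  training patterns have the higher *mean* Pearson correlation with it.
  Zero-variance patterns correlate 0 with everything; exact score ties
  fall to a seeded fair coin.

## Cross-validation

* **Random time-point CV**: per repeat, `floor(0.8·n_c)` volumes per
  class (equal counts, so training is exactly balanced) train the
  classifier; all remaining volumes are tested. 100 repeats by default.
* **LBO-CV**: a fold holds out one block from each class and trains on
  the rest, so the binomial "N" equals the blocks per class. With
  `n_pairings = k`, pairing j pairs A-block i with B-block
  `(i + offset_j) mod reps` (offset 0 first, further offsets in seeded
  order), so each block is tested k times, always with a distinct
  partner.
* Under a *global* label shuffle blocks lose their class identity, so
  permuted-label re-runs fall back to the design's geometric pairing of
  consecutive blocks — identical to the label-based pairing on
  unshuffled data, and well-defined on shuffled data.

## Significance procedures

* **Binomial**: one-sided exact tail `P(X ≥ k | N, ½)`. The default
  success count is `k = round(mean performance × N)` — the mean
  accuracy read as a fraction of N coin flips, which is how the test is
  typically (mis)applied to repeated-CV results and the convention
  whose failure mode this package measures: at N = 15 it essentially
  never rejects on null data (k ≥ 12, i.e. 80 % mean, is required),
  while at N = 150 repeated pairings it rejects ≈ 3× the nominal rate.
  The alternative rule `binomial_success_rule='fold_majority'` counts
  folds with a strict majority of test points correct (exact ties to a
  seeded coin, keeping the null per-trial rate at ½); it is even more
  anticonservative under repeated pairings because fold outcomes are
  positively correlated.
* **T-test**: two-sided one-sample test of fold accuracies against
  50 %. Zero-variance inputs are defined as p = 1 (mean = 50) or p = 0
  (mean ≠ 50).
* **Permutation tests**: the observed LBO-CV mean is compared against
  the same statistic recomputed under label permutations — *global*
  (free shuffle over time points) or *balanced block* (whole-block
  reassignment, equal block counts per class, sampled with replacement
  from the `C(2r, r)` balanced assignments). Decision rule: reject iff
  the observed value strictly exceeds the order statistic at 1-based
  index `ceil(0.95·n_perm)` (no interpolation); an add-one p-value
  `(1 + #{null ≥ obs})/(n_perm + 1)` is reported alongside, which is
  never anticonservative. The identity permutation is not forced into
  the null set.

## Seeding and reproducibility

Everything is a pure function of (parameters, seed). Monte-Carlo runs
spawn one `SeedSequence` child per dataset from the base seed, further
split into simulation / CV / test / permutation streams; children are
assigned before dispatch, so `n_jobs > 1` cannot change any number.
Run manifests record the base seed and derivation rule.

## Problem sizes

The Monte-Carlo drivers default to 200–500 datasets and 200
permutations per test. At those sizes the binomial 95 % confidence
interval on an estimated false-positive rate has half-width ≈ 2–5
percentage points, which resolves the effects of interest (5 % vs 16 %
vs 35 %) cleanly; full-scale runs (1000–5000 datasets) are a matter of
passing larger `n_datasets` / `n_perm`. The HRF-width sweep uses 300
datasets per cell so that adjacent-cell differences of ~3 percentage
points are resolved at several standard errors.

## What the simulator does and does not capture

The generator reproduces exactly the mechanisms the statistics depend
on: block-structured labels, HRF-induced temporal autocorrelation,
optional class signal of controlled strength and spatial correlation.
It deliberately omits much of real fMRI: voxels live on a 1-D lattice
with no vasculature geometry; neural noise is white in time and
independent across voxels (no noise correlations, which can offset
signal-correlation gains); there is no scanner drift, breathing, head
motion, or slow confounds beyond the HRF. Passing tests therefore show
that the analysis procedures behave as claimed *under these
mechanisms* — in real data, longer-range temporal correlations can only
widen the gap between the parametric tests and the block permutation
test, and quantitative rates will differ per dataset. The simulation is
a measurement of procedures, not a proxy for a significance test on any
particular real dataset.

## Known limitations

* Two classes only; multi-class and event-related designs are out of
  scope (the block permutation logic generalises, the pairing schedule
  does not).
* The SVM hyperparameters and standardisation choice shift quantitative
  rates slightly; the qualitative orderings (random > LBO inflation,
  global > block variance, parametric > nominal FPR) are insensitive.
* Group-level (across-subject) inference is not modelled.
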