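# Methods

## Feature extraction

All nine statistics are computed from a rectangular region of interest
(ROI) of a 2-D temperature map in °C; ROI coordinates are 0-based and
half-open so they compose directly with array slicing.

Mean and variance use the raw (unquantized) temperatures; the variance
is the population (÷N) form. Every other statistic is computed on the
quantized map: temperatures rounded to 0.1 °C with half-away-from-zero
rounding (the MATLAB-style convention; numpy's default banker's
rounding would shift level boundaries), min-shifted, scaled by 10 and
cast to integers, so one level = 0.1 °C and the minimum level is
exactly 0. Skewness and kurtosis are population central-moment ratios
m₃/m₂^{3/2} and m₄/m₂² (Pearson kurtosis, normal reference 3) of the
level distribution; both affine-match the raw-temperature values up to
rounding. Entropy is Shannon entropy in bits of the level histogram.

The co-occurrence matrix tallies *ordered* level pairs at a fixed pixel
offset, default (0, +20) — 20 px horizontally — normalized to total
mass 1, with pairs restricted to the ROI interior. Counting is
single-direction (asymmetric) by default, matching classical GLCM
toolboxes; a `symmetric` flag doubles the directions. The full
quantized level range is used with no re-binning to a coarser gray
scale, because the 0.1 °C quantization *is* the discretization of this
analysis; `rebin`/`n_gray_levels` expose optional coarsening since it
changes the contrast and energy scales. An ROI narrower than the offset
has no pairs and raises an explicit error.

Degenerate inputs are defined, not NaN: a constant ROI gives skewness,
kurtosis and GLCM correlation 0, homogeneity and energy 1, entropy and
contrast 0 — so clustering never receives undefined values.

## Embedding

t-SNE is implemented directly from its equations (no tree
approximations; at N ≈ 10 everything is dense). Per-point bandwidths
σ_i are found by bisection on β = 1/(2σ²) (bracket grown by doubling,
≤ 64 iterations) so each row's perplexity 2^{H(P_i)} hits the target
within 1e−5; non-convergence raises with the row and bracket. The
low-dimensional similarities use the Student-t kernel normalized over
**all** ordered pairs — the standard joint formulation; a row-style
normalization would not define a single distribution Q.

Optimization: Gaussian initialization (sd 1e−4), 1000 iterations,
learning rate 100, momentum 0.5 switching to 0.8 at iteration 250, and
early exaggeration ×4 for the first 100 iterations. Two refinements
proved necessary on tiny cohorts. First, the delta-bar-delta gains of
the reference t-SNE optimizer (per-coordinate step grown by +0.2 when
gradient and velocity disagree in sign, shrunk ×0.8 otherwise, floor
0.01): without them, plain momentum left a single point trapped on the
wrong side of the embedding in roughly a fifth of multi-week runs even
though the feature space was perfectly separated. Second, a monotone
safeguard: if a momentum step increases the current phase's objective,
the step is reverted, velocity and gains are reset, and a plain
gradient step is halved until the objective decreases — so the KL
trace never increases outside the early-exaggeration phase. The trace
is recorded against the true (un-exaggerated) P.

Features are standardized (population z-score per column, constant
columns to zero) before embedding by default: the nine features span
about four orders of magnitude in units, and without scaling the
variance column dominates all distances. Perplexity defaults to 3 —
with 10 points, the effective-neighbor count must sit well below N and
near the within-group size of 5.

## Clustering and scoring

k-means uses Lloyd iterations stopped when the partition no longer
changes, with distance-weighted (k-means++ style) seeding and 10 seeded
restarts scored by within-cluster sum of squares. For k = 2 on small
inputs (N(N−1)/2 ≤ 128 pairs) every distinct point pair is additionally
used as a deterministic initialization; random restarts alone missed
the global WCSS optimum on rare instances. An emptied cluster is
re-seeded at the point farthest from its centroid.

The detection rate scores assignments against the true binary groups
under the best injective cluster→label mapping: with k = 2 this is the
better of the two labelings, so a perfectly flipped clustering still
scores 1.0. Chance level for 5+5 labels under this scoring is well
above 0.5 (the best permutation is taken after seeing the split),
which is why the null-calibration check uses a median threshold of 0.7
rather than 0.5.

Weekly analysis concatenates each mouse's feature vectors from week 2
through the analysis week W (dimension 9·(W−1)); baseline and week-1
data may exist in a manifest but are excluded by default. Multiple
images per (mouse, week) are aggregated by the mean feature vector
(median/first available).

## Group comparison

`compare_groups` returns the Mann–Whitney U of the first sample
(midranks for ties) and a two-sided p-value. For both n ≤ 10 the p is
exact by full enumeration of the C(n₁+n₂, n₁) label arrangements,
defined as P(|U − n₁n₂/2| ≥ |U_obs − n₁n₂/2|) — the U distribution is
symmetric about n₁n₂/2 even under ties. At the cohort's n = 5 + 5 the
smallest attainable two-sided p is 2/252 ≈ 0.0079. Larger samples use
the tie-corrected normal approximation. Identical samples give p = 1.
No multiple-testing correction is applied across the nine features;
the comparison is reported per feature.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline relies
on, not the physics of the animal:

    T(r,c) = base_temp + gradient·c/(cols−1) + A·Z(r,c;ℓ) + ε(r,c)

with Z a zero-mean correlated Gaussian field (white noise smoothed by a
Gaussian kernel of length ℓ, then rescaled to unit empirical variance)
and ε i.i.d. sensor noise. Defaults: 64×64 maps, base 34 °C and a
1 °C lateral gradient (plausible for depilated mouse abdominal skin; no
value is dictated by data), noise sd 0.1 °C from the camera's 100 mK
thermal sensitivity, 5 mice per group imaged at weeks 2–5. The disease
signature is a larger amplitude *and* a shorter correlation length
(0.6 °C at 4 px vs 0.15 °C at 12 px), which jointly raises variance,
entropy and contrast and lowers homogeneity and energy — the direction
observed for diseased livers; the diseased amplitude grows by a factor
(1 + 0.1·week) to emulate progression. The effect size in °C on the
skin is not constrained by published data; these defaults are
direction-calibrated, so passing end-to-end tests shows the pipeline
recovers a structure of the assumed kind, not that real mice are this
separable. Not modeled: anatomy, perfusion, bioheat transfer,
radiometric camera effects beyond additive Gaussian noise, or
between-image registration error.

Every (mouse, week) image draws from its own random substream keyed by
(cohort seed, group code, mouse index, week) via `SeedSequence`, so
cohorts are bit-reproducible independently of generation order.

## Problem sizes and determinism

All shipped analyses run on 64×64 (or smaller) maps with N = 10 mice;
the full four-week experiment takes ~1 s, and the replicate suites used
in the tests (20 strong-effect and 50 null cohorts) complete in well
under a minute. Every stochastic entry point takes an explicit seed and
is exactly reproducible under it.

## Known limitations

* Rectangular ROIs only; the original analyses used user-drawn regions.
* No radiometric-container decoding — inputs are plain CSV/TIFF °C
  matrices.
* The rounding of temperatures lying exactly halfway between 0.1 °C
  levels depends on their binary representation (e.g. 30.05 stored as
  30.049999… rounds down); quantities built from 0.1-multiples are
  exact.
* k-means global optimality is guaranteed-by-sweep only for k = 2 on
  small N; larger problems rely on the seeded restarts.
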