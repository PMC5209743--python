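# Methods

This note records the models, conventions and design choices behind
`chromatex`, in the order the pipeline runs.

## Image preparation

A nucleus enters the texture engine as a 2-D image: z-stacks are
**average-projected** (arithmetic mean over z; not maximum projection —
the mean preserves relative intensity structure across planes).
Background is removed by grayscale **morphological opening** with a disk
(default radius 50 px at 1024 × 1024, scaled proportionally to the image
side), a deterministic rolling-ball-style estimate; the result is
clipped at zero and is idempotent. **Segmentation** is Gaussian
smoothing (σ = 2 px) → Otsu global threshold → hole filling → largest
connected component of at least `min_area_px`. These steps are standard
high-content practice; the upstream acquisition software that inspired
them does not document its parameters, so the values here are the
package's own defaults and are all configurable.

Two-channel handling: by default the green (H3K4me3) and red (H3K27me3)
channels are each min-max normalized over the shared nucleus mask and
averaged with weights (0.5, 0.5) into one composite image, so exactly
104 descriptors describe one nucleus. A per-channel mode (2 × 104
descriptors) is deliberately not the default.

Intensities are **quantized** to N<sub>g</sub> levels by min-max
binning over in-mask pixels: level = min(N<sub>g</sub>−1,
⌊(v−v<sub>min</sub>)/(v<sub>max</sub>−v<sub>min</sub>)·N<sub>g</sub>⌋),
all zeros when the range is zero. The rule is invariant under any
strictly increasing affine intensity transform, which makes the whole
descriptor invariant to gain and offset changes. Defaults:
N<sub>g</sub> = 16 for sliding-window maps (a 9 × 9 window holds ~288
symmetric pairs, enough to populate a 16-level GLCM), N<sub>g</sub> = 32
for whole-image GLCMs.

## Texture engine

GLCMs accumulate over the four standard offsets
{(0,d), (d,0), (d,d), (d,−d)} symmetrically (each pair counted in both
orders); both pixels of a pair must be in-mask. Distances d = 1 and
2 px. Conventions in the 13 Haralick statistics:

* entropies use log base 2 (bits); 0·log 0 ≡ 0;
* *sum variance* is the variance of the sum histogram about the sum
  average (the classic 1973 text substitutes the sum entropy here, a
  known erratum we do not reproduce);
* *variance* ("sum of squares") is taken about the marginal mean;
* correlation and the first information measure return 0 when a
  marginal variance or the entropy denominator vanishes; the second
  information measure uses the classic form
  √(1 − e^(−2(HXY2−HXY))) with entropies converted to nats inside the
  exponential, clamped to [0, 1];
* the 14th Haralick feature (maximal correlation coefficient) is
  excluded; the descriptor uses thirteen.

The "four statistical values" are taken as the mean, sample standard
deviation (n−1), biased moment skewness m₃/m₂^1.5 and biased excess
kurtosis m₄/m₂²−3 of each feature's **sliding-window map** over all
valid in-mask pixels (windows with fewer than `min_pairs` = 8 pairs are
invalid). Four whole-image directional feature values alone could not
support meaningful skewness/kurtosis, which is why the windowed
population is the default; a `directional` mode computing the moments
over the four per-direction whole-image values exists for comparison.
Canonical order is feature-major (Haralick 1973 order), then statistic
(mean, std, skew, kurt), then distance (1, 2):
`energy_mean_d1, energy_mean_d2, energy_std_d1, …`.

The inner loops (per-window GLCM accumulation and feature evaluation)
are numba-compiled; a single jitted kernel serves both the whole-image
and windowed paths, and the test suite checks it against an independent
pure-Python pair-enumeration oracle to 1e−10.

## Analytics

* **t-test matrix**: equal-variance two-sided Student per descriptor
  (Welch behind a flag). Heat maps report raw p-values; a
  Benjamini–Hochberg column is available but off by default, because the
  treated-vs-untreated heat map this mirrors annotates, rather than
  filters by, significance thresholds.
* **PCA**: columns z-scored (zero-variance columns get unit scale),
  top-3 eigenvectors of the correlation structure, each loading's sign
  fixed so its largest-magnitude coefficient is positive; scores are the
  standardized data projected on the loadings.
* **Classifier**: linear SVM, C = 1, trained on 3-D PC scores of the
  two calibration cohorts ("open" = suppressed repressive-mark
  deposition, "closed" = suppressed activating-mark deposition); margin
  positive on the open side. A 104-D standardized-feature mode exists
  behind a flag; 3-D is the default. Evaluation is stratified 5-fold
  cross-validation (folds capped at the smallest class size), refitting
  standardization, PCA and SVM inside every training fold; sensitivity
  TP/(TP+FN) and specificity TN/(TN+FP) are reported per class with
  macro averages.
* **k-means**: Lloyd's algorithm in 3-D score space, Euclidean metric,
  10 seeded restarts, best inertia kept; centroid-to-centroid distances
  exposed.
* **Phenotype parsing index**: the one-sentence description this
  realizes ("averaging eigenvector coefficients of centroid
  coordinates") is ambiguous, so the default is the construction that
  provably satisfies the one hard constraint — calibration cohorts at
  the extremes: the signed scalar projection of a centroid onto the
  closed→open axis, affinely scaled so PPI(open ref) = +1 and
  PPI(closed ref) = −1. The literal coordinate-mean reading ships as
  `mode="coordinate_mean"`.
* **Open chromatin index**: raw OCI =
  (k4_eu/k27_eu)/(k27_het/k4_het); reported on log2 scale by default so
  balanced chromatin is 0 and closed states are negative (a raw positive
  ratio could never be negative, yet closed states must plot below
  zero). Optional +0.5 pseudocount tolerates zero counts.
* **FRET**: corrected sensitized emission F = B − bA − cC with
  b = B/A and c = B/C from single-labeled references; E = max(0, F)/C.
  The donor/acceptor cross-factor a = A/C is recorded on the sample but
  unused by the default correction, whose full published form is not
  recoverable; this is flagged here deliberately.

## Synthetic phantoms

The generator emulates exactly the image properties the texture
descriptor is sensitive to, driven by a latent openness θ ∈ [0, 1]:

| parameter | default | meaning |
|---|---|---|
| shape | 256 × 256 px | desk-scale; 1024 × 1024 mirrors the acquisition geometry |
| semi-axes | (0.35, 0.27)·side, 10 % jitter | elliptical nucleus, random orientation |
| ℓ_green | 1.5 + 3(1−θ) px | green-field correlation length (finer when open) |
| ℓ_red | 1.5 + 6(1−θ) px | red-field correlation length (coarsens faster) |
| peripheral bias | 0.8(1−θ) | radial ρ² weight on the red field (rim aggregation) |
| channel balance | θ | expected green share of total signal |
| photon gain | 200 | per-channel in-mask mean photons at share 0.5 |

Each channel is a Gaussian random field (spectrally low-pass-filtered
seeded white noise at its correlation length, mean-offset and rectified
to non-negative), the red field multiplied by the radial weight, each
field normalized to in-mask mean 1 and scaled to 2·share·photon_gain
expected photons, then Poisson-sampled. Because the mean field is 1, the
relative RMS shot noise is ≤ 1/√gain, so phantoms converge to their
noiseless fields at high gain. Cohort members draw counter-based child
seeds (`SeedSequence(master, spawn_key=(condition, index))`), making
cohorts order-independent and bit-reproducible from their provenance
record.

Synthetic immunogold tables draw k4_eu ~ Binomial(n_eu, σ(κ(θ−0.5)))
and k27_het ~ Binomial(n_het, σ(κ(0.5−θ))) with the logistic σ and
contrast κ = 4, so the expected log2 OCI ≈ 2κ(θ−0.5)/ln 2 is zero at
θ = 0.5 and strictly increasing in θ.

What the phantoms do **not** emulate: microscope optics (no PSF, no
depletion-beam physics), chromocenter-like discrete blob anatomy,
inter-nucleus intensity variation from staining efficiency, and
multi-nucleus scenes. Passing tests therefore demonstrate that the
pipeline recovers latent texture/balance/localization differences from
noisy images — not that real chromatin states are classified with any
particular accuracy.

## Problem sizes and numerical choices

The test suite and acceptance script run simulations at desk scale,
chosen once: the two-cohort classification study uses θ = 0.1 vs 0.9
with 20 nuclei per condition at 256 × 256 px; gradient studies use
128 × 128 px phantoms with 5–12 nuclei per condition over 5- to
20-point θ grids; the resolution-degradation study uses a θ = 0.2/0.8
cohort (n = 10 per class) over median kernels {1, 3, 7, 15}. On the
degradation study: small median kernels can *raise* accuracy for weakly
separated cohorts by suppressing Poisson noise before erasing texture,
so the monotone-degradation property is stated (and tested) for a
strongly separated cohort, where it holds with accuracy starting — and
staying — at 1.0 until texture is destroyed.

Ties and degeneracies: quantization maps a zero-range nucleus to level
0 everywhere (descriptors then take their closed-form constant-texture
values); zero-variance descriptor samples return skew = kurt = 0;
coincident calibration cohorts trigger a degenerate-margin warning, and
coincident PPI references raise an error rather than returning ±∞.

## Known limitations

* Whether published descriptors were computed on one channel, the
  overlay, or both channels per nucleus is not documented anywhere we
  can recover; the 0.5/0.5 composite is this package's choice.
* The windowed realization of the four map statistics is likewise an
  informed reconstruction (see above), not a verbatim port of the
  original (unreleased) analysis script.
* The FRET correction omits the donor/acceptor cross-factor *a* (see
  Analytics).
* Haralick descriptors are rotation-aggregated but not scale-invariant:
  comparisons are only meaningful at a fixed pixel size, which the I/O
  layer therefore tracks explicitly.
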