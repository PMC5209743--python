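# chromatex

High-content texture analytics of nuclear histone-mark organization.

Stem cells re-organize the activating mark H3K4me3 and the repressive
mark H3K27me3 inside the nucleus as they commit to a lineage: chromatin
"opens" (fine, dispersed euchromatic texture) or "closes" (coarse
heterochromatic aggregates drifting to the nuclear periphery).
`chromatex` turns two-channel fluorescence images of these marks into a
quantitative per-nucleus fingerprint and uses it to parse cell
phenotypes, for imaging groups who want a label-level readout of
chromatin state without bulk assays.

## The method

For each segmented nucleus the package computes **grey-level
co-occurrence matrices (GLCMs)**: for quantized intensities
*i*, *j* ∈ {0, …, N<sub>g</sub>−1}, the symmetric joint probability
p(i, j) of observing levels *i* and *j* at pixel pairs separated by
distance *d* along the four standard directions. From each GLCM the 13
classic Haralick statistics are evaluated — energy Σp², contrast
Σ(i−j)²p, correlation, variance, inverse difference moment, the sum- and
difference-histogram statistics, entropies (in bits), and the two
information measures of correlation. GLCMs are computed in a sliding
window (default 9 px) around every in-nucleus pixel, yielding 13 feature
maps per distance; the **mean, standard deviation, skewness and
kurtosis** of each map, at distances *d* = 1 and 2 px, give the

> 13 features × 4 statistics × 2 distances = **104 descriptors per nucleus**.

On top of the descriptors the package provides the calibration
analytics: per-descriptor Student t-test matrices, 3-component PCA of
the standardized descriptors, a linear SVM calibrated on chemically
"opened" vs "closed" cohorts (margin > 0 ⇒ open), k-means centroids in
PC space, the **phenotype parsing index** (PPI; the signed position of a
condition's centroid on the closed→open calibration axis, scaled so the
calibration cohorts sit at −1 and +1), the **open chromatin index**
(OCI; log2 of (K4<sub>eu</sub>/K27<sub>eu</sub>)/(K27<sub>het</sub>/K4<sub>het</sub>)
immunogold counts), and a sensitized-emission FRET efficiency
E = max(0, B − bA − cC)/C.

Because no imaging data ships with the package, a seeded **phantom
generator** produces two-channel nuclei whose texture granularity,
peripheral aggregation of the red channel and green/red balance all vary
with a single latent openness parameter θ ∈ [0, 1], plus matched
synthetic immunogold tables — every stage of the pipeline is testable
end to end.

## Worked example

`examples/02_parse_phenotypes.py` simulates five conditions along an
openness gradient, calibrates on the extremes and parses the rest:

```
condition   theta    PPI
theta_0.1   0.10  -1.000
theta_0.3   0.30  -0.697
theta_0.5   0.50  -0.025
theta_0.7   0.70   0.323
theta_0.9   0.90   1.000
cross-validated macro sensitivity/specificity: 0.90/0.97
```

The calibration extremes land at −1/+1 by construction; the
intermediate conditions fall between them in openness order, i.e. the
104-descriptor fingerprint recovers the latent chromatin state. The
other examples cover single-nucleus descriptor extraction, the OCI/FRET
calculators, and the loss of parsing power under median-filter
resolution degradation.

A thin CLI mirrors the workflow for shell use:

```sh
chromatex simulate --seed 5 --theta 0.2 --theta 0.8 --n-per-condition 4 --out images/
chromatex features --input-dir images/ --seed 5
chromatex train --descriptors chromatex_out/descriptors.csv \
    --open-condition theta_0.8 --closed-condition theta_0.2
```

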