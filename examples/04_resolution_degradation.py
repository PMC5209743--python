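"""How digital resolution loss erodes phenotype parsing.

Median-filters a fixed two-class synthetic cohort with growing kernels
before descriptor extraction and reports the cross-validated accuracy at
each kernel.  Texture classification relies on fine intranuclear
structure: as kernels grow large, accuracy collapses toward chance
(0.5).  For moderately separated cohorts like this one, small kernels
can transiently help by suppressing shot noise; for strongly separated
cohorts the accuracy is monotonically non-increasing.
"""

import chromatex as cx

cohort = cx.synth_cohort(
    [0.3, 0.7], 8, cx.PhantomSpec(shape=(128, 128)), seed=31,
    labels=["more_closed", "more_open"],
)
print("median kernel -> cross-validated accuracy")
for kernel in (1, 3, 7, 15):
    descriptors = cx.cohort_descriptors(
        cohort, pre=cx.PreprocessConfig(median_kernel=kernel)
    )
    accuracy = cx.evaluate_classifier(descriptors, seed=31).accuracy
    print(f"  {kernel:2d} -> {accuracy:.2f}")
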