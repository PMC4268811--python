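"""Equator/midline partitioning and repeated G-tests per strain and sex.

Each retina is split at the equator (dorsal vs ventral) and at the
central column (anterior vs posterior); pale enrichment of a half is its
percentage-point deviation from the whole retina, and replicate retinas
of one group are combined with the pooled/heterogeneity G decomposition.
"""

import retmosaic as rm

maps = rm.generate_cohort(rm.default_cohort_design(seed=0))
report = rm.region_test_report(maps, axis="anteroposterior")

cols = ["strain", "sex", "n_retinas", "mean_deviation", "g_pooled", "p_pooled", "p_het"]
print(report[cols].round(4).to_string(index=False))
print()
print(
    "mean_deviation is the anterior half's pale percentage minus the whole\n"
    "retina's (negative = posterior-enriched). The ZOM4 groups show clear\n"
    "posterior enrichment (pooled G significant); the heterogeneity p\n"
    "checks that replicate retinas agree before the pooled test is read."
)
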