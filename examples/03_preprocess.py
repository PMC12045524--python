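"""Variable constructions: carrier coding, cosine hour, PAL adjustment,
and covariate-adjusted percentiles against a synthetic reference cohort.
"""

from supergee import (
    CohortConfig,
    adjust_pal,
    carrier_status,
    cosine_hour,
    generate_cohort,
    percentile_vs_reference,
)

print("carrier('3/3') =", carrier_status("3/3"), " carrier('2/4') =", carrier_status("2/4"))
print("cosine_hour(0) = %.3f, cosine_hour(12) = %.3f, cosine_hour(23) = %.3f"
      % (cosine_hour(0), cosine_hour(12), cosine_hour(23)))
print("PAL 20 measured 5.9 years ago projects to", adjust_pal(20, 5.9))

# percentile of a PAL score relative to peers of the same age decade,
# sex and education in a large synthetic reference cohort
reference = generate_cohort(CohortConfig(n=5000), seed=1)
me = {"age": 62.0, "sex": "female", "education": "four-year degree"}
for pal in (10, 22, 34):
    p = percentile_vs_reference(pal, me, reference, "pal_raw")
    print(f"PAL {pal} -> {p:.0f}th percentile for a 62-year-old female college graduate")
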