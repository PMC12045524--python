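"""Generate a synthetic 54-person cohort with the observed marginals.

Exact-proportion sampling reproduces the integer margins of the study
sample: 23 APOE e4 carriers (20 heterozygous, 3 homozygous), 39 female,
and the four-level education split.
"""

from supergee import CohortConfig, carrier_status, generate_cohort

cohort = generate_cohort(CohortConfig(n=54, sampling="exact"), seed=0)
carriers = cohort["apoe_genotype"].map(carrier_status)

print(cohort.head().to_string(index=False))
print()
print("carriers / noncarriers:", int(carriers.sum()), "/", int((~carriers).sum()))
print("genotypes:", cohort["apoe_genotype"].value_counts().to_dict())
print("sex:", cohort["sex"].value_counts().to_dict())
print("age mean (SD): %.1f (%.1f)" % (cohort["age"].mean(), cohort["age"].std(ddof=1)))
print("PAL mean, range:", cohort["pal_raw"].mean().round(1),
      (cohort["pal_raw"].min(), cohort["pal_raw"].max()))
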