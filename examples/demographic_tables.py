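"""Re-aggregate a cohort's demographics into publication-style tables.

Expands the packaged per-drug marginal counts (sex, age bands, reporter
region, worst outcome, indication, report year) into one synthetic record
per case, rebuilds the cohort, and prints the sex and worst-outcome facets
with counts and percentages of each drug's cohort size.
"""
from pvsignal import CohortSpec, build_cohort, read_meddra_map, summarize
from pvsignal.reference import expand_demographics, packaged_path

records = expand_demographics()
drugs = sorted({r.drugs[0][0] for r in records})
meddra = read_meddra_map(packaged_path("pt_soc_map.tsv"))
spec = CohortSpec.create(drugs, "Psychiatric disorders")
summary = summarize(build_cohort(records, spec, meddra), records)

for facet in ("sex", "outcome"):
    print(f"\n== {facet} ==")
    print(summary.to_frame(facet).to_string(index=False))

pooled = summary.POOLED
male = summary.percent("sex", pooled, "Males", ndigits=1)
print(f"\nPooled cohort: {summary.cohort_sizes[pooled]} cases, {male}% male.")
print("Counts in each facet column sum to the drug's cohort size; every "
      "percentage is count/cohort-size, so the table is self-consistent.")
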