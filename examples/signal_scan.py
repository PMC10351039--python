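"""Detect an elevated drug–event reporting rate in a synthetic cohort.

Builds a spontaneous-report stream of 30,000 background cases plus 1,500
sorafenib cases in which "feeding disorder" is reported at 6x its baseline
rate, then runs the four-algorithm disproportionality scan. The elevated
pair should fire all four criteria; the null PTs mostly should not.
"""
from pvsignal import (
    CohortSpec,
    SyntheticConfig,
    build_cohort,
    generate,
    read_meddra_map,
    run_signal_scan,
)
from pvsignal.reference import packaged_path

config = SyntheticConfig(
    seed=1,
    n_background=30_000,
    n_cases={"sorafenib": 1500},
    pt_baseline={
        "feeding disorder": 0.005,
        "insomnia": 0.005,
        "confusional state": 0.004,
        "hypersomnia": 0.003,
    },
    rr_multiplier={("sorafenib", "feeding disorder"): 6.0},
    duplicate_rate=0.0,
    missingness={},
)
records, truth = generate(config)
meddra = read_meddra_map(packaged_path("pt_soc_map.tsv"))
spec = CohortSpec.create(["sorafenib"], "Psychiatric disorders")
results = run_signal_scan(build_cohort(records, spec, meddra))

print(f"{'PT':22s} {'N':>4s} {'ROR (05)':>14s} {'PRR':>6s} {'chi2':>8s} "
      f"{'IC025':>6s} {'EBGM05':>7s} signal")
for r in results:
    print(f"{r.pt:22s} {r.n:4d} {r.ror:7.2f} ({r.ror05:4.2f}) {r.prr:6.2f} "
          f"{r.chi2:8.2f} {r.ic025:6.2f} {r.ebgm05:7.2f} {r.signal}")
print()
print("A pair is a signal when any criterion fires: ROR05>1 & N>=2; "
      "PRR>=2 & chi2>=4 & N>=3; IC025>0; EBGM05>2.")
print(f"True reporting-rate multiplier for feeding disorder: "
      f"{truth.multipliers[('sorafenib', 'feeding disorder')]}x")
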