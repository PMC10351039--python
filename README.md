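# pvsignal

Disproportionality signal detection and descriptive analysis for
spontaneous adverse-event reports (individual case safety reports, ICSRs).

Spontaneous reporting systems such as FAERS collect adverse-event reports
with no denominator: the only way to ask "is event *E* reported unusually
often under drug *D*?" is to compare the pair's reporting frequency with
the rest of the database. `pvsignal` implements that workflow end to end
for people running pharmacovigilance analyses on flat ICSR extracts —
ingestion, duplicate removal, cohort selection by drug and MedDRA System
Organ Class, four classical signal-detection statistics with their decision
criteria, and publication-style demographic tables — plus a synthetic ICSR
generator with known ground truth so that every stage can be validated
without access to a live database.

## The statistics

For a (drug, event) pair the deduplicated case universe is laid out as a
2×2 table — *a* (drug & event), *b* (drug, other events), *c* (other drugs,
event), *d* (neither) — with T = a+b+c+d, N = a, and the shared Wald
log-scale standard error SE = √(1/a + 1/b + 1/c + 1/d):

| Algorithm | Estimate | Lower bound | Signal criterion |
|---|---|---|---|
| ROR | ad/(bc) | ROR·e^(−1.96·SE) | ROR05 > 1 and N ≥ 2 |
| PRR + χ² | [a/(a+b)]/[c/(c+d)]; uncorrected Pearson χ² | — | PRR ≥ 2, χ² ≥ 4, N ≥ 3 |
| BCPNN IC | log₂ of observed/expected, a·T/((a+c)(a+b)) | IC·e^(−1.96·SE) | IC025 > 0 |
| MGPS EBGM | a·T/((a+c)(a+b)) (= 2^IC) | EBGM·e^(−1.645·SE) | EBGM05 > 2 |

A pair is a **signal** when at least one criterion fires. IC and EBGM here
are the simplified closed forms used in published signal tables (no
Bayesian shrinkage, multiplicative interval on the IC value itself); the
EBGM lower bound uses the one-sided 1.645 multiplier, with 1.96 available
via `ebgm_z`. See `docs/methods.md` for why.

Duplicates are collapsed when two reports agree on at least three of the
four key fields (event date, age in whole years, sex, reporter country),
closed transitively; a missing field never counts as agreement.

## Worked example

`examples/signal_scan.py` generates 30,000 background reports plus 1,500
sorafenib reports in which "feeding disorder" is reported at 6× its
baseline rate, then scans the psychiatric-SOC cohort:

```
PT                        N       ROR (05)    PRR     chi2  IC025  EBGM05 signal
confusional state         8    1.57 (0.76)   1.57     1.53   0.30    0.83 True
feeding disorder         53    7.59 (5.52)   7.36   214.30   1.82    4.32 True
hypersomnia               4    0.96 (0.35)   0.96     0.01    nan    0.42 False
insomnia                  7    0.94 (0.44)   0.94     0.03    nan    0.50 False
Total                    69    3.01 (2.33)   2.92    77.22   1.10    2.15 True
```

The injected pair is recovered with ROR ≈ 7.6 against a true multiplier of
6 and fires all four criteria. The null PTs sit near 1; `confusional
state` shows the anticonservatism of the OR-of-four rule — its IC025 is
positive whenever the observed count exceeds expectation, so chance
excesses can flag (quantified in `docs/methods.md`). Other examples cover
duplicate collapsing (`dedup_demo.py`), demographic re-aggregation
(`demographic_tables.py`) and replaying published interval bounds
(`replay_published_bounds.py`).

The same pipeline is scriptable from the shell:

```sh
pvsignal generate --config scenario.yaml --out synth.tsv --truth truth.json
pvsignal dedup    --in synth.tsv --out kept.tsv --dup-report dups.tsv
pvsignal signals  --in kept.tsv --drugs sorafenib,sunitinib --out signals.tsv
pvsignal describe --in kept.tsv --drugs sorafenib,sunitinib --outdir tables/
pvsignal run      --config run.yaml   # all of the above, end to end
```

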