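# Methods

## Data model and scope

The unit of analysis is the individual case safety report (ICSR): one
patient, one or more drugs with role codes (primary suspect, secondary
suspect, concomitant, interacting), one or more reactions coded as MedDRA
Preferred Terms (PTs), indications, outcome codes (death, life-threatening,
hospitalization, disability, congenital anomaly, other) and the source
database's ADR yes/no classification. The ADR flag is treated strictly as
an input column: upstream extraction tools attach it without a published
derivation, so it cannot be recomputed and is never inferred here.

Two flat-file dialects of one column contract are read and written:
`case_per_row` (multi-valued fields ";"-separated) and `reaction_per_row`
(one row per reaction, merged on case id). Dates are ISO 8601 or compact
`YYYYMMDD`; any other form becomes missing with a logged warning. A
malformed field never drops a record; a missing mandatory column is a hard
error. The PT→SOC map is single-axial — each PT belongs to exactly one
System Organ Class — which is a deliberate simplification of MedDRA's
multi-axial hierarchy: the pipeline filters on one SOC at a time, so the
secondary axes would never be consulted. The shipped map covers the
40 psychiatric PTs used in the tests plus common non-psychiatric terms;
analyses on real extracts should supply their own table (`--meddra`).

## Duplicate detection

Spontaneous reporting channels overlap, so the same clinical event often
arrives several times. Two reports are probable duplicates when they agree
on at least **three of the four key fields**: event date, age (compared in
whole years, since ages are reported at mixed precision), sex, and reporter
country. Design choices where the convention leaves room:

* **Missing never matches.** A field missing on either side counts as
  disagreement. Sparse reports would otherwise collapse en masse.
* **Transitive closure.** The pairwise relation is closed with union–find,
  so duplicate groups are well defined even when A~B and B~C but A≁C.
* **Representative.** The member with the fewest missing key fields is
  kept; ties break by earliest report date, then input order.
* **Exactness.** Agreement on ≥3 of 4 fields implies exact agreement on at
  least one complete 3-field projection of the key, so hashing the four
  projections finds exactly the pairs the O(n²) scan finds, in near-linear
  time. The brute-force implementation is retained and cross-checked.

A property of the rule worth knowing: on large files the {age, sex,
country} projection is coarse (tens of thousands of reports share a
triple), so demographically colliding non-duplicates merge. That is the
rule, not an artifact; calibration experiments that need undistorted counts
run with duplicate injection disabled and skip the dedup stage.

## Cohort and contingency assembly

A record enters cell (drug *d*, PT *p*) iff *d* passes the role filter
(default: primary suspect only), *p* maps to the SOC filter, and the
record passes the ADR filter. A case reporting *k* cohort PTs contributes
to each of the *k* cells but once to the drug margin — the standard
PT-level 2×2 convention. The case universe *T* is every deduplicated
record in the input, made explicit rather than inherited from a live
database. When an ADR filter is active it restricts the event column on
both the drug and comparator rows (the comparator should be the same kind
of event), while the universe stays all cases; upstream tools do not
document their convention here, so this one is stated. Per-drug "Total"
rows pool all of the drug's cohort PTs as one composite event (unions of
case sets, not sums, so multi-PT cases are not double-counted).

## The four algorithms

All four share the Wald log-scale standard error
SE = √(1/a + 1/b + 1/c + 1/d) and the multiplicative interval
`point·e^(±z·SE)`:

* **ROR** = ad/(bc), z = 1.96 both sides; criterion ROR05 > 1, N ≥ 2.
* **PRR** = [a/(a+b)]/[c/(c+d)] with the uncorrected Pearson
  χ² = (ad−bc)²T/[(a+b)(c+d)(a+c)(b+d)]; criterion PRR ≥ 2, χ² ≥ 4, N ≥ 3.
* **IC** = log₂[a·T/((a+c)(a+b))]; lower bound IC·e^(−1.96·SE), defined
  only for IC > 0; criterion IC025 > 0.
* **EBGM** = a·T/((a+c)(a+b)) — identically 2^IC, a property the tests
  assert exactly; lower bound EBGM·e^(−1.645·SE); criterion EBGM05 > 2.

Three conventions here differ from the textbook forms and were chosen
because they are what published signal tables of this kind actually use —
verified by replaying printed rows (the Wald SE recovered from each
ROR/ROR05 pair reproduces the printed IC025 and EBGM05 columns):

1. **IC interval is multiplicative on IC itself**, not the BCPNN posterior
   interval. Consequence: IC025 > 0 ⇔ IC > 0, so the BCPNN criterion fires
   for any observed excess, however small. The proper posterior interval is
   deliberately not implemented — it would not reproduce the published
   convention this package targets.
2. **EBGM is the unshrunk observed/expected ratio** (the relative
   reporting ratio), not the gamma–Poisson shrinker. No shrinkage, no
   multiplicity adjustment.
3. **EBGM05 uses z = 1.645** (one-sided 95%), which reproduces the printed
   bounds that the two-sided 1.96 form contradicts; `ebgm_z=1.96` switches
   to the two-sided form.

Because of (1), the OR-of-four signal rule is strongly anticonservative:
in a null synthetic scenario (all multipliers 1) roughly half the cells
flag, driven almost entirely by IC025 > 0 on chance excesses. The recovery
report quantifies this (`null_scenario_signal_pct` in the acceptance
output, ~46% at the default null scenario); users who want a conservative
screen should read the per-algorithm flags, not only the union.

**Zero cells.** Any zero cell leaves the affected statistics undefined
(reported as NA, flags False) and logs the event. The Haldane–Anscombe
+0.5 correction to all four cells is available (`zero_correction=True` /
`--zero-correction`); N always reports the raw co-report count.

**Monotonicity.** ROR and PRR increase strictly in *a* on every table.
The observed/expected ratio (IC, EBGM) does not: d ln f/da = 1/a + 1/T −
1/(a+c) − 1/(a+b) is positive only while *a* is small against both
margins, the regime of every realistic signal table. The property tests
assert monotonicity exactly there.

**Rounding.** Report output prints ratios (ror, bounds) at 3 decimals and
prr/χ²/ic/ic025/ebgm/ebgm05 at 2, half-up; in-memory values are full
precision and percentages are always recomputable from emitted counts.

## Descriptives

A report carrying several outcome codes is classified by its **most
severe** outcome, ranked death > life-threatening > disability >
hospitalization > congenital anomaly > other (death first; the ordering is
a module constant, `SEVERITY_ORDER`, and can be re-ranked). The outcome
facet tabulates Death/Disability/Hospitalization/Life-Threatening; worst
outcomes of other/congenital-anomaly and empty outcome sets fall under
Missing, matching how published tables of this kind leave OT-coded reports
uncategorised. Age bands are closed on both ends (50–64, 65–74, …) with a
dedicated "<18" band rather than merging children into 18–29. Reporter
regions come from a shipped ISO-3166-alpha-2 → region table; Oceania and
Africa map to "Other", unknown codes to Missing. Indications are grouped
by first-match keyword rules (renal → Renal cancer, hepat/liver → Hepatic
cancer, …, fallback Other). Report years before 2013 pool into one
2006–2012 bin, later years are single bins; years outside the window log a
validation warning and count as Missing.

## Synthetic data generator

The generator emulates a spontaneous reporting stream at desk scale, not a
full database: a background of `n_background` reports (default 50,000)
suspecting 20 comparator drugs, plus per-target-drug streams (defaults
150–3,500 cases per drug). Each case draws each psychiatric PT
independently — baseline probabilities 0.0003–0.006 per PT for background,
multiplied by the per-(drug, PT) reporting-rate multiplier for target
cases — and always carries one non-psychiatric filler PT so no report has
an empty reaction list. Demographic margins default to the packaged
reference cohort's printed distributions (≈70% male, ≈72% North America,
hospitalization-dominated outcomes, renal/hepatic-cancer indications) and
missingness rates are derived from the same table's Missing rows (age
≈33%, outcome ≈47%, sex ≈3%, country ≈0.7%), so generated descriptive
tables are visually comparable to real ones. The ADR flag is set with
probability `adr_prob` (default 0.637) on reports carrying a psychiatric
PT.

Duplicates are injected by cloning a case and re-drawing **exactly one**
of the four dedup key fields to a different value, so every injected pair
satisfies the 3-of-4 rule by construction and dedup recall is measurable.
Ground truth (per-cell a/b/c/d, duplicate group assignments, per-case
worst outcome) is recorded after duplicate injection and before
missingness, so a cohort built from the emitted records with missingness
disabled matches it exactly — an invariant the tests check. A fixed seed
makes records, files and truth byte-identical.

What the generator does **not** emulate: reporting dynamics over calendar
time (Weber effect, stimulated reporting), drug–drug interaction signals,
correlated missingness, within-case correlation between PTs, or free-text
narratives. Passing recovery tests therefore demonstrate correctness of
the estimators and plumbing under independent-reporting assumptions, not
robustness to real-world reporting biases.

## Validation experiment sizes

Chosen so the whole suite runs in well under a minute of statistics time
on a single core, while keeping expected cell counts in the regime the
criteria are designed for:

* Formula fidelity: 1,000 random tables, cells 1–10⁵, against an exact
  `fractions.Fraction` oracle (observed worst relative error ~2×10⁻¹⁶);
  χ² cross-checked against `scipy.stats.chi2_contingency(correction=False)`.
* Null calibration: 5 drugs × 40 psychiatric PTs = 200 cells, 2,000 cases
  per drug over a 100,000-report background, multipliers ≡ 1; the median
  PRR across cells sits within 1 ± 0.1 (slightly below 1, as the median of
  a small-count ratio estimator should).
* Strong-signal sensitivity: 20 seeded replicates of a 6× multiplier on a
  0.005 baseline with 1,500 target cases over 30,000 background (expected
  a ≈ 45); all four criteria fire in every replicate.
* Dedup: exact agreement with the brute-force oracle on fixtures up to
  n = 200 over deliberately collision-prone field domains; 100% recall of
  injected duplicates.

## Known limitations

* The interval conventions (multiplicative IC bound, one-sided EBGM05)
  reproduce published signal tables but are not the statistically
  preferred BCPNN/MGPS procedures; treat IC025 > 0 as a weak criterion.
* Replaying printed rows is limited by print precision: bounds recomputed
  from 2–3-decimal inputs can land one unit of the final digit away.
* Single-axial SOC mapping; PT-level analysis only (no HLT/HLGT rollups).
* The 3-of-4 dedup rule over-merges on coarse demographics at scale, and
  no probabilistic record linkage is attempted.
* The ADR flag's semantics are inherited from the data source; analyses
  split on it reproduce the source's classification, whatever it was.
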