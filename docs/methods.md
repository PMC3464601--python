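# Methods

`hddlink` studies a measurement problem in injury epidemiology: hospital
discharge data record *episodes of care*, not people. Where no system-wide
unique patient identifier exists, a single fall-related hip fracture in an
older person can appear as several records — an inter-hospital transfer, a
30- or 120-day readmission, a planned revision procedure, a non-acute
rehabilitation stay — and naive episode counting overstates incidence and
distorts patient profiles. The package implements, end to end, both the
person-linked ("reference standard") and the episode-level ("unlinked")
ways of identifying incident fall-related hip fractures in
community-dwelling people aged 65+, and quantifies the biases of the
unlinked route on synthetic data with known ground truth.

## The synthetic cohort

Real admitted-episodes collections of this type are restricted; the
generator (`hddlink.synthetic`) emulates their structure rather than any
real data. The simulated cohort is the set of people aged 65+ with at
least one fall-related admission during a three-fiscal-year window
(defaults: 1 July 2005 – 30 June 2008, labelled 2005/06–2007/08).

Key generator parameters (all in `SimulationConfig`, all probabilities per
the unit stated):

| parameter | default | meaning |
|---|---|---|
| `n_persons` | 5,000 | cohort size |
| `female_fraction` | 0.72 | share of women among fall-admitted 65+ |
| `nursing_home_fraction` | 0.25 | persons admitted from nursing homes (excluded from the community-dwelling analysis by the admission-source criterion) |
| `fracture_hazard` | 0.50 | probability a cohort member's fall injury is a hip fracture event |
| `second_fracture_prob` | 0.023 | probability a fractured person suffers a second incident fracture inside the window |
| `transfer_prob` | 0.25 | index admission ends in an inter-hospital transfer |
| `readmission_30d_prob` / `readmission_120d_prob` | 0.12 / 0.10 | readmission within 1–30 / 31–120 days of the chain's last discharge |
| `revision_readmission_prob` | 0.30 | a readmission carries only hip-revision procedure codes |
| `nonacute_episode_prob` | 0.20 | a follow-on episode is non-acute care |
| `inhospital_death_prob` | 0.05 | the event ends in in-hospital death (on the last episode of the acute chain) |
| `public_hospital_fraction` | 0.80 | episodes occur in public hospitals (private hospitals expose no usable cross-site identifier) |
| `same_hospital_readmission_prob` | 0.81 | a readmission returns to the previous hospital; combined with the public share this puts roughly 65% of multi-admission patients at one public hospital |
| `per_episode_coding_prob` | 0.75 | a truly present comorbidity is coded on a given episode (administrative under-coding) |
| `hospital_acquired_prob` | 0.05 | a coded condition carries the "arose during episode" onset flag |

Ages are drawn from a monotone (PCHIP) quantile function anchored at
(0, 65), (0.25, 72), (0.5, 81), (0.75, 86), (1, 105) years. A two-parameter
truncated lognormal cannot reproduce this left-skewed profile (its best
fit puts the median near 79.4); the quantile-anchored sampler hits the
target median and interquartile range exactly and gives the population
table an age-band distribution that is exactly consistent with the
sampler.

The gap between first and second fracture admissions is lognormal
(log-median 335 days, log-sd 0.694), truncated below at the 120-day
clearance minimum and above by the study window — as any observed
between-fracture gap in a fixed window must be — giving a realised median
near 320–335 days. Second events draw an external-cause triple
(mechanism W00–W19, place, activity) that differs from the first event's
in all three components; a config switch (`ext_cause_triple_always_differs`)
lets users violate this assumption to study the selection rule's failure
mode. No person has more than two incident events.

Non-hip-fracture fall injuries (wrist, humerus, vertebral and femoral-shaft
fractures, head injuries) are emitted alongside fracture chains so that
specificity has a denominator; about 10% of them carry a non-fall
mechanism code and are dropped at extraction, exercising that filter.

Population denominators are synthetic: each fiscal year's age-sex
population is the quantile-function band shares times a total (default 44
source-population persons per cohort member, which yields admission rates
of a few hundred per 100,000 — the realistic order of magnitude), and the
community denominator subtracts nursing-home residents.

What the generator does *not* emulate: seasonal admission patterns,
hospital-level case-mix differences, coding-quality drift over time, age-
or sex-dependent comorbidity prevalence, and mortality outside hospital.
Passing tests therefore demonstrate correctness of the algorithms under
the stated statistical structure, not performance on any real collection.

## Linkage

`link_records` is a configurable multi-pass exact matcher over standardised
keys with transitive (union-find) merging; it emulates the *shape* of a
production stepwise deterministic linkage system without claiming its
actual pass list. Defaults: (1) sex + date of birth + Medicare number,
(2) sex + date of birth + postcode + country of birth, (3) Medicare number
alone (10-digit format enforced at standardisation). Missing keys never
match. Cluster labels are canonical (ordered by first episode), so output
is independent of input order.

Key corruption defaults (`CorruptionSpec`) are calibrated so the shipped
passes reproduce a documented error regime for this kind of linkage:
1–2% of matched pairs are wrong (false positives, driven mainly by a
shared family-Medicare-card mechanism) and about 15% of same-person
inter-hospital transfer pairs stay unlinked (false negatives). The false
negative rate is scored exactly as that definition: unmatched transfer
pairs over all same-person transfer pairs.

## Case selection

All six algorithms require principal diagnosis S72.0–S72.2 and admission
source "private residence/accommodation". The unlinked scenarios add
exclusions per the shipped flag bundles (see `selection` module docstring);
readmission exclusions use the hospital-generated patient identifier,
which only works when both episodes occurred at the same public hospital.
Gaps are measured as next admission date minus previous discharge date in
whole days; the windows are inclusive (`0 ≤ gap ≤ 30`, resp. 120), and a
new incident under the reference standard requires `gap ≥ 120` — both
window anchors and widths are configurable because printed descriptions of
such rules rarely pin the boundary.

The reference standard orders each person's qualifying episodes
(emergency, acute, non-revision-only; discharge status disregarded) by
admission date. The first founds an incident; a later one founds a new
incident only if the clearance period has elapsed since the *last
discharge of the current incident's chain* (a rolling anchor — the
alternative, anchoring on the index discharge only, would let a long
readmission chain straddle the clearance boundary) and the external-cause
triple differs in all three components. "Revision only" means a non-empty
procedure list consisting entirely of configured revision codes; a
revision code alongside a fixation code does not exclude.

Same-day ties are broken by (admission date, discharge date, episode id),
so selection is deterministic.

## Comorbidity

The Deyo adaptation of the Charlson index is computed from an editable
CSV code map (condition → ICD-10 prefix set, Charlson flag, weight). The
shipped map uses published Deyo/Quan-style ICD-10 prefixes plus five
fall/fracture risk factors (osteoporosis, Parkinson's disease, visual
impairment, deafness, delirium) and ataxia; it is a faithful stand-in for
jurisdiction-specific published lists, not a reproduction, and the engine
is list-agnostic. Severity hierarchies (diabetes with complications over
diabetes; moderate/severe over mild liver disease; metastatic over solid
cancer) apply to index computation only — prevalence tables report both
levels separately, as published profiles do.

Ascertainment searches the index hospitalisation — the first multiday
record of the incident's chain, or the index episode if none is multiday —
plus, with lookback enabled, all earlier records available in the
(fall-related) extract. Only codes flagged present-on-admission count.
Lookback on unlinked data is necessarily restricted to the same
public-hospital pseudo-person; this is exactly the mechanism by which the
unlinked route underestimates prevalence, and the package reproduces it
rather than patching it.

## Evaluation

Accuracy is computed at episode level over the extracted fall-injury
episodes: an episode is a true positive when both the reference standard
and the scenario label it an incident case. True negatives are episodes
neither labels — the largest analytic judgement call in the package, since
discharge collections have no natural non-case unit; the alternative
(event-level matching) is not what published accuracy tables for this
problem use. Confidence intervals are Wilson score by default (exact
binomial and Wald are available); report tables round half-up to one
decimal. Overestimation is `(N_scenario − N_reference)/N_reference × 100`.

Two-sample proportion comparisons use the chi-square test without
continuity correction, switching to Fisher's exact test when any expected
cell is below 5. Age-specific rates are cases per 100,000 community
denominator by fiscal year, sex and 5-year band (65–69 … 85+,
configurable); direct standardisation pools sexes within (year, band) and
weights by a standard population's age structure (default: the synthetic
population itself; any `(age_band, weight)` table can be substituted).

The pipeline evaluates every scenario against *two* reference standards:
one built on the generator's true person partition (pure algorithm bias)
and one built on the linkage output (algorithm bias plus linkage error).
Published analyses necessarily conflate these; separating them is the
main analytical affordance ground truth buys.

## Problem sizes and expected behaviour

Property and recovery tests run at 6,000–20,000 persons; the full
pipeline test and the acceptance script use 10,000 and 20,000 persons
respectively — sizes at which binomial 99% recovery intervals are tight
while a complete run stays in the minutes range. Under default
conditions the base case overestimates incidence by roughly 8–10%, S1 by
more (it readmits in-hospital deaths), S2 and especially S3/S4 by less;
S3's in-hospital-death exclusion makes it slightly *under*-count relative
to the reference (which keeps deaths), so the scenario sharing the
reference's criteria, S4, lands closest — consistent with the published
recommendation of the most stringent unlinked criteria. Unlinked
prevalence estimates sit at or below linked ones for most conditions
because of duplicate denominators and truncated lookback.

## Known limitations

* The generator's nuisance-process frequencies (transfer, readmission,
  death rates) are free parameters documented above; collections differ,
  and no published extract reports them directly.
* Comorbidity prevalence is age- and sex-independent in the generator, so
  confounding of comorbidity by demographic mix cannot be studied.
* Accuracy is defined at episode level; event-level sensitivity would
  differ where a scenario selects a different episode of the same event.
* The linkage emulates exact-match passes only; probabilistic
  (Fellegi–Sunter) linkage and clerical review are out of scope.
* The Poisson time-trend regression over the rate table is deliberately
  out of scope; `rates.csv` is emitted in a shape any GLM tool consumes.
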