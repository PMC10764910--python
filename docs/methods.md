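# Methods

This note documents the models, rules and numerical choices implemented in
`statinsim`, the parameters that matter, what the synthetic-data generator
does and does not emulate, and the package's known limitations.

## Study design being modelled

The pipeline reproduces a cross-sectional EMR analysis: each patient's
**index date** is the date of their last valid LDL-C measurement inside a
one-year selection window (default July 2020 – June 2021). All look-backs
anchor to the index date:

| window | default | used for |
| --- | --- | --- |
| SI look-back | 1095 d (3 y) | prescription-pattern signals, SI events |
| risk-factor look-back | 365 d | hypertension, current smoking |
| CKD look-back | 1825 d (60 mo) | chronic kidney disease |
| unrestricted | — | ASCVD, diabetes, liver disease, gout, hyperuricaemia |

An LDL-C measurement is **valid** if the patient is on no lipid-lowering
therapy (LLT) at the draw, or every active drug class started its current
coverage run at least 28 days (4 weeks) earlier. Supply holes up to the
discontinuation threshold within a class count as refill gaps of the same
regimen, not a new start — otherwise ordinary quarterly refill jitter would
invalidate stable patients' labs. Before index selection, 0.1 % of the
pooled LDL-C values per tail are excluded as laboratory outliers; the
cutoffs use midpoint (Hazen) plotting positions, so tiny samples lose
nothing and a 1,000-value sample loses exactly its minimum and maximum.
All dates are whole calendar days and all intervals half-open `[start, end)`.

## Prescription timelines and discontinuation

Prescriptions carry a supply duration (default 90 days — typical quarterly
prescribing; overridable per row). Discontinuation is measured from **end of
supply**, not prescription date: a 180-day rule on raw prescription dates
would misclassify quarterly refills as discontinuation. Statin-free **gaps**
are holes in the day-level union of supply intervals, including the trailing
hole up to the index date.

* **Long-term discontinuation**: any gap strictly > 180 days in the look-back.
* **Permanent discontinuation**: the trailing gap (last supply end → index)
  strictly > 180 days, i.e. no statin after the gap.
* Consecutive same-regimen prescriptions merge into one episode when the
  hole between them is ≤ 180 days; a regimen (molecule/dose) change always
  starts a new episode. Same-day duplicate statin prescriptions keep the
  higher-intensity, then higher-dose regimen — deterministic and
  conservative for down-titration detection.

Statin intensity comes from a dose-band catalog (low/moderate/high per
molecule). The published registry table behind the original intensity
definition is not public; the default catalog is a conventional reading
(e.g. rosuvastatin 5 mg low, 10 mg moderate, 20–40 mg high; atorvastatin
40–80 mg high) chosen so the specific-switch rule's destination, 5 mg
rosuvastatin, is low-intensity. The catalog is configuration and can be
swapped wholesale. "Low-dose statin" is identified with low intensity, as
the two are used interchangeably in the source rule table.

## SI classification

Signals computed per patient: same-/different-molecule down-titration (a
later episode of strictly lower intensity rank, any pair), statin switch
(molecule change between consecutive episodes), the specific switch
atorvastatin/simvastatin → 5 mg rosuvastatin or any-dose
pravastatin/fluvastatin, documented SI note / statin-associated muscle
symptoms (SAMS) / other SI events from the diagnosis stream, intermittent
dosing, low-dose latest statin, non-statin LLT at index, and the
discontinuation flags above.

The rule set is declarative — named boolean expressions over signal names in
the config file — because the source rule table's row/column structure is
ambiguous in flattened text. The default reading preserves the load-bearing
prose distinction exactly:

* **absolute SI** = permanent discontinuation AND any of {documented SI
  note, SAMS, other SI event, down-titration, switch, intermittent dosing,
  low-dose latest statin};
* **partial SI** = continued statin use (no gap > 180 d, statin active at
  index) AND any of {specific switch to low, different-molecule
  down-titration, documented SI note, same-molecule down-titration with
  switch, low-dose statin plus non-statin LLT};
* otherwise **none**. Absolute is evaluated first; a patient satisfying both
  is absolute (permanent discontinuation dominates clinically). Statin-naïve
  patients with no SI events are none — never intolerant by definition.

**Intermittent dosing** is not defined in the source prose; the default is
≥ 2 supply gaps each in (60, 180] days: gaps ≤ 60 days are refill noise, and
> 180 days is discontinuation by the rule above. The lower bound is
configurable (`intermittent_min_gap_days`).

## Risk categorisation

A configurable rule table implements the two-category ESC/EAS-2019 reading:
very-high = documented ASCVD (coronary, cerebrovascular or peripheral
arterial disease), chronic kidney disease, or diabetes with both additional
risk factors (hypertension and current smoking); high = diabetes otherwise,
or hypertension with current smoking; neither → excluded from the study
population. Organ-damage modifiers for diabetes are approximated by the
risk-factor count because the data model has no organ-damage category.
Targets are strict: LDL-C < 55 mg/dL (very-high), < 70 mg/dL (high).

## Treatment simulation

Per replicate: patients at goal at baseline receive nothing; patients not at
goal and not on ezetimibe receive one draw of the ezetimibe effect; patients
already on ezetimibe pass through with their measured LDL-C (it already
reflects ezetimibe); patients still above goal receive one bempedoic-acid
draw from the model matching their baseline statin stratum (moderate/high
intensity vs low/none). Effects multiply the current LDL-C.

Fractional reductions follow Beta(α, β) fitted by the method of moments,
ν = m(1−m)/s² − 1, α = mν, β = (1−m)ν, for both drugs (both published
moment pairs are beta-feasible; the ezetimibe fit gives α ≈ 1.617,
β ≈ 5.444). A zero-SD **degenerate mode** makes every draw equal the mean,
which turns the whole Monte Carlo into a hand-checkable deterministic
computation — the oracle used in the tests. Because beta support is [0, 1],
no simulated patient's LDL-C ever increases; real patient-level trial data
contain increases, so simulated dispersion at the patient level is slightly
optimistic in the upper tail.

Monte Carlo protocol: `n_runs` (default 10,000) independent replicates, one
RNG substream per run spawned from the master seed; within a run, draws are
consumed in sorted patient-id order, so results are bit-identical for a
given seed and independent of input row order. Draws are independent across
patients, drugs and runs (no persistent responder effect). Aggregation is by
medians over runs: the within-run mean LDL-C (median-of-means), the
within-run median LDL-C, and the within-run count at goal. Median counts can
be half-integral for even `n_runs`; attainment proportions are computed on
the unrounded median and displayed to one decimal percent, round-half-up.
Attainment is reported against two denominators, both labelled: the cohort
entering the simulation (cumulative) and the patients above goal after the
previous stage (prior-step). Patients on bempedoic acid or a PCSK9 inhibitor
at baseline are excluded before the simulation; PCSK9-inhibitor escalation
itself is deliberately out of scope.

## Synthetic cohorts

The generator emulates the structure the pipeline needs, with exact planted
ground truth:

* **Mixes** (SI categories, risk categories, LLT strata, rule templates) are
  apportioned by largest remainder, so integer counts are exact: 1,000
  default patients contain exactly 18 absolute and 68 partial SI patients.
* **SI histories** are built from one canonical template per classifier rule
  with ±15-day date jitter that provably stays inside the rule's bounds
  (e.g. permanent-discontinuation templates end supply ≥ 245 days before
  index; intermittent templates produce holes within [70, 150] days). Label
  recovery is therefore a logical property, not a statistical one, and the
  tests require 100 % recovery.
* **Risk** is planted jointly with SI status (73.7 % very-high within SI vs
  a compensating non-SI share yielding 66.1 % overall); decorating
  diagnoses are restricted so they can never escalate or demote a planted
  category.
* **LDL-C** is log-normal per treatment stratum with shape/scale solved from
  the target arithmetic moments (no LLT: mean 152.1, SD 43.5 mg/dL; on LLT:
  92.1, 31.5) — strictly positive and right-skewed like real lipid panels.
  `si_cohort_spec()` builds a pure-SI cohort with both strata at the SI
  stratum's moments (105.6, 39.8).
* 1.3 % of SI patients are placed on bempedoic acid or a PCSK9 inhibitor at
  baseline so the exclusion filter is exercised.

What the generator does **not** emulate: the joint distribution of LDL-C
with therapy intensity and risk within the SI subgroup (only marginal
summaries are public), inter-practice clustering, seasonality, insurance
type, or ICD/ATC coding (events arrive as normalised categories). Passing
tests therefore demonstrate the correctness and calibration of the pipeline
mechanics under the documented population structure, not replication of the
original cohort's headline attainment percentages, which depend on that
unavailable joint structure. The within-SI therapy mix arises from the rule
templates and is approximate.

## Problem sizes and determinism

The test suite and the acceptance script use a 1,000-patient SI cohort and a
mixed 10,000-patient cohort at 10,000 Monte Carlo runs — sizes at which the
binomial noise on attainment proportions is well under one percentage point
while a full run stays interactive on one CPU core. Every stochastic
component takes an explicit seed; identical seeds give byte-identical tables
and bit-identical simulation results, and distinct seeds move attainment by
less than two percentage points at the default run count.

## Known limitations

* The declarative default rule set is one concrete reading of an ambiguous
  source table; alternative readings are drop-in config replacements.
* Supply-based discontinuation depends on the 90-day default supply when a
  prescription carries none; data with true supply fields should provide them.
* Effects are independent across patients and runs; no responder phenotype.
* The two-category risk model omits SCORE2 numeric estimation and
  organ-damage modifiers by design.
* Descriptive group-comparison statistics (ANOVA/chi-square) are not
  computed; only the Bonferroni threshold helper is provided.
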