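# Methods

This note documents the models, conventions and design choices behind
`qibench`, in the order the pipeline runs.

## Indicator registry

The default registry holds 43 indicators over eight chronic diseases
(DM2 8, HT 5, CHD 7, CBVD 6, PAD 6, CHF 5, AF 3, COPD 3): one prevalence
indicator per disease and 35 scored process/outcome indicators. Lookback
windows are 15 months for documentation and most measurements (chronic
patients usually see their GP at least yearly, plus a tolerance quarter),
9 months for HbA1c, 3 months for drug prescriptions (continuous therapy),
8 months for antithrombotic therapy (low dosing frequency, large packs),
and unlimited for spirometry (any electronic record counts). Antithrombotic
therapy is modelled as one drug class covering antiplatelet and
anticoagulant agents. Each indicator carries consensus quality standards
(acceptable / ideal percentage); the prevalence standards are descriptive
only and never enter the score. Indicator ids are disease-prefixed
snake-case keys; registry order is stable and drives all report layouts.

## Achievement engine

* **Windows.** All windows are half-open calendar-month intervals
  `(reference_date − N months, reference_date]`; month subtraction clips
  day-of-month overflow (31 March − 1 month → 28/29 February). Only the
  month counts are defined by the indicator definitions, so calendar-month
  arithmetic is a package convention.
* **Eligibility.** A patient enters a disease's denominators when a
  diagnosis of that disease is recorded on or before the reference date
  (chronic diagnoses are treated as permanent) and at least one encounter
  falls in the 15-month window.
* **Prevalence.** Raw prevalence = eligible diagnosed patients / all
  patients with an encounter in the window. Because visitor-based
  prevalence overstates population prevalence, reports carry the adjusted
  value `raw × visit_coverage`, where `visit_coverage` is the fraction of
  the population that visits a GP within the window. The default is 1.0
  (no adjustment) because no authoritative coverage fraction ships with
  the package; it is a single global config scalar.
* **Conditional denominators.** The HbA1c-control indicator uses diagnosed
  patients with ≥ 1 HbA1c value in the 9-month window; "below target"
  means *any* in-window value < 7.5 %. Symmetrically, the metformin
  denominator is patients with *any* in-window value ≥ 7.5 % (a
  most-recent-value variant would be a one-line change in
  `engine._denominator`; the any-value rule mirrors the below-target
  indicator's stated "any value" semantics). With one measurement per
  patient the two rules coincide.
* **Exclusions.** After the table is built: practices with prevalence 0
  for a disease get all of that disease's dependent indicators marked
  `prevalence_zero` (an empty denominator under a zero prevalence is the
  same phenomenon and is relabelled; capability gaps keep their own
  reason), and any percentage outside [0, 100] — possible in manually
  extracted real data — becomes `invalid_value`. The operation is
  idempotent and never turns a missing cell into a valued one.
* **Precision.** Percentages are carried at full precision internally and
  rounded only in rendered output.

## Quality score

Bins are anchored at the baseline median of each scored indicator:
`zero_point_upper = 10` if the median is below 20 %, else the median minus
10 percentage points rounded to the nearest multiple of 5 with half-way
ties rounded **down** (the tie direction is pinned by the single observable
tie in the reference spreadsheet, median 57.5 → bound 45). Five consecutive
bins of width 5 follow; achievement at or above `zero_point_upper + 20`
earns the maximal 5 points. Bin membership is `[lower, lower + 5)` in exact
arithmetic — the printed "…–x9.9" upper edges are display formatting of
one-decimal data, so 49.95 belongs to the higher bin. A small absolute
tolerance (1e-9) guards binary-float edge effects at bin boundaries.

Missing cells contribute 0 points by default (practices with excluded
indicators remain on the common 0–175 scale); a practice with no scoreable
cell at all — e.g. a prevalence-only record system — is flagged not
calculable rather than scored 0. The shipped
`data/baseline_medians.csv` contains the published reference baseline
medians from which the reference cutoff table derives; cohort-specific
cutoffs are derived from the cohort's own baseline achievement medians
over non-missing practices.

## Benchmarking reports

Each practice's report contains its own values (self-audit), the peers'
values with identifiers stripped and order shuffled per report from a
caller-supplied seed (anonymised benchmarking), the regional median, and a
classification against the quality standards. Classification boundaries
are inclusive at the lower edge (pct = acceptable ⇒ acceptable,
pct = ideal ⇒ ideal). Quantiles use linear interpolation between order
statistics (the common statistics-package default); the rule is a
configurable argument. Reports render as delimited tables plus plain
text; no graphics dependency is taken.

## Longitudinal analysis

Units of analysis are practices. Per indicator and for the total score,
each wave is summarised as median/Q1/Q3 over non-missing practices, and
each wave pair — consecutive pairs plus (first, last) when more than two
waves — is tested with a two-sided paired Wilcoxon signed-rank test on
pairwise-complete practices. Zero differences are excluded (classic
signed-rank reduction; achievement data are skewed, which is why the
nonparametric paired test is the primary analysis). The exact null
distribution is used for n ≤ 25 nonzero untied differences, otherwise the
normal approximation with tie correction. All paired differences equal to
zero yields a degenerate result reported as p = 1. Direction flags
(increase/decrease) are set only at p < 0.05, from the median nonzero
paired difference. A one-sample Kolmogorov–Smirnov p-value against a
normal with estimated mean/sd (no small-sample correction) is attached as
an advisory; it never switches the test. No familywise correction gates
the flags — each indicator is reported on its own — but a Holm-adjusted
p-value column is emitted alongside for transparency.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes:

* **Between-practice heterogeneity.** Each practice draws a fulfilment
  probability per scored indicator from a Beta distribution, optionally
  quantile-matched to a (Q1, median, Q3) percent triple by Nelder-Mead
  minimisation of squared quantile error over (log α, log β) with
  multiple starts. The shipped default spec calibrates all 35 indicators
  to published baseline dispersion triples; the wide interquartile spans
  reproduce the large between-practice differences seen in real audits.
  A two-parameter family cannot interpolate every triple exactly — the
  median achieved-quantile error over the default spec is < 2 pp with a
  worst case ≈ 5 pp for the most skewed triple. Point-mass fulfilment
  (`prob`) is available for exact-probability tests.
* **Within-practice variation.** Patients are assigned diseases by
  independent Bernoulli draws at the (visitor-scale) prevalence; each
  patient's records follow independent Bernoulli fulfilment events, with
  event dates uniform inside the indicator window when fulfilled and
  (with probability ½) just before the window otherwise. The diabetes
  HbA1c chain is generated jointly (measured → value below/above target →
  metformin if above), so the conditional-denominator nesting holds by
  construction. Since a patient's record is shared across diseases, a
  criterion monitored by several of the patient's diseases is drawn once
  using one applicable disease's probability chosen at random; with the
  default low prevalences this perturbs marginal achievements by at most
  ~1–2 pp. Parameter-recovery tests therefore use single-disease specs.
* **Waves.** Practice identities, capabilities and latent probabilities
  persist across waves (the paired structure); wave effects shift the
  probabilities on the log-odds scale. Patient panels are redrawn per
  wave, which leaves the practice-level quantities the analysis consumes
  untouched. A configurable fraction of practices (default 15 %, i.e. 3
  of 20) has a prevalence-only extraction capability, mirroring
  heterogeneous record systems.
* **Determinism.** All randomness flows from the single spec seed through
  a spawned seed tree (profiles, then one stream per practice per wave);
  identical specs produce identical cohorts.

What passing tests on synthetic data do **not** show: the generator has no
free-text records, no extraction error, no comorbidity-correlated
fulfilment and no patient-level persistence across waves, so results on
real extracts inherit none of those guarantees.

## Problem sizes in the shipped tests

The test suite runs the oracle-equivalence checks on randomized fixtures
of up to 200 patients, the Wilcoxon type-I-error simulation with 1000
replicates at 17 practices, parameter recovery on 5000-patient practices,
wave-effect detection on 9 replicate 17-practice cohorts of ~150 patients,
and the calibrated power check on 5 replicate 20-practice cohorts of ~250
patients — sizes chosen so the full suite completes in about a minute
while keeping Monte-Carlo error small relative to the tolerances tested.

## Known limitations

* Prevalence adjustment applies one global coverage factor, not
  per-practice factors.
* The generator's comorbidity is independent across diseases with no
  cross-indicator correlation within practices; both are modelling
  choices, not estimates.
* The KS normality screen estimates mean/sd from the sample without a
  Lilliefors correction; it is advisory only.
* Exception reporting (deliberate patient exclusion) is out of scope; low
  prescription achievements in real data may partly reflect its absence.
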