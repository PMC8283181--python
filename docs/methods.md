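# Methods

This note documents the statistical conventions, data-handling rules and
design choices behind `faerspv`, in the order the pipeline applies them.

## Data model and file handling

A quarter is the six-file FAERS ASCII convention: `$`-delimited, one header
row, no quoting. All fields are kept as raw string tokens; dates gain a
parsed companion that preserves *precision* (day / month / year). Precision
is load-bearing: day-level arithmetic (time to onset) is only defined when
both operands are day-precise, so a month-precision therapy start yields a
missing onset rather than a fabricated one.

Field conventions:

* **Ages** are converted to years with unit factors YR ×1, DEC ×10, MON /12,
  WK /52, DY /365, HR /8760. The 365-day year makes whole multiples convert
  exactly (730 DY → 2.0 y). An empty unit is read as years (the dominant
  convention in spontaneous-report extracts); unknown units, negative values
  and ages above 120 y become missing with a logged warning.
* **Region** is derived from the ISO-3166 alpha-2 occurrence-country code via
  a shipped two-column table, collapsed to the five-region scheme
  Europe / America / Asia / Oceania / Africa (North and South America are one
  region). The mapping is total: any unmapped code becomes missing, never an
  exception.
* **Reporter** qualification codes MD/PH/OT map to health-professional,
  CN/LW to non-health-professional; anything else is missing.
* **Referential integrity**: child rows whose primary id is absent from DEMO
  are dropped and counted; reports with no reaction term are dropped and
  counted. Reports-in always equals reports-out plus logged drops.

## Case definition and cohort

Deduplication keeps one report per case id — highest case version, ties
broken by latest receipt date, then highest primary id — mirroring how a
revised spontaneous report supersedes its earlier versions.

A cohort case needs (i) at least one of the 15 pericardial-disorder MedDRA
preferred terms among its reactions (matched by normalized name or 8-digit
code; a report with several pericardial terms counts once), and (ii) at
least one checkpoint inhibitor as a *suspect* drug (role PS or SS; a
concomitant or interacting ICI never qualifies). Drug names are normalized
by stripping parentheticals, dose text and punctuation, then word-matching
against generic and brand names; a string matching two different generics is
treated as unresolvable.

Regimens: one suspect ICI gives that monotherapy; a suspect set equal to one
of the three marketed pairs (ipilimumab+nivolumab, ipilimumab+pembrolizumab,
tremelimumab+durvalumab) gives that combination; any other multi-ICI set is
"other". The strategy (anti-PD-1 / anti-PD-L1 / anti-CTLA-4 mono,
combination, other) is a function of the label, so the strategies partition
the cohort.

Time to onset is event date minus the *earliest day-precision* therapy start
among suspect ICIs — the most conservative onset when several therapy
records exist. Negative intervals are incorrect records: set to missing and
counted. Onset bins are closed on the left as displayed
(0–30, 31–60, 61–90, 91–180, >180 days).

Fatality is "outcome set contains DE", regardless of other codes. For the
mutually exclusive outcome *display* rows the precedence is
DE > LT > DS > HO > other-serious (OT, CA and RI fold into other-serious);
this precedence affects rendering only, never the fatality flag.

Indications map to the twelve display groups through a shipped keyword
table (substring match, specific groups ranked above the generic
"non-specified malignant neoplasm"); unmatched terms are unknown/missing.

## Disproportionality statistics

For a target/comparator design, each report falls in exactly one cell of

|              | event | no event |
|--------------|-------|----------|
| target       | a     | b        |
| comparator   | c     | d        |

With the full database as comparator, b/c/d are the non-target remainder and
both statistics are computed. Between two named subgroups the frame is
restricted to the two groups and only the ROR is computed — the IC's
expected count presumes a whole-database frame.

* `ROR = (a·d)/(b·c)`; 95% CI by the Woolf log-normal method with
  z = 1.959964. Any zero cell triggers the Haldane–Anscombe +0.5 on all four
  cells, with an explicit `zero_cell_corrected` flag rather than a dropped
  row. Rows with a = 0 are emitted with empty statistics (a tabulated dash,
  not a zero).
* `IC = log₂((N_obs+0.5)/(N_exp+0.5))` with `N_exp = N_drug·N_event/N_total`.
  The lower 95% credibility bound uses the analytic approximation
  `IC025 = IC − 3.3(N_obs+0.5)^−1/2 − 2(N_obs+0.5)^−3/2`, isolated in
  `ic_credibility_lower` so a posterior-simulation bound can be swapped in
  without touching callers. The IC needs no zero-cell correction; the +0.5
  shrinkage is built into the definition.
* Signal criteria: `IC025 > 0`; `ROR025 > 1` **and** a ≥ 3 (the minimum-case
  rule, configurable per design). Both bounds are strict.

Statistics count *reports*, never drug records, consistently with the
cohort's counting unit. The "combination vs monotherapy" comparison uses
anti-PD-1 and anti-PD-L1 monotherapy as the comparator (the clinically
relevant baseline for a CTLA-4-plus-PD-(L)1 combination); class-vs-class
comparisons condition on the two compared regimens' reports only.

The model surface (`DisproportionalityModel(reports, designs).fit()`)
returns a results object holding one row per design with estimates,
interval bounds, flags and a `summary()` rendering; the row kinds
(total / class / drug / combination / comparison) drive table layout.

## Clinical-feature analyses

Two denominators coexist by design and are both exposed: characteristic-
table percentages divide by the column size — cohort size for the total
column, fatal and non-fatal counts for theirs, unknown rows included — while
shares of documented onset ("within 30 days") divide by the documented-TTO
count. Percentages are rounded half-up to two decimals using integer
arithmetic, so boundary cases (36.585 → 36.59) do not depend on binary
float representation.

Tests between fatal and non-fatal cases: chi-square without continuity
correction on the fatal-by-category table, excluding unknown/missing rows
and zero-margin levels (expected-cell adequacy < 5 is reported in the result
note but never switches the test); Mann-Whitney for onset days;
Kruskal-Wallis across regimens; for age, a Shapiro pre-check per group at
the 5% level chooses between a Welch t test and Mann-Whitney. Degenerate
tables after exclusions are flagged untestable rather than raising.
Quantiles use the linear-interpolation convention throughout.

## Synthetic databases

The generator emulates the features the pipeline must survive: case/version
duplication, role-coded drug rows with brand-name and dose-suffix noise,
reaction rows as preferred terms, outcome codes, demographic missingness,
and imprecise or inverted therapy dates.

**Association injection is on the odds scale.** Each report's pericardial
event odds are the baseline odds times the product of the multipliers of its
suspect-role study drugs. Because exposure is assigned before the event
draw, the true reporting odds ratio of a drug–event pair equals the
configured multiplier exactly — the property the recovery studies measure.

Defaults describe a plausible oncology-pharmacovigilance slice: eight
checkpoint inhibitors with exposure shares echoing the case series
(nivolumab most common), two non-ICI co-medications, a small catalogue of
frequent background events, demographics weighted like the case series
(sex 36/54/10 F/M/missing, age ~ N(63, 10²) truncated to [0, 120], region
and reporter weights, report years concentrated 2016–2020), onset
log-normal with μ = 3.6, σ = 1.0 log-days (median ≈ 37 d), case fatality
0.1745, 10% duplicate injection, and missingness rates that leave roughly
40% of onsets undocumented (25% missing starts, 10% month-precision starts,
10% missing event dates, 2% inverted start/event pairs).

Duplicates mutate only the case version, primary id and receipt date, so
correct deduplication is observable: the retained version carries identical
analytic content. A ground-truth ledger accompanies every generation (one
row per emitted report, duplicates flagged) and can recompute any design's
contingency cells; the generator-vs-pipeline identity checks compare those
cells against the full file → read → assemble → deduplicate → classify
path, exactly.

`sample_ledger` draws the same association structure without materializing
files — the cheap path for studies needing hundreds of replicate databases.

**Onset-time study cohorts** (`generate_tto_cohort`) draw group-specific
log-normal onsets with Bernoulli fatality. The default design is the
shifted comparison — fatal μ = 3.2 vs non-fatal μ = 3.7 (σ = 1.0) at
n = 400 with 30% fatal allocation, a balance chosen for a two-group method
study; setting the two locations equal gives the null design used for
type-I-error calibration.

## The deterministic fixture cohort

The published characteristics table fixes, for each of nine characteristic
blocks, the two-way margin against outcome status (123 fatal, 580
non-fatal, 2 unknown-outcome, 705 total). The fixture reconstructs a
705-record cohort by sequential fill: within each status group, each block's
labels are repeated by their published counts, independently across blocks.
This is margin-exact on every published figure and deliberately non-unique
in the joint distribution — the table constrains nothing beyond the
two-way margins. The two unknown-outcome records are recovered from the
per-row gaps total − fatal − nonfatal in each block.

Onset values are bin-representative integers (15, 45, 75, 135, 270 days);
bin membership, not the published medians, is the reproducible surface, and
likewise the published age/onset medians and the exact region p-value are
not recoverable from binned margins. A self-audit runs on every
construction: all nine blocks are re-derived through the characteristics
pipeline and compared against a shipped machine-readable copy of the table,
so any drift between construction logic and the reference raises
immediately, naming the block. Four stored percentages correct printed
rounding slips in the source rendering (the anti-PD-1 row's three columns
and the anti-PD-L1 total column); all stored *counts* are as published, and
the corrected values are the exact half-up roundings of those counts.

## Problem sizes and numerical choices

The shipped studies use: 1,000 random tables for closed-form agreement
(tolerance 1e-8); 200 replicate 50,000-report null databases for IC
false-positive calibration; 100 replicates for recovery of an injected
reporting odds of 5 at ≈100 co-reported cases; one 200,000-report
generation for the ledger-vs-pipeline identity; 500 replicates for rank-
test size and 100 for onset-shift power. The acceptance script runs
moderately smaller replicate counts of the same studies. Reproducibility:
all randomness flows from a single integer seed through
`numpy.random.SeedSequence`; identical (config, seed) pairs give
byte-identical generated files and analysis bundles.

## Limitations

* Synthetic databases emulate structure, not content: no free-text
  narratives, no MedDRA hierarchy beyond the shipped 15-term list, no
  realistic drug-name typos beyond dose/brand suffixing, independent
  characteristic assignment in the fixture. Passing tests demonstrate the
  pipeline's correctness and calibration on data with known truth — not
  the clinical validity of any signal on real data.
* Disproportionality measures reporting, not risk: no causal or incidence
  interpretation attaches to a flagged pair, and no multiple-testing
  adjustment is applied across the design set.
* The IC lower bound is an analytic approximation to the posterior
  quantile; it is conservative for very small counts.
* The indication keyword map is intentionally small; terms outside it fall
  into unknown/missing rather than a best-guess group.
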