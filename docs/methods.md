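# Methods

## Counting model

The unit of analysis is the deduplicated safety report. A report contributes
at most one count to a term's `a` cell however often the term is mentioned,
and the drug margin `a+b` is therefore constant across all terms at a given
level. This is the reading of disproportionality in which "exposed" means
*reports naming the drug* and "unexposed" means *all other reports*; it is
also why a database's reaction count can be several times its report count
without affecting the tables. A pair-counting mode (`unit="pair"`), in which
the margins count distinct (report, term) pairs instead, is available
because database-wide denominators in published analyses are not always
explicit about their unit.

Reports enter the database through two deduplication stages:

1. **Case-version dedup** — spontaneous reporting systems re-submit updated
   versions of a case under the same CASEID. For each CASEID the row with
   the maximal FDA receipt date is kept; ties keep the highest PRIMARYID.
   This stage is idempotent and runs over the whole database.
2. **Field-based dedup** — the same event is sometimes re-entered as a brand
   new case. Within the target drug's primary-suspect cohort, reports
   agreeing exactly on age, sex, occurrence country and event date (all four
   present) are collapsed to the earliest FDA receipt date, ties to the
   lowest PRIMARYID. Reports with any missing key field are never dropped.
   Which copy to keep is underdetermined in standard practice; retaining the
   earliest receipt is this package's fixed choice. The stage is restricted
   to the target cohort because the four key fields are far too coarse to be
   a safe global collapse rule.

Target-cohort selection requires a drug record with role code `PS` (primary
suspect) and a name matching the synonym list case-insensitively after
trimming; substring matching is off by default so that combination products
and lookalike names do not leak in silently.

## The four algorithms

Cells are `a, b, c, d` as in the README; `N` and `E = (a+b)(a+c)/N` follow.

**ROR and PRR** use the standard closed forms with log-normal Wald
intervals. When any cell is zero the Haldane–Anscombe correction adds 0.5 to
all four cells (flag-controlled); with the correction disabled a zero cell
yields NaN, which screening treats as an explicit "undefined" verdict of
False rather than an exception. The χ² statistic is Pearson's without the
Yates continuity correction by default (the Yates variant sits behind a
flag); its p-value is the upper tail at 1 df, Bonferroni-adjusted by the
number of terms screened at that level — the number of tests actually
performed in that results table.

**BCPNN** uses the closed-form posterior moments of the information
component (Bate et al. 1998), with the conventional priors γ₁₁ = 1,
α = β = 2, α₁ = β₁ = 1. The lower bound is `E(IC) − k·√V(IC)` with k = 2,
the "IC − 2SD" convention common in FAERS studies; k = 1.96 is selectable.
A Monte-Carlo variant samples the joint and marginal reporting
probabilities from their beta posteriors and must agree with the
delta-method closed form within Monte-Carlo error; it exists as an
independent check on the algebra, not as the production path. The
prior-free maximum-likelihood IC, `log₂(a/E)`, is exposed separately and is
the quantity used in exactness tests (it is 0 precisely when observed
equals expected).

**MGPS** places a two-component gamma mixture prior
`w·Gamma(α₁,β₁) + (1−w)·Gamma(α₂,β₂)` on the latent rate ratio λ and fits
the five hyperparameters by maximizing the marginal likelihood, a mixture
of negative binomials evaluated at the observed `a` with each term's own
`E`. The optimizer is Nelder-Mead on log/logit-transformed parameters from
the conventional start (0.2, 0.1, 2.0, 4.0, 1/3); it is deterministic given
data and start, reports convergence and final log-likelihood, and returns
the best point found even when the convergence flag is false. The fit uses
the terms of the level being screened (a single-drug stratum), not an
all-drug-pair fit over the whole database — the only tables this pipeline
constructs — which is a documented deviation from full MGPS practice and
can make the prior collapse toward degenerate spikes when very few terms
are available; the posterior quantities remain well defined. The posterior
for each term is again a two-component gamma mixture; EBGM uses the
digamma closed form for `E[log₂ λ | a]`, and EBGM05 is found by bisecting
the posterior mixture CDF to `|ΔCDF| ≤ 1e-8`. The unshrunk ratio `a/E` is
reported alongside EBGM because published tables sometimes print values
closer to the unshrunk ratio than a full mixture fit would produce.

## Screening and ranking

PT-level screening applies the all-four consensus rule; SOC-level screening
the any-one rule (SOC aggregates are so heterogeneous that the conjunction
essentially never holds, which is why published SOC tables use the
disjunction). Thresholds (ROR CI > 1; PRR ≥ 2 ∧ χ² ≥ 4; IC025 > 0;
EBGM05 > 2; min 5 reports) are the standard pharmacovigilance criteria and
every one is config-overridable. Ranked tables sort stably by report count
or EBGM, breaking ties by the other key then term name, so output order is
reproducible across runs. The EBGM-ranked table additionally filters on
EBGM05 > 2; under the default policy this is a no-op on all-four survivors
and matters only when screening with relaxed thresholds.

## Cohort statistics

Percentages are rounded half-up to two decimals against an explicit
denominator column. Outcome rows carry two percentages — per report and per
outcome entry — because a report may have several outcomes and published
tables are inconsistent about the denominator. A report is "serious" when
any outcome code is DE, LT, HO or DS (death, life-threatening,
hospitalization, disability); CA, RI and OT are classified non-serious,
configurable. Time-to-onset is the day difference between the event date
and the earliest primary-suspect therapy start, computed only at day
precision; missing and negative deltas are excluded *and counted*, and the
bins 0–30/31–60/61–90/91–180/181–360/>360 partition the included records.
Quartiles use linear interpolation (type-7). Serious-vs-non-serious
contrasts use the two-sided Pearson χ² without continuity correction,
flagging (not correcting) tables with expected cells below 5.
Pediatric-vs-adult disproportionality is a within-drug ROR over reports
with known age, cutoff < 18 years; swapping the subgroups returns the
reciprocal ROR.

Age-unit harmonization divides by 0.1 (decades), 1 (years), 12 (months),
52.143 (weeks), 365.25 (days) or 8766 (hours). Partial dates (YYYYMM,
YYYY) are retained with their precision, participate in comparisons via
zero-padded integer keys (a partial date sorts before any complete date of
the same period — an arbitrary but fixed choice), and are excluded from
day-resolution arithmetic.

## The synthetic generator

`simulate.generate` emulates the statistical structure the pipeline
assumes, with ground truth recorded for every mechanism:

- **Disproportionality** — each background PT has a baseline reporting
  probability (default panel: 50 terms, log-spread 0.002–0.08 across ten
  SOCs); in target-drug reports the probability is multiplied by the
  planted rate ratio, clipped to 1. A rate ratio of 1 everywhere gives an
  exactly null database. Every report carries at least one PT (a forced
  draw proportional to baselines when the Bernoulli pass yields none).
- **Demographics** — categorical draws matching a real teduglutide-style
  cohort: ~57% female, age unknown in ~42% of reports with 45–64 the
  largest known stratum, consumer-dominated reporting, ~73% US reports.
  Young children's ages are emitted in MON/DY units (and a small fraction
  of all ages in MON) to exercise harmonization.
- **Time to onset** — a two-piece lognormal (split at the median, separate
  lower/upper sigmas) calibrated so the median is ~393 days with IQR
  ~97–996 days, the asymmetric quartiles a symmetric lognormal cannot
  reproduce; draws are capped at 30 years to keep dates representable.
  FDA receipt follows the event by 7–180 days.
- **Duplicates** — two disjoint kinds per the two dedup stages:
  same-CASEID revisions (new PRIMARYID, later FDA date, otherwise exact
  copies) and field-level clones re-entered under a brand-new CASEID
  (cloned only from target reports with all four key fields present, so
  ground-truth recall is well defined). A report receives at most one kind,
  keeping the expected-removal bookkeeping exact.
- **Missingness and partial dates** — per-field missingness and a
  configurable partial-date rate exercise the parser's tolerance paths.

What the generator does **not** emulate: free-text drug-name noise beyond
the synonym list, multi-drug interaction structure, correlated PT
co-occurrence (terms are conditionally independent given the drug arm),
reporting trends over calendar time, and informative missingness. Passing
tests therefore demonstrate the pipeline's correctness under the stated
generative model, not robustness to every pathology of real spontaneous
data.

## Problem sizes and numerical choices

The end-to-end validation uses databases of 5×10⁴ reports (5% target share,
one PT planted at rate ratio 10 on baseline 0.02) for sensitivity and 10⁵
reports with 200 null terms for specificity, twenty seeds each — sizes at
which the planted signal's expected `a` ≈ 500 makes detection near-certain
while keeping a full run in minutes on one CPU. Null calibration of the ROR
interval uses fixed binomial margins (200 vs 2,000 draws at p = 0.2, 10⁴
replicates), where the Wald log-interval's coverage is close to nominal.
MGPS recovery simulates 500 terms from a single Gamma(2, 4) prior with
log-normal expected counts and checks the recovered prior mean within 15%.
Degenerate inputs follow one rule throughout: statistics that cannot be
computed return NaN with an "undefined" flag downstream, never an
exception, and never a silent drop — every exclusion is counted in a
manifest or summary field.
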