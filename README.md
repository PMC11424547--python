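# pvsignal

Disproportionality-based safety-signal detection for FAERS-style
spontaneous-report databases.

Spontaneous adverse-event reporting systems such as the FDA Adverse Event
Reporting System (FAERS) collect millions of voluntarily submitted reports,
each linking drugs to MedDRA-coded adverse-event terms. Pharmacovigilance
analysts mine these data by asking, for each drug–event pair, whether the
event is reported *disproportionately* often with the drug compared to the
rest of the database. `pvsignal` implements that workflow end to end for
researchers and safety scientists: tolerant parsing of the quarterly
`$`-delimited ASCII tables, two-stage duplicate removal, primary-suspect
cohort selection, PT→SOC aggregation, four standard disproportionality
algorithms with consensus screening, and the descriptive cohort statistics
that accompany a published signal-detection study. A synthetic report
generator with known ground truth (planted reporting-rate ratios, injected
duplicates, partial dates, unit-coded ages, missing fields) makes every
stage testable without downloading real data.

## The statistics

Each drug–event pair is summarised by a 2×2 contingency table — `a` reports
with drug and event, `b` with drug only, `c` with event only, `d` with
neither (`N = a+b+c+d`, `E = (a+b)(a+c)/N` the count expected under
independence):

- **ROR** (reporting odds ratio): `ad/bc`, with the log-normal 95% CI
  `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`.
- **PRR** (proportional reporting ratio): `[a/(a+b)] / [c/(c+d)]` with its
  log-normal CI and the 1-df Pearson χ² statistic
  `N(ad−bc)² / [(a+b)(c+d)(a+c)(b+d)]`.
- **BCPNN IC** (information component): the posterior mean of
  `log₂[P(drug,event)/(P(drug)P(event))]` under the Bate et al. prior, with
  `IC025 = E(IC) − 2√V(IC)`.
- **MGPS EBGM**: a two-component gamma mixture prior on the rate ratio
  `λ = a/E` is fitted across all terms by maximum marginal likelihood
  (each component integrates to a negative binomial); `EBGM = 2^{E[log₂λ|a]}`
  is the shrunk posterior geometric mean and `EBGM05` its 5th posterior
  percentile.

A PT is a **signal** under the strict consensus rule when, with at least 5
reports, all four criteria hold simultaneously: ROR CI lower bound > 1,
PRR ≥ 2 with χ² ≥ 4, IC025 > 0, EBGM05 > 2. SOC-level screening uses the
permissive any-one-of-four rule. Per-term p-values are Bonferroni-adjusted
within each screened level.

## Worked example

`examples/simulate_and_screen.py` plants one PT at a reporting-rate ratio of
10 in a 20,000-report synthetic database (10% target-drug share) and runs
the full pipeline:

```
stage counts: {'parsed': 20608, 'after_caseid_dedup': 20021,
 'target_before_field_dedup': 1970, 'target': 1949, 'database': 20000,
 'reactions': 28116, 'terms_tested_pt': 49, 'terms_tested_soc': 10,
 'signals_pt': 1, 'signals_soc': 1}

terms flagged by the all-four consensus rule:
  term   a   ror   prr    chi2  ic025  ebgm  ebgm05  adjusted_p
Pt 015 109 7.689 7.315 336.177  1.792 4.525   4.525         0.0
```

The manifest shows every row drop: 20,608 parsed rows (originals plus
injected duplicates) become 20,021 after keeping the latest version of each
case, and the target cohort shrinks from 1,970 to 1,949 when re-entered
reports with identical age/sex/country/event-date are removed. Exactly one
term is flagged — the planted one — with all four statistics estimating its
disproportionality at 4.5–7.7 (shrinkage pulls the Bayesian estimates below
the frequentist ones). The other examples print a single table's four
statistics (`closed_form_statistics.py`) and the cohort descriptives
(`cohort_descriptives.py`).

The same workflow is available from the shell:

```sh
pvsignal simulate --seed 1 --n-reports 20000 --out db/
pvsignal signals db/ --out results/        # Table-style TSVs + manifest
pvsignal descriptives db/ --out tables/    # demographics, onset, contrasts
```

Real FAERS quarters can be analysed by pointing `pvsignal signals` at a
directory with DEMO/DRUG/REAC/OUTC/THER files (a manual download step), a
two-column PT→SOC TSV and `--synonym` flags for the drug of interest.

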