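# mdepriv

Multidimensional economic-deprivation analysis for categorical survey data.

Household surveys often record hardship as categorical answers — "just
getting by", "temporarily laid off", "cannot pay some bills" — rather than
as incomes. `mdepriv` turns such responses into binary deprivation
indicators via a codebook, and summarises how hardships **overlap within
individuals** using the Alkire–Foster dual-cutoff counting indices, with
survey weights and standard errors. It is aimed at analysts of surveys such
as the Federal Reserve Board's Survey of Household Economics and
Decision-making (SHED): the packaged default codebook encodes four
economic-deprivation indicators from the April 2020 SHED supplement
(overall financial condition, employment status, month-over-month income
change, ability to pay bills in full), each weighted 1/4.

## The indices

For individual *i* and indicator *j*, let *b<sub>ij</sub>* ∈ {0, 1} mark
deprivation and *w<sub>j</sub>* the indicator weight (Σ<sub>j</sub>
*w<sub>j</sub>* = 1). The weighted deprivation score is *c<sub>i</sub>* =
Σ<sub>j</sub> *w<sub>j</sub> b<sub>ij</sub>*. Individual *i* is identified
as multidimensionally deprived at cross-indicator cutoff *k* when
*c<sub>i</sub>* ≥ *k*/*m*. With sampling weights *s<sub>i</sub>*:

- **HCR** (headcount ratio): weighted share of identified individuals
  (*q*/*n* under unit weights);
- **A** (average intensity): weighted mean score among the identified —
  the average share of indicators in which the deprived are deprived;
- **M** (adjusted headcount ratio): weighted mean of the *censored* score
  (scores below the cutoff set to 0) over everyone, so **M = HCR × A** —
  actual deprivations as a share of the maximum possible.

Scores and identification use exact rational arithmetic, so *c<sub>i</sub>*
≥ *k*/*m* never depends on floating-point rounding, and M decomposes
exactly across population subgroups: M = Σ<sub>g</sub> share<sub>g</sub> ·
M<sub>g</sub>. Standard errors come from linearization (each index as a
weighted mean; A by the delta method) or a seeded bootstrap.

Around this core the package provides subgroup decomposition, pairwise
joint-deprivation ("overlap") rates with phi correlations, OLS/Poisson
regressions of the deprivation count on covariates with robust sandwich
standard errors (via statsmodels), and a seeded synthetic-data generator
that emulates a SHED-like weighted survey with known structure.

## Worked example

The classic five-individual illustration ships with the package. Its
deprivation matrix and scores:

| individual | fin. condition | employment | income | bills | score |
|---|---|---|---|---|---|
| 1 | 0 | 1 | 1 | 1 | 3/4 |
| 2 | 0 | 0 | 0 | 0 | 0 |
| 3 | 1 | 1 | 1 | 1 | 4/4 |
| 4 | 1 | 0 | 1 | 0 | 2/4 |
| 5 | 0 | 0 | 1 | 0 | 1/4 |

```python
import mdepriv as md

codebook = md.load_default_codebook()
dataset = md.worked_example(codebook)
matrix = md.dichotomize(dataset, codebook)
scores = md.deprivation_scores(matrix, codebook)
print(md.headcount_ratio(scores, 2, 4))   # 3/5
print(md.average_intensity(scores, 2, 4)) # 3/4
print(md.adjusted_headcount(scores, 2, 4))# 9/20
```

At cutoff k = 2, individuals 1, 3 and 4 are identified: HCR = 3/5 (60% are
deprived in two or more indicators), their average intensity is A = (3/4 +
4/4 + 2/4)/3 = 9/12, and M = HCR × A = 9/20 (the sample experiences 45% of
its maximum possible deprivation among the identified). The same numbers
come out of the CLI in display convention (HCR/M in percent, A on [0, 1]):

```bash
$ mdepriv estimate --survey survey.csv --out table3.csv
# k=2 row: hcr_pct=60.0, intensity_a=0.75, m_pct=45.0
```

`mdepriv` subcommands: `dichotomize`, `estimate`, `subgroups`, `overlap`,
`regress`, `simulate`, `recover`, `run` (full bundle with metadata). The
survey CSV schema is: `respondent_id`, one integer response column per
indicator (`financial_condition`, `employment_status`, `income_change`,
`pay_bills` for the default codebook), a `weight` column, and covariate
columns (`race_ethnicity`, `age`, `education`, `gender`, `marital`,
`household_size`, `income_category` 1–21, `metro`, `stay_home`).

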