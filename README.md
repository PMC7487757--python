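# sleeptrends

Survival-analysis tooling for long-run trends in **self-reported sleep
duration** from repeated mailed questionnaires in a population-based twin
cohort. Respondents do not report sleep in hours and minutes; they tick an
ordinal category ("7", "7.5", "10 h or more", ...), and the categories
changed between survey waves (whole hours in 1975, half hours in 1981, 1990
and 2011). `sleeptrends` treats each response as an **interval-censored
observation of a latent continuous sleep duration** and provides:

- **Interval-censored Weibull proportional-hazards regression with nested
  random effects.** The latent duration *T* of subject *s* in twin pair *p*
  has hazard

  $$h(t \mid x, u) = k\,t^{k-1}\exp(\beta_0 + x^\top\beta + u_p + u_{ps}),$$

  so $S(t \mid x,u) = \exp\{-t^{k}e^{\beta_0 + x^\top\beta + u_p + u_{ps}}\}$,
  with fixed effects for birth cohort (<1900 reference, 1900–1919,
  1920–1939, 1940–1957), age group (18–34 reference, 35–54, 55+) and gender
  (female reference), and mean-zero normal random intercepts
  $u_p \sim N(0,\sigma_p^2)$ shared by a twin pair and
  $u_{ps} \sim N(0,\sigma_i^2)$ shared by one person's responses across
  waves. A category $[L, R)$ contributes $S(L)-S(R)$; the frailties are
  integrated out by nested Gauss–Hermite quadrature and the marginal
  likelihood is maximised with an analytic gradient. $e^{\beta_j}$ is a
  hazard ratio *for shorter sleep*: above 1 means the group sleeps less.
- **Turnbull NPMLE** (self-consistency EM) and a midpoint Kaplan–Meier
  estimator for nonparametric survival curves of sleep duration per wave.
- **Descriptive tables**: midpoint-coded means and SDs by wave × gender or
  wave × age group, and minutes-per-year trend statistics.
- **A synthetic twin-cohort generator** reproducing the study design (four
  waves 1975/1981/1990/2011, wave-specific eligibility and response rates,
  same-gender pairs born 1880–1957) so the whole pipeline is testable
  without the original, non-public cohort data.

## Worked example

Simulate a 500-pair cohort, summarise it, and fit the regression:

```bash
sleeptrends simulate --n-pairs 500 --seed 7 --out responses.csv
sleeptrends describe --input responses.csv --group wave_gender --out table_means.csv
sleeptrends fit --input responses.csv --quad 15 --out fit.json --hr-out hr.csv
```

The describe step writes stratum means of the midpoint-coded responses
(hours of sleep):

```
wave_year,stratum,n,mean_hours,sd_hours,note
1975,female,462,7.348484848484849,0.9724494215516092,
1975,male,422,7.355450236966824,0.9167768395798354,
```

and the fit prints the hazard-ratio table (the generating truth of the
simulation was HR 1.11/1.41/1.62 for the birth cohorts, 1.24/1.23 for the
age groups and 1.13 for male gender):

```
      factor     level       hr   ci_low  ci_high  is_reference
birth_cohort     <1900 1.000000      NaN      NaN          True
birth_cohort 1900-1919 1.090488 0.935175 1.271594         False
birth_cohort 1920-1939 1.288022 1.072352 1.547068         False
birth_cohort 1940-1957 1.533420 1.272032 1.848521         False
   age_group     18-34 1.000000      NaN      NaN          True
   age_group     35-54 1.202409 1.021915 1.414783         False
   age_group       55+ 1.057739 0.877335 1.275238         False
      gender    female 1.000000      NaN      NaN          True
      gender      male 1.149386 1.042261 1.267522         False
```

Every 95% Wald interval covers its generating value; later-born cohorts and
older age groups show hazard ratios above 1, i.e. shorter sleep. At 2000
pairs the point estimates tighten to within a few percent of the truth.

`sleeptrends report --outdir report --n-pairs 500 --seed 7` runs the whole
pipeline (simulate → describe → Turnbull curves per wave → fit →
model-implied survival curves per age group × birth cohort) and writes all
artifacts with their settings and seeds.

The same functionality is available as a library:

```python
from sleeptrends import SyntheticConfig, generate, fit, hazard_ratios

observations, truth = generate(SyntheticConfig(n_pairs=500, seed=7))
result = fit(observations, quad_order=15)
print(hazard_ratios(result, level=0.95))
```

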