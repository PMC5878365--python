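# seasonsync

Seasonal variation confounds pre/post evaluations of chronic-disease
interventions: hospital admissions and length of stay (LOS) in chronically
ill cohorts peak in winter and spring, so an intervention rolled out in
autumn can look effective simply because its follow-up window lands in a
milder season. `seasonsync` implements, for multi-year patient admission
records grouped into climate zones (subtropical wet/dry, temperate,
colder):

1. **Seasonal trend estimation.** Admissions and LOS are summed per calendar
   month per zone over a 3-year (36-month) pre-intervention window. A linear
   baseline `y_t = β₀ + β₁ t` (OLS on the month index, with 95%
   new-observation prediction bounds) removes the secular "aging" growth of a
   chronically ill cohort; the remainder is expressed as the percentage
   deviation from baseline, `dev_t = 100·(y_t − ŷ_t)/ŷ_t`, and averaged by
   calendar month across years into a 12-point seasonal profile `P_z(m)`
   (mean ± across-years SD) per zone.

2. **Commencement synchronization.** When patients start the intervention in
   different calendar months `c_k`, the expected seasonal deviation they
   jointly experience `i` months after commencement is the synchronized
   profile

   `S_p(i) = Σ_k P_{z(k)}( ((c_k + i − 2) mod 12) + 1 ) / n(i)`, `i = 1..12`,

   where the sum runs over patients still monitored at month `i` and `n(i)`
   counts them. Heterogeneous commencement dates average seasonal peaks
   against troughs, attenuating the confound.

3. **Recruitment-distribution Monte Carlo.** The recruitment rate is fitted
   by the Poisson MLE (the sample mean of monthly recruit counts), and
   alternative recruitment-date distributions (observed, Poisson-rate
   clamped to the intervention window, discrete uniform, point mass) are
   compared by simulating recruitment schedules and measuring the peak
   `|S_p(i)|` per replicate.

A synthetic-cohort generator with known multiplicative seasonality, aging
trend, Poisson monthly counts and negative-binomial LOS makes every stage
testable as a parameter-recovery problem.

## Worked example

The `analysis/` scripts run the full study on a synthetic cohort:

```bash
python analysis/01_generate_cohort.py
python analysis/02_seasonal_trends.py
python analysis/03_synchronized_profile.py
python analysis/04_recruitment_simulation.py
python analysis/05_report_tables.py
```

Output (abridged):

```
cohort: 136 patients (61 test), 873 admissions in 2010-2012
mean LOS per admission: 6.28 days (target 6.3)
colder: LOS baseline slope +0.19/month (R2 0.00); peak seasonal deviation 47.8% (SD 17.1%) at calendar month 8
subtropical: LOS baseline slope +0.61/month (R2 0.08); peak seasonal deviation 57.7% (SD 35.3%) at calendar month 3
temperate: LOS baseline slope -0.48/month (R2 0.08); peak seasonal deviation 56.1% (SD 58.1%) at calendar month 1
synchronized over 61 test patients: peak 10.4% (contribution SD 31.4%)
poisson(6.5) clamped to 15 months: mean peak 12.97% (SD 2.63%)
uniform over 15 months:           mean peak 8.76% (SD 2.79%)
uniform smaller in 85/100 paired replicates (t = -10.99, p = 3.1e-22)
```

Read: each zone's estimated LOS seasonal profile swings by ~50% around its
aging baseline, but pooling the 61 test patients by months-since-commencement
shrinks the residual seasonal signal to ~10%. Simulated recruitment
schedules show that spreading recruitment uniformly over the 15-month
intervention window attenuates the confound more than the Poisson-shaped
recruitment stream actually observed in such trials.

The same stages are available as a CLI
(`seasonsync generate|aggregate|simulate-recruitment|run`) and as library
functions (`seasonsync.monthly_series`, `fit_linear_trend`,
`percent_deviation`, `seasonal_profile`, `synchronized_profile`,
`run_recruitment_simulation`, ...).

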