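# Methods

## Model and procedure

The analysis treats a zone's monthly outcome total (admission count or summed
LOS days) as seasonal multiplicative structure around a slowly growing
baseline. The baseline is an OLS line on the month index t = 1..36; it is
interpreted as the non-seasonal secular ("aging") growth of a chronically ill
cohort, not as a forecast model. Diagnostics are the standard OLS set (R²,
adjusted R², residual sum of squares, residual standard error
√(RSS/(n−2))), and the 95% prediction bounds are the classical
new-observation interval, fitted ± t₀.₉₇₅,ₙ₋₂ · s · √(1 + 1/n + (t−t̄)²/Sxx).
For a zero-residual fit R² is defined as 1 (statsmodels returns 0/0 when the
centered total SS is also zero).

Seasonality is then measured scale-free as the percentage deviation from the
fitted line, dev_t = 100·(y_t − ŷ_t)/ŷ_t, and summarized as a 12-point
calendar-month profile: mean and sample SD (ddof 1) of the deviations at each
calendar month across years. This requires a whole number of years ≥ 2; the
window may start at any calendar month (deviations are aligned to calendar
months, not window positions). A fitted value at or below
ε = 1e-9 · mean(fitted) raises an error naming the month rather than
producing an unstable percentage.

The synchronized profile pools zone profiles over a recruitment schedule:

    S_p(i) = Σ_{k: monitored at i} P_{z(k)}[ ((c_k + i − 2) mod 12) + 1 ] / n(i)

with c_k the patient's commencement calendar month and n(i) the number of
patients monitored at least i months. Each patient is weighted equally (not
each zone); rotation is modular on the 12-month yearly profile, so patients
monitored past December wrap into the same profile; months with n(i) = 0 are
undefined (NaN), never 0. The peak is max |S_p(i)| over defined months, with
dispersion reported as the SD (ddof 1) of the individual patient
contributions at the argmax month — one of several defensible dispersion
choices; alternatives (across-months SD, across-years SD) would give
different numbers, which is why published peak dispersions are not treated as
reproducible targets.

The recruitment Monte Carlo fits λ by the Poisson MLE (sample mean of monthly
recruit counts) and, per replicate, draws one commencement-month index per
patient: uniform on {1..W}, or Poisson(λ) mapped by k → min(k+1, W). The
shift-and-clamp mapping is a declared convention: a Poisson draw over
commencement-month indices can produce 0 or exceed the window, and no
standard mapping exists; shifting so a zero draw means the first window month
and clamping overruns to the window end preserves the distribution's
concentration, which is the property under study. Replicate r of a
simulation uses the deterministic child seed SeedSequence([seed, r]), so two
simulations sharing a root seed are paired replicate-by-replicate (common
random numbers), which is what the paired win-count comparison relies on.

Between-season significance tests operate on monthly aggregate values within
each season across the years (temperate/colder: 9 values per season over 3
years; subtropical: 18). The sampling unit behind published seasonal
p-values of this kind is typically unstated, so p-values are reported under
this declared convention and not chased against printed ones. The Wilcoxon
rank-sum test uses the exact null distribution of the rank sum for combined
n ≤ 20 — a subset-sum count over doubled midranks, valid under ties, written
in-house because scipy's exact method excludes ties — and the normal
approximation with tie and continuity corrections beyond; two-sided p is
2·min(lower, upper) capped at 1. The t test is the pooled-variance
two-sample test; a zero pooled variance with unequal means is an error, with
equal means it returns t = 0, p = 1.

## Synthetic cohort

The generator emulates a ~136-patient, three-zone, 36-month cohort. Monthly
admission counts per patient are Poisson with mean
base_rate · multiplier(zone, calendar month) · (1 + aging_slope · t):
seasonality is multiplicative on the rate, which makes percentage deviation
the natural recovered quantity. Defaults: 37/31/68 patients
(subtropical/temperate/colder), base_rate 0.17 admissions per patient-month
(≈ 817 admissions for 136 patients over 36 months), aging_slope 0.005/month
(≈ 20% growth over 3 years, a mild secular trend), winter-peaking cosine
multipliers with amplitude 0.45/0.30/0.20 by zone (strongest swing in the
two-season subtropical zone; all means ≈ 1 so base_rate stays interpretable),
test fraction 61/136, commencements uniform over a 15-month intervention
window after the observation window. LOS per admission is
1 + NegBin(mean = los_mean − 1, size = los_dispersion) with los_mean = 6.3
days and dispersion 1.5 — integer LOS ≥ 1 with realistic right skew.

What the generator does not emulate: comorbidity mixes, mortality and
dropout, weather covariates, within-patient correlation of admissions beyond
the shared seasonal/aging structure, and stays are attributed wholly to the
admission month (no splitting of multi-month stays, consistent with the
aggregation convention). Passing parameter-recovery tests therefore shows
the estimators are correct under this generative model, not that real
admission series satisfy its independence assumptions.

## Numerical and design choices

- Calendar months are (year, month) pairs with closed-form arithmetic;
  windows are closed intervals of whole months; month indices are 1-based.
- An admission belongs to the calendar month of its admission date even if
  the stay spans months — the simplest convention consistent with summing
  outcomes per calendar month.
- Report rounding: admission shares 1 dp, cohort-wide LOS shares and
  LOS-per-admission 2 dp; all internal computation is full precision.
- Peak extraction breaks ties by the earliest calendar month.
- Exact Wilcoxon: midranks are doubled to keep the DP over rank sums in
  integers; the exact path bounds combined n at 20 (≤ 184,756 subsets,
  counted in O(n·na·Σranks) by DP, not enumerated).
- CSV with headers is the only on-disk format; a malformed admissions row is
  logged with its line number and dropped, but more than 1% bad rows aborts.
- Simulation sizes: recruitment comparisons use 100 replicates of 61
  patients; attenuation checks use 1200 patients over 20 seeds; seasonal
  parameter recovery uses 50 replicates of 200 patients at base rate 50
  admissions/patient-month via the generator's vectorized monthly-count path
  (the record-level path is equivalent in distribution and is validated
  separately at smaller n).

## Limitations

- The linear baseline can leak a little seasonal signal into the trend when
  the window does not cover whole years or seasonality is asymmetric; with
  36 whole months the leakage is negligible relative to the profile SDs.
- Percentage deviations are undefined for near-zero baselines; very sparse
  subgroups (few patients, low rates) should be aggregated further before
  profiling.
- The synchronized profile assumes a stable yearly seasonal pattern across
  the monitoring period; year-to-year climatic shifts enter only through the
  across-years SD, not the mean profile.
- The Poisson recruitment model treats each patient's commencement-month
  index as an independent Poisson draw — statistically unusual but the shape
  under comparison; it is not a model of the recruitment process itself.
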