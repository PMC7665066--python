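# maizecast

Within-season statistical forecasting of annual regional maize yields
from climate and sea-surface-temperature (SST) predictors, built for the
data situation typical of East-African agriculture: short official yield
series (~10 years), no field-level surveys, and only global gridded
weather products. The package targets analysts building operational
sub-national yield forecasts — and anyone who wants to stress-test this
class of method on synthetic data with known ground truth.

## The method

For each region *i* with harvest years *t = 1..T*:

1. **Growing season** — the onset is the first day with ≥ 25 mm of rain
   in 6 days, a wet (> 0.1 mm) starting day plus ≥ 2 further wet days in
   the window, and no ≥ 10-day dry spell in the following 40 days;
   seasons last a fixed 110 days. Bimodal (Vuli + Masika) regions use the
   long-rains onset. The static regional calendar is the median over grid
   cells, then over years. The vegetative/reproductive split falls where
   half the season's growing-degree-day sum (base 10 °C, cap 30 °C) is
   reached — day ~55, the forecast lead time.
2. **Predictors** — per phase: median daily mean/max/min temperature,
   precipitation sum, days above/below 5/10/15 mm, dry spells longer than
   5/10/15/20 days, and exceedances of region-specific long-term 1%/99%
   percentiles; per SST index (Niño 3.4, West Pacific, Indian Ocean
   Dipole at 120/120/30-day lead): window median and whole-series
   1%/99% exceedance counts. All predictors are standardized.
3. **Model** — log yields are detrended (mean/linear/quadratic by lowest
   AIC) and the anomalies regressed without intercept,

   log(y_it) = Σₖ β_ki·x_kit + ε_it,

   on predictors chosen by a four-step chain: zero-variance filter,
   collinearity filter (|r| > 0.7 keeps the better yield correlate),
   LASSO with leave-one-year-out CV penalty, and a 5-variable cap.
   Diagnostics: Breusch–Godfrey, Breusch–Pagan, VIF.
4. **Validation** — level 1 (selection fixed, coefficients refit per
   left-out year), level 2 (the whole chain rerun inside every fold,
   cap 4 — the operational setting), and an independent holdout forecast
   of the final year using vegetative + SST predictors only. Skill is
   Nash–Sutcliffe efficiency (NSE) and RMSE against a constant
   leave-one-year-out mean-yield baseline.

Real CHIRPS/ERA5/NOAA/ministry inputs are out of scope; a
synthetic-data module generates daily Bernoulli-gamma rainfall with
unimodal or bimodal seasonality, sinusoid + AR(1) temperature, AR(1)
monthly SST anomalies, and yields from a known linear model on known
catalogue features — so every stage can be tested against ground truth.
See `docs/methods.md` for assumptions, defaults, and known limits.

## Worked example

The demonstration study (`configs/demo.yaml`: 4 regions, 2010–2019,
truth = +0.7 sd on vegetative extreme-rain days `precip.p99_v` and
−0.6 sd on reproductive cold snaps `tas.min01_r`, noise 0.05) runs as
numbered scripts:

```bash
python analysis/01_simulate.py   # inputs + truth sidecar
python analysis/02_calendar.py   # onset/split/lead per region
python analysis/04_fit.py        # selection + regression + diagnostics
python analysis/05_validate.py   # level-1 and level-2 LOOCV
python analysis/06_holdout.py    # independent final-year forecast
```

`02_calendar.py` prints the static calendars — unimodal onsets in
mid-December, bimodal (Masika) onsets in mid-March, leads ≈ 57–61 days:

```
region   regime  onset_doy  split_day  end_doy  lead_time_days
   R00 unimodal        363         52      108              58
   R01  bimodal         73         49      183              61
   R02 unimodal        354         53       99              57
   R03  bimodal         69         50      179              60
```

`05_validate.py` summarizes both validation levels (NSE on log
anomalies, RMSE in t/ha):

```
region  level  nse_anom  rmse_abs  baseline_rmse
   R00 level1     0.989     0.225          1.778
   R01 level1     0.927     0.366          1.868
   R02 level1     0.865     0.443          5.073
   R03 level1     0.987     0.201          2.167
  median NSE 0.957; forecast RMSE < baseline in 4/4 regions

   R00 level2     0.759     1.029          1.778
   R01 level2     0.397     1.595          1.868
   R02 level2     0.216     5.383          5.073
   R03 level2     0.522     0.664          2.167
  median NSE 0.460; forecast RMSE < baseline in 3/4 regions
```

Read: with the selection held fixed, out-of-sample skill is high
everywhere (level 1); once the variable selection itself must be made
without the forecast year (level 2), skill drops sharply on a 10-year
series — the central caveat for operational use. `04_fit.py` shows the
planted truth recovered in the two regions where no spurious correlate
displaced it, with standardized coefficients close to (+0.7, −0.6).

The same pipeline is scriptable via the `maizecast` CLI
(`simulate | calendar | features | fit | validate | forecast | all`).

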