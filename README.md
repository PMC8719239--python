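# graftcast

Patient-specific forecasting of kidney-transplant function.

After a kidney transplant, the estimated glomerular filtration rate
(eGFR, mL/min/1.73 m²) fluctuates strongly — technical and biological
variability on top of a recovery trend toward a patient-specific plateau.
Because chronically transplanted kidneys sit far outside healthy-population
reference ranges, a new measurement is only informative relative to *that
patient's* expected trajectory. `graftcast` builds exactly that reference:
a sequence-to-sequence recurrent model maps a window of a patient's recent
daily eGFR values to a predicted range of future values, and a measured
value that falls strictly below the lower quartile (Q1) of the predictions
flags *worsening graft function* — the kind of deviation that prompts an
indication biopsy.

The package is aimed at researchers in transplant nephrology and clinical
time-series methodology. It contains the full pipeline:

* **`data_io`** — longitudinal cohort model, CSV formats, MDRD-4 eGFR
  (`175 · Scr^−1.154 · age^−0.203 · 0.742_if-female · 1.212_if-Black`);
* **`preprocess`** — last-observation-carried-forward daily grids with an
  observed/imputed mask, sliding (input, target) window pairs, z-scaling;
* **`seq2seq`** — a GRU encoder-decoder (pure NumPy: forward, BPTT, Adam)
  with a residual output head, trained in patient-level 5-fold
  cross-validation; the five fold models form the predictive ensemble;
* **`arima_baseline`** — per-window ARIMA multistep out-of-sample
  forecasts (AIC order selection) as the conventional benchmark;
* **`alarm`** — masked RMSE (scored on truly measured days only), the
  5-candidate quartile range, and the biopsy-day worsening alarm with
  cohort sensitivity;
* **`simulate`** — a synthetic post-transplant cohort generator
  (exponential recovery, delayed graft function, AR(1) biological noise,
  measurement noise, injuries that trigger biopsies) calibrated so pooled
  first-3-month measurements match 39.2 (11.8) mL/min/1.73 m².

Accuracy is masked RMSE in mL/min/1.73 m²: predictions are compared with
the real measured eGFR on the same day, never with imputed values. Two
aggregations are used — `cv_rmse` (mean of the 5 fold RMSEs, derivation
mode) and `ensemble_rmse` (per-day mean candidate, locked-model mode).

## Worked example

`examples/benchmark_models.py` simulates a 120-patient noisy cohort and
scores both forecasters on identical evaluation windows:

```
IN  5 / OUT  5:  ARIMA 12.71   seq2seq cv  6.31  (masked RMSE, mL/min/1.73 m2)
IN  5 / OUT 15:  ARIMA 10.48   seq2seq cv  6.87  (masked RMSE, mL/min/1.73 m2)
```

The sequence model wins clearly at short input lengths: ARIMA has to
estimate orders and coefficients from 5 points per window, while the
sequence model has learned the population's recovery dynamics and only
conditions on the window. The sequence model's error grows with the
demanded output length; ARIMA's 5-day forecasts are actually *worse* than
its 15-day ones because short-window order selection overfits and the
error concentrates in the first days after an unstable fit.

`examples/biopsy_alarm.py` trains ensembles on an injury-rich cohort
(150 patients, injected eGFR drops of 30–60%) and assesses every
indication biopsy after withholding the 4 last pre-biopsy measurements:

```
sensitivity: 100.0% (194/194 assessable biopsies flagged; 0 unassessable)
```

with a histogram of deviations (measured eGFR − predicted Q1) that is
almost entirely negative — biopsied kidneys sit below their
patient-specific expected range.

Other examples: `examples/simulate_cohort.py` (generator and LOCF grid),
`examples/forecast_patient.py` (candidate range for one patient). A thin
CLI wraps the same stages for shell use (`graftcast simulate | train |
forecast | evaluate | arima | alarm | benchmark`); every run writes a
`resolved_config.yaml` for reproducibility.

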