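# dcekin

Pharmacokinetic quantification of focused-ultrasound (FUS)-induced
blood-brain-barrier (BBB) disruption from dynamic contrast-enhanced MRI
(DCE-MRI) time series.

When FUS is applied to the brain together with circulating microbubbles,
the BBB opens locally and an MRI contrast agent (gadolinium) leaks from
plasma into the extravascular extracellular space (EES). `dcekin`
quantifies that leakage from ROI-averaged T1-weighted signal time
series, for researchers running FUS/DCE-MRI permeability experiments:

* **Relaxometry** — convert image signals to gadolinium concentration
  under the saturation-recovery signal model, S ∝ 1 − exp(−TR/T1) with
  1/T1 = 1/T10 + r1·C, using protocol constants T10 = 0.9 s (tissue) /
  1.5 s (artery), r1 = 4.62 mM⁻¹s⁻¹, TR = 500 ms, and a 0.55 plasma
  correction for the arterial compartment.
* **Arterial input function (AIF)** — biexponential washout
  C_p(t) = A₁e^(−m₁t) + A₂e^(−m₂t), fit by Levenberg–Marquardt.
* **General kinetic model (GKM, Tofts)** — tissue uptake
  dC_t/dt = K_trans·C_p − K_ep·C_t, fit through its closed form
  C_t(t) = K_trans·Σᵢ Aᵢ(e^(−K_ep·t) − e^(−mᵢt))/(mᵢ − K_ep).
  K_trans (min⁻¹) is the plasma→EES transfer constant — the indicator of
  BBB opening; v_e = K_trans/K_ep is the derived distribution-volume
  ratio.
* **Two-stage GKM** — for *repeated* FUS irradiation: smooth the tissue
  curve with a 5th-order Fourier series, split it at the second
  irradiation time, resample 40 points per stage, fit stage-wise
  transfer constants against the single all-frame AIF, and report a
  duration-weighted mean v_e. A single GKM fit on such data
  underestimates K_trans and K_ep; the two-stage fit removes that bias.
* **Forward simulator** — the 40-frame acquisition (97 s per frame, 2
  pre-contrast frames, ~1 h post-injection), single- or two-stage
  permeability schedules, exact piecewise kinetics, Gaussian/Rician
  noise; every estimator is testable without scan data.

## Worked example

Simulate a single-irradiation experiment (default truth
K_trans = 0.059, K_ep = 0.049 min⁻¹) and estimate the constants back:

```sh
$ dcekin simulate --seed 7 -o signals.csv
$ dcekin fit-gkm signals.csv
{
  "aif": { "A1": 0.2000, "A2": 0.1000, "m1": 0.0500, "m2": 0.4000, ... },
  "gkm": { "Ktrans": 0.0590, "Kep": 0.0490, "ve": 1.204, "converged": true }
}
```

The noiseless loop returns the simulation truth exactly; `ve = 1.204`
says the apparent distribution volume is ~1.2 times the tissue volume
(values above 1 are routinely reported in this assay and are used as a
relative leakage index, not a physical volume fraction).

A repeated-irradiation experiment (kinetics switch at 20 min,
stage truths 0.093/0.053 and 0.068/0.015 min⁻¹), analysed two-stage:

```sh
$ cat two_stage.yaml
design:
  truth_stage1: {Ktrans: 0.093, Kep: 0.053}
  truth_stage2: {Ktrans: 0.068, Kep: 0.015}
  split_min: 20.0
mode: two_stage
$ dcekin simulate -c two_stage.yaml -o repeated.csv
$ dcekin fit-two-stage -c two_stage.yaml repeated.csv
{
  "two_stage": {
    "split_min": 20.0,
    "stage1": { "Ktrans": 0.0926, "Kep": 0.0523, "ve": 1.771, ... },
    "stage2": { "Ktrans": 0.0658, "Kep": 0.0135, "ve": 4.875, ... },
    "weighted_ve": 3.837
  }
}
```

Stage-wise estimates recover the truth to within the smoothing bias of
the Fourier trend curve (≲5% stage 1, ≲15% stage 2); the weighted v_e
combines the 20-min and 40-min stages. Fitting the same data with the
plain single-stage model gives K_trans ≈ 0.069, K_ep ≈ 0.018 — both
*below* the stage-1 estimates, the underestimation that motivates the
two-stage analysis.

`dcekin report -c config.yaml` runs the full pipeline (convert → AIF →
kinetic fit) and writes `report.json` (validated against
`src/dcekin/report_schema.json`) plus a fitted-vs-observed plot. 4D
NIfTI volumes with a binary ROI mask can be reduced to a mean time
series with `dcekin.io.roi_mean_series`.

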