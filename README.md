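# eitflow

Regional respiratory gas-flow analysis of electrical impedance tomography
(EIT) time series recorded during mechanical ventilation, together with the
spirometry comparison statistics and a pressure-controlled-ventilation (PCV)
simulator that provides closed-form ground truth for every stage.

## What it does

An EIT record is a `T x 32 x 32` stack of relative-impedance tomograms
(default 13 frames/s, 60 s). The analysis chain:

1. **ROI sums** (`eitflow.eit_signal`) — rows 0–23 form the global region of
   interest, split into ventral/middle/dorsal 8×32 strips; the dorsal-most
   8×32 block contains no lung and is excluded. `Z_global = Z_ventral +
   Z_middle + Z_dorsal` holds by construction.
2. **Breath segmentation** (`eitflow.breath_phase`) — inspiration onsets
   from upward zero-crossings of the global backward-difference flow, with
   amplitude hysteresis and a half-cycle refractory period.
3. **Volume calibration** — the mean per-breath peak-to-trough amplitude of
   the global impedance (`Z_T`) maps impedance to millilitres via the
   ventilator tidal volume: `V_ROI(t) = Z_ROI(t) * V_T / Z_T`.
4. **Flow** — backward difference `V'(t_n) = (V(t_n) - V(t_{n-1})) * fs`,
   defined for every time point except the first.
5. **Phase metrics** — per breath and region: peak inspiratory/expiratory
   flow (PIF/PEF, cycle extrema of the flow) and late inspiratory/expiratory
   flow (LIF/LEF, average slope of the volume curve over 3.0 s starting
   0.5 s after the respective peak; OLS slope by default, endpoint slope as
   an option). The windowed slope rejects the cardiac oscillation.
6. **Spirometry arm** (`eitflow.spirometry`) — the same four metrics from a
   100 Hz flow trace (late flow = mean flow in the window, since flow is
   measured directly), plus optional cross-correlation lag alignment.
7. **Comparison statistics** (`eitflow.validation_stats`) — per-metric OLS
   regression (EIT on spirometry) with r², Bland-Altman bias / 95% limits of
   agreement / proportional-error slope, and the regional tidal-volume
   distribution in percent of the global amplitude.

The simulator (`eitflow.synthetic_data`) generates paired EIT + spirometry
records from a three-compartment PCV model (exponential filling/emptying,
normalized for exact per-breath volume conservation), with optional cardiac
sinusoid, pixel noise, a "tissue inertance" low-pass on the EIT path, a
lavage-injury preset, and analytic per-breath ground truth on both sampling
grids (`analytic_ground_truth`).

## Command line

```sh
# simulate a 60 s paired record (writes eit_frames.txt, spirometry.txt,
# ground_truth.tsv, config_resolved.ini)
eitflow simulate --out run/ --seed 1 --rr 8 --vt 300

# analyze an EIT record (per-breath metrics, per-ROI summary,
# tidal-volume distribution)
eitflow analyze --eit run/eit_frames.txt --out run/analysis \
    --rr 8 --vt 300 --estimator ols

# compare EIT against paired spirometry (regression + Bland-Altman
# per metric; repeat --eit/--spiro for multi-record studies)
eitflow compare --eit run/eit_frames.txt --spiro run/spirometry.txt \
    --out run/comparison --lag-correction --plots
```

All file formats are plain text (see `eitflow/cli_io.py` docstring); every
command writes its resolved configuration next to the outputs.

## Layout

```
src/eitflow/
  eit_signal.py        ROI sums, calibration, backward-difference flow
  breath_phase.py      segmentation, PIF/LIF/PEF/LEF, summaries
  spirometry.py        spirometric metrics, lag estimation, pairing
  validation_stats.py  regression, Bland-Altman, tidal distribution
  synthetic_data.py    PCV simulator + closed-form ground truth
  cli_io.py            file formats, pipeline binding, CLI
tests/                 unit, property and acceptance suites
scripts/acceptance.py  acceptance-target report
```
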