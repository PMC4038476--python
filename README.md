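# touchzap

Simulation and analysis of **touch-and-zap** whole-cell patch-clamp
recordings: passive-parameter extraction with electrode-artifact handling,
electroporation ("zap") event detection and endpoint classification,
neuron/glia typing, and cohort statistics — together with an electrode+cell
equivalent-circuit simulator that synthesizes complete recording sessions
with ground truth, so every analysis stage is testable without real data.

## The problem

In the touch-and-zap protocol for obtaining whole-cell access in vivo, a
patch electrode descends through cortex under current clamp while a 10 Hz,
50% duty-cycle train of −1.11 nA pulses monitors its impedance.  Cell
contact (the *touch*) shows as a small sustained rise in per-pulse
resistance; releasing the pipette pressure starts spontaneous seal
formation, and as the seal resistance R_seal grows, the pulse voltage
V = I·(R_e + R_seal) becomes deeply hyperpolarizing until it crosses the
membrane breakdown voltage (≈ −300 to −400 mV) and electroporates the patch
— the *zap* — yielding whole-cell access with no suction.  Sessions end in
one of three endpoints: **TZ** (zap only), **TZS** (zap, membrane reseals,
access re-established by suction) or **TS** (no zap; seal formed slowly and
broken by suction).

Off-line, the linear cell parameters are extracted from 0.5 s current steps
by a heuristic modeled on visual bridge balancing.  For each sweep:

* V_rest — mean of spike-free pre-stimulus baseline windows;
* V_ss — mean over [onset+100 ms, onset+200 ms);
* V_O — cubic fit to the 2 ms before onset, evaluated at onset;
* τ0 — two-pass log-linear regression of V′ = ±(V − V_ss): the first pass
  runs from onset+0.5 ms (after the fast electrode artifact has decayed)
  until V′ reaches 0.3·|V_ss − V_rest|; the second pass restarts at
  onset + 0.2·τ0⁽¹⁾;
* R_a error = (V_fit(onset) − V_O) / I — the uncompensated access
  resistance left by the amplifier bridge;
* R_in = (V_ss − I·R_a_error − V_rest) / I.

Cohort statistics include the relative cell-size proxy
L_rel = √(1/R_in) normalized to the cell-type mean, endpoint proportions,
pooled two-proportion z tests, Student/Welch t tests and Pearson/Spearman
correlations.

## A worked example

`examples/01_fit_passive_parameters.py` simulates a sweep with a known
20 MOhm uncompensated bridge residual (τ_e = 0.1 ms) on a 100 MOhm / 10 ms
membrane with 0.3 mV noise, and fits it:

```
V_rest      -70.00 mV   (truth -70.0)
V_ss        -82.00 mV
tau0         10.13 ms   (truth 10.0)
R_a error    20.79 MOhm (truth 20.0)
R_in         99.21 MOhm (truth 100.0)
```

The fitted charging curve extrapolated to stimulus onset sits I·R_a_error
away from the pre-step voltage, recovering the bridge residual; removing
that drop from the steady state gives the true input resistance.

`examples/02_detect_access_events.py` runs the detection pipeline on a
simulated two-zap TZS session:

```
endpoint: TZS   (simulated: TZS)
V_zap = -330.7 mV   (breakdown voltage -330 mV)
T_zap = 2.50 s   (delay from pressure release to first zap)
detected events:
    1.50 s  touch  value=0.5
    4.50 s  zap  value=-330.7
    4.83 s  zap  value=-211.2
    7.40 s  reseal  value=302.1
   11.00 s  suction_break  value=94.5
```

The other examples run the full simulate → fit → classify → summarize
pipeline on a 12-cell cohort and recompute the reference cohort's headline
numbers (endpoint proportions, glial yield, relative access resistance,
L_rel ratio).

## Command line

A thin CLI wraps the same pipeline on TSV/CSV files:

```
touchzap simulate --seed 7 --n-cells 20 --out cohort/
touchzap fit      --in cohort/ --out cohort/fits.csv
touchzap detect   --in cohort/ --out cohort/endpoints.csv
touchzap classify --in cohort/ --fits cohort/fits.csv \
                  --endpoints cohort/endpoints.csv --out cohort/records.csv
touchzap cohort   --records cohort/records.csv --out cohort/report.txt
```

All detection and fitting thresholds are overridable through a flat TOML
config (`--config`); identical seed + config reproduce outputs
byte-identically.

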