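# Methods

This note documents the models, estimators and design choices behind
`touchzap`: what the simulator generates, how the analysis stages work, the
tunable parameters that matter, and what the tests do and do not establish
about real recordings.

## Equivalent-circuit model

A whole-cell step response is modeled as two first-order components in
series with the resting potential:

    V(t) = E_rest + I·R_a_eff·(1 − e^(−t/τ_e)) + I·R_in·(1 − e^(−t/τ_m))

* `R_a_eff = bridge_error` — the **residual** access resistance the analyst
  sees after on-line bridge compensation (the full R_a is what the bridge
  setting plus this residual reconstruct);
* `τ_e` — electrode time constant, default 0.15 ms.  Only its order of
  magnitude is constrained (a few hundred microseconds, one to two decades
  below the cell); all fast dynamics, including pipette capacitance, are
  folded into this single exponential;
* `τ_m`, `R_in`, `E_rest` — passive membrane parameters.

Units everywhere: mV, nA, MΩ (so V = I·R directly), time constants in ms,
protocol times in s; sample intervals are half-open.  Gaussian voltage
noise of sd `noise_rms` is added last.  A causal 4th-order Bessel low-pass
(`bessel_lowpass`, default cutoff 10 kHz) models the acquisition filter but
is **off by default**, so the simulator's output is exactly the analytic
solution plus noise; tests rely on that.

Spiking cells are leaky integrate-and-fire: the passive trajectory runs to
an absolute threshold (default E_rest + 22 mV), where a stereotyped 2 ms
piecewise-linear spike is pasted — linear rise at exactly `dvdt_max`
(default 230 mV/ms) to `peak_mv` (default +11 mV), linear fall to a reset.
This is deliberately non-biophysical: it exists to exercise spike
detection, the 50 mV classification criterion, and the dV/dt / peak
metrics with known ground truth.

## Session model

A session log renders the monitoring pulse train (10 Hz, 50% duty,
−1.11 nA) against a piecewise resistance trajectory:

* bath: R_e (4–8 MΩ), optionally modulated by a sinusoidal artifact
  (`artifact_frac`, default 0) emulating cardiac/movement coupling;
* touch: + a few hundred kΩ (`delta_r_touch`, default 0.5 MΩ);
* sealing: after pressure release the seal grows exponentially toward a
  2 GΩ ceiling.  No functional form is prescribed by the phenomenology
  ("seals form within seconds"), so the exponential is a modeling choice;
  its initial slope is the scenario's `seal_rate_mohm_s`, and
  `seal_rate_for_delay` inverts the growth law so the breakdown voltage is
  reached at a prescribed delay after release;
* zap: fires at the **first sample** where the pulse voltage reaches the
  breakdown threshold (V_bd for the first zap; `second_zap_offset_mv`
  (100–150 mV) less hyperpolarized for a second zap, present in ~75% of
  simulated TZ/TZS attempts).  Because the seal grows continuously within
  the on-phase, the true zap voltage equals the threshold to within one
  sample of envelope growth;
* whole cell: the electrode sees R_e + R_a instantaneously plus R_in
  charging with τ_m; the command is reduced to −0.111 nA at the next pulse
  (as the experimenter would), and the DC level settles to E_rest on the
  membrane time scale;
* TZS: the membrane reseals `reseal_delay_s` (1.5 s) after the final zap
  and regrows at `reseal_rate_mohm_s` (250 MΩ/s — resealing is a distinct,
  faster process than the initial approach seal); scripted suction then
  restores access;
* TS: the seal grows slowly, the command is stepped down whenever
  deflections would exceed ~150 mV, and access comes from suction alone.

Ground truth (touch, zaps with true V_zap, reseal, suction break) and
experimenter annotations (pressure release, current changes, suction) are
attached to every log.

Session logs default to 5 kHz sampling (IV sweeps to 40 kHz): per-pulse
plateau estimation needs only millisecond resolution, and sub-sample
electrode charging does not affect the last-25%-of-on-phase plateau.  The
`dt ≤ τ_e/2` resolution requirement is enforced for step sweeps, where the
artifact shape matters.

## Cohort generator

`simulate_cohort` draws per-cell parameters from truncated normals whose
defaults are the recorded cohort summaries shipped in
`touchzap.reference`: neurons R_in 56±31 MΩ, τ_m 9.8±5.2 ms, V_rest
−76±7.5 mV, V_bd −330±53 mV, endpoint mix 48/40/12% (TZ/TZS/TS); glia
R_in 90±62 MΩ, τ_m 1.5±2.9 ms truncated below 5 ms (so ground-truth glia
satisfy the classifier's criterion by construction), V_bd −350±64 mV, mix
61/24/15%.  The zap delay T_zap is sampled **lognormally**: the recorded
delay distributions are right-skewed, and a lognormal matched to the
published median and mean (2.1/2.6 s neurons, 3.2/4.2 s glia) reproduces
the published SDs almost exactly (1.86 vs 1.9; 3.56 vs 3.2) — so matching
median+mean was preferred over matching mean+SD.

Each cell gets a session plus IV sweeps whose amplitude targets an ~8 mV
steady-state deflection (inside the ±10 mV acceptance screen).  The bridge
is modeled as recompensated before each sweep: every sweep carries a fresh
residual around the cell's `bridge_error` (mean 4 MΩ), while the stored
bridge *setting* follows the drifting true R_a (drift ~1.3 MΩ/min), so
setting + fitted residual recovers R_a(t) and its trend.  Sweep noise
defaults to 0.5 mV rms — clean relative to in vivo synaptic bombardment,
which the generator does not model (see Limitations).

## Passive-fit heuristic

Implemented exactly as described in the README, with these numerical
choices where the procedure is under-specified:

* minimum points: 10 for the log-linear regression, 8 samples for the
  cubic V_O fit;
* non-positive V′ samples (noise crossing the asymptote) are excluded;
  if they exceed 20% of the window the fit aborts;
* the stop crossing is the first sample at or below threshold, no
  interpolation (sub-sample timing is immaterial at 40 kHz);
* if the 0.3·ΔV stop threshold is crossed before the window opens (very
  fast cells), the stop is extended to preserve the minimum point count;
  the resulting τ0 is biased when τ_m approaches τ_e, and a test
  quantifies that bias against a two-exponential NLS oracle rather than
  hiding it — confidence in sub-millisecond glial time constants is
  correspondingly lower;
* acceptance screen: steady state within ±10 mV of rest; spike screen
  dV/dt > 10 mV/ms with amplitude > 20 mV above the envelope; sag screen:
  a > 2 mV non-monotonic excursion beyond V_ss after 3·τ0⁽¹⁾, judged on a
  5 ms-smoothed trace so noise extremes over the long late window cannot
  mimic a sag.  The exclusions are named by the protocol; the thresholds
  are ours;
* whether the R_a-error adjustment is applied to V_ss or to the whole
  trace is immaterial for the steady-state R_in formula; the steady-state
  adjustment is implemented;
* per-cell values are unweighted means of accepted sweeps; the R_a mean
  and drift come from OLS over (time, R_a) estimates (for OLS the
  regression mean equals the arithmetic mean, but the regression is kept
  as the defining procedure).

Accuracy under the simulator (noiseless, τ_e ≤ 0.3 ms, τ_m ≥ 5 ms, over
random draws): τ0 within 5%, R_in within 2%, R_a error within 10% of
ground truth, and within 10% of a brute-force two-exponential nonlinear
least-squares oracle whenever τ_m/τ_e ≥ 20.

## Event detection

Per pulse, total resistance = (plateau − baseline deflection)/amplitude,
with the plateau over the last 25% of the on-phase and the baseline over
the preceding off-phase; amplitudes are measured from the current channel,
so command reductions are handled per pulse.  With τ_m ~10 ms the membrane
does not fully charge in the 50 ms on-phase and its discharge leaks into
the baseline window, so whole-cell estimates sit a few percent below
R_e + R_a + R_in; this truncation is accepted, not corrected.

* **touch** — first pulse ≥ 5% above the rolling 10-pulse median,
  sustained 3 pulses.  Electrode stability is judged on the pre-touch
  stretch by an sd-based peak-to-peak equivalent (2√2·sd of a median-of-3
  smoothed relative series, with the smoothing attenuation undone); at
  ~20% the attempt is flagged `unstable` and abandoned, emulating the
  protocol's abort rule for cardiac/movement artifacts;
* **zap** — a ≥ 40% drop in per-pulse resistance at full command
  amplitude with a pulse peak at or below −150 mV.  Electroporation inside
  a plateau window leaves one mixed-value pulse, so the drop may complete
  over two pulses; and a cell whose whole-cell load is close to the seal
  at breakdown produces a genuinely small drop, so a ≥ 10% drop is also
  accepted when the off-phase DC level shifts ≥ 15 mV toward rest right
  after it (the envelope signature of whole-cell access).  V_zap is the
  most hyperpolarized sample over the pulse pair spanning the drop; up to
  two zaps, separated by ≥ 0.25 s;
* **reseal** — post-zap growth to ≥ 3× the settled post-zap level,
  sustained ≥ 1 s;
* **suction break** — taken from the experimenter annotation, kept only
  when a ≥ 20% resistance drop corroborates it within 0.5 s; drops in that
  window are never counted as zaps;
* **T_zap** — first zap minus pressure release (ordering enforced).

Endpoints: TZ = zap(s) with neither reseal nor suction; TZS = zap →
reseal → suction; TS = touch and suction with no zap; otherwise FAIL with
a named reason.  On simulated neuron-parameterized sessions the noiseless
confusion matrix is diagonal and accuracy stays above 95% at 2 mV noise.
All thresholds live in `DetectionConfig`; none are hard-coded.

## Classification and QC

Neuron: any current-evoked spike ≥ 50 mV from rest.  Glia: no spikes and
τ0 < 5 ms.  Everything else unclassified.  Spike detection (threshold
rest + 20 mV, 1 ms refractory) merges threshold crossings whose
excursions fall within one refractory period, because noise chatters
around the threshold just before a genuine upstroke.  The four-way firing
taxonomy (RS/FS/IB/CH) is an externally supplied label only.  QC flags:
`high_Ra` (initial > 50 MΩ), `Ra_drift` (> 1.5× initial), `Vrest_drift`
(> 20 mV), `excluded_Rin` (> 500 GΩ), `movement`; flags are monotone in
new samples.  The oblique-trajectory depth correction (depth·cos θ) is a
helper and never applied silently.

## Statistics

Closed-form implementations (pooled two-proportion z; Student/Welch t;
Pearson r², Spearman ρ with a one-sided Fisher-z p on the rank
correlation), cross-checked in tests against scipy/statsmodels to 1e-10.
Group comparisons in reports are per-variable pairwise tests; no
multivariate test is attempted, and report headers say so.  L_rel group
means equal 1 over their own normalization cohort by construction.
Percentages are rounded half-away-from-zero only at presentation.

Two inconsistencies in the reference numbers are surfaced, not silently
resolved: the wash-and-suction glial yield is quoted as "5 of 28" where
the count table gives 33 (5/33 = 15.2% matches the quoted 15%, so the
table is used); and the quoted 73% of glia reaching TZ+TZS differs from
the tabulated 85%.  The tabulated neuron TS share is 11.5%, quoted as 12%.

## What passing tests do and do not show

The simulator provides exact ground truth and clean noise, which is what
makes the recovery guarantees sharp; real recordings add synaptic
bombardment, slow drift, electrode nonlinearity at large currents and
non-exponential seal growth, none of which are modeled.  Passing tests
therefore establish that the estimators are correct under the stated
model, and bound their artifact-induced biases (electrode-artifact
truncation, plateau truncation, fast-τ_m bias) — they do not certify
performance on arbitrary in vivo data.  Known limitations: glial cells
whose whole-cell resistance approaches the seal resistance at breakdown
can defeat any drop-based zap detector (the DC-shift corroboration
recovers most, not all, of that tail); and the single-exponential fit is
the procedure's own simplification — higher-order fits are out of scope.

## Problem sizes

Default suites run: 100 random draws for parameter recovery and oracle
equivalence, 200 sessions for the endpoint confusion matrix, 60 noisy
sessions for noise robustness, and cohorts of 12–91 cells elsewhere; the
acceptance script simulates 150 sessions per cell type and a 60-cell
cohort for the bridge-residual mean.
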