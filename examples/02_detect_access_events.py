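"""Detect touch, zap, reseal and suction in a simulated access attempt.

Simulates a full touch-zap-suction (TZS) session: the electrode touches the
cell at 1.5 s, pressure is released at 2.0 s, the growing seal drives the
-1.11 nA pulse train to the membrane breakdown voltage (two zaps), the
membrane reseals, and whole-cell access is re-established by suction.  The
detection pipeline then recovers the endpoint from the raw log alone.
"""

from touchzap import CircuitParams, analyze_session, scenario_for, simulate_session

params = CircuitParams(R_in=56.0, R_a=35.0, E_rest=-76.0, V_bd=-330.0, noise_rms=0.5)
scenario = scenario_for("TZS", params, t_zap_s=2.5, n_zaps=2)
log = simulate_session(params, scenario, seed=4)

call = analyze_session(log)

print(f"endpoint: {call.endpoint}   (simulated: {log.meta['endpoint_true']})")
print(f"V_zap = {call.V_zap:.1f} mV   (breakdown voltage {params.V_bd:.0f} mV)")
print(f"T_zap = {call.T_zap:.2f} s   (delay from pressure release to first zap)")
print("detected events:")
for e in log.events:
    val = "" if e.value is None else f"  value={e.value:.1f}"
    print(f"  {e.time_s:6.2f} s  {e.kind}{val}")
print()
print("TZ = zap only; TZS = zap, reseal, then suction; TS = no zap, seal")
print("formed slowly and broken by suction; anything inconsistent is FAIL.")
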