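"""Recompute the reference cohort's headline numbers.

Uses the recorded counts and example-cell values shipped in
``touchzap.reference`` — the published inputs the simulator defaults are
built from — and recomputes endpoint proportions, glial recording yield,
relative access resistances, and the relative-cell-size ratio.
"""

from touchzap import endpoint_proportions, relative_access_resistance
from touchzap.reference import COHORT_COUNTS, EXAMPLE_RA_RIN, L_REL_GLIA
from touchzap.stats import class_proportion

counts = COHORT_COUNTS.groupby("cell_class").sum()
props = endpoint_proportions(counts)
print("endpoint proportions (denominator = TZ+TZS+TS recordings):")
for cls in ("neuron", "glia"):
    row = ", ".join(f"{ep}: {100 * props.loc[cls, ep]:.0f}%" for ep in ("TZ", "TZS", "TS"))
    print(f"  {cls:7s} {row}")

p, x, n = class_proportion(COHORT_COUNTS, "glia")
print(f"\nglial share of touch-step recordings: {x}/{n} = {100 * p:.0f}%")
p, x, n = class_proportion(COHORT_COUNTS, "glia", endpoints=("WS",))
print(f"glial share of wash-and-suction recordings: {x}/{n} = {100 * p:.0f}%")
print("(the touch step nearly doubles the glial yield)")

print("\nrelative access resistance R_a/R_in of the example recordings:")
for label, ra, rin in EXAMPLE_RA_RIN:
    print(f"  {label:28s} {ra:4.0f}/{rin:3.0f} = {relative_access_resistance(ra, rin):.2f}")

ratio = L_REL_GLIA["TZ+TZS"][0] / L_REL_GLIA["WS"][0]
print(f"\nglial relative cell size, touch-zap vs wash-and-suction: "
      f"{L_REL_GLIA['TZ+TZS'][0]:.2f}/{L_REL_GLIA['WS'][0]:.1f} = {ratio:.3f}")
print("(touch-zap reaches smaller glial cells than the classical approach)")
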