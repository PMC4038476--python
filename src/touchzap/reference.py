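"""Reference cohort data: recorded counts and summary statistics from an
adult rat/cat cortical in vivo whole-cell dataset obtained with the
touch-and-zap and wash-and-suction access methods.

These published summary numbers are the inputs to the package's worked
examples and parameterize the cohort simulator defaults: cell counts by
species, class and access endpoint; per-recording (R_a, R_in) pairs from
individual example cells; group means of the relative-size statistic L_rel;
and the zap voltage/delay distributions.

Note: the source text quotes the wash-and-suction (WS) glial proportion as
"5 out of 28"; the count table gives 33 WS recordings, and 5/33 = 15.2%
matches the quoted 15%, so the tabulated 33 is used here (the 28 is treated
as a typo).  Similarly the quoted 73% of glia reaching TZ+TZS differs from
the tabulated counts (85%); the counts are authoritative in this package.
"""

from __future__ import annotations

import pandas as pd

#: recordings by species, cell class and whole-cell access method
COHORT_COUNTS = pd.DataFrame(
    [
        ("rat", "neuron", 28, 22, 14, 3),
        ("rat", "glia", 5, 8, 3, 2),
        ("cat", "neuron", 0, 37, 35, 11),
        ("cat", "glia", 0, 20, 8, 5),
    ],
    columns=["species", "cell_class", "WS", "TZ", "TZS", "TS"],
).set_index(["species", "cell_class"])

#: example recordings: (label, on-line/off-line corrected R_a in MOhm, R_in in MOhm)
EXAMPLE_RA_RIN = [
    ("regular_spiking_neuron_TZ", 21.0, 102.0),
    ("bursting_neuron_TZ", 61.0, 70.0),
    ("fast_spiking_neuron_TS", 37.0, 26.0),
    ("glia_TZ", 45.0, 105.0),
    ("glia_TZS", 40.0, 99.0),
    ("glia_WS", 48.0, 100.0),
]

#: group means of the relative linear cell size L_rel (mean, sd, n)
L_REL_GLIA = {"TZ+TZS": (0.92, 0.9, 39), "WS": (1.6, 1.4, 5)}

#: zap voltage V_zap in mV (mean, sd, n) for pooled TZ+TZS recordings
V_ZAP = {"neuron": (-330.0, 53.0, 91), "glia": (-350.0, 64.0, 34)}

#: zap delay T_zap in s (mean, sd, n, median) for pooled TZ+TZS recordings
T_ZAP = {"neuron": (2.6, 1.9, 87, 2.1), "glia": (4.2, 3.2, 33, 3.2)}

#: glial vs neuronal recording yield: (glia recordings, total recordings)
GLIA_YIELD = {"touch": (46, 168), "WS": (5, 33)}

__all__ = [
    "COHORT_COUNTS",
    "EXAMPLE_RA_RIN",
    "L_REL_GLIA",
    "V_ZAP",
    "T_ZAP",
    "GLIA_YIELD",
]
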