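"""Compare fold-change and mean scaling on a replicate with a bad first reading.

Builds a two-replicate melting curve where the second replicate's reading at
the lowest temperature is corrupted, then prints the between-replicate
divergence (median difference M, variance of differences V) under both
scalings.  Fold change divides by exactly that corrupted reading, spreading
the error across every temperature; mean scaling confines it to one point.
"""

import numpy as np
import pandas as pd

from meltgp import read_long_table, replicate_divergence

temps = np.linspace(37, 67, 10)
curve = 1.0 / (1.0 + np.exp((temps - 50) / 4)) + 0.05

rows = []
for rep, vals in (("R1", curve), ("R2", curve.copy())):
    vals = vals.copy()
    if rep == "R2":
        vals[0] *= 2.5  # corrupted lowest-temperature reading
    for t, v in zip(temps, vals):
        rows.append(("EXAMPLE", "Ctrl", rep, t, 1e6 * v))
table = pd.DataFrame(
    rows, columns=["id", "condition", "replicate", "temperature", "abundance"]
)

dataset = read_long_table(table)["EXAMPLE"]
for method in ("fold_change", "mean"):
    (div,) = replicate_divergence(dataset, method=method)
    print(f"{method:12s}  M = {div.median:+.4f}   V = {div.variance:.6f}")

print(
    "\nV is the between-replicate variance of per-temperature differences: "
    "a large V under fold change but not under mean scaling is the "
    "signature of an outlier at the first temperature."
)
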