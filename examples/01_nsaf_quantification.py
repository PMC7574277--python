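"""NSAF quantification and the preprocessing chain on a tiny count table.

Builds a 4-protein x 2-sample spectral-count table, converts it to NSAF
(spectral count over protein length, normalized so each sample sums to 1),
replaces zeros by 1/8 of the smallest nonzero value, and log2-transforms.
"""

import pandas as pd

from protasca import (
    PreprocessParams,
    SpectralCountTable,
    compute_nsaf,
    log2_transform,
    replace_zeros,
)

counts = pd.DataFrame(
    {"s1": [10, 20, 40, 0], "s2": [8, 0, 12, 30]},
    index=pd.Index(["pA", "pB", "pC", "pD"], name="protein_id"))
lengths = pd.Series([100, 200, 400, 150], index=counts.index)
table = SpectralCountTable(counts=counts, lengths=lengths)

nsaf = compute_nsaf(table)
print("NSAF (each sample column sums to 1):")
print(nsaf.values.round(4))
print("column sums:", nsaf.values.sum().round(9).to_dict())

replaced = replace_zeros(nsaf, PreprocessParams(zero_replacement_fraction=0.125))
mn = nsaf.values.to_numpy()[nsaf.values.to_numpy() > 0].min()
print(f"\nminimum nonzero NSAF {mn:.4f}; zeros became {0.125 * mn:.6f}")

logged = log2_transform(replaced)
print("\nlog2 NSAF (input to PCA/ASCA):")
print(logged.values.round(3))
# Each value is a relative abundance on a doubling scale: a difference of 1
# between two samples means a two-fold change for that protein.
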