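"""Rarity index and group assignment on a tiny abundance table.

Three genomes screened against 10 runs: one detected often at high
abundance, one sporadically at low abundance, one never.
"""

import pandas as pd

from rarescope.rarity import assign_rarity_groups, rarity_index

rows = []
for i in range(1, 11):
    rows.append((f"R{i}", "MAG_common", 0.30 if i <= 8 else 0.0))
    rows.append((f"R{i}", "MAG_rare", 0.02 if i <= 3 else 0.0))
    rows.append((f"R{i}", "MAG_absent", 0.0))
abundance = pd.DataFrame(rows, columns=["run_id", "genome_id",
                                        "relative_abundance"])

results = assign_rarity_groups(rarity_index(abundance, total_runs=10))
print(results.to_string(index=False))
print(f"\nmedian rarity cutoff: {results.attrs['median_rarity']:.4f}")
# rarity = median detected abundance x occurrence fraction, in percent units.
# MAG_common: 0.30 x 0.8 = 0.24 -> common; MAG_rare: 0.02 x 0.3 = 0.006 -> rare;
# MAG_absent is never detected and forms the third group.
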