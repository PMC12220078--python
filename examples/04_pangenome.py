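"""Core genome, group-specific orthogroups and pairwise sharing."""

import pandas as pd

from rarescope.pangenome import (
    core_orthogroups,
    group_specific_orthogroups,
    shared_fraction_matrix,
)

counts = pd.DataFrame(
    {
        "sed1": [1, 1, 1, 0, 0, 1],
        "sed2": [1, 1, 0, 0, 0, 1],
        "wat1": [1, 0, 0, 1, 1, 1],
        "wat2": [1, 0, 0, 1, 0, 1],
    },
    index=[f"og{i}" for i in range(1, 7)],
)

print("core (tau=0.9):", core_orthogroups(counts, 0.9))
# 4 genomes -> an orthogroup must be present in ceil(3.6) = 4 of them

grouping = {"sed1": "sediment", "sed2": "sediment",
            "wat1": "water", "wat2": "water"}
specific, intersections = group_specific_orthogroups(counts, grouping)
print("sediment-specific:", specific["sediment"])
print("water-specific:", specific["water"])
print("\nintersection cells (partition the orthogroup universe):")
print(intersections.to_string(index=False))

print("\nshared orthogroup percentage (100 x |∩|/|∪|):")
print(shared_fraction_matrix(counts).round(1).to_string())
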