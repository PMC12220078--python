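"""Relative evolutionary divergence (RED) and rank assignment.

RED maps every node of a rooted tree onto [0, 1] (root 0, leaves 1) so
clade depths are comparable; internal nodes are then matched to the
nearest user-supplied reference RED value per rank.
"""

from rarescope.io_formats import parse_newick
from rarescope.phylo import assign_ranks, compute_red

tree = parse_newick("(((A:1,B:1):0.5,(C:1,D:1.5):0.8):1.2,(E:2,F:2.5):0.9);")
red = compute_red(tree)
print(red.to_frame().to_string(index=False))

# reference values are release-dependent (e.g. GTDB medians); supplied here
reference = {"order": 0.35, "family": 0.55, "genus": 0.80}
ranks = assign_ranks(red, reference, tolerance=0.25)
print("\nrank assignments (internal nodes):")
for node_id, rank in ranks.items():
    print(f"  {node_id}: red={red.values[node_id]:.3f} -> {rank}")
# Nodes farther than the tolerance from every reference come back
# "unassigned"; the root (red 0) typically does.
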