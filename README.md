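# rarescope

Characterization of rare-biosphere lineages from metagenome-assembled
genomes (MAGs). Most microbial taxa in the environment are rare — present
at very low relative abundance, in few samples, or both — which makes
them hard to quantify and leaves large fractions of their gene content
without functional annotation. `rarescope` implements, as a tested and
reusable Python library, the analysis chain used to study such lineages
when a set of MAGs is screened against thousands of public sequencing
runs:

- **Screening & quantification** — per-read alignment filters (minimum
  read identity, aligned fraction, overlap), per-genome mean coverage and
  breadth, cumulative-coverage study selection (strict `> 2` fold), and
  breadth/identity-filtered relative abundance:
  `RA(g) = 100 · mapped_fraction · cov(g) / Σ_h cov(h)` over genomes with
  breadth ≥ 50 %, with genome quality gates (completeness > 80 %,
  contamination < 5 %) and two-level ANI dereplication (primary 0.90,
  secondary 0.95, minimum aligned fraction 0.5).
- **Rarity index** — per genome,
  `rarity = median(RA | detected) · n_detected / n_screened`, followed by
  a median split into *rare* / *common*, with never-detected genomes as a
  third group.
- **Annotation-status classification** — blast-score-ratio filtering
  (BSR = bitscore / self-bitscore ≥ 0.4), then a three-way partition of
  genes into *annotated* / *hypothetical* / *unknown* from their KEGG/NR
  hits, plus extracellular-peptidase (SignalP "SP" + MEROPS) and CAZyme
  (> 1 dbCAN annotation + KEGG/NR backing) validation rules.
- **Pan/core-genome analysis** — core orthogroups (present in ≥ 90 % of
  genomes, ceiling rule), group-specific orthogroups with upset-style
  intersections, pairwise shared-orthogroup percentages and Jaccard
  dissimilarities, and focal-vs-rest carriage proportions by status.
- **Phylogenetics** — relative evolutionary divergence
  `red(v) = red(p) + d/(d+u) · (1 − red(p))` for taxonomic rank
  delineation, and Wagner-parsimony ancestral gene-content reconstruction
  (Sankoff dynamic program, configurable gain penalty, per-branch
  gain/loss/expansion/contraction calls).
- **Statistics** — two-sided Wilcoxon rank-sum tests (exact by full
  enumeration for small tie-free samples), Bonferroni-adjusted thresholds
  (`α/m`), Cliff's delta effect sizes, and the headline comparison of
  unknown-gene percentages across rarity groups.
- **Synthetic data** — generators for every input (Yule trees, gene
  content evolved with recorded events, abundance matrices with planted
  rare/common structure, annotation tables with a tunable rarity →
  unknown-gene effect) so the whole chain is testable against known
  ground truth with no downloads.

## Worked example

```python
import pandas as pd
from rarescope.rarity import rarity_index, assign_rarity_groups

rows = []
for i in range(1, 11):
    rows.append((f"R{i}", "MAG_common", 0.30 if i <= 8 else 0.0))
    rows.append((f"R{i}", "MAG_rare",   0.02 if i <= 3 else 0.0))
    rows.append((f"R{i}", "MAG_absent", 0.0))
abundance = pd.DataFrame(rows, columns=["run_id", "genome_id", "relative_abundance"])
print(assign_rarity_groups(rarity_index(abundance, total_runs=10)).to_string(index=False))
```

prints

```
 genome_id  median_detected_abundance  occurrence_fraction  rarity        group
MAG_absent                       0.00                  0.0   0.000 not_detected
MAG_common                       0.30                  0.8   0.240       common
  MAG_rare                       0.02                  0.3   0.006         rare
```

`MAG_common` is detected in 8 of 10 screened runs at median 0.30 % →
rarity 0.24; `MAG_rare` in 3 of 10 at 0.02 % → 0.006; the median split
over detected genomes separates them, and the never-detected genome forms
its own group. The `examples/` directory holds one short script per
capability (rarity, RED and ranks, Wagner events, pangenome, full
pipeline).

## Command line

A thin CLI mirrors the library:

```
rarescope simulate --seed 3 --out-dir fixtures
rarescope all --config pipeline.yaml        # simulate -> ... -> stats
rarescope rarity --abundance abundance.tsv --metadata runs.tsv
rarescope red --tree tree.nwk
rarescope wagner --tree tree.nwk --gene-counts counts.tsv --gain-penalty 1
```

All inputs are plain TSV (OrthoFinder gene-count dialect, coverm-like
coverage tables, blast outfmt-6 hit tables plus database/description
columns) and Newick; reports are deterministic TSV directories.

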