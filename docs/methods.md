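# Methods

## Scope and data model

`rarescope` covers the downstream, tabular half of a rare-biosphere MAG
survey: it consumes the outputs of read mappers, annotation engines,
orthology inference and ANI estimation (as TSV), and implements the
screening statistics, rarity index, annotation-status rules, pangenome
set analyses, tree statistics and group tests on top of them. It does
not map reads, assemble, bin, infer trees, or run homology searches.

All tables are UTF-8 TSV with a header; floats serialize at six
significant digits so reports are byte-reproducible. Abundance data are
canonically long-form `(run_id, genome_id, relative_abundance)` in
percent. Gene counts follow the OrthoFinder `Orthogroups.GeneCount.tsv`
dialect (trailing `Total` column ignored). Annotation hits follow blast
outfmt-6 order plus a database tag (`KEGG, NR, MEROPS, dbCAN, TCDB,
SignalP`) and a free-text description.

## Screening and quantification

Alignment retention is inclusive (≥) for read identity (default 50 % for
the broad screening pass, 95 % for quantification), aligned fraction of
the read (0.5), reference overlap (30 bp) and breadth of coverage
(0.5) — whether the original tools treat the exact boundary as inclusive
is not documented, so a single inclusive convention is used and tested.
The cumulative-coverage study cutoff (> 2-fold) and the genome quality
gates (completeness > 80 %, contamination < 5 %) are strict, matching the
operators these rules are stated with.

Mean coverage is summed aligned span over genome length; breadth is
computed by a difference-array sweep and agrees with per-base counting.
Relative abundance splits `100 · mapped_fraction` of a run across the
genomes surviving the breadth filter, proportionally to mean coverage;
per run the abundances therefore sum to `100 · mapped_fraction` whenever
any genome survives, and "detected" means RA > 0 after all filters.
This is a documented reimplementation of the coverm-style quantity, not
a bit-for-bit clone of any particular coverm mode.

Dereplication clusters genomes as connected components at a primary ANI
of 0.90, then secondary components at ANI 0.95 with aligned fraction
≥ 0.5; asymmetric estimates are symmetrized by the maximum of the two
directions (component intent), missing pairs are no-edges with a
warning. The representative score is `completeness − 5·contamination`
(ties by lexicographic id); the full dRep score has additional terms
(N50, strain heterogeneity) whose inputs are outside this data model,
so they are intentionally omitted and the weights are configurable.

## Rarity

`rarity(g) = median(RA_g | RA_g > 0) · (runs with detection / screened
runs)`, in percent units. The median split into rare/common is computed
over detected genomes only; never-detected genomes are a separate group
(reported rarity 0) and excluded from the cutoff by default (switchable
via `include_not_detected_in_median`, since the original convention is
not stated). The defining inequalities are strict on both sides of the
median, so equality needs a rule: ties are assigned to *rare*. The
screened-run denominator defaults to the distinct runs in the table (or
the run metadata) and is overridable — surveys often screen more runs
than appear in the detection table.

## Annotation statuses

Hits from scored databases (KEGG, NR, MEROPS, TCDB) must pass a blast
score ratio of 0.4 (inclusive; strictness unstated upstream, inclusive
documented here); SignalP and dbCAN rows carry no bitscores and pass
through. Sub-threshold hits can be returned separately (e.g. when
inspecting incomplete pathways) but never enter statuses.

A gene is *annotated* if any KEGG/NR hit has a functional description,
*hypothetical* if its only KEGG/NR hits match a hypothetical marker, and
*unknown* with no KEGG/NR hits. The default marker list ("hypothetical
protein", "uncharacterized protein", "unknown function", "DUF";
case-insensitive substrings) is configurable because the exact strings
used by any given annotation run differ. A KEGG hit whose description is
hypothetical-style does not count as functional.

Extracellular peptidases require a SignalP "SP" call *and* a MEROPS hit;
validated CAZymes require more than one dbCAN annotation *and* KEGG/NR
backing.

## Pangenome

Presence ignores copy number. The core genome takes orthogroups present
in ≥ `ceil(tau · n_genomes)` genomes (tau = 0.9): "at least 90 %" with a
fractional genome count must round up. Shared percentage and Jaccard
dissimilarity are linked cell-wise by `shared% = 100·(1 − J)`; Jaccard
(union-normalized) is used rather than min-set normalization for
consistency with its role as an ordination input. Orthogroup status is
aggregated from member genes by precedence annotated > hypothetical >
unknown (any annotated gene makes the orthogroup annotated); a
majority-rule alternative is available, as no aggregation rule is
canonical.

## Trees

RED follows the `castor::getreds` recursion: preorder,
`red(v) = red(p) + d/(d+u)·(1 − red(p))` with `u` the mean patristic
distance from `v` to its descendant leaves; root 0, leaves 1, invariant
under uniform branch scaling, monotone along root-to-tip paths. (The
original GTDB formulation averages slightly differently and is out of
scope.) Zero-length degenerate clades inherit the parental RED with a
warning. Rank assignment matches internal nodes to the nearest
user-supplied reference RED (the package ships none — reference medians
are database-release-dependent); exact midpoints go to the shallower
rank, and nodes beyond the tolerance are "unassigned".

Wagner parsimony uses a linear asymmetric branch cost (each unit of
increase costs `gain_penalty`, default 1; each decrease costs 1) and a
Sankoff dynamic program over count states `0..max(leaf count)` per
family — under linear costs no optimum needs ancestral counts above the
observed maximum. Ties are resolved toward the smallest ancestral count
(deterministic, and biased against unobservable ancestral content; the
reference implementation's internal tie-breaking is undocumented, so this
is this package's own documented choice). Events are called from inferred
parent/child counts: gain 0→>0, loss >0→0, expansion/contraction for
nonzero increases/decreases; per-clade summaries recount the event list
exactly.

## Statistics

Wilcoxon rank-sum tests are two-sided (sidedness unstated upstream;
two-sided is conservative); exact by permutation when
`max(n_x, n_y) ≤ 8` with no ties, else normal approximation with tie and
continuity corrections. The exact branch is validated against a
from-scratch full-enumeration oracle for all sizes ≤ 6. Bonferroni is
applied as an adjusted threshold `α/m` (with three rarity groups,
0.05/3 ≈ 0.0167), matching the threshold-reporting style; multiplying
p-values instead is algebraically equivalent for the decision. The
default effect size is Cliff's delta, exactly testable by pair counting;
the Impact effect size used in some surveys has internal choices not
restated publicly, so it is not the default and not used in any check.
In the sharing comparison, orthogroups (not genomes) are the
observations, per the convention of reporting N as orthogroup counts.

## Synthetic data

The generators define the study conditions used throughout the tests:

- **Tree**: Yule pure-birth, `n_tips = 20`, birth rate 1; waiting times
  `Exp(k·b)` plus one final `Exp(n·b)` so pendant branches are positive.
  Expected depth `Σ_{k=2..n} 1/(k·b)` is the Monte-Carlo oracle.
- **Gene content**: `N0 = 100` root families; per branch of length `t`
  each family is lost w.p. `1 − e^{−μt}` (μ = 0.3), `Poisson(λt)` new
  families are gained (λ = 0.5), and an optional duplication rate
  (default 0) produces expansions, so expansion recovery can be tested
  separately from presence/absence. Only families observed in ≥ 1 leaf
  are exported; all events are recorded.
- **Abundance**: 40 MAGs × 100 runs; 10 % planted never-detected; the
  rest split 50/50 rare/common. Occupancy is Beta(2, 38) (mean 0.05)
  for rare and Beta(12, 8) (mean 0.6) for common; detected cells draw
  lognormal percent abundances with log-means ln 0.01 and ln 0.1
  (a > 2 log-unit gap) and shared σ = 0.5 — a standard
  occupancy–abundance model, chosen because the generating distribution
  of real surveys is unknown.
- **Annotations**: 120 genes per MAG; unknown probability
  `logistic(logit(0.25) + β·z)` with `z` the standardized negative
  rarity and β = 1.5 by default (monotone, bounded, one knob); of the
  remaining genes 30 % are hypothetical (`hypothetical_frac`, a
  parameter this package adds because the non-unknown split needs one).
  Statuses are emitted as hit rows (KEGG functional row / NR
  "hypothetical protein" row / no rows) so the classifier must actually
  run to recover them.
- **Alignments**: reads placed uniformly, full-length, identity
  `Normal(97, 2)` clipped to [0, 100].

All generators are bit-reproducible under a seed. What the generators do
*not* emulate: phylogenetic autocorrelation of abundance or gene content
with rarity, compositional coupling between genomes in a run, mapping
noise, chimeric or contaminated bins, or database-specific annotation
biases. Passing tests therefore demonstrate correctness of the
computations and recoverability of planted structure under a clean
generative model — not performance on real survey data.

## Verification and problem sizes

The test suite checks every operation against an independent oracle or a
closed form where one exists: per-base coverage counting, BFS connected
components, exhaustive Wagner labelings (≥ 500 random instances, ≤ 6
leaves, counts ≤ 3, gain penalties 0.5/1/2), rank-sum enumeration (all
sizes ≤ 6), hand-derived RED values, and Monte-Carlo means within three
standard errors. Stochastic recovery checks use 100 seeds (rarity-group
recovery ≥ 90 %, scored strictly: a truly rare genome that is never
detected counts as an error; gain-event recovery ≥ 90 % among gains of
families observed at ≥ 1 leaf — families gained and entirely lost again
are unrecoverable in principle) and 400 seeds for the type-I error of
the rarity/unknown comparison (nominal 0.05 ± 0.03). These problem
sizes keep the full suite and the acceptance script each within about
half a minute while leaving the Monte-Carlo standard errors small.

## Known limitations

- The relative-abundance formula is a documented reimplementation, not a
  coverm clone; unmapped-read handling is delegated to the
  `mapped_fraction` input.
- The dereplication score omits assembly-quality terms by design.
- Rank assignment ships no reference RED values.
- Exact Wilcoxon is limited to small tie-free samples; beyond that the
  corrected normal approximation is used.
- Orthogroup status aggregation and the hypothetical-marker list are
  conventions, exposed as parameters rather than fixed truths.
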