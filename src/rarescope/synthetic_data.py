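"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical structure of a rare-biosphere MAG
survey: a phylogeny of genomes (Yule process), presence/absence gene
content evolved on that phylogeny with recorded gain/loss events, a MAG x
sequencing-run abundance matrix with planted rare/common occupancy–
abundance structure, per-gene annotation tables whose unknown-gene
fraction depends on a tunable rarity effect, and per-read alignment
summaries for exercising the screening filters.

Every generator is bit-reproducible under a fixed seed and returns the
ground truth needed to score the corresponding inference stage (event
lists, group labels, gene statuses, target coverage).

Model choices, in brief: occupancy (per-run detection probability) is
Beta-distributed per rarity group; detected cells draw lognormal percent
abundances with a group-specific log-mean and shared log-sd (a standard
occupancy–abundance model); the rarity -> unknown-gene link is a logistic
regression on the standardized negative rarity, so a single coefficient
(``rarity_effect_beta``) controls how much rarer genomes are enriched in
functionally unknown genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd

from .phylo import PhyloTree

__all__ = [
    "SimulationConfig",
    "TrueEvents",
    "simulate_tree",
    "simulate_gene_content",
    "simulate_abundance",
    "simulate_annotations",
    "simulate_alignments",
    "simulate_all",
]

_FUNCTIONAL_DESCRIPTIONS = (
    "aspartate aminotransferase",
    "alanine aminotransferase",
    "pyruvate ferredoxin oxidoreductase",
    "acetyl-CoA synthetase (ADP-forming)",
    "enoyl-CoA hydratase",
    "thioredoxin reductase",
    "oligopeptide ABC transporter permease",
    "succinyl-CoA synthetase alpha subunit",
    "V-type ATP synthase subunit A",
    "arsenate reductase",
)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic-data generators.

    Defaults describe the study conditions the pipeline is meant to
    operate under: a few dozen MAGs screened against ~100 sequencing
    runs, rare genomes occupying ~5% of runs at ~0.01% abundance versus
    common genomes at ~60% occupancy and ~0.1% abundance, and a strong
    positive link between rarity and the unknown-gene fraction.
    """

    seed: int = 0
    # tree / gene content
    n_tips: int = 20
    birth_rate: float = 1.0
    root_families: int = 100          # N0 families at the root
    gain_rate: float = 0.5            # lambda, gains per unit branch length
    loss_rate: float = 0.3            # mu, per-family per unit branch length
    duplication_rate: float = 0.0     # optional copy-number expansions
    # abundance matrix
    n_mags: int = 40
    n_runs: int = 100
    rare_fraction: float = 0.5        # of the detectable MAGs
    not_detected_fraction: float = 0.1
    occupancy_rare: tuple[float, float] = (2.0, 38.0)    # Beta, mean 0.05
    occupancy_common: tuple[float, float] = (12.0, 8.0)  # Beta, mean 0.6
    abundance_mu_rare: float = math.log(0.01)    # log percent scale
    abundance_mu_common: float = math.log(0.1)
    abundance_sigma: float = 0.5
    # annotations
    genes_per_mag: int = 120
    unknown_base: float = 0.25
    hypothetical_frac: float = 0.3    # of non-unknown genes
    rarity_effect_beta: float = 1.5
    # alignments
    genome_length: int = 10_000
    read_length: int = 100
    target_coverage: float = 5.0
    identity_mean: float = 97.0
    identity_sd: float = 2.0

    def validate(self) -> None:
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        for name in ("birth_rate",):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("root_families", "n_mags", "n_runs", "genes_per_mag",
                     "genome_length", "read_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("gain_rate", "loss_rate", "duplication_rate",
                     "abundance_sigma", "target_coverage", "identity_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("rare_fraction", "not_detected_fraction", "unknown_base",
                     "hypothetical_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("occupancy_rare", "occupancy_common"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ValueError(f"{name} Beta parameters must be positive")
        if self.genome_length < self.read_length:
            raise ValueError("genome_length must be >= read_length")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("occupancy_rare", "occupancy_common"):
            if key in d and isinstance(d[key], (list, tuple)):
                d[key] = tuple(float(x) for x in d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class TrueEvents:
    """Planted gene-content history.

    ``events`` has one row per (branch, orthogroup, event); branch is
    identified by its child node id.  ``node_counts`` holds the true
    count of every family at every node (orthogroups x node ids).
    """

    events: pd.DataFrame
    node_counts: pd.DataFrame


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def mag_ids(n: int) -> list[str]:
    return [f"MAG{i:04d}" for i in range(1, n + 1)]


# -- tree ------------------------------------------------------------------


def simulate_tree(n_tips: int, birth_rate: float = 1.0, seed=0) -> PhyloTree:
    """A rooted binary Yule (pure-birth) tree with ``n_tips`` leaves.

    Waiting times between speciations are Exponential(k * birth_rate)
    with k the number of extant lineages; after the final speciation one
    more Exponential(n * birth_rate) waiting time is appended so pendant
    branches have positive length.  The tree is ultrametric with expected
    depth sum_{k=2..n} 1/(k * birth_rate).
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = _rng(seed)

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    # active lineages, each with the time at which its branch started
    first = [dendropy.Node(), dendropy.Node()]
    for child in first:
        root.add_child(child)
    start_time = {id(node): 0.0 for node in first}
    active = list(first)
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        i = int(rng.integers(k))
        parent = active.pop(i)
        parent.edge.length = t - start_time.pop(id(parent))
        children = [dendropy.Node(), dendropy.Node()]
        for child in children:
            parent.add_child(child)
            start_time[id(child)] = t
            active.append(child)
    t_end = t + rng.exponential(1.0 / (n_tips * birth_rate))
    labels = mag_ids(n_tips)
    # deterministic label order: leaves in the order they were created
    for node, label in zip(active, labels):
        node.edge.length = t_end - start_time[id(node)]
        node.taxon = taxa.new_taxon(label)
    return PhyloTree(tree)


# -- gene content ----------------------------------------------------------


def simulate_gene_content(
    tree: PhyloTree, config: SimulationConfig, rng=None
) -> tuple[pd.DataFrame, TrueEvents]:
    """Evolve gene families along a tree, recording every event.

    The root carries ``root_families`` families.  Along a branch of
    length t each present family is lost with probability 1 - exp(-mu t);
    Poisson(lambda t) brand-new families are gained (count 1); with a
    nonzero duplication rate each surviving single-copy family gains a
    copy with probability 1 - exp(-nu t) (an expansion).  Leaf counts are
    exported as the orthogroup matrix; with the default duplication rate
    of 0 they are presence/absence (0/1).
    """
    config.validate()
    rng = _rng(rng if rng is not None else config.seed)
    mu, lam, nu = config.loss_rate, config.gain_rate, config.duplication_rate

    counter = [0]

    def new_family() -> str:
        counter[0] += 1
        return f"OG{counter[0]:07d}"

    root_fams = {new_family(): 1 for _ in range(config.root_families)}
    node_state: dict[str, dict[str, int]] = {}
    event_rows: list[tuple[str, str, str]] = []

    for node in tree.preorder():
        if node.parent_node is None:
            node_state[node.node_id] = dict(root_fams)
            continue
        parent = dict(node_state[node.parent_node.node_id])
        t = node.edge.length
        p_loss = 1.0 - math.exp(-mu * t) if mu > 0 else 0.0
        p_dup = 1.0 - math.exp(-nu * t) if nu > 0 else 0.0
        state: dict[str, int] = {}
        for fam in sorted(parent):
            count = parent[fam]
            if p_loss > 0 and rng.random() < p_loss:
                event_rows.append((node.node_id, fam, "loss"))
                continue
            if p_dup > 0 and rng.random() < p_dup:
                event_rows.append((node.node_id, fam, "expansion"))
                count += 1
            state[fam] = count
        n_gain = rng.poisson(lam * t) if lam > 0 else 0
        for _ in range(n_gain):
            fam = new_family()
            state[fam] = 1
            event_rows.append((node.node_id, fam, "gain"))
        node_state[node.node_id] = state

    all_fams = sorted({f for s in node_state.values() for f in s} | set(root_fams))
    node_ids = tree.node_ids()
    node_counts = pd.DataFrame(
        {nid: [node_state[nid].get(f, 0) for f in all_fams] for nid in node_ids},
        index=pd.Index(all_fams, name="orthogroup"),
    )
    leaf_counts = node_counts[tree.leaf_labels]
    # only families observed in >= 1 leaf enter the exported matrix
    observed = leaf_counts.sum(axis=1) > 0
    matrix = leaf_counts.loc[observed]
    events = pd.DataFrame(event_rows, columns=["child_id", "orthogroup", "event"])
    return matrix, TrueEvents(events=events, node_counts=node_counts)


# -- abundance -------------------------------------------------------------


def simulate_abundance(
    config: SimulationConfig, rng=None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """A MAG x run abundance matrix with planted rarity structure.

    Returns ``(abundance, metadata, truth)``:

    - ``abundance``: long table (run_id, genome_id, relative_abundance in
      percent); undetected cells are 0.
    - ``metadata``: run table (run_id, study_id, environment).
    - ``truth``: per-MAG planted group (rare/common/not_detected), true
      occupancy probability and log-mean abundance.
    """
    config.validate()
    rng = _rng(rng if rng is not None else config.seed)
    mags = mag_ids(config.n_mags)
    runs = [f"RUN{i:05d}" for i in range(1, config.n_runs + 1)]

    n_nd = int(round(config.not_detected_fraction * config.n_mags))
    n_detectable = config.n_mags - n_nd
    n_rare = int(round(config.rare_fraction * n_detectable))
    groups = (["rare"] * n_rare
              + ["common"] * (n_detectable - n_rare)
              + ["not_detected"] * n_nd)
    groups = list(rng.permutation(groups))

    occupancy = np.zeros(config.n_mags)
    mu = np.full(config.n_mags, np.nan)
    for i, g in enumerate(groups):
        if g == "rare":
            a, b = config.occupancy_rare
            occupancy[i] = rng.beta(a, b)
            mu[i] = config.abundance_mu_rare
        elif g == "common":
            a, b = config.occupancy_common
            occupancy[i] = rng.beta(a, b)
            mu[i] = config.abundance_mu_common
    detected = rng.random((config.n_mags, config.n_runs)) < occupancy[:, None]
    values = np.where(
        detected,
        np.exp(np.nan_to_num(mu)[:, None]
               + config.abundance_sigma * rng.standard_normal(detected.shape)),
        0.0,
    )

    abundance = pd.DataFrame(
        {
            "run_id": np.repeat(runs, config.n_mags),
            "genome_id": np.tile(mags, config.n_runs),
            "relative_abundance": values.T.ravel(),
        }
    )
    n_studies = max(1, config.n_runs // 10)
    environments = ("marine sediment", "marine water column", "lake sediment",
                    "hydrothermal sediment", "cold seep")
    metadata = pd.DataFrame(
        {
            "run_id": runs,
            "study_id": [f"STUDY{(i % n_studies) + 1:03d}" for i in range(config.n_runs)],
            "environment": [environments[i % len(environments)] for i in range(config.n_runs)],
        }
    )
    truth = pd.DataFrame(
        {
            "genome_id": mags,
            "group": groups,
            "occupancy": occupancy,
            "log_mean_abundance": mu,
        }
    )
    return abundance, metadata, truth


# -- annotations -----------------------------------------------------------


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def simulate_annotations(
    rarity: pd.Series, config: SimulationConfig, rng=None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-gene annotation hits with a planted rarity–unknownness link.

    ``rarity`` maps genome_id -> rarity index value (>= 0).  Each genome
    gets ``genes_per_mag`` genes; a gene is functionally unknown with
    probability logistic(logit(unknown_base) + beta * z) where z is the
    standardized negative rarity of its genome, hypothetical with
    probability ``hypothetical_frac`` of the remainder, else annotated.

    Statuses are emitted as hit rows so the classifier must be run to
    recover them: annotated genes get a KEGG row with a functional
    description, hypothetical genes an NR row whose description contains
    "hypothetical protein", unknown genes no rows at all.  Every gene
    gets a self-alignment score; emitted hits always pass a 0.4 blast
    score ratio.

    Returns ``(hits, self_scores, truth)`` where truth lists the planted
    status per gene.
    """
    config.validate()
    rng = _rng(rng if rng is not None else config.seed)
    r = rarity.astype(float)
    if (r < 0).any():
        raise ValueError("rarity values must be non-negative")
    neg = -r.to_numpy()
    sd = neg.std()
    z = (neg - neg.mean()) / sd if sd > 0 else np.zeros_like(neg)

    if config.unknown_base <= 0.0:
        p_unknown = np.zeros_like(z)
    elif config.unknown_base >= 1.0:
        p_unknown = np.ones_like(z)
    else:
        eta = _logit(config.unknown_base) + config.rarity_effect_beta * z
        p_unknown = 1.0 / (1.0 + np.exp(-eta))

    n_mags, n_genes = len(r), config.genes_per_mag
    genomes = np.repeat(r.index.to_numpy(), n_genes)
    gene_ids = np.array(
        [f"{g}_g{j + 1:05d}" for g in r.index for j in range(n_genes)]
    )
    self_scores = np.round(rng.uniform(300.0, 900.0, n_mags * n_genes), 1)

    u = rng.random(n_mags * n_genes)
    h = rng.random(n_mags * n_genes)
    p_gene = np.repeat(p_unknown, n_genes)
    status = np.where(
        u < p_gene, "unknown",
        np.where(h < config.hypothetical_frac, "hypothetical", "annotated"),
    )

    truth = pd.DataFrame(
        {"gene_id": gene_ids, "genome_id": genomes, "status": status}
    )
    self_scores_df = pd.DataFrame(
        {"gene_id": gene_ids, "self_bitscore": self_scores, "genome_id": genomes}
    )

    with_rows = status != "unknown"
    n_hits = int(with_rows.sum())
    # hits always pass a 0.4 blast score ratio
    bitscore = np.round(self_scores[with_rows] * rng.uniform(0.5, 1.0, n_hits), 1)
    annotated = status[with_rows] == "annotated"
    ko = rng.integers(1, 99999, n_hits)
    fn = rng.integers(len(_FUNCTIONAL_DESCRIPTIONS), size=n_hits)
    wp = rng.integers(1, 10**9, n_hits)
    desc = np.where(
        annotated,
        [f"K{k:05d} {_FUNCTIONAL_DESCRIPTIONS[i]}" for k, i in zip(ko, fn)],
        "hypothetical protein",
    )
    subject = np.where(
        annotated,
        [f"ko:K{k:05d}" for k in ko],
        [f"WP_{w:09d}.1" for w in wp],
    )
    hits = pd.DataFrame(
        {
            "qseqid": gene_ids[with_rows],
            "sseqid": subject,
            "pident": 98.0,
            "length": 200,
            "mismatch": 4,
            "gapopen": 0,
            "qstart": 1,
            "qend": 200,
            "sstart": 1,
            "send": 200,
            "evalue": 1e-50,
            "bitscore": bitscore,
            "database": np.where(annotated, "KEGG", "NR"),
            "description": desc,
            "genome_id": genomes[with_rows],
        }
    )
    return hits, self_scores_df, truth


# -- alignments ------------------------------------------------------------


def simulate_alignments(
    config: SimulationConfig,
    genome_id: str = "MAG0001",
    run_id: str = "RUN00001",
    rng=None,
) -> pd.DataFrame:
    """Per-read alignment summaries at a target fold-coverage.

    Reads of ``read_length`` bp are placed uniformly on a genome of
    ``genome_length`` bp; the read count is round(target_coverage *
    genome_length / read_length).  Per-read percent identity is drawn
    Normal(identity_mean, identity_sd) clipped to [0, 100]; reads align
    over their full length.
    """
    config.validate()
    rng = _rng(rng if rng is not None else config.seed)
    n_reads = int(round(config.target_coverage * config.genome_length
                        / config.read_length))
    if n_reads == 0:
        return pd.DataFrame(
            columns=["read_id", "genome_id", "run_id", "read_length",
                     "aligned_length", "percent_identity", "start", "end"]
        )
    starts = rng.integers(1, config.genome_length - config.read_length + 2,
                          size=n_reads)
    identity = np.clip(
        rng.normal(config.identity_mean, config.identity_sd, size=n_reads),
        0.0, 100.0,
    )
    return pd.DataFrame(
        {
            "read_id": [f"{run_id}.{i + 1}" for i in range(n_reads)],
            "genome_id": genome_id,
            "run_id": run_id,
            "read_length": config.read_length,
            "aligned_length": config.read_length,
            "percent_identity": identity,
            "start": starts,
            "end": starts + config.read_length - 1,
        }
    )


# -- convenience -----------------------------------------------------------


def simulate_all(config: SimulationConfig) -> dict:
    """Generate every pipeline input plus ground truth in one call.

    Uses independent child seeds (spawned from ``config.seed``) per
    generator so outputs stay individually reproducible.
    """
    config.validate()
    seeds = np.random.SeedSequence(config.seed).spawn(5)
    tree = simulate_tree(config.n_tips, config.birth_rate,
                         np.random.default_rng(seeds[0]))
    counts, true_events = simulate_gene_content(
        tree, config, np.random.default_rng(seeds[1]))
    abundance, metadata, abundance_truth = simulate_abundance(
        config, np.random.default_rng(seeds[2]))
    from .rarity import rarity_index  # local import to avoid cycle at import time

    rar = rarity_index(abundance, total_runs=config.n_runs)
    rarity_values = rar.set_index("genome_id")["rarity"]
    hits, self_scores, status_truth = simulate_annotations(
        rarity_values, config, np.random.default_rng(seeds[3]))
    alignments = simulate_alignments(config, rng=np.random.default_rng(seeds[4]))
    return {
        "tree": tree,
        "gene_counts": counts,
        "true_events": true_events,
        "abundance": abundance,
        "run_metadata": metadata,
        "abundance_truth": abundance_truth,
        "annotation_hits": hits,
        "self_scores": self_scores,
        "status_truth": status_truth,
        "alignments": alignments,
    }
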