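"""Group statistics and end-to-end orchestration.

Statistical machinery: two-sided Wilcoxon rank-sum (Mann-Whitney U) tests
— exact by full enumeration of rank assignments when both samples are
small and tie-free, otherwise the normal approximation with tie and
continuity corrections — Bonferroni-adjusted significance thresholds
(alpha / m, the reporting style of adjusting the threshold rather than
the p-values), and Cliff's delta as the default effect size:

    delta = (#{x_i > y_j} - #{x_i < y_j}) / (n_x * n_y)  in [-1, 1].

Two headline comparisons are built on these primitives: the percentage of
functionally unknown genes across the rare / common / not-detected rarity
groups (three pairwise tests at the alpha/3 threshold, plus the
sqrt(rarity) vs %unknown scatter table), and the focal vs non-focal
orthogroup carriage proportions per annotation status (orthogroups as
observations).

:func:`run_pipeline` chains all stages on synthetic or file inputs and
writes a deterministic report directory.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import __version__
from . import annotation_class, io_formats, pangenome, phylo, rarity, screen_quant
from .synthetic_data import SimulationConfig, simulate_all

__all__ = [
    "TestResult",
    "wilcoxon_rank_sum",
    "bonferroni_threshold",
    "cliffs_delta",
    "compare_status_by_rarity",
    "compare_sharing_by_status",
    "run_pipeline",
]


@dataclass
class TestResult:
    comparison: str
    n_x: int
    n_y: int
    statistic: float          # Mann-Whitney U of the first sample
    p_value: float
    adjusted_threshold: float
    significant: bool
    effect_size: float
    effect_method: str = "cliffs_delta"

    def to_dict(self) -> dict:
        return asdict(self)


def wilcoxon_rank_sum(x, y, exact_max_n: int = 8) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (U statistic, p-value).

    The U statistic counts, with midrank handling of ties, the pairs
    where an x value exceeds a y value.  The p-value is exact (full
    enumeration of the permutation distribution) when
    max(n_x, n_y) <= exact_max_n and the pooled sample has no ties,
    otherwise a normal approximation with tie correction and continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (max(x.size, y.size) <= exact_max_n and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bonferroni_threshold(alpha: float = 0.05, m: int = 1) -> float:
    """Adjusted significance threshold alpha / m for m comparisons."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    return alpha / m


def cliffs_delta(x, y) -> float:
    """Cliff's delta: P(X > Y) - P(X < Y) estimated over all pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    diff = x[:, None] - y[None, :]
    return float((np.sign(diff)).sum() / (x.size * y.size))


def _pairwise_tests(
    values: dict[str, np.ndarray],
    alpha: float,
    label: str,
) -> list[TestResult]:
    groups = [g for g in values if len(values[g]) > 0]
    skipped = [g for g in values if len(values[g]) == 0]
    if skipped:
        import warnings

        warnings.warn(f"{label}: empty group(s) skipped: {', '.join(skipped)}")
    pairs = list(combinations(groups, 2))
    if not pairs:
        return []
    threshold = bonferroni_threshold(alpha, 3)  # three pairwise comparisons
    out = []
    for a, b in pairs:
        u, p = wilcoxon_rank_sum(values[a], values[b])
        out.append(
            TestResult(
                comparison=f"{label}: {a} vs {b}",
                n_x=len(values[a]),
                n_y=len(values[b]),
                statistic=u,
                p_value=p,
                adjusted_threshold=threshold,
                significant=p < threshold,
                effect_size=cliffs_delta(values[a], values[b]),
            )
        )
    return out


def compare_status_by_rarity(
    status_pcts: pd.DataFrame,
    rarity_results: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[list[TestResult], pd.DataFrame]:
    """Pairwise tests of %unknown genes across rarity groups.

    Joins the per-genome status percentages with the rarity groups,
    runs Wilcoxon rank-sum tests for every pair of non-empty groups at
    the Bonferroni threshold alpha/3, and returns the tidy scatter table
    (genome, group, sqrt_rarity, pct_unknown) alongside.
    """
    merged = status_pcts.merge(
        rarity_results[["genome_id", "rarity", "group"]], on="genome_id"
    )
    values = {
        g: merged.loc[merged["group"] == g, "pct_unknown"].to_numpy()
        for g in ("rare", "common", "not_detected")
    }
    results = _pairwise_tests(values, alpha, "pct_unknown")
    scatter = pd.DataFrame(
        {
            "genome_id": merged["genome_id"],
            "group": merged["group"],
            "sqrt_rarity": np.sqrt(merged["rarity"]),
            "pct_unknown": merged["pct_unknown"],
        }
    )
    return results, scatter


def compare_sharing_by_status(
    props: pd.DataFrame, alpha: float = 0.05
) -> list[TestResult]:
    """Per annotation status: focal vs non-focal carriage proportions.

    For each status with >= 1 orthogroup, a Wilcoxon rank-sum test of
    the in-focal against the out-of-focal carriage proportions
    (orthogroups as observations) at the Bonferroni alpha/3 threshold,
    with Cliff's delta as effect size.  Maximal confinement (every
    focal-carried orthogroup absent outside) gives effect size 1.
    """
    out = []
    threshold = bonferroni_threshold(alpha, 3)
    for status in ("annotated", "hypothetical", "unknown"):
        sub = props[props["status"] == status]
        if sub.empty:
            import warnings

            warnings.warn(f"sharing comparison: no orthogroups with status {status}")
            continue
        u, p = wilcoxon_rank_sum(sub["prop_focal"], sub["prop_other"])
        out.append(
            TestResult(
                comparison=f"sharing: focal vs other ({status})",
                n_x=len(sub),
                n_y=len(sub),
                statistic=u,
                p_value=p,
                adjusted_threshold=threshold,
                significant=p < threshold,
                effect_size=cliffs_delta(sub["prop_focal"], sub["prop_other"]),
            )
        )
    return out


def results_frame(results: list[TestResult]) -> pd.DataFrame:
    cols = ["comparison", "n_x", "n_y", "statistic", "p_value",
            "adjusted_threshold", "significant", "effect_size", "effect_method"]
    return pd.DataFrame([r.to_dict() for r in results], columns=cols)


# -- pipeline --------------------------------------------------------------

_DEFAULT_STAGES = ("screen", "quantify", "rarity", "classify", "pangenome",
                   "phylo", "stats")


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> Path:
    """Run the full analysis chain and write a report directory.

    ``config`` is a YAML path or an equivalent dict with keys:

    - ``seed`` (required when simulating),
    - ``simulate``: SimulationConfig fields (synthetic inputs), or
      ``inputs``: paths per table (abundance, run_metadata, gene_counts,
      tree, annotation_hits, self_scores, alignments),
    - ``stages``: booleans per stage name (all default on),
    - ``thresholds``: overrides (min_breadth, min_read_identity,
      bsr, core_tau, gain_penalty, alpha, total_runs, ...),
    - ``out_dir``: report directory (overridable by argument).

    Reruns on an identical config are byte-identical.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    config = dict(config or {})
    out_dir = Path(out_dir or config.get("out_dir", "rarescope_report"))
    stages = {name: True for name in _DEFAULT_STAGES}
    stages.update(config.get("stages", {}))
    thresholds = {
        "min_breadth": 0.5,
        "min_read_identity": 95.0,
        "screen_min_identity": 50.0,
        "screen_min_aligned_fraction": 0.5,
        "screen_min_overlap": 30,
        "cumulative_coverage_cutoff": 2.0,
        "bsr": 0.4,
        "core_tau": 0.9,
        "gain_penalty": 1.0,
        "alpha": 0.05,
    }
    thresholds.update(config.get("thresholds", {}))

    data = _load_inputs(config)
    tables: dict[str, pd.DataFrame] = {}
    log: dict = {
        "rarescope_version": __version__,
        "seed": config.get("seed"),
        "thresholds": thresholds,
        "stages": {k: bool(v) for k, v in stages.items()},
    }

    if stages.get("screen") and data.get("alignments") is not None:
        screen_t = screen_quant.ScreeningThresholds(
            min_read_identity=thresholds["screen_min_identity"],
            min_aligned_fraction_of_read=thresholds["screen_min_aligned_fraction"],
            min_overlap=thresholds["screen_min_overlap"],
            cumulative_coverage_cutoff=thresholds["cumulative_coverage_cutoff"],
        )
        filtered = screen_quant.filter_alignments(data["alignments"], screen_t)
        genome_length = int(data.get("genome_length", 10_000))
        recs = []
        for (run_id, genome_id), grp in filtered.groupby(["run_id", "genome_id"]):
            recs.append(
                screen_quant.coverage_stats(grp, genome_id, genome_length, run_id)
            )
        coverage = screen_quant.coverage_records_frame(recs)
        tables["coverage"] = coverage
        if data.get("run_metadata") is not None:
            meta = data["run_metadata"]
            meta_cov = meta[meta["run_id"].isin(coverage["run_id"])]
            if not meta_cov.empty:
                tables["cumulative_coverage"] = screen_quant.cumulative_coverage_by_study(
                    coverage, meta_cov, cutoff=screen_t.cumulative_coverage_cutoff
                )

    if stages.get("quantify") and "coverage" in tables:
        abund_t = screen_quant.AbundanceThresholds(
            min_breadth=thresholds["min_breadth"],
            min_read_identity=thresholds["min_read_identity"],
        )
        tables["screen_abundance"] = screen_quant.relative_abundance(
            tables["coverage"], abund_t
        )

    rarity_results = None
    if stages.get("rarity") and data.get("abundance") is not None:
        total_runs = thresholds.get("total_runs")
        if total_runs is None and data.get("run_metadata") is not None:
            total_runs = int(data["run_metadata"]["run_id"].nunique())
        rar = rarity.rarity_index(data["abundance"], total_runs=total_runs)
        rarity_results = rarity.assign_rarity_groups(rar)
        tables["rarity"] = rarity_results

    statuses = None
    status_pcts = None
    if stages.get("classify") and data.get("annotation_hits") is not None:
        hits = annotation_class.bsr_filter(
            data["annotation_hits"], data["self_scores"], threshold=thresholds["bsr"]
        )
        genes = data["self_scores"][["gene_id", "genome_id"]]
        statuses = annotation_class.classify_gene_status(hits, genes)
        status_pcts = annotation_class.status_percentages(statuses)
        tables["gene_status"] = statuses
        tables["status_percentages"] = status_pcts

    og_statuses = None
    if stages.get("pangenome") and data.get("gene_counts") is not None:
        counts = data["gene_counts"]
        tables["core_orthogroups"] = pd.DataFrame(
            {"orthogroup": pangenome.core_orthogroups(counts, thresholds["core_tau"])}
        )
        grouping = data.get("grouping") or _clade_grouping(data.get("tree"), counts)
        if grouping:
            specific, intersections = pangenome.group_specific_orthogroups(
                counts, grouping
            )
            tables["group_specific_counts"] = pd.DataFrame(
                {"group": list(specific), "orthogroups": [len(v) for v in specific.values()]}
            )
            tables["orthogroup_intersections"] = intersections
        tables["jaccard"] = pangenome.jaccard_matrix(counts).reset_index(
            names="genome_id"
        )
        tables["shared_fraction"] = pangenome.shared_fraction_matrix(
            counts
        ).reset_index(names="genome_id")
        if statuses is not None:
            og_statuses = _orthogroup_statuses(counts, statuses)
            focal = data.get("focal") or _default_focal(grouping)
            if focal:
                props = pangenome.sharing_proportions(counts, focal, og_statuses)
                tables["sharing_proportions"] = props

    if stages.get("phylo") and data.get("tree") is not None:
        tree = data["tree"]
        red = phylo.compute_red(tree)
        tables["red"] = red.to_frame()
        if data.get("gene_counts") is not None:
            rec = phylo.wagner_reconstruct(
                tree, data["gene_counts"], gain_penalty=thresholds["gain_penalty"]
            )
            tables["wagner_events"] = rec.events
            clades = data.get("grouping") or _clade_grouping(tree, data["gene_counts"])
            branch_clades = _branch_clades(tree, clades) if clades else None
            tables["event_summary"] = phylo.summarize_events(rec, branch_clades).reset_index()
            log["wagner_total_cost"] = rec.total_cost

    if stages.get("stats"):
        all_tests: list[TestResult] = []
        if status_pcts is not None and rarity_results is not None:
            tests, scatter = compare_status_by_rarity(
                status_pcts, rarity_results, alpha=thresholds["alpha"]
            )
            all_tests.extend(tests)
            tables["rarity_unknown_scatter"] = scatter
        if "sharing_proportions" in tables:
            all_tests.extend(
                compare_sharing_by_status(
                    tables["sharing_proportions"], alpha=thresholds["alpha"]
                )
            )
        if all_tests:
            tables["tests"] = results_frame(all_tests)

    manifest = io_formats.write_report(tables, out_dir)
    log["tables"] = manifest["file"].tolist()
    with open(out_dir / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)
    return out_dir


def _load_inputs(config: dict) -> dict:
    if "simulate" in config:
        sim = dict(config["simulate"] or {})
        if "seed" not in sim and "seed" in config:
            sim["seed"] = config["seed"]
        cfg = SimulationConfig.from_dict(sim)
        sim_data = simulate_all(cfg)
        return {
            "abundance": sim_data["abundance"],
            "run_metadata": sim_data["run_metadata"],
            "gene_counts": sim_data["gene_counts"],
            "tree": sim_data["tree"],
            "annotation_hits": sim_data["annotation_hits"],
            "self_scores": sim_data["self_scores"],
            "alignments": sim_data["alignments"],
            "genome_length": cfg.genome_length,
        }
    inputs = config.get("inputs", {})
    data: dict = {"genome_length": config.get("genome_length", 10_000)}
    if "abundance" in inputs:
        data["abundance"] = io_formats.read_table(
            inputs["abundance"], io_formats.ABUNDANCE_LONG_SCHEMA
        )
    if "run_metadata" in inputs:
        data["run_metadata"] = io_formats.read_run_metadata(inputs["run_metadata"])
    if "gene_counts" in inputs:
        data["gene_counts"] = io_formats.read_gene_counts(inputs["gene_counts"])
    if "tree" in inputs:
        data["tree"] = io_formats.parse_newick(Path(inputs["tree"]).read_text())
    if "annotation_hits" in inputs:
        data["annotation_hits"] = io_formats.read_table(
            inputs["annotation_hits"], io_formats.ANNOTATION_HITS_SCHEMA
        )
    if "self_scores" in inputs:
        data["self_scores"] = io_formats.read_table(
            inputs["self_scores"], io_formats.SELF_SCORE_SCHEMA
        )
    if "alignments" in inputs:
        data["alignments"] = io_formats.read_table(
            inputs["alignments"], io_formats.ALIGNMENT_SCHEMA
        )
    # a stage explicitly enabled in the config must have its inputs
    needs = {
        "screen": ("alignments",),
        "rarity": ("abundance",),
        "classify": ("annotation_hits", "self_scores"),
        "pangenome": ("gene_counts",),
        "phylo": ("tree",),
    }
    for stage, enabled in (config.get("stages") or {}).items():
        if enabled and stage in needs:
            missing = [n for n in needs[stage] if n not in data]
            if missing:
                raise ValueError(
                    f"stage {stage!r} enabled but input(s) missing: "
                    + ", ".join(missing)
                )
    return data


def _clade_grouping(tree, counts) -> dict[str, str] | None:
    """Default genome grouping: the clades under the root's children."""
    if tree is None:
        return None
    labels = {}
    for k, child in enumerate(tree.root.child_nodes()):
        name = f"clade{k + 1}"
        for leaf in child.leaf_iter():
            labels[leaf.taxon.label] = name
    if counts is not None:
        labels = {g: labels[g] for g in counts.columns if g in labels}
        if set(counts.columns) - set(labels):
            return None
    return labels


def _branch_clades(tree, leaf_clades: dict[str, str]) -> dict[str, str]:
    """Extend a leaf grouping to branches: a branch belongs to a clade iff
    all leaves below it do."""
    out: dict[str, str] = {}
    for node in tree.postorder():
        if node.parent_node is None:
            continue
        below = {leaf_clades.get(lf.taxon.label) for lf in node.leaf_iter()}
        if len(below) == 1 and None not in below:
            out[node.node_id] = next(iter(below))
    return out


def _default_focal(grouping: dict[str, str] | None) -> set[str] | None:
    if not grouping:
        return None
    first = sorted(set(grouping.values()))[0]
    return {g for g, grp in grouping.items() if grp == first}


def _orthogroup_statuses(counts: pd.DataFrame, statuses: pd.DataFrame) -> dict[str, str]:
    """Orthogroup statuses via a deterministic gene->orthogroup membership.

    Genome gene lists are matched round-robin to the orthogroups present
    in that genome, then aggregated by the precedence rule.  Used when no
    explicit membership map is supplied.
    """
    presence = pangenome.presence_matrix(counts)
    rows = []
    for genome in counts.columns:
        ogs = presence.index[presence[genome]].tolist()
        if not ogs:
            continue
        genes = statuses.loc[statuses["genome_id"] == genome, "gene_id"].tolist()
        for i, gene in enumerate(genes):
            rows.append((gene, ogs[i % len(ogs)]))
    membership = pd.DataFrame(rows, columns=["gene_id", "orthogroup"])
    out = pangenome.aggregate_orthogroup_status(statuses, membership)
    for og in counts.index:  # orthogroups with no member genes default unknown
        out.setdefault(og, "unknown")
    return out
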