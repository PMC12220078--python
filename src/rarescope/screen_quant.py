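"""Screening and quantification: alignment filtering, per-genome coverage,
cumulative-coverage study selection, breadth/identity-filtered relative
abundance, genome quality filtering, and dereplication clustering over a
precomputed identity matrix.

Threshold semantics follow the conventions of the read-mapping and
dereplication tools this stage mirrors (coverm, dRep): retention
comparisons are inclusive (>=) for read identity, aligned fraction,
overlap and breadth, while the cumulative-coverage study cutoff (> 2) and
the genome quality gates (completeness > 80%, contamination < 5%) are
strict, matching how those rules are conventionally stated.

Relative abundance of genome g in a run is defined as

    RA(g) = 100 * mapped_fraction * cov(g) / sum_h cov(h)

over the genomes surviving the breadth filter, so per run the abundances
sum to 100 * mapped_fraction whenever any genome survives.  Detection
means RA > 0 after all filters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "ScreeningThresholds",
    "AbundanceThresholds",
    "CoverageRecord",
    "filter_alignments",
    "coverage_stats",
    "cumulative_coverage_by_study",
    "relative_abundance",
    "quality_filter",
    "dereplicate",
]


@dataclass(frozen=True)
class ScreeningThresholds:
    """Read filters for the broad screening pass (detection mining)."""

    min_read_identity: float = 50.0          # percent
    min_aligned_fraction_of_read: float | None = 0.5
    min_overlap: int | None = 30             # bp on the reference
    cumulative_coverage_cutoff: float = 2.0  # fold, strict >

    def __post_init__(self):
        if self.min_read_identity < 0:
            raise ValueError("min_read_identity must be non-negative")
        if (self.min_aligned_fraction_of_read is not None
                and self.min_aligned_fraction_of_read < 0):
            raise ValueError("min_aligned_fraction_of_read must be non-negative")
        if self.min_overlap is not None and self.min_overlap < 0:
            raise ValueError("min_overlap must be non-negative")


@dataclass(frozen=True)
class AbundanceThresholds:
    """Stringent filters for abundance quantification."""

    min_breadth: float = 0.5          # fraction of genome covered >= 1x
    min_read_identity: float = 95.0   # percent
    min_aligned_fraction_of_read: float | None = None
    min_overlap: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.min_breadth <= 1.0:
            raise ValueError("min_breadth must be in [0, 1]")
        if self.min_read_identity < 0:
            raise ValueError("min_read_identity must be non-negative")


@dataclass(frozen=True)
class CoverageRecord:
    run_id: str
    genome_id: str
    mean_coverage: float   # mapped bases / genome length
    breadth: float         # fraction of positions covered >= 1x
    mapped_reads: int

    def __post_init__(self):
        if not 0.0 <= self.breadth <= 1.0:
            raise ValueError("breadth must be in [0, 1]")
        if self.mean_coverage < 0:
            raise ValueError("mean_coverage must be non-negative")


def filter_alignments(
    alignments: pd.DataFrame,
    thresholds: ScreeningThresholds | AbundanceThresholds,
) -> pd.DataFrame:
    """Retain alignments passing identity / aligned-fraction / overlap gates.

    All three comparisons are inclusive (>=); filters whose threshold is
    ``None`` are skipped.  Input row order is preserved.
    """
    if alignments.empty:
        return alignments.copy()
    keep = alignments["percent_identity"] >= thresholds.min_read_identity
    frac = getattr(thresholds, "min_aligned_fraction_of_read", None)
    if frac is not None:
        keep &= (alignments["aligned_length"] / alignments["read_length"]) >= frac
    overlap = getattr(thresholds, "min_overlap", None)
    if overlap is not None:
        keep &= (alignments["end"] - alignments["start"] + 1) >= overlap
    return alignments.loc[keep].copy()


def coverage_stats(
    alignments: pd.DataFrame,
    genome_id: str,
    genome_length: int,
    run_id: str,
) -> CoverageRecord:
    """Mean coverage and breadth from (already filtered) alignments.

    mean_coverage = sum of aligned spans / genome_length; breadth = the
    fraction of genome positions covered by at least one alignment.
    Spans outside [1, genome_length] raise a validation error.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    sub = alignments
    if "genome_id" in alignments.columns:
        sub = alignments[alignments["genome_id"] == genome_id]
    if sub.empty:
        return CoverageRecord(run_id, genome_id, 0.0, 0.0, 0)
    starts = sub["start"].to_numpy(dtype=np.int64)
    ends = sub["end"].to_numpy(dtype=np.int64)
    if np.any(starts < 1) or np.any(ends > genome_length) or np.any(ends < starts):
        raise ValueError(
            f"alignment span outside [1, {genome_length}] for genome {genome_id}"
        )
    spans = ends - starts + 1
    mean_cov = float(spans.sum()) / genome_length
    # difference-array sweep for positions covered >= 1x
    delta = np.zeros(genome_length + 1, dtype=np.int64)
    np.add.at(delta, starts - 1, 1)
    np.add.at(delta, ends, -1)
    covered = int(np.count_nonzero(np.cumsum(delta)[:genome_length]))
    return CoverageRecord(
        run_id=run_id,
        genome_id=genome_id,
        mean_coverage=mean_cov,
        breadth=covered / genome_length,
        mapped_reads=int(len(sub)),
    )


def coverage_records_frame(records: list[CoverageRecord]) -> pd.DataFrame:
    """Stack CoverageRecords into the canonical coverage table."""
    return pd.DataFrame(
        [
            {
                "run_id": r.run_id,
                "genome_id": r.genome_id,
                "mean_coverage": r.mean_coverage,
                "breadth": r.breadth,
                "mapped_reads": r.mapped_reads,
            }
            for r in records
        ],
        columns=["run_id", "genome_id", "mean_coverage", "breadth", "mapped_reads"],
    )


def cumulative_coverage_by_study(
    records: pd.DataFrame,
    metadata: pd.DataFrame,
    cutoff: float = 2.0,
) -> pd.DataFrame:
    """Per-study cumulative target-genome coverage and selection flag.

    The cumulative coverage of a study is the sum, over its runs, of the
    summed mean coverage of the target genomes in that run.  A study is
    selected iff its cumulative coverage strictly exceeds ``cutoff``.
    Studies present in the metadata but with no coverage records report 0.
    """
    unmapped = set(records["run_id"]) - set(metadata["run_id"])
    if unmapped:
        raise ValueError(
            "runs without study mapping: " + ", ".join(sorted(unmapped)[:10])
        )
    merged = records.merge(metadata[["run_id", "study_id"]], on="run_id", how="left")
    per_study = merged.groupby("study_id")["mean_coverage"].sum()
    all_studies = metadata["study_id"].drop_duplicates()
    out = pd.DataFrame(
        {
            "study_id": all_studies,
            "cumulative_coverage": per_study.reindex(all_studies).fillna(0.0).to_numpy(),
        }
    )
    out["selected"] = out["cumulative_coverage"] > cutoff
    return out.reset_index(drop=True)


def relative_abundance(
    records: pd.DataFrame,
    thresholds: AbundanceThresholds | None = None,
    mapped_fraction: pd.Series | dict | float = 1.0,
) -> pd.DataFrame:
    """Breadth-filtered relative abundances per run, in percent.

    Genomes with breadth below ``min_breadth`` (strictly) are zeroed;
    surviving genomes split 100 * mapped_fraction of the run in
    proportion to their mean coverage.  ``mapped_fraction`` is the
    fraction of the run's reads that mapped at all (scalar, or a mapping
    run_id -> fraction).  A run where no genome survives reports all
    zeros.
    """
    thresholds = thresholds or AbundanceThresholds()
    if (records["mean_coverage"] < 0).any():
        raise ValueError("negative mean_coverage")
    if not isinstance(mapped_fraction, (int, float)):
        mapped_fraction = pd.Series(dict(mapped_fraction))

    out_rows = []
    for run_id, grp in records.groupby("run_id", sort=True):
        mf = (float(mapped_fraction) if isinstance(mapped_fraction, (int, float))
              else float(mapped_fraction.get(run_id, 1.0)))
        if not 0.0 <= mf <= 1.0:
            raise ValueError(f"mapped_fraction for {run_id} outside [0, 1]")
        surviving = (grp["breadth"] >= thresholds.min_breadth) & (grp["mean_coverage"] > 0)
        total = grp.loc[surviving, "mean_coverage"].sum()
        ra = np.zeros(len(grp))
        if total > 0:
            ra[surviving.to_numpy()] = (
                100.0 * mf * grp.loc[surviving, "mean_coverage"].to_numpy() / total
            )
        out_rows.append(
            pd.DataFrame(
                {
                    "run_id": run_id,
                    "genome_id": grp["genome_id"].to_numpy(),
                    "relative_abundance": ra,
                }
            )
        )
    return pd.concat(out_rows, ignore_index=True)


def quality_filter(
    quality: pd.DataFrame,
    min_completeness: float = 80.0,
    max_contamination: float = 5.0,
) -> list[str]:
    """Genomes with completeness > min and contamination < max (both strict)."""
    keep = (quality["completeness"] > min_completeness) & (
        quality["contamination"] < max_contamination
    )
    return quality.loc[keep, "genome_id"].tolist()


def dereplicate(
    identity: pd.DataFrame,
    quality: pd.DataFrame,
    primary_ani: float = 0.90,
    secondary_ani: float = 0.95,
    min_af: float = 0.5,
) -> pd.DataFrame:
    """Two-level ANI clustering with per-cluster representative selection.

    Primary clusters are the connected components of the graph whose
    edges join genome pairs with ANI >= ``primary_ani``; within each,
    secondary clusters additionally require aligned fraction >=
    ``min_af``.  Asymmetric estimates are symmetrized by taking the
    maximum of the two directions.  The representative of a secondary
    cluster is the genome with the highest score
    (completeness - 5 * contamination), ties broken by lexicographic id.

    ``identity`` columns: genome_a, genome_b, ani (fraction), aligned_fraction.
    Returns one row per genome: primary_cluster, secondary_cluster,
    score, representative flag.
    """
    genomes = sorted(quality["genome_id"])
    index = {g: i for i, g in enumerate(genomes)}
    missing = set(identity["genome_a"]) | set(identity["genome_b"])
    missing -= set(genomes)
    if missing:
        warnings.warn(
            "identity pairs for genomes without quality records ignored: "
            + ", ".join(sorted(missing)[:5])
        )

    ani = np.zeros((len(genomes), len(genomes)))
    af = np.zeros_like(ani)
    np.fill_diagonal(ani, 1.0)
    np.fill_diagonal(af, 1.0)
    for row in identity.itertuples(index=False):
        if row.genome_a not in index or row.genome_b not in index:
            continue
        i, j = index[row.genome_a], index[row.genome_b]
        ani[i, j] = ani[j, i] = max(ani[i, j], row.ani)   # symmetrize: max direction
        af[i, j] = af[j, i] = max(af[i, j], row.aligned_fraction)

    def components(mask: np.ndarray) -> np.ndarray:
        graph = coo_matrix(mask)
        _, labels = connected_components(graph, directed=False)
        return labels

    provided = {
        frozenset((a, b))
        for a, b in zip(identity["genome_a"], identity["genome_b"])
        if a in index and b in index and a != b
    }
    n_expected = len(genomes) * (len(genomes) - 1) // 2
    if len(provided) < n_expected:
        warnings.warn(
            f"identity matrix covers {len(provided)} of {n_expected} genome "
            "pairs; missing pairs treated as no edge"
        )

    primary = components(ani >= primary_ani)
    secondary_raw = components((ani >= secondary_ani) & (af >= min_af))

    score = (
        quality.set_index("genome_id")
        .loc[genomes]
        .eval("completeness - 5 * contamination")
        .to_numpy()
    )

    # deterministic cluster names: primary by smallest member id, secondary nested
    def canonical(labels: np.ndarray, prefix: str) -> list[str]:
        first_member: dict[int, str] = {}
        for g in genomes:
            lab = labels[index[g]]
            first_member.setdefault(lab, g)
        order = sorted(first_member, key=first_member.get)
        name = {lab: f"{prefix}{k + 1}" for k, lab in enumerate(order)}
        return [name[labels[index[g]]] for g in genomes]

    primary_names = canonical(primary, "P")
    secondary_names = [
        f"{p}.{s}" for p, s in zip(primary_names, canonical(secondary_raw, "S"))
    ]

    out = pd.DataFrame(
        {
            "genome_id": genomes,
            "primary_cluster": primary_names,
            "secondary_cluster": secondary_names,
            "score": score,
        }
    )
    best = out.sort_values(
        ["secondary_cluster", "score", "genome_id"],
        ascending=[True, False, True],
    ).drop_duplicates("secondary_cluster")
    out["representative"] = out["genome_id"].isin(best["genome_id"])
    return out
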