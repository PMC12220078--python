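"""Orthogroup presence analyses: core genome, group-specific orthogroups,
pairwise shared fractions, Jaccard dissimilarities, and focal vs non-focal
carriage proportions by annotation status.

All analyses are presence-based: an orthogroup is present in a genome iff
its gene count is >= 1; copy number is ignored.  The core genome at
threshold tau contains the orthogroups present in at least
ceil(tau * n_genomes) genomes ("at least 90%" with fractional counts
rounds up to a genome count).  Shared percentage and Jaccard dissimilarity
are two views of the same quantity: shared% = 100 * (1 - Jaccard).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "presence_matrix",
    "core_orthogroups",
    "group_specific_orthogroups",
    "shared_fraction_matrix",
    "jaccard_matrix",
    "sharing_proportions",
    "aggregate_orthogroup_status",
]


def presence_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Boolean orthogroup x genome presence (count >= 1). Idempotent."""
    if (matrix.to_numpy() < 0).any():
        raise ValueError("negative gene counts")
    return matrix >= 1


def core_orthogroups(matrix: pd.DataFrame, tau: float = 0.9) -> list[str]:
    """Orthogroups present in at least ceil(tau * n_genomes) genomes."""
    if not 0.0 < tau <= 1.0:
        raise ValueError("tau must be in (0, 1]")
    presence = presence_matrix(matrix)
    required = math.ceil(tau * presence.shape[1])
    return presence.index[presence.sum(axis=1) >= required].tolist()


def group_specific_orthogroups(
    matrix: pd.DataFrame, grouping: dict[str, str]
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Per-group exclusive orthogroups and upset-style intersection counts.

    ``grouping`` labels every genome with exactly one group.  An
    orthogroup is specific to group X iff it is present in >= 1 genome
    of X and in no genome of any other group.  The second return value
    lists every non-empty group combination with its orthogroup count;
    the disjoint combination cells partition the orthogroups present in
    >= 1 genome.
    """
    missing = set(matrix.columns) - set(grouping)
    if missing:
        raise ValueError("grouping misses genome(s): " + ", ".join(sorted(missing)[:5]))
    presence = presence_matrix(matrix)
    groups = sorted(set(grouping[g] for g in matrix.columns))
    group_presence = pd.DataFrame(
        {
            grp: presence[[g for g in matrix.columns if grouping[g] == grp]].any(axis=1)
            for grp in groups
        }
    )
    nonempty = group_presence.any(axis=1)
    combo = group_presence.loc[nonempty].apply(
        lambda row: "+".join(g for g in groups if row[g]), axis=1
    )
    combo_counts = (
        combo.value_counts().rename_axis("groups").reset_index(name="orthogroups")
    )
    specific = {
        grp: group_presence.index[
            group_presence[grp] & (group_presence.drop(columns=grp).sum(axis=1) == 0)
        ].tolist()
        for grp in groups
    }
    return specific, combo_counts


def _presence_bool(matrix: pd.DataFrame) -> np.ndarray:
    return presence_matrix(matrix).to_numpy(dtype=bool).T  # genomes x orthogroups


def jaccard_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Jaccard dissimilarity 1 - |∩|/|∪| between genomes.

    Symmetric with a zero diagonal; the exported input for NMDS
    ordination.  A genome with no orthogroups is maximally dissimilar
    (1) to every other genome, with a warning.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 genomes")
    presence = _presence_bool(matrix)
    empty = ~presence.any(axis=1)
    if empty.any():
        warnings.warn(
            "genome(s) with zero orthogroups: "
            + ", ".join(np.asarray(matrix.columns)[empty][:5])
        )
    n = presence.shape[0]
    dist = np.zeros((n, n))
    if presence.any():
        # scipy's jaccard metric is |symmetric difference| / |union|
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            dist = squareform(pdist(presence, metric="jaccard"))
    # a genome with no orthogroups shares nothing with any other genome
    for i in np.flatnonzero(empty):
        for j in range(n):
            if i != j:
                dist[i, j] = dist[j, i] = 1.0
    return pd.DataFrame(dist, index=matrix.columns, columns=matrix.columns)


def shared_fraction_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise shared-orthogroup percentage, 100 * |∩|/|∪|.

    Cell-wise equal to 100 * (1 - Jaccard dissimilarity); diagonal 100.
    """
    return 100.0 * (1.0 - jaccard_matrix(matrix))


def sharing_proportions(
    matrix: pd.DataFrame,
    focal: set[str] | list[str],
    statuses: dict[str, str],
) -> pd.DataFrame:
    """Focal vs non-focal carriage proportions per focal-carried orthogroup.

    For every orthogroup present in >= 1 focal genome: the proportion of
    focal genomes carrying it, the proportion of non-focal genomes
    carrying it, and its annotation status (required for each such
    orthogroup).  The comparison of the two proportions by status is the
    basis of the "confined to the focal clade" test.
    """
    focal = set(focal)
    if not focal:
        raise ValueError("focal genome set is empty")
    unknown_genomes = focal - set(matrix.columns)
    if unknown_genomes:
        raise ValueError(
            "focal genome(s) absent from matrix: " + ", ".join(sorted(unknown_genomes)[:5])
        )
    focal_cols = [g for g in matrix.columns if g in focal]
    other_cols = [g for g in matrix.columns if g not in focal]
    presence = presence_matrix(matrix)
    in_focal = presence[focal_cols].sum(axis=1)
    carried = presence.index[in_focal > 0]
    missing_status = [og for og in carried if og not in statuses]
    if missing_status:
        raise ValueError(
            "orthogroup(s) without status: " + ", ".join(missing_status[:5])
        )
    out = pd.DataFrame(
        {
            "orthogroup": carried,
            "prop_focal": (in_focal.loc[carried] / len(focal_cols)).to_numpy(),
            "prop_other": (
                presence.loc[carried, other_cols].sum(axis=1) / len(other_cols)
            ).to_numpy()
            if other_cols
            else 0.0,
            "status": [statuses[og] for og in carried],
        }
    ).reset_index(drop=True)
    return out


def aggregate_orthogroup_status(
    gene_statuses: pd.DataFrame,
    membership: pd.DataFrame,
    method: str = "precedence",
) -> dict[str, str]:
    """Orthogroup status from its member genes' statuses.

    ``membership`` maps gene_id -> orthogroup.  With ``precedence`` (the
    default) an orthogroup with any annotated gene is annotated, else
    hypothetical if any hypothetical gene, else unknown.  ``majority``
    takes the most frequent member status (ties broken by the same
    precedence order).
    """
    order = {"annotated": 0, "hypothetical": 1, "unknown": 2}
    merged = membership.merge(gene_statuses[["gene_id", "status"]], on="gene_id")
    out: dict[str, str] = {}
    for og, grp in merged.groupby("orthogroup"):
        vals = grp["status"]
        if method == "precedence":
            out[og] = min(vals, key=order.get)
        elif method == "majority":
            counts = vals.value_counts()
            best = counts[counts == counts.max()].index
            out[og] = min(best, key=order.get)
        else:
            raise ValueError(f"unknown aggregation method {method!r}")
    return out
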