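"""Annotation post-processing: blast-score-ratio filtering, gene status
classification, extracellular-peptidase and CAZyme validation, and
per-genome status percentages.

The blast score ratio (BSR) of a hit is its bitscore divided by the
query gene's self-alignment bitscore, a length-normalized similarity; hits
below the threshold (default 0.4, inclusive) are discarded before
classification.  Rows from databases without bitscores (SignalP, dbCAN)
pass through the filter untouched.

Gene statuses partition every gene into exactly one of three classes:

- ``annotated``  — at least one KEGG or NR hit whose description is
  functional (does not match a hypothetical marker);
- ``hypothetical`` — otherwise, at least one KEGG/NR hit matching a
  hypothetical marker (e.g. "hypothetical protein");
- ``unknown``    — no KEGG/NR hits at all.

A KEGG hit with a KO identifier but a hypothetical-style description
counts as hypothetical, not annotated.  The marker list is a
case-insensitive substring match and configurable; the default covers the
common uninformative descriptions.
"""

from __future__ import annotations

import warnings

import pandas as pd

__all__ = [
    "DEFAULT_HYPOTHETICAL_MARKERS",
    "SCORED_DATABASES",
    "bsr_filter",
    "classify_gene_status",
    "extracellular_peptidases",
    "validate_cazymes",
    "status_percentages",
]

DEFAULT_HYPOTHETICAL_MARKERS = (
    "hypothetical protein",
    "uncharacterized protein",
    "unknown function",
    "DUF",
)

#: databases whose rows carry bitscores and are subject to the BSR filter
SCORED_DATABASES = frozenset({"KEGG", "NR", "MEROPS", "TCDB"})

STATUSES = ("annotated", "hypothetical", "unknown")


def bsr_filter(
    hits: pd.DataFrame,
    self_scores: pd.DataFrame,
    threshold: float = 0.4,
    return_subthreshold: bool = False,
):
    """Keep scored hits with bitscore / self_bitscore >= threshold.

    Rows from unscored databases (SignalP, dbCAN) pass through.  A scored
    hit whose gene lacks a self score raises a validation error naming
    the gene.  With ``return_subthreshold`` the discarded scored hits are
    returned as a second frame (they are reported separately, e.g. when
    checking incomplete pathways, and never merged into statuses).
    """
    if hits.empty:
        return (hits.copy(), hits.copy()) if return_subthreshold else hits.copy()
    selfs = self_scores.set_index("gene_id")["self_bitscore"]
    if (selfs <= 0).any():
        raise ValueError("self bitscores must be positive")
    scored = hits["database"].isin(SCORED_DATABASES)
    gene_self = hits["qseqid"].map(selfs)
    missing = scored & gene_self.isna()
    if missing.any():
        names = hits.loc[missing, "qseqid"].unique()
        raise ValueError(
            "missing self score for scored hit(s) of gene(s): "
            + ", ".join(names[:10])
        )
    ratio = hits["bitscore"] / gene_self
    keep = ~scored | (ratio >= threshold)
    if return_subthreshold:
        return hits.loc[keep].copy(), hits.loc[scored & ~keep].copy()
    return hits.loc[keep].copy()


def _matches_marker(descriptions: pd.Series, markers) -> pd.Series:
    hit = pd.Series(False, index=descriptions.index)
    lowered = descriptions.fillna("").str.lower()
    for marker in markers:
        hit |= lowered.str.contains(marker.lower(), regex=False)
    return hit


def classify_gene_status(
    hits: pd.DataFrame,
    genes: pd.DataFrame,
    hypothetical_markers=DEFAULT_HYPOTHETICAL_MARKERS,
) -> pd.DataFrame:
    """One status per gene from its (BSR-filtered) KEGG/NR hits.

    ``genes`` is the full gene universe (columns gene_id, genome_id) —
    required because unknown genes have no hit rows at all.  Returns a
    frame (gene_id, genome_id, status).
    """
    if genes["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id in gene universe")
    functional = hits[hits["database"].isin(("KEGG", "NR"))]
    if not functional.empty:
        marker = _matches_marker(functional["description"], hypothetical_markers)
        annotated_genes = set(functional.loc[~marker, "qseqid"])
        hypothetical_genes = set(functional.loc[marker, "qseqid"]) - annotated_genes
    else:
        annotated_genes, hypothetical_genes = set(), set()
    status = genes["gene_id"].map(
        lambda g: "annotated" if g in annotated_genes
        else ("hypothetical" if g in hypothetical_genes else "unknown")
    )
    return pd.DataFrame(
        {
            "gene_id": genes["gene_id"],
            "genome_id": genes["genome_id"],
            "status": status,
        }
    )


def extracellular_peptidases(hits: pd.DataFrame) -> set[str]:
    """Genes with a SignalP "SP" call and at least one MEROPS hit.

    A signal-peptide call alone (no peptidase homology) or a MEROPS hit
    alone (intracellular peptidase) does not qualify.
    """
    sp = set(
        hits.loc[
            (hits["database"] == "SignalP")
            & (hits["description"].str.strip() == "SP"),
            "qseqid",
        ]
    )
    merops = set(hits.loc[hits["database"] == "MEROPS", "qseqid"])
    return sp & merops


def validate_cazymes(hits: pd.DataFrame) -> set[str]:
    """Genes with more than one dbCAN annotation that are also in KEGG or NR."""
    dbcan_counts = hits.loc[hits["database"] == "dbCAN", "qseqid"].value_counts()
    multi = set(dbcan_counts[dbcan_counts > 1].index)
    backed = set(hits.loc[hits["database"].isin(("KEGG", "NR")), "qseqid"])
    return multi & backed


def status_percentages(statuses: pd.DataFrame) -> pd.DataFrame:
    """Per-genome gene counts and percentages by status.

    Percentages sum to 100 per genome (up to rounding).  Genomes with
    zero genes cannot occur in a valid status frame; an empty input
    yields an empty table with a warning.
    """
    if statuses.empty:
        warnings.warn("no genes to summarize")
        return pd.DataFrame(
            columns=["genome_id", "n_genes"]
            + [f"n_{s}" for s in STATUSES]
            + [f"pct_{s}" for s in STATUSES]
        )
    counts = (
        statuses.pivot_table(
            index="genome_id", columns="status", values="gene_id", aggfunc="count"
        )
        .reindex(columns=list(STATUSES))
        .fillna(0)
        .astype(int)
    )
    total = counts.sum(axis=1)
    out = pd.DataFrame({"genome_id": counts.index, "n_genes": total.to_numpy()})
    for s in STATUSES:
        out[f"n_{s}"] = counts[s].to_numpy()
    for s in STATUSES:
        out[f"pct_{s}"] = 100.0 * counts[s].to_numpy() / total.to_numpy()
    return out.reset_index(drop=True)
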