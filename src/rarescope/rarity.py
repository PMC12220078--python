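"""The rarity index and rare/common/not-detected group assignment.

For each genome the rarity index is the median of its relative abundance
over the sequencing runs in which it was detected (RA > 0 after all
filters), weighted by its fraction of occurrence — the number of runs
with detection divided by the total number of screened runs:

    rarity = median(RA | RA > 0) * n_detected / n_screened

The index is on the percent scale of the abundances.  Genomes are split
at the median rarity of the detected genomes: below the median is rare,
above is common; a genome exactly at the median is assigned rare (the
defining inequalities are strict on both sides, so the boundary needs a
fixed documented rule).  Genomes never detected in any screened run form
a third group, ``not_detected``, reported with rarity 0 and excluded
from the median cutoff (both choices switchable).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["occurrence_fraction", "rarity_index", "assign_rarity_groups"]


def _wide(abundance: pd.DataFrame) -> pd.DataFrame:
    """Long (run_id, genome_id, relative_abundance) -> genome x run wide."""
    return abundance.pivot_table(
        index="genome_id",
        columns="run_id",
        values="relative_abundance",
        aggfunc="first",
        fill_value=0.0,
    )


def occurrence_fraction(
    abundance: pd.DataFrame, genome_id: str, total_runs: int
) -> float:
    """Fraction of all screened runs in which the genome is detected.

    ``total_runs`` is the number of screened runs, which may exceed the
    number of runs present in the table (runs with no detections at all
    are often omitted from long-form abundance tables).
    """
    if total_runs <= 0:
        raise ValueError("total_runs must be positive")
    sub = abundance[abundance["genome_id"] == genome_id]
    n_runs_present = sub["run_id"].nunique()
    if total_runs < n_runs_present:
        raise ValueError("total_runs smaller than the number of runs in the table")
    detected = int((sub["relative_abundance"] > 0).sum())
    return detected / total_runs


def rarity_index(abundance: pd.DataFrame, total_runs: int | None = None) -> pd.DataFrame:
    """Per-genome median detected abundance, occurrence fraction and rarity.

    Returns one row per genome with columns genome_id,
    median_detected_abundance, occurrence_fraction, rarity and group
    (``not_detected`` for genomes with no detection, empty otherwise —
    use :func:`assign_rarity_groups` to fill in rare/common).

    ``total_runs`` defaults to the number of distinct runs in the table.
    """
    if (abundance["relative_abundance"] < 0).any():
        raise ValueError("negative abundance values")
    wide = _wide(abundance)
    if total_runs is None:
        total_runs = wide.shape[1]
    if total_runs <= 0:
        raise ValueError("total_runs must be positive")
    if total_runs < wide.shape[1]:
        raise ValueError("total_runs smaller than the number of runs in the table")

    values = wide.to_numpy()
    detected_mask = values > 0
    n_detected = detected_mask.sum(axis=1)
    medians = np.zeros(len(wide))
    for i in range(len(wide)):
        if n_detected[i] > 0:
            medians[i] = np.median(values[i][detected_mask[i]])
    frac = n_detected / total_runs
    out = pd.DataFrame(
        {
            "genome_id": wide.index,
            "median_detected_abundance": medians,
            "occurrence_fraction": frac,
            "rarity": medians * frac,
            "group": np.where(n_detected == 0, "not_detected", ""),
        }
    ).reset_index(drop=True)
    return out


def assign_rarity_groups(
    results: pd.DataFrame, include_not_detected_in_median: bool = False
) -> pd.DataFrame:
    """Fill in rare/common labels by a median split of the rarity index.

    The median is computed over detected genomes only by default
    (never-detected genomes form their own group); genomes at or below
    the median are rare, above it common.  Requires at least one
    detected genome.
    """
    out = results.copy()
    detected = out["group"] != "not_detected"
    if not detected.any():
        raise ValueError("no detected genomes; cannot compute median rarity")
    pool = out["rarity"] if include_not_detected_in_median else out.loc[detected, "rarity"]
    cutoff = float(np.median(pool))
    out.loc[detected, "group"] = np.where(
        out.loc[detected, "rarity"] <= cutoff, "rare", "common"
    )
    out.attrs["median_rarity"] = cutoff
    return out
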