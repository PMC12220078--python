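"""Tree-based computations: relative evolutionary divergence (RED),
RED-interval rank assignment, and Wagner-parsimony ancestral gene-content
reconstruction with per-branch event calls.

The central container is :class:`PhyloTree`, a validated wrapper around a
rooted :class:`dendropy.Tree` with branch lengths.  Node identifiers are
deterministic: leaves keep their taxon labels verbatim, internal nodes are
numbered ``N<k>`` in postorder.

RED places every node of a rooted tree on a [0, 1] scale — 0 at the root,
1 at every leaf — so that clade depths become comparable across lineages
with very different substitution rates.  For an internal node ``v`` with
parent ``p``, incoming branch length ``d`` and mean patristic distance
``u`` from ``v`` to its descendant leaves,

    red(v) = red(p) + d / (d + u) * (1 - red(p))

computed root-to-tip (preorder).  The statistic is invariant under uniform
rescaling of all branch lengths.

Wagner parsimony reconstructs ancestral gene-family counts that minimize a
linear asymmetric change cost along branches: each unit of increase costs
``gain_penalty`` units, each unit of decrease costs one unit.  The optimum
is found per family by a Sankoff dynamic program over the count states
0..max(leaf count), with ties broken toward the smallest ancestral count
(biased against unobservable ancestral content).  Per-branch events are
then called from the inferred parent/child counts: a family appearing
(0 -> >0) is a gain, disappearing (>0 -> 0) a loss, increasing from a
nonzero parent an expansion, decreasing to a nonzero child a contraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PhyloTree",
    "REDResult",
    "AncestralReconstruction",
    "compute_red",
    "assign_ranks",
    "wagner_reconstruct",
    "summarize_events",
    "EVENT_TYPES",
]

EVENT_TYPES = ("gain", "loss", "expansion", "contraction")


class TreeError(ValueError):
    """Raised for malformed or invalid trees."""


class PhyloTree:
    """A rooted tree with branch lengths on every non-root edge.

    Parameters
    ----------
    tree:
        A ``dendropy.Tree``.  Validated on construction: every non-root
        node must carry a finite non-negative edge length, and leaf labels
        must be unique.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()
        self._assign_node_ids()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        """Parse a Newick string into a validated tree.

        Raises :class:`TreeError` on malformed input or missing branch
        lengths.
        """
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parser errors
            raise TreeError(f"newick parse error: {exc}") from exc
        return cls(tree)

    def _validate(self) -> None:
        missing = []
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            length = node.edge.length
            label = node.taxon.label if node.taxon else "<internal>"
            if length is None:
                missing.append(label)
            elif not np.isfinite(length) or length < 0:
                raise TreeError(f"invalid branch length {length!r} on node {label}")
        if missing:
            raise TreeError(
                "missing branch length on node(s): " + ", ".join(missing)
            )
        labels = [lf.taxon.label for lf in self._tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise TreeError("duplicate leaf labels")
        if len(labels) < 1:
            raise TreeError("tree has no leaves")

    def _assign_node_ids(self) -> None:
        counter = 0
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                node.node_id = node.taxon.label
            else:
                node.node_id = f"N{counter}"
                counter += 1

    # -- accessors ---------------------------------------------------------

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def root(self) -> dendropy.Node:
        return self._tree.seed_node

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    def postorder(self):
        return self._tree.postorder_node_iter()

    def preorder(self):
        return self._tree.preorder_node_iter()

    def node_ids(self) -> list[str]:
        """All node ids in postorder (leaves by label, internals ``N<k>``)."""
        return [n.node_id for n in self.postorder()]

    def branches(self) -> list[tuple[str, str, float]]:
        """(parent_id, child_id, length) for every non-root edge, postorder."""
        out = []
        for node in self.postorder():
            if node.parent_node is not None:
                out.append((node.parent_node.node_id, node.node_id, node.edge.length))
        return out

    def to_newick(self) -> str:
        s = self._tree.as_string(schema="newick", suppress_rooting=True)
        return s.strip()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PhyloTree(n_leaves={self.n_leaves})"


# -- RED -------------------------------------------------------------------


@dataclass
class REDResult:
    """RED value per node id; 0 at the root, 1 at every leaf."""

    values: dict[str, float]
    is_leaf: dict[str, bool]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": list(self.values),
                "red": [self.values[k] for k in self.values],
                "is_leaf": [self.is_leaf[k] for k in self.values],
            }
        )


def compute_red(tree: PhyloTree) -> REDResult:
    """Relative evolutionary divergence for every node of a rooted tree.

    Requires at least two leaves.  Zero-length degenerate clades
    (``d + u == 0``) inherit the parental RED with a warning.
    """
    if tree.n_leaves < 2:
        raise TreeError("RED requires a tree with at least 2 leaves")

    # postorder: mean patristic distance u from each node to its descendant leaves
    for node in tree.postorder():
        if node.is_leaf():
            node._leaf_count = 1
            node._dist_sum = 0.0
        else:
            node._leaf_count = sum(c._leaf_count for c in node.child_nodes())
            node._dist_sum = sum(
                c._dist_sum + c.edge.length * c._leaf_count
                for c in node.child_nodes()
            )

    values: dict[str, float] = {}
    is_leaf: dict[str, bool] = {}
    for node in tree.preorder():
        if node.parent_node is None:
            node._red = 0.0
        elif node.is_leaf():
            node._red = 1.0
        else:
            d = node.edge.length
            u = node._dist_sum / node._leaf_count
            parent_red = node.parent_node._red
            if d + u == 0:
                warnings.warn(
                    f"zero-length clade at {node.node_id}; RED inherited from parent"
                )
                node._red = parent_red
            else:
                node._red = parent_red + (d / (d + u)) * (1.0 - parent_red)
        values[node.node_id] = node._red
        is_leaf[node.node_id] = node.is_leaf()
    return REDResult(values=values, is_leaf=is_leaf)


def assign_ranks(
    red: REDResult,
    reference: dict[str, float],
    tolerance: float = np.inf,
    include_leaves: bool = False,
) -> dict[str, str]:
    """Label nodes with the taxonomic rank whose reference RED is nearest.

    ``reference`` maps rank name to its reference RED value (e.g. GTDB
    release medians) and must be strictly increasing with rank depth; no
    defaults ship with the package because reference values are
    release-dependent.  Nodes farther than ``tolerance`` from every
    reference are labeled ``"unassigned"``.  An exact midpoint between two
    references goes to the shallower rank (the smaller reference value).
    """
    if not reference:
        raise ValueError("empty rank reference")
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    ranks = sorted(reference, key=reference.get)
    ref_vals = np.array([reference[r] for r in ranks])
    if np.any(np.diff(ref_vals) <= 0):
        raise ValueError("reference RED values must be strictly increasing")

    out: dict[str, str] = {}
    for node_id, value in red.values.items():
        if red.is_leaf[node_id] and not include_leaves:
            continue
        dist = np.abs(ref_vals - value)
        # exact midpoints (up to float error) go to the shallower rank
        best = int(np.flatnonzero(dist <= dist.min() + 1e-9)[0])
        out[node_id] = ranks[best] if dist[best] <= tolerance else "unassigned"
    return out


# -- Wagner parsimony ------------------------------------------------------


@dataclass
class AncestralReconstruction:
    """Result of a Wagner-parsimony gene-content reconstruction.

    Attributes
    ----------
    counts:
        Inferred count per orthogroup (rows) and node id (columns).
    events:
        One row per (orthogroup, branch) with a non-``none`` event.
        Columns: orthogroup, parent_id, child_id, event, delta.
    total_cost:
        Summed weighted change cost over all orthogroups and branches.
    cost_per_orthogroup:
        Series of per-orthogroup minimal costs.
    gain_penalty:
        The cost of one unit of count increase (decreases cost 1 unit).
    """

    counts: pd.DataFrame
    events: pd.DataFrame
    total_cost: float
    cost_per_orthogroup: pd.Series
    gain_penalty: float


def _branch_cost_matrix(n_states: int, gain_penalty: float) -> np.ndarray:
    """cost[s, t] of a branch from parent count s to child count t."""
    s = np.arange(n_states)[:, None]
    t = np.arange(n_states)[None, :]
    return gain_penalty * np.maximum(0, t - s) + np.maximum(0, s - t)


def classify_event(parent_count: int, child_count: int) -> str:
    """Event label for a branch given inferred parent/child counts."""
    if parent_count == 0 and child_count > 0:
        return "gain"
    if parent_count > 0 and child_count == 0:
        return "loss"
    if child_count > parent_count > 0:
        return "expansion"
    if 0 < child_count < parent_count:
        return "contraction"
    return "none"


def wagner_reconstruct(
    tree: PhyloTree,
    counts: pd.DataFrame,
    gain_penalty: float = 1.0,
) -> AncestralReconstruction:
    """Minimum-cost ancestral counts for every orthogroup on a rooted tree.

    Parameters
    ----------
    tree:
        Rooted tree whose leaf labels are the genome ids.
    counts:
        Orthogroup x genome integer matrix; every leaf of the tree must
        have a column.
    gain_penalty:
        Cost per unit of count increase along a branch (default 1, the
        setting used for gene-family reconstruction with COUNT-style
        Wagner parsimony); decreases cost 1 per unit.

    Ancestral count states range over 0..max(leaf count) per orthogroup
    (the observed maximum; ancestral counts above every observed count are
    never optimal under linear costs).  Ties are resolved toward the
    smallest ancestral count, deterministically.
    """
    if gain_penalty <= 0:
        raise ValueError("gain_penalty must be positive")
    leaves = tree.leaf_labels
    missing = [lf for lf in leaves if lf not in counts.columns]
    if missing:
        raise ValueError(f"missing leaf counts for: {', '.join(missing)}")
    mat = counts[leaves].to_numpy()
    if np.any(mat < 0) or not np.issubdtype(mat.dtype, np.number):
        raise ValueError("counts must be non-negative integers")
    mat = mat.astype(int)

    nodes = list(tree.postorder())
    node_index = {id(n): i for i, n in enumerate(nodes)}
    node_ids = [n.node_id for n in nodes]
    leaf_pos = {lab: j for j, lab in enumerate(leaves)}

    n_og = mat.shape[0]
    inferred = np.zeros((n_og, len(nodes)), dtype=int)
    costs = np.zeros(n_og)
    event_rows: list[tuple[str, str, str, str, int]] = []

    INF = np.inf
    for og_i in range(n_og):
        leaf_counts = mat[og_i]
        smax = int(leaf_counts.max())
        n_states = smax + 1
        if smax == 0:
            continue  # absent everywhere: zero at every node, no events
        C = _branch_cost_matrix(n_states, gain_penalty)
        # Sankoff bottom-up: cost[i][s] = min cost of subtree of node i
        # given node i has count s; choice[i][s] = argmin child state later.
        node_cost = np.full((len(nodes), n_states), INF)
        # argmin child state for each (child node, parent state)
        child_choice = np.zeros((len(nodes), n_states), dtype=int)
        for i, node in enumerate(nodes):
            if node.is_leaf():
                node_cost[i] = INF
                node_cost[i, leaf_counts[leaf_pos[node.taxon.label]]] = 0.0
            else:
                total = np.zeros(n_states)
                for child in node.child_nodes():
                    j = node_index[id(child)]
                    # through[s, t] = branch cost + child's subtree cost
                    through = C + node_cost[j][None, :]
                    # argmin returns the first (= smallest) optimal state
                    best_t = np.argmin(through, axis=1)
                    child_choice[j] = best_t
                    total += through[np.arange(n_states), best_t]
                node_cost[i] = total
        root_i = node_index[id(tree.root)]
        root_state = int(np.argmin(node_cost[root_i]))  # ties -> smallest
        costs[og_i] = node_cost[root_i, root_state]
        # top-down traceback (preorder)
        states = np.zeros(len(nodes), dtype=int)
        states[root_i] = root_state
        for node in tree.preorder():
            i = node_index[id(node)]
            if node.parent_node is not None:
                p = node_index[id(node.parent_node)]
                states[i] = child_choice[i, states[p]]
                ev = classify_event(states[p], states[i])
                if ev != "none":
                    event_rows.append(
                        (
                            counts.index[og_i],
                            nodes[p].node_id,
                            node.node_id,
                            ev,
                            int(states[i] - states[p]),
                        )
                    )
        inferred[og_i] = states

    counts_out = pd.DataFrame(inferred, index=counts.index, columns=node_ids)
    events = pd.DataFrame(
        event_rows, columns=["orthogroup", "parent_id", "child_id", "event", "delta"]
    )
    cost_series = pd.Series(costs, index=counts.index, name="cost")
    return AncestralReconstruction(
        counts=counts_out,
        events=events,
        total_cost=float(costs.sum()),
        cost_per_orthogroup=cost_series,
        gain_penalty=gain_penalty,
    )


def summarize_events(
    rec: AncestralReconstruction,
    clades: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Totals of gains/losses/expansions/contractions per clade.

    ``clades`` maps a branch's child node id to a clade label; branches
    without a label are pooled under ``"unassigned"``.  With ``None``,
    tree-wide totals are reported under a single ``"all"`` row.  Totals
    always equal a direct recount of the per-branch event list.
    """
    ev = rec.events.copy()
    if ev.empty:
        cols = list(EVENT_TYPES)
        if clades is None:
            return pd.DataFrame(0, index=pd.Index(["all"], name="clade"), columns=cols)
        labels = sorted(set(clades.values()))
        return pd.DataFrame(0, index=pd.Index(labels, name="clade"), columns=cols)
    if clades is None:
        ev["clade"] = "all"
    else:
        ev["clade"] = ev["child_id"].map(clades).fillna("unassigned")
    table = (
        ev.pivot_table(
            index="clade", columns="event", values="orthogroup", aggfunc="count"
        )
        .reindex(columns=list(EVENT_TYPES))
        .fillna(0)
        .astype(int)
    )
    table.columns.name = None
    return table
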