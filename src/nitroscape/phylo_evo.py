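"""Phylogenetic mapping of structural data.

Root-to-node distances, attribute–depth rank correlation, hierarchical
clustering of structure-distance matrices against clade labels, and
insertion/deletion event detection from alignment gap blocks with Fitch
parsimony branch assignment and per-lineage length trajectories.

Alignment column intervals are 0-based and half-open throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from .core_io import MSA, Phylogeny

logger = logging.getLogger(__name__)


@dataclass
class InsertionEvent:
    """A presence/absence switch of an alignment block on one branch."""

    block: tuple[int, int]  # half-open column interval [start, end)
    event_branch: str  # child-node id of the branch where state flips
    direction: str  # "insertion" or "deletion"
    length_by_node: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.block[1] <= self.block[0]:
            raise ValueError(f"empty block interval {self.block}")
        if self.direction not in ("insertion", "deletion"):
            raise ValueError(f"direction must be insertion|deletion, got {self.direction!r}")


@dataclass
class GapBlock:
    """A run of alignment columns absent from a consistent row subset."""

    start: int
    end: int
    presence: frozenset[str]

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class ClusterResult:
    linkage: np.ndarray  # scipy linkage record (average linkage)
    labels: dict[str, int]  # flat labels at k clusters
    ids: list[str]
    k: int


# ---------------------------------------------------------------------------
# Tree quantities
# ---------------------------------------------------------------------------


def root_distances(t: Phylogeny) -> dict[str, float]:
    """Sum of branch lengths from the root to each node (root = 0)."""
    out: dict[str, float] = {}
    for node in t.preorder():
        if node.branch_length < 0:
            raise ValueError(f"node {node.id}: negative branch length")
        if node.parent is None:
            out[node.id] = 0.0
        else:
            out[node.id] = out[node.parent] + node.branch_length
    return out


# ---------------------------------------------------------------------------
# Rank correlation
# ---------------------------------------------------------------------------


def spearman(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 0,
    seed: int = 0,
) -> tuple[float, Optional[float]]:
    """Spearman rank correlation (average ranks for ties) with an optional
    seeded permutation p-value (two-sided)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-d arrays with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    rho = float(scipy.stats.spearmanr(x, y).statistic)
    if n_perm <= 0:
        return rho, None
    rng = np.random.default_rng(seed)
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(ry))
        r = np.corrcoef(rx, ry[perm])[0, 1]
        if abs(r) >= abs(rho) - 1e-12:
            hits += 1
    return rho, (hits + 1) / (n_perm + 1)


def attribute_depth_correlation(
    t: Phylogeny,
    attr_table: pd.DataFrame,
    attribute_name: str,
    n_perm: int = 0,
    seed: int = 0,
) -> dict[str, float]:
    """Spearman correlation between root distance and an attribute, over the
    nodes present in both the tree and the attribute table."""
    depths = root_distances(t)
    shared = [i for i in attr_table.index if i in depths and pd.notna(attr_table.loc[i, attribute_name])]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} nodes have both depth and {attribute_name!r}")
    x = np.array([depths[i] for i in shared])
    y = attr_table.loc[shared, attribute_name].to_numpy(dtype=float)
    rho, p = spearman(x, y, n_perm=n_perm, seed=seed)
    return {"rho": rho, "n": len(shared), "p": p}


# ---------------------------------------------------------------------------
# Clustering vs clades
# ---------------------------------------------------------------------------


def hierarchical_cluster(matrix: pd.DataFrame, k: int) -> ClusterResult:
    """Average-linkage agglomeration of a symmetric distance matrix, cut
    into ``k`` flat clusters."""
    values = matrix.to_numpy(dtype=float)
    n = values.shape[0]
    if values.shape[0] != values.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(values, values.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(values), 0.0, atol=1e-8):
        raise ValueError("distance matrix diagonal must be zero")
    if k > n:
        raise ValueError(f"k={k} exceeds number of items {n}")
    Z = sch.linkage(squareform(values, checks=False), method="average")
    flat = sch.fcluster(Z, t=k, criterion="maxclust")
    ids = list(matrix.index)
    return ClusterResult(linkage=Z, labels=dict(zip(ids, flat.tolist())), ids=ids, k=k)


def clade_recovery(labels_clusters: dict[str, int], labels_clades: dict[str, object]) -> float:
    """Adjusted Rand index between a flat clustering and clade labels."""
    if set(labels_clusters) != set(labels_clades):
        raise ValueError("cluster and clade labelings cover different ids")
    ids = sorted(labels_clusters)
    a = [labels_clusters[i] for i in ids]
    b = [labels_clades[i] for i in ids]
    return float(adjusted_rand_score(a, b))


# ---------------------------------------------------------------------------
# Indel blocks
# ---------------------------------------------------------------------------


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def detect_indel_blocks(
    msa: MSA, min_block: int = 5, merge_jaccard: float = 0.9
) -> list[GapBlock]:
    """Find alignment column blocks occupied by a consistent row subset.

    A column participates when at least one row is gapped there. Adjacent
    such columns merge into one block while their presence sets stay
    similar (Jaccard ≥ ``merge_jaccard``) or nested — the nested rule
    admits the ragged edges of terminal extensions that elongated
    progressively along a lineage. Blocks shorter than ``min_block``
    columns are discarded. The block's presence set is the union of rows
    occupying any of its columns.
    """
    ids = msa.ids
    n_rows = len(ids)
    cols: list[Optional[frozenset]] = []
    for j in range(msa.length):
        col = msa.column(j)
        present = frozenset(i for i in ids if col[i] != "-")
        cols.append(present if len(present) < n_rows else None)

    blocks: list[GapBlock] = []
    j = 0
    while j < msa.length:
        if cols[j] is None or not cols[j]:
            j += 1
            continue
        start = j
        presence = cols[j]
        prev = cols[j]
        j += 1
        while j < msa.length and cols[j] is not None and cols[j]:
            cur = cols[j]
            nested = cur <= prev or prev <= cur
            if _jaccard(cur, prev) < merge_jaccard and not nested:
                break
            presence = presence | cur
            prev = cur
            j += 1
        if j - start >= min_block:
            blocks.append(GapBlock(start=start, end=j, presence=presence))
    return blocks


# ---------------------------------------------------------------------------
# Fitch parsimony and event assignment
# ---------------------------------------------------------------------------


def fitch_states(t: Phylogeny, leaf_states: dict[str, int]) -> dict[str, int]:
    """Minimum-change presence/absence reconstruction on a rooted tree.

    Classic two-pass Fitch: bottom-up state sets, then top-down resolution
    inheriting the parent state whenever admissible. Root-level ties prefer
    absence, so an ambiguous history is explained by insertions rather than
    deletions.
    """
    sets: dict[str, set[int]] = {}
    for node in t.postorder():
        if node.is_leaf:
            if node.id not in leaf_states:
                raise ValueError(f"leaf {node.id} missing a state")
            sets[node.id] = {leaf_states[node.id]}
        else:
            child_sets = [sets[c] for c in node.children]
            inter = set.intersection(*child_sets)
            sets[node.id] = inter if inter else set.union(*child_sets)
    states: dict[str, int] = {}
    for node in t.preorder():
        options = sets[node.id]
        if node.parent is None:
            states[node.id] = 0 if 0 in options else 1
        else:
            parent_state = states[node.parent]
            states[node.id] = parent_state if parent_state in options else next(iter(options))
    return states


def assign_events_to_branches(
    blocks: list[GapBlock],
    t: Phylogeny,
    msa: MSA,
    use_ancestral_rows: bool = True,
) -> list[InsertionEvent]:
    """Map gap blocks to the branches where presence switches state.

    Leaf presence comes from the block itself. Internal-node states come
    from the MSA's ancestral rows when available (a node is "present" when
    it has any residue inside the block), otherwise from Fitch parsimony
    on the leaves. A 0→1 flip along a branch is an insertion, 1→0 a
    deletion; a block can yield several events.
    """
    leaf_ids = set(t.leaf_ids())
    events: list[InsertionEvent] = []
    for block in blocks:
        leaf_states = {i: (1 if i in block.presence else 0) for i in leaf_ids}
        if not any(leaf_states.values()):
            raise ValueError(f"block {block.start}:{block.end} present in no leaf")
        length_by_node = {
            row_id: sum(1 for ch in seq[block.start : block.end] if ch != "-")
            for row_id, seq in msa.rows.items()
        }
        ancestral_available = use_ancestral_rows and all(
            node.id in msa.rows for node in t.preorder() if not node.is_leaf
        )
        if ancestral_available:
            states = {node.id: (1 if length_by_node.get(node.id, 0) > 0 else 0) for node in t.preorder()}
        else:
            states = fitch_states(t, leaf_states)
        for node in t.preorder():
            if node.parent is None:
                continue
            parent_state, child_state = states[node.parent], states[node.id]
            if parent_state == child_state:
                continue
            events.append(
                InsertionEvent(
                    block=(block.start, block.end),
                    event_branch=node.id,
                    direction="insertion" if child_state > parent_state else "deletion",
                    length_by_node=length_by_node,
                )
            )
    return events


def length_trajectory(
    event: InsertionEvent, t: Phylogeny, msa: MSA, lineage_tip: str
) -> list[tuple[str, Optional[int]]]:
    """Non-gap residue count inside the event block for every node on the
    root→tip path, in root-to-tip order. Nodes without an MSA row are
    reported as missing (None)."""
    if lineage_tip not in t.nodes:
        raise ValueError(f"lineage tip {lineage_tip!r} not in tree")
    path = list(reversed(t.path_to_root(lineage_tip)))
    start, end = event.block
    out: list[tuple[str, Optional[int]]] = []
    for node_id in path:
        if node_id not in msa.rows:
            logger.warning("node %s has no alignment row; reported missing", node_id)
            out.append((node_id, None))
            continue
        segment = msa.rows[node_id][start:end]
        out.append((node_id, sum(1 for ch in segment if ch != "-")))
    return out
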