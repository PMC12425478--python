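"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid the code paths they check: superposition by dense
rotation search, average linkage by naive cluster merging, ARI by the
contingency-table formula, Fitch by exhaustive state enumeration, Spearman
by the explicit rank formula.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def grid_search_rmsd(P: np.ndarray, Q: np.ndarray, n_grid: int = 16) -> float:
    """Minimum RMSD over rotations by dense SO(3) search + local refinement.

    Translation is optimal at centroids for any rotation, so only the
    rotation is searched: a coarse Euler-angle grid followed by Nelder–Mead
    polish from the best grid point.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    n = len(P)

    def rmsd_for(euler: np.ndarray) -> float:
        R = Rotation.from_euler("zyz", euler).as_matrix()
        diff = Pc - Qc @ R.T
        return math.sqrt((diff**2).sum() / n)

    alphas = np.linspace(0, 2 * np.pi, n_grid, endpoint=False)
    betas = np.linspace(0, np.pi, n_grid)
    best_val, best_euler = np.inf, None
    for a in alphas:
        for b in betas:
            for c in alphas:
                v = rmsd_for(np.array([a, b, c]))
                if v < best_val:
                    best_val, best_euler = v, np.array([a, b, c])
    res = minimize(rmsd_for, best_euler, method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-12})
    return min(best_val, float(res.fun))


def average_linkage_heights(dist: np.ndarray) -> list[float]:
    """Merge heights of naive average-linkage agglomeration."""
    n = dist.shape[0]
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    heights: list[float] = []
    next_id = n

    def cluster_dist(a: int, b: int) -> float:
        vals = [dist[i, j] for i in members[a] for j in members[b]]
        return float(np.mean(vals))

    while len(members) > 1:
        keys = sorted(members)
        best = None
        for a, b in itertools.combinations(keys, 2):
            v = cluster_dist(a, b)
            if best is None or v < best[0]:
                best = (v, a, b)
        v, a, b = best
        heights.append(v)
        members[next_id] = members.pop(a) + members.pop(b)
        next_id += 1
    return heights


def ari_formula(labels_a: list, labels_b: list) -> float:
    """Adjusted Rand index straight from the contingency-table formula."""
    from math import comb

    a_values = sorted(set(labels_a))
    b_values = sorted(set(labels_b))
    table = np.zeros((len(a_values), len(b_values)), dtype=int)
    for x, y in zip(labels_a, labels_b):
        table[a_values.index(x), b_values.index(y)] += 1
    n = len(labels_a)
    sum_ij = sum(comb(int(v), 2) for v in table.ravel())
    sum_a = sum(comb(int(v), 2) for v in table.sum(axis=1))
    sum_b = sum(comb(int(v), 2) for v in table.sum(axis=0))
    expected = sum_a * sum_b / comb(n, 2)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


def fitch_min_changes(tree, leaf_states: dict[str, int]) -> int:
    """Minimum number of state changes by exhaustive internal-node assignment."""
    internal = [n.id for n in tree.preorder() if not n.is_leaf]
    best = None
    for assignment in itertools.product((0, 1), repeat=len(internal)):
        states = dict(zip(internal, assignment))
        states.update(leaf_states)
        changes = sum(
            1
            for node in tree.preorder()
            if node.parent is not None and states[node.id] != states[node.parent]
        )
        if best is None or changes < best:
            best = changes
    return best


def spearman_rank_formula(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho as the Pearson correlation of average ranks."""

    def ranks(v: np.ndarray) -> np.ndarray:
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v), dtype=float)
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(np.asarray(x, float)), ranks(np.asarray(y, float))
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / math.sqrt((rx**2).sum() * (ry**2).sum()))
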