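"""Phylogenetic mapping: root distances, rank correlation, clustering vs
clades, Fitch parsimony, and indel-block detection/assignment."""

import numpy as np
import pandas as pd
import pytest

from helpers import count_state_changes, manual_tree
from nitroscape.core_io import MSA, read_newick
from nitroscape.phylo_evo import (
    GapBlock,
    assign_events_to_branches,
    attribute_depth_correlation,
    clade_recovery,
    detect_indel_blocks,
    fitch_states,
    hierarchical_cluster,
    length_trajectory,
    root_distances,
    spearman,
)
from nitroscape.synthetic_data import simulate_tree
from oracles import (
    ari_formula,
    average_linkage_heights,
    fitch_min_changes,
    spearman_rank_formula,
)

# ---------------------------------------------------------------------------
# Root distances
# ---------------------------------------------------------------------------


def test_root_distances_simple():
    t = read_newick("(A:1,B:2)R;")
    assert root_distances(t) == {"R": 0.0, "A": 1.0, "B": 2.0}


def test_root_distances_chain():
    t = manual_tree({"R": (None, 0.0), "X": ("R", 1.0), "A": ("X", 1.0)}, root_id="R")
    assert root_distances(t)["A"] == pytest.approx(2.0)


def test_root_distances_match_recursive_oracle():
    t = simulate_tree(15, 3, seed=5)

    def recurse(node_id, acc, out):
        out[node_id] = acc
        for c in t.nodes[node_id].children:
            recurse(c, acc + t.nodes[c].branch_length, out)
        return out

    oracle = recurse(t.root_id, 0.0, {})
    fast = root_distances(t)
    assert fast.keys() == oracle.keys()
    for k in oracle:
        assert fast[k] == pytest.approx(oracle[k], abs=1e-12)


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------


def test_spearman_perfect_correlations():
    rho, _ = spearman(np.array([1.0, 2.0, 3.0]), np.array([6.0, 5.0, 4.0]))
    assert rho == pytest.approx(-1.0)
    rho, _ = spearman(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
    assert rho == pytest.approx(1.0)


def test_spearman_with_ties_matches_rank_formula_oracle():
    x = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0, 5.0, 3.0])
    y = np.array([2.0, 7.0, 1.0, 8.0, 2.0, 8.0, 1.0, 8.0, 2.0, 8.0])
    rho, _ = spearman(x, y)
    assert rho == pytest.approx(spearman_rank_formula(x, y), abs=1e-12)


def test_spearman_invariant_under_ranking():
    import scipy.stats

    rng = np.random.default_rng(1)
    x, y = rng.normal(size=20), rng.normal(size=20)
    rho_raw, _ = spearman(x, y)
    rho_rank, _ = spearman(scipy.stats.rankdata(x), scipy.stats.rankdata(y))
    assert rho_raw == pytest.approx(rho_rank, abs=1e-12)


def test_spearman_constant_vector_errors():
    with pytest.raises(ValueError):
        spearman(np.ones(5), np.arange(5.0))


def test_spearman_permutation_p_under_null():
    rng = np.random.default_rng(3)
    x = rng.normal(size=30)
    y = rng.permutation(rng.normal(size=30))
    rho, p = spearman(x, y, n_perm=2000, seed=0)
    assert abs(rho) < 0.4
    assert p > 0.05


def test_spearman_permutation_p_small_for_strong_trend():
    x = np.arange(20.0)
    y = -x + np.random.default_rng(0).normal(0, 0.1, 20)
    _, p = spearman(x, y, n_perm=2000, seed=0)
    assert p < 0.01


# ---------------------------------------------------------------------------
# Attribute–depth correlation
# ---------------------------------------------------------------------------


def test_depth_correlation_planted_monotone_decrease():
    t = simulate_tree(12, 3, seed=2)
    depths = root_distances(t)
    attr = pd.DataFrame({"charged_fraction": [1.0 - depths[i] for i in depths]}, index=list(depths))
    out = attribute_depth_correlation(t, attr, "charged_fraction")
    assert out["rho"] == pytest.approx(-1.0)
    assert out["n"] == len(depths)


def test_depth_correlation_excludes_missing_nodes_and_reports_n():
    t = simulate_tree(12, 3, seed=2)
    depths = root_distances(t)
    ids = list(depths)[:8]
    attr = pd.DataFrame({"a": [depths[i] for i in ids]}, index=ids)
    out = attribute_depth_correlation(t, attr, "a")
    assert out["n"] == 8
    assert out["rho"] == pytest.approx(1.0)


def test_depth_correlation_too_few_nodes_errors():
    t = simulate_tree(12, 3, seed=2)
    attr = pd.DataFrame({"a": [1.0, 2.0]}, index=["L000", "L001"])
    with pytest.raises(ValueError):
        attribute_depth_correlation(t, attr, "a")


# ---------------------------------------------------------------------------
# Clustering and ARI
# ---------------------------------------------------------------------------


def _two_group_matrix():
    ids = ["a1", "a2", "a3", "b1", "b2", "b3"]
    d = np.zeros((6, 6))
    for i in range(6):
        for j in range(6):
            if i != j:
                same = (i < 3) == (j < 3)
                d[i, j] = 1.0 if same else 10.0
    return pd.DataFrame(d, index=ids, columns=ids)


def test_hierarchical_cluster_two_tight_groups():
    mat = _two_group_matrix()
    res = hierarchical_cluster(mat, k=2)
    labels = res.labels
    assert labels["a1"] == labels["a2"] == labels["a3"]
    assert labels["b1"] == labels["b2"] == labels["b3"]
    assert labels["a1"] != labels["b1"]


def test_hierarchical_cluster_k_equals_n_singletons():
    mat = _two_group_matrix()
    res = hierarchical_cluster(mat, k=6)
    assert len(set(res.labels.values())) == 6


def test_hierarchical_cluster_merge_heights_match_oracle():
    rng = np.random.default_rng(4)
    pts = rng.uniform(0, 10, (6, 2))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    mat = pd.DataFrame(d, index=list("abcdef"), columns=list("abcdef"))
    res = hierarchical_cluster(mat, k=2)
    heights = res.linkage[:, 2]
    oracle = average_linkage_heights(d)
    np.testing.assert_allclose(heights, oracle, atol=1e-10)
    assert np.all(np.diff(heights) >= -1e-12)  # non-decreasing merge heights


def test_hierarchical_cluster_input_validation():
    mat = _two_group_matrix()
    with pytest.raises(ValueError):
        hierarchical_cluster(mat, k=7)
    asym = mat.copy()
    asym.iloc[0, 1] = 99.0
    with pytest.raises(ValueError):
        hierarchical_cluster(asym, k=2)
    diag = mat.copy()
    diag.iloc[0, 0] = 1.0
    with pytest.raises(ValueError):
        hierarchical_cluster(diag, k=2)


def test_clade_recovery_identical_labelings():
    labels = {f"x{i}": i % 3 for i in range(9)}
    clades = {k: f"c{v}" for k, v in labels.items()}
    assert clade_recovery(labels, clades) == pytest.approx(1.0)


def test_clade_recovery_chance_level():
    singletons = {f"x{i}": i for i in range(8)}
    all_same = {f"x{i}": "c" for i in range(8)}
    assert clade_recovery(singletons, all_same) == pytest.approx(0.0, abs=1e-12)


def test_clade_recovery_matches_ari_formula_oracle():
    rng = np.random.default_rng(7)
    for _ in range(5):
        a = {f"x{i}": int(rng.integers(3)) for i in range(8)}
        b = {f"x{i}": int(rng.integers(3)) for i in range(8)}
        ids = sorted(a)
        expected = ari_formula([a[i] for i in ids], [b[i] for i in ids])
        assert clade_recovery(a, b) == pytest.approx(expected, abs=1e-12)


def test_ari_invariant_under_label_permutation():
    a = {f"x{i}": i % 3 for i in range(9)}
    b = {f"x{i}": (i // 3) for i in range(9)}
    permuted = {k: {0: 2, 1: 0, 2: 1}[v] for k, v in b.items()}
    assert clade_recovery(a, b) == pytest.approx(clade_recovery(a, permuted), abs=1e-12)


def test_clade_recovery_id_mismatch_errors():
    with pytest.raises(ValueError):
        clade_recovery({"a": 1}, {"b": 1})


# ---------------------------------------------------------------------------
# Indel blocks
# ---------------------------------------------------------------------------


def test_no_gaps_no_blocks():
    msa = MSA({"a": "ACDEFGHIKL", "b": "ACDEFGHIKL"})
    assert detect_indel_blocks(msa) == []


def test_single_block_presence_set():
    rows = {
        "a": "AAAA----------AAAA",
        "b": "AAAA----------AAAA",
        "c": "AAAACCCCCCCCCCAAAA",
        "d": "AAAACCCCCCCCCCAAAA",
    }
    blocks = detect_indel_blocks(MSA(rows))
    assert len(blocks) == 1
    b = blocks[0]
    assert (b.start, b.end, b.span) == (4, 14, 10)
    assert b.presence == frozenset({"c", "d"})


def test_two_blocks_split_by_occupied_column():
    rows = {
        "a": "AA------A------AA",
        "b": "AACCCCCCACCCCCCAA",
    }
    blocks = detect_indel_blocks(MSA(rows), min_block=5)
    assert [(b.start, b.end) for b in blocks] == [(2, 8), (9, 15)]


def test_min_block_filters_short_runs():
    rows = {"a": "AA---AAAA", "b": "AACCCAAAA"}
    assert detect_indel_blocks(MSA(rows), min_block=5) == []
    assert len(detect_indel_blocks(MSA(rows), min_block=3)) == 1


def test_nested_presence_merging_for_ragged_edges():
    # terminal extension: row c has 8 columns, row d only the last 4
    rows = {
        "a": "--------AAAA",
        "b": "--------AAAA",
        "c": "CCCCCCCCAAAA",
        "d": "----DDDDAAAA",
    }
    blocks = detect_indel_blocks(MSA(rows), min_block=5)
    assert len(blocks) == 1
    assert (blocks[0].start, blocks[0].end) == (0, 8)
    assert blocks[0].presence == frozenset({"c", "d"})


# ---------------------------------------------------------------------------
# Fitch parsimony
# ---------------------------------------------------------------------------


def test_fitch_minimizes_changes_vs_exhaustive_oracle():
    for seed in range(6):
        t = simulate_tree(int(np.random.default_rng(seed).integers(4, 9)), 2, seed=seed)
        rng = np.random.default_rng(seed + 100)
        leaf_states = {i: int(rng.integers(2)) for i in t.leaf_ids()}
        states = fitch_states(t, leaf_states)
        for leaf, st in leaf_states.items():
            assert states[leaf] == st
        assert count_state_changes(t, states) == fitch_min_changes(t, leaf_states)


def test_fitch_root_tie_prefers_absence():
    t = read_newick("(A:1,B:1)R;")
    states = fitch_states(t, {"A": 0, "B": 1})
    assert states["R"] == 0


def test_fitch_missing_leaf_state_errors():
    t = read_newick("(A:1,B:1)R;")
    with pytest.raises(ValueError):
        fitch_states(t, {"A": 0})


# ---------------------------------------------------------------------------
# Event assignment and trajectories
# ---------------------------------------------------------------------------


def test_insertion_assigned_to_mrca_branch():
    t = read_newick("((A:1,B:1)N1:1,(C:1,D:1)N2:1)R;")
    rows = {
        "A": "AAAA------",
        "B": "AAAA------",
        "C": "AAAACCCCCC",
        "D": "AAAACCCCCC",
    }
    msa = MSA(rows)
    blocks = detect_indel_blocks(msa, min_block=5)
    events = assign_events_to_branches(blocks, t, msa)
    assert len(events) == 1
    assert events[0].event_branch == "N2"
    assert events[0].direction == "insertion"
    assert events[0].block == (4, 10)


def test_block_present_in_all_leaves_yields_no_event():
    t = read_newick("((A:1,B:1)N1:1,C:1)R;")
    block = GapBlock(start=0, end=5, presence=frozenset({"A", "B", "C"}))
    msa = MSA({"A": "AAAAA", "B": "AAAAA", "C": "AAAAA"})
    assert assign_events_to_branches([block], t, msa) == []


def test_block_present_in_no_leaf_errors():
    t = read_newick("(A:1,B:1)R;")
    block = GapBlock(start=0, end=5, presence=frozenset())
    msa = MSA({"A": "-----", "B": "-----"})
    with pytest.raises(ValueError):
        assign_events_to_branches([block], t, msa)


def test_ancestral_rows_override_fitch_and_report_deletion():
    # root carries the block; one leaf lost it → deletion on that branch
    t = read_newick("((A:1,B:1)N1:1,C:1)R;")
    rows = {
        "R": "CCCCCAAAA",
        "N1": "CCCCCAAAA",
        "A": "CCCCCAAAA",
        "B": "-----AAAA",
        "C": "CCCCCAAAA",
    }
    msa = MSA(rows)
    block = GapBlock(start=0, end=5, presence=frozenset({"A", "C"}))
    events = assign_events_to_branches([block], t, msa)
    assert len(events) == 1
    assert events[0].event_branch == "B"
    assert events[0].direction == "deletion"


def test_length_trajectory_zeros_off_lineage_and_bounded_by_span():
    t = read_newick("((A:1,B:1)N1:1,C:1)R;")
    rows = {
        "R": "-----AAAA",
        "N1": "CC---AAAA",
        "A": "CCCCCAAAA",
        "B": "CC---AAAA",
        "C": "-----AAAA",
    }
    msa = MSA(rows)
    blocks = detect_indel_blocks(msa, min_block=5)
    events = assign_events_to_branches(blocks, t, msa)
    ins = [e for e in events if e.direction == "insertion"]
    assert ins
    traj_a = length_trajectory(ins[0], t, msa, "A")
    assert traj_a == [("R", 0), ("N1", 2), ("A", 5)]
    traj_c = length_trajectory(ins[0], t, msa, "C")
    assert [v for _, v in traj_c] == [0, 0]
    span = ins[0].block[1] - ins[0].block[0]
    assert all(v <= span for _, v in traj_a)


def test_length_trajectory_missing_row_reported_none():
    t = read_newick("((A:1,B:1)N1:1,C:1)R;")
    msa = MSA({"A": "CCCCCAAAA", "B": "-----AAAA", "C": "-----AAAA"})
    block = GapBlock(start=0, end=5, presence=frozenset({"A"}))
    events = assign_events_to_branches([block], t, msa)
    traj = length_trajectory(events[0], t, msa, "A")
    assert traj[0] == ("R", None)
    assert traj[-1] == ("A", 5)
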