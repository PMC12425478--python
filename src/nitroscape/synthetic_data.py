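"""Synthetic datasets with the statistical structure the analysis assumes.

The generator emulates what the real pipeline consumes — a clade-structured
phylogeny, sequences evolved with substitutions plus clade-specific planted
insertions (optionally elongating progressively along a lineage), toy Cα
coordinates whose structural divergence tracks sequence divergence, and
ancestral posterior matrices with a controlled fraction of ambiguous
sites — while recording complete ground truth for parameter-recovery
tests. It stands in for the GPU structure-prediction stage, so every
downstream operation runs at desk scale.

All randomness flows through seeds derived from a single integer;
identical seeds give identical datasets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .core_io import (
    AMINO_ACIDS,
    MSA,
    Phylogeny,
    PhyloNode,
    PosteriorMatrix,
    Structure,
    structure_from_sequence_coords,
    write_fasta,
    write_pdb,
    write_posterior_table,
)

#: helix geometry for toy backbones: rise per residue (Å), radius (Å),
#: twist per residue (degrees)
HELIX_RISE = 1.5
HELIX_RADIUS = 2.3
HELIX_TWIST_DEG = 100.0


def _child_seed(seed: int, *salt: object) -> int:
    """Deterministic sub-seed below 2**31 derived from a parent seed."""
    import zlib

    tag = zlib.crc32("|".join(map(str, salt)).encode())
    h = np.random.SeedSequence([seed & 0x7FFFFFFF, tag & 0x7FFFFFFF])
    return int(h.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------


def simulate_tree(
    n_leaves: int, n_clades: int, seed: int, branch_mean: float = 0.05
) -> Phylogeny:
    """Yule-process topology with exponential branch lengths and clade labels.

    Clades are assigned by repeatedly splitting the subtree with the most
    leaves until ``n_clades`` subtrees remain; every leaf gets a label.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    if n_clades > n_leaves or n_clades < 1:
        raise ValueError("n_clades must be in [1, n_leaves]")
    rng = np.random.default_rng(seed)
    nodes: dict[str, PhyloNode] = {"root": PhyloNode("root", None, [], 0.0)}
    leaves = []
    counter = {"leaf": 0, "internal": 0}

    def new_leaf(parent: str) -> str:
        nid = f"L{counter['leaf']:03d}"
        counter["leaf"] += 1
        nodes[nid] = PhyloNode(nid, parent, [], float(rng.exponential(branch_mean)))
        nodes[parent].children.append(nid)
        leaves.append(nid)
        return nid

    new_leaf("root")
    new_leaf("root")
    while len(leaves) < n_leaves:
        # split a uniformly chosen extant lineage (Yule process)
        victim = leaves.pop(int(rng.integers(len(leaves))))
        internal_id = f"N{counter['internal']:03d}"
        counter["internal"] += 1
        old = nodes[victim]
        internal = PhyloNode(internal_id, old.parent, [], old.branch_length)
        nodes[internal_id] = internal
        parent_children = nodes[old.parent].children
        parent_children[parent_children.index(victim)] = internal_id
        old.parent = internal_id
        old.branch_length = float(rng.exponential(branch_mean))
        internal.children.append(victim)
        leaves.append(victim)
        new_leaf(internal_id)

    tree = Phylogeny(nodes, "root")
    # carve clades: repeatedly split the largest *internal* subtree root
    # until n_clades subtrees remain (leaf roots cannot be split further)
    clade_roots = [c for c in nodes["root"].children]
    while len(clade_roots) < n_clades:
        splittable = [r for r in clade_roots if nodes[r].children]
        if not splittable:
            break
        biggest = max(splittable, key=lambda r: (len(tree.subtree_leaf_ids(r)), r))
        clade_roots.remove(biggest)
        clade_roots.extend(nodes[biggest].children)
    # stable labeling: clade1 is the largest clade, ties by id
    clade_roots.sort(key=lambda r: (-len(tree.subtree_leaf_ids(r)), r))
    for k, r in enumerate(clade_roots, start=1):
        for nid in tree.subtree_ids(r):
            nodes[nid].clade_label = f"clade{k}"
    return tree


# ---------------------------------------------------------------------------
# Sequence evolution with planted indels
# ---------------------------------------------------------------------------


@dataclass
class PlantedEvent:
    """A planted insertion: appears on ``branch`` (child-node id) at root
    coordinate ``position`` and is inherited by all descendants.

    ``length`` fixes the size for a one-shot insertion; ``schedule`` lists
    ``(node_id, length)`` elongation steps along a root→tip path, modelling
    a terminal extension that grows through successive ancestors. Nodes
    reached after a schedule step inherit its length.
    """

    branch: str
    position: int
    length: Optional[int] = None
    schedule: Optional[list[tuple[str, int]]] = None

    @property
    def span(self) -> int:
        if self.schedule:
            return max(l for _, l in self.schedule)
        if self.length is None:
            raise ValueError("planted event needs length or schedule")
        return self.length

    def initial_length(self) -> int:
        return self.schedule[0][1] if self.schedule else self.length


def evolve_sequences(
    t: Phylogeny,
    root_sequence: str,
    sub_rate: float,
    planted_events: list[PlantedEvent],
    seed: int,
) -> tuple[MSA, dict]:
    """Evolve sequences down the tree; returns an MSA with internal rows
    plus a layout dict mapping each event to its alignment-column block.

    Per branch, substitutions are Poisson(branch_length × sub_rate × L)
    with positions uniform over the carried residues and replacement
    uniform over the 19 alternatives. Insertions appear on their stated
    branch and are inherited; scheduled elongation adds residues at the
    outward edge of the block.
    """
    L = len(root_sequence)
    for ev in planted_events:
        if ev.branch not in t.nodes:
            raise ValueError(f"planted event branch {ev.branch!r} not in tree")
        if not 0 <= ev.position <= L:
            raise ValueError(f"event position {ev.position} beyond root sequence length {L}")

    # global column layout: root columns interleaved with event blocks
    events_sorted = sorted(enumerate(planted_events), key=lambda kv: (kv[1].position, kv[0]))
    columns: list[tuple[str, int]] = []  # ("root", pos) or ("event<k>", offset)
    block_of_event: dict[int, tuple[int, int]] = {}
    for p in range(L + 1):
        for k, ev in events_sorted:
            if ev.position == p:
                start = len(columns)
                columns.extend((f"event{k}", off) for off in range(ev.span))
                block_of_event[k] = (start, start + ev.span)
        if p < L:
            columns.append(("root", p))
    n_cols = len(columns)
    root_col_index = {p: j for j, (kind, p) in enumerate(columns) if kind == "root"}

    # per-event current length along each lineage
    rows: dict[str, np.ndarray] = {}
    gap = "-"
    rng_master = seed

    def event_columns(k: int, length: int) -> list[int]:
        start, end = block_of_event[k]
        # occupy the trailing `length` columns so elongation grows outward
        return list(range(end - length, end))

    lengths_state: dict[str, dict[int, int]] = {}
    for node in t.preorder():
        rng = np.random.default_rng(_child_seed(seed, "evolve", node.id))
        if node.parent is None:
            row = np.full(n_cols, gap, dtype="<U1")
            for p, aa in enumerate(root_sequence):
                row[root_col_index[p]] = aa
            lengths_state[node.id] = {k: 0 for k, _ in enumerate(planted_events)}
        else:
            row = rows[node.parent].copy()
            lengths_state[node.id] = dict(lengths_state[node.parent])
            # event starts and scheduled elongations on this branch
            for k, ev in enumerate(planted_events):
                target = None
                if ev.schedule:
                    for nid, ln in ev.schedule:
                        if nid == node.id:
                            target = ln
                elif ev.branch == node.id:
                    target = ev.length
                if ev.schedule and ev.branch == node.id and target is None:
                    target = ev.initial_length()
                if target is not None and target > lengths_state[node.id][k]:
                    current_cols = set(event_columns(k, lengths_state[node.id][k]))
                    for j in event_columns(k, target):
                        if j not in current_cols:
                            row[j] = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
                    lengths_state[node.id][k] = target
            # substitutions
            occupied = np.nonzero(row != gap)[0]
            n_sub = rng.poisson(node.branch_length * sub_rate * len(occupied))
            for _ in range(n_sub):
                j = occupied[rng.integers(len(occupied))]
                old = row[j]
                choices = [a for a in AMINO_ACIDS if a != old]
                row[j] = choices[rng.integers(19)]
        rows[node.id] = row

    msa = MSA({nid: "".join(rows[nid]) for nid in (n.id for n in t.preorder())})
    layout = {
        "n_columns": n_cols,
        "blocks": {str(k): block_of_event[k] for k in block_of_event},
        "columns": columns,
    }
    return msa, layout


# ---------------------------------------------------------------------------
# Toy structures
# ---------------------------------------------------------------------------


def helix_coords(positions: np.ndarray) -> np.ndarray:
    """Idealized helix Cα coordinates for integer residue positions.

    The helix is translated so that position 0 sits at the origin; the
    shift is a rigid motion and leaves every downstream metric unchanged.
    """
    theta = np.deg2rad(HELIX_TWIST_DEG) * positions
    return np.column_stack(
        (HELIX_RADIUS * (np.cos(theta) - 1.0), HELIX_RADIUS * np.sin(theta), HELIX_RISE * positions)
    )


def build_toy_structure(
    sequence: str,
    seed: int = 0,
    structure_id: str = "toy",
    positions: Optional[np.ndarray] = None,
    chain_id: str = "A",
) -> Structure:
    """Cα-only backbone on an idealized helix; deterministic given seed.

    ``positions`` optionally places residues at arbitrary helix indices
    (e.g. alignment columns), so that homologous residues of related toy
    structures share base coordinates and insertions appear as bulges.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    if positions is None:
        positions = np.arange(len(sequence), dtype=float)
    positions = np.asarray(positions, dtype=float)
    if positions.shape != (len(sequence),):
        raise ValueError("positions must match sequence length")
    coords = helix_coords(positions)
    return structure_from_sequence_coords(structure_id, sequence, coords, chain_id=chain_id)


def perturb_structure(s: Structure, sigma: float, seed: int) -> Structure:
    """Add independent N(0, sigma²) noise to every coordinate axis."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    out = s.copy()
    rng = np.random.default_rng(seed)
    for atom in out.atoms():
        atom.coords = atom.coords + rng.normal(0.0, sigma, size=3)
    for atom in out.ligands:
        atom.coords = atom.coords + rng.normal(0.0, sigma, size=3)
    return out


#: Cα–Cα spacing along a rendered insertion bulge (Å)
BULGE_SPACING = 3.0


def _smooth_field(raw: np.ndarray, sigma: float, window: float = 8.0) -> np.ndarray:
    """Spatially smooth deformation field with per-column marginal std sigma.

    White noise filtered along the column axis models a collective,
    domain-scale deformation rather than per-residue jitter, so local
    backbone geometry (and hence contact-graph connectivity) survives.
    """
    from scipy.ndimage import gaussian_filter1d

    field = gaussian_filter1d(raw, sigma=window, axis=0, mode="nearest")
    scale = field.std()
    if scale > 0:
        field = field * (sigma / scale)
    return field


def _column_base_coords(
    columns: list[tuple[str, int]], events: list["PlantedEvent"], root_length: int
) -> np.ndarray:
    """Shared base coordinate for every alignment column.

    Root columns sit on the idealized helix. Insertion-block columns are
    rendered as loop bulges: a straight chain leaving the helix radially at
    the insertion anchor, with the column nearest the core closest to the
    anchor, so progressively elongated variants extend the same loop
    outward and homologous residues of different nodes share coordinates.
    """
    out = np.zeros((len(columns), 3))
    for j, (kind, idx) in enumerate(columns):
        if kind == "root":
            out[j] = helix_coords(np.array([float(idx)]))[0]
        else:
            k = int(kind.removeprefix("event"))
            ev = events[k]
            anchor_pos = min(max(ev.position, 0), root_length - 1)
            anchor = helix_coords(np.array([float(anchor_pos)]))[0]
            theta = math.radians(HELIX_TWIST_DEG) * anchor_pos
            u = np.array([math.cos(theta), math.sin(theta), 0.0])
            out[j] = anchor + u * BULGE_SPACING * (ev.span - idx)
    return out


def _column_anchor_positions(
    columns: list[tuple[str, int]], events: list["PlantedEvent"], root_length: int
) -> np.ndarray:
    """Root helix position governing each alignment column's deformation:
    root columns map to themselves, insertion columns to their anchor."""
    out = np.zeros(len(columns), dtype=int)
    for j, (kind, idx) in enumerate(columns):
        if kind == "root":
            out[j] = idx
        else:
            ev = events[int(kind.removeprefix("event"))]
            out[j] = min(max(ev.position, 0), root_length - 1)
    return out


def displace_structure(s: Structure, displacements: dict[int, np.ndarray]) -> Structure:
    """Shift atoms of residue i (0-based within the structure) by a fixed
    3-vector; used to give all members of a clade a shared deformation."""
    out = s.copy()
    i = 0
    for chain in out.chains:
        for res in chain.residues:
            d = displacements.get(i)
            if d is not None:
                for atom in res.atoms:
                    atom.coords = atom.coords + d
            i += 1
    return out


# ---------------------------------------------------------------------------
# Posterior matrices
# ---------------------------------------------------------------------------


def make_posterior_matrix(
    true_sequence: str, ambiguous_fraction: float, seed: int, node_id: str = "anc"
) -> PosteriorMatrix:
    """Posterior matrix concentrated on a known true sequence.

    Ambiguous sites (Bernoulli(``ambiguous_fraction``)) put a top
    probability uniform in [0.4, 0.7) on the true state and spread the
    remainder over 2–3 decoy states; unambiguous sites put ≥ 0.9 on the
    true state. Rows are exactly normalized.
    """
    if not 0.0 <= ambiguous_fraction <= 1.0:
        raise ValueError("ambiguous_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(true_sequence)
    probs = np.zeros((n, len(AMINO_ACIDS)))
    for i, aa in enumerate(true_sequence):
        true_idx = AMINO_ACIDS.index(aa)
        others = [j for j in range(len(AMINO_ACIDS)) if j != true_idx]
        if rng.random() < ambiguous_fraction:
            top = rng.uniform(0.4, 0.7 - 1e-9)
            k = int(rng.integers(2, 4))
            decoys = rng.choice(others, size=k, replace=False)
            weights = 1.0 + rng.uniform(-0.1, 0.1, size=k)
            weights /= weights.sum()
            probs[i, true_idx] = top
            probs[i, decoys] = (1.0 - top) * weights
        else:
            top = rng.uniform(0.9, 1.0)
            decoys = rng.choice(others, size=2, replace=False)
            probs[i, true_idx] = top
            probs[i, decoys] = (1.0 - top) / 2.0
        probs[i] /= probs[i].sum()
    return PosteriorMatrix(node_id=node_id, probs=probs)


def planted_depth_attribute(
    depths: np.ndarray, rho: float, seed: int
) -> np.ndarray:
    """An attribute with a planted rank correlation against node depth.

    Gaussian-copula construction: the normal scores of the depth ranks are
    mixed with independent noise at Pearson weight ``rho``, which yields a
    Spearman correlation of (6/π)·asin(rho/2) ≈ rho in the weak-trend
    regime. ``rho = ±1`` degenerates to an exactly monotone attribute.
    """
    import scipy.stats

    rng = np.random.default_rng(seed)
    depths = np.asarray(depths, dtype=float)
    n = len(depths)
    ranks = scipy.stats.rankdata(depths)
    z = scipy.stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    if abs(rho) >= 1.0:
        return np.sign(rho) * z
    noise = rng.standard_normal(n)
    return rho * z + math.sqrt(1 - rho**2) * noise


# ---------------------------------------------------------------------------
# End-to-end dataset
# ---------------------------------------------------------------------------


@dataclass
class SynthConfig:
    """Generator defaults define the study conditions emulated throughout.

    24 leaves in 4 labeled clades mirror the major-clade structure of the
    family; the three planted insertions mirror the observed events — a
    ~60-residue C-terminal extension, a ~55-residue internal insertion,
    and a terminal extension elongating 8→20→40 through successive
    ancestors. Inter-clade structural noise is 5× the intra-clade noise so
    between-clade divergence dominates.
    """

    n_leaves: int = 24
    n_clades: int = 4
    root_length: int = 300
    sub_rate: float = 0.5
    branch_mean: float = 0.05
    sigma_intra: float = 0.3
    sigma_inter: float = 1.5
    ambiguous_fraction: float = 0.15
    insertion_lengths: tuple[int, int] = (60, 55)
    progressive_schedule: tuple[int, ...] = (8, 20, 40)
    plddt: float = 90.0


@dataclass
class SyntheticDataset:
    tree: Phylogeny
    msa: MSA
    structures: dict[str, Structure]
    posteriors: dict[str, PosteriorMatrix]
    truth: dict


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=length))


def _clade_root(tree: Phylogeny, label: str) -> str:
    labeled = [n.id for n in tree.preorder() if n.clade_label == label]
    # preorder guarantees the first labeled node is the shallowest
    return labeled[0]


def plan_events(tree: Phylogeny, config: SynthConfig) -> list[PlantedEvent]:
    """Plant the three clade-defining insertions on clade-root branches.

    The clade whose root→deepest-leaf path carries the most internal nodes
    receives the progressively elongating N-terminal extension (schedule
    applied along that path); the two largest remaining clades receive the
    internal and C-terminal one-shot insertions; any further clade stays
    insertion-free as a negative control.
    """
    from .phylo_evo import root_distances

    labels = sorted({n.clade_label for n in tree.preorder() if n.clade_label})
    if len(labels) < 3:
        raise ValueError("need at least 3 clades to plant the standard events")
    depths = root_distances(tree)

    def deepest_path(label: str) -> list[str]:
        root_id = _clade_root(tree, label)
        tips = tree.subtree_leaf_ids(root_id)
        deep_tip = max(tips, key=lambda i: depths[i])
        path = list(reversed(tree.path_to_root(deep_tip)))
        return path[path.index(root_id) :]

    def internal_path_len(label: str) -> int:
        return sum(1 for nid in deepest_path(label) if not tree.nodes[nid].is_leaf)

    progressive_label = max(labels, key=lambda lb: (internal_path_len(lb), lb))
    remaining = [lb for lb in labels if lb != progressive_label]
    remaining.sort(key=lambda lb: (-len(tree.subtree_leaf_ids(_clade_root(tree, lb))), lb))

    events: list[PlantedEvent] = []
    path = deepest_path(progressive_label)
    internal_path = [nid for nid in path if not tree.nodes[nid].is_leaf] or path[:1]
    schedule_nodes = internal_path[: len(config.progressive_schedule)]
    schedule = [(nid, ln) for nid, ln in zip(schedule_nodes, config.progressive_schedule)]
    events.append(PlantedEvent(branch=_clade_root(tree, progressive_label), position=0, schedule=schedule))

    events.append(
        PlantedEvent(
            branch=_clade_root(tree, remaining[0]),
            position=config.root_length // 2,
            length=config.insertion_lengths[1],
        )
    )
    events.append(
        PlantedEvent(
            branch=_clade_root(tree, remaining[1]),
            position=config.root_length,
            length=config.insertion_lengths[0],
        )
    )
    return events


def generate_dataset(config: SynthConfig, seed: int) -> SyntheticDataset:
    """End-to-end synthetic dataset with full planted ground truth."""
    rng = np.random.default_rng(_child_seed(seed, "root"))
    tree = simulate_tree(config.n_leaves, config.n_clades, _child_seed(seed, "tree"), config.branch_mean)
    root_seq = _random_sequence(config.root_length, rng)
    events = plan_events(tree, config)
    msa, layout = evolve_sequences(tree, root_seq, config.sub_rate, events, _child_seed(seed, "seqs"))

    # shared per-clade deformation fields over alignment columns
    n_cols = layout["n_columns"]
    labels = sorted({n.clade_label for n in tree.preorder() if n.clade_label})
    anchor_of_column = _column_anchor_positions(layout["columns"], events, config.root_length)
    clade_fields = {}
    for label in labels:
        root_field = _smooth_field(
            np.random.default_rng(_child_seed(seed, "field", label)).standard_normal(
                (config.root_length, 3)
            ),
            config.sigma_inter,
        )
        # insertion bulges ride rigidly with their anchor's displacement
        clade_fields[label] = root_field[anchor_of_column]

    base_coords = _column_base_coords(layout["columns"], events, config.root_length)
    structures: dict[str, Structure] = {}
    for node in tree.preorder():
        row = msa.rows[node.id]
        cols = np.array([j for j, ch in enumerate(row) if ch != "-"])
        seq = row.replace("-", "")
        coords = base_coords[cols]
        if node.clade_label is not None:
            coords = coords + clade_fields[node.clade_label][cols]
        s = structure_from_sequence_coords(node.id, seq, coords, confidence=config.plddt)
        s = perturb_structure(s, config.sigma_intra, _child_seed(seed, "noise", node.id))
        structures[node.id] = s

    posteriors = {
        node.id: make_posterior_matrix(
            msa.ungapped(node.id),
            config.ambiguous_fraction,
            _child_seed(seed, "posterior", node.id),
            node_id=node.id,
        )
        for node in tree.preorder()
        if not node.is_leaf
    }

    truth = {
        "seed": seed,
        "config": asdict(config),
        "newick": tree.to_newick(),
        "clade_labels": {n.id: n.clade_label for n in tree.preorder()},
        "events": [
            {
                "branch": ev.branch,
                "position": ev.position,
                "length": ev.length,
                "schedule": ev.schedule,
                "block": list(layout["blocks"][str(k)]),
            }
            for k, ev in enumerate(events)
        ],
        "layout": {"n_columns": n_cols},
    }
    return SyntheticDataset(tree=tree, msa=msa, structures=structures, posteriors=posteriors, truth=truth)


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, str]:
    """Write the dataset as newick + FASTA + PDB dir + posterior TSVs +
    truth JSON; returns the path manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "structures").mkdir(exist_ok=True)
    (outdir / "posteriors").mkdir(exist_ok=True)
    paths = {"tree": str(outdir / "tree.nwk"), "msa": str(outdir / "msa.fasta"), "truth": str(outdir / "truth.json")}
    (outdir / "tree.nwk").write_text(ds.tree.to_newick() + "\n")
    write_fasta(ds.msa.rows, outdir / "msa.fasta")
    for nid, s in ds.structures.items():
        write_pdb(s, outdir / "structures" / f"{nid}.pdb")
    for nid, p in ds.posteriors.items():
        write_posterior_table(p, outdir / "posteriors" / f"{nid}.tsv")
    (outdir / "truth.json").write_text(json.dumps(ds.truth, indent=2, sort_keys=True) + "\n")
    return paths
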