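"""Small structure/tree builders shared across the test modules."""

from __future__ import annotations

import numpy as np

from nitroscape.core_io import (
    Atom,
    Chain,
    Phylogeny,
    PhyloNode,
    Residue,
    Structure,
    structure_from_sequence_coords,
)
from nitroscape.synthetic_data import build_toy_structure


def ca_structure(
    sequence: str,
    coords: np.ndarray,
    structure_id: str = "s",
    chain_id: str = "A",
    confidence: float = 90.0,
) -> Structure:
    return structure_from_sequence_coords(
        structure_id, sequence, coords, chain_id=chain_id, confidence=confidence
    )


def helix_structure(n: int, structure_id: str = "helix", sequence: str | None = None) -> Structure:
    seq = sequence or ("A" * n)
    return build_toy_structure(seq, structure_id=structure_id)


def make_residue(
    name: str,
    index: int,
    chain_id: str,
    atom_specs: list[tuple[str, str, tuple[float, float, float]]],
    confidence: float = 90.0,
    serial_start: int = 1,
) -> Residue:
    """Residue from (atom_name, element, xyz) triples."""
    res = Residue(index=index, name=name)
    for k, (aname, element, xyz) in enumerate(atom_specs):
        res.atoms.append(
            Atom(
                serial=serial_start + k,
                name=aname,
                element=element,
                residue_index=index,
                residue_name=name,
                chain_id=chain_id,
                coords=np.asarray(xyz, dtype=float),
                confidence=confidence,
            )
        )
    return res


def single_atom_structure(
    element: str = "C", xyz=(0.0, 0.0, 0.0), name: str = "CA", resname: str = "ALA"
) -> Structure:
    chain = Chain(id="A", residues=[make_residue(resname, 1, "A", [(name, element, xyz)])])
    return Structure(id="single", chains=[chain])


def two_chain_complex(separation: float = 4.0) -> Structure:
    """Minimal all-heavy-atom two-chain complex: LYS (chain D) facing ASP
    (chain K) with nearest heavy atoms exactly ``separation`` Å apart."""
    lys = make_residue(
        "LYS",
        1,
        "D",
        [
            ("CA", "C", (0.0, 0.0, 0.0)),
            ("CB", "C", (1.5, 0.0, 0.0)),
            ("NZ", "N", (3.0, 0.0, 0.0)),
        ],
    )
    asp = make_residue(
        "ASP",
        1,
        "K",
        [
            ("OD1", "O", (3.0 + separation, 0.0, 0.0)),
            ("CB", "C", (4.5 + separation, 0.0, 0.0)),
            ("CA", "C", (6.0 + separation, 0.0, 0.0)),
        ],
        serial_start=4,
    )
    return Structure(
        id="pair",
        chains=[Chain(id="D", residues=[lys]), Chain(id="K", residues=[asp])],
    )


def manual_tree(edges: dict[str, tuple[str | None, float]], root_id: str = "root") -> Phylogeny:
    """Phylogeny from {node_id: (parent_id, branch_length)}."""
    nodes = {
        nid: PhyloNode(id=nid, parent=parent, children=[], branch_length=bl)
        for nid, (parent, bl) in edges.items()
    }
    for nid, node in nodes.items():
        if node.parent is not None:
            nodes[node.parent].children.append(nid)
    return Phylogeny(nodes, root_id)


def count_state_changes(tree: Phylogeny, states: dict[str, int]) -> int:
    return sum(
        1
        for node in tree.preorder()
        if node.parent is not None and states[node.id] != states[node.parent]
    )
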