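"""Canonical in-memory data model and readers/writers for the pipeline formats.

The pipeline works on four kinds of objects:

* :class:`Structure` — an atomic protein model (predicted or experimental),
  with per-residue confidence (pLDDT for predicted models, carried in the
  B-factor column of PDB files; crystallographic B-factor otherwise).
* :class:`MSA` — a gapped multiple sequence alignment.
* :class:`Phylogeny` — a rooted tree with branch lengths in
  substitutions/site, node ids and optional clade labels.
* :class:`PosteriorMatrix` — site-wise amino-acid posterior probabilities
  for one ancestral node, as produced by marginal ancestral sequence
  reconstruction.

PDB is the canonical structure format here; mmCIF is out of scope.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning
from Bio.SeqUtils import seq1, seq3

logger = logging.getLogger(__name__)

#: One-letter amino-acid alphabet in fixed alphabetical order. Posterior
#: matrix columns are indexed by this order throughout the package.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


class ParseError(ValueError):
    """A file could not be parsed into a valid object."""


# ---------------------------------------------------------------------------
# Structure model
# ---------------------------------------------------------------------------


@dataclass
class Atom:
    """A single atom with coordinates in Å.

    ``confidence`` holds pLDDT (0–100) for predicted models and the
    crystallographic B-factor otherwise; both travel in the B-factor
    column of PDB files.
    """

    serial: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    coords: np.ndarray
    confidence: float = 0.0
    icode: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coordinates must be a finite 3-vector")


@dataclass
class Residue:
    """One residue: author numbering plus insertion code, 3-letter name, atoms."""

    index: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""

    @property
    def key(self) -> tuple[int, str]:
        return (self.index, self.icode)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Optional[Atom]:
        return self.atom("CA")

    @property
    def one_letter(self) -> str:
        return seq1(self.name.capitalize()) or "X"

    @property
    def confidence(self) -> float:
        return float(np.mean([a.confidence for a in self.atoms]))


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def sequence(self) -> str:
        return "".join(seq1(r.name.capitalize()) or "X" for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca.coords for r in self.residues if r.ca is not None])

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Structure:
    """An ordered multi-chain protein model.

    ``model_kind`` is ``"predicted"`` (confidence = pLDDT in [0, 100]) or
    ``"experimental"`` (confidence = B-factor). HETATM records are kept in
    ``ligands`` and excluded from all residue-level analyses.
    """

    id: str
    model_kind: str = "predicted"
    chains: list[Chain] = field(default_factory=list)
    ligands: list[Atom] = field(default_factory=list)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.id}")

    @property
    def chain_ids(self) -> list[str]:
        return [c.id for c in self.chains]

    def atoms(self) -> Iterator[Atom]:
        for c in self.chains:
            for r in c.residues:
                yield from r.atoms

    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    def sequences(self) -> dict[str, str]:
        return {c.id: c.sequence() for c in self.chains}

    def validate(self) -> None:
        if self.model_kind not in ("predicted", "experimental"):
            raise ValueError(f"model_kind must be predicted|experimental, got {self.model_kind!r}")
        seen: set[tuple[str, int, str, str]] = set()
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    key = (c.id, r.index, r.icode, a.name)
                    if key in seen:
                        raise ValueError(f"duplicate atom {key} in structure {self.id}")
                    seen.add(key)
                if self.model_kind == "predicted":
                    for a in r.atoms:
                        if not 0.0 <= a.confidence <= 100.0:
                            raise ValueError(
                                f"predicted model {self.id}: confidence {a.confidence} outside [0, 100]"
                            )

    def copy(self) -> "Structure":
        import copy as _copy

        return _copy.deepcopy(self)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------


def read_pdb(path: str | Path, structure_id: Optional[str] = None, model_kind: str = "predicted") -> Structure:
    """Read a PDB file into a :class:`Structure`.

    ATOM records populate the chains; HETATM records (excluding waters) go
    to ``ligands``. Alternate locations keep the highest-occupancy conformer
    only. Insertion codes and author residue numbering are preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ParseError(f"{path}: empty file")
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            bio_struct = parser.get_structure(structure_id or path.stem, str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc

    models = list(bio_struct)
    if not models:
        raise ParseError(f"{path}: no coordinate records")
    model = models[0]

    struct = Structure(id=structure_id or path.stem, model_kind=model_kind)
    for bio_chain in model:
        chain = Chain(id=bio_chain.id)
        for bio_res in bio_chain:
            hetflag, resseq, icode = bio_res.id
            icode = icode.strip()
            if hetflag.strip():  # HETATM
                if bio_res.get_resname() in ("HOH", "WAT"):
                    continue
                for bio_atom in bio_res.get_atoms():
                    struct.ligands.append(
                        Atom(
                            serial=bio_atom.serial_number,
                            name=bio_atom.get_name(),
                            element=(bio_atom.element or "").strip() or bio_atom.get_name()[0],
                            residue_index=resseq,
                            residue_name=bio_res.get_resname(),
                            chain_id=bio_chain.id,
                            coords=bio_atom.coord,
                            confidence=float(bio_atom.bfactor or 0.0),
                            icode=icode,
                        )
                    )
                continue
            res = Residue(index=resseq, name=bio_res.get_resname(), icode=icode)
            # iterating a disordered residue yields the selected (highest
            # occupancy) conformer only
            for bio_atom in bio_res.get_atoms():
                res.atoms.append(
                    Atom(
                        serial=bio_atom.serial_number,
                        name=bio_atom.get_name(),
                        element=(bio_atom.element or "").strip() or bio_atom.get_name()[0],
                        residue_index=resseq,
                        residue_name=bio_res.get_resname(),
                        chain_id=bio_chain.id,
                        coords=bio_atom.coord,
                        confidence=float(bio_atom.bfactor or 0.0),
                        icode=icode,
                    )
                )
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            struct.chains.append(chain)
    if not struct.chains and not struct.ligands:
        raise ParseError(f"{path}: no ATOM/HETATM records")
    return struct


def _format_atom_line(record: str, serial: int, atom: Atom, chain_id: str) -> str:
    name = atom.name
    if len(name) < 4:
        name = f" {name:<3s}"
    return (
        f"{record:<6s}{serial:>5d} {name:<4s}{'':1s}{atom.residue_name:>3s} "
        f"{chain_id:1s}{atom.residue_index:>4d}{atom.icode or '':1s}   "
        f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
        f"{1.00:6.2f}{atom.confidence:6.2f}          {atom.element:>2s}"
    )


def write_pdb(s: Structure, path: str | Path) -> None:
    """Write a :class:`Structure` in fixed-column PDB format.

    Confidence is written to the B-factor column with two decimals, so a
    round-trip through :func:`read_pdb` preserves pLDDT to 0.01.
    """
    if s.n_atoms() == 0:
        raise ValueError(f"structure {s.id}: refusing to write 0-atom structure")
    for c in s.chains:
        if len(c.id) != 1:
            raise ValueError(f"chain id {c.id!r} is not a single character")
    lines: list[str] = []
    serial = 0
    for chain in s.chains:
        for res in chain.residues:
            for atom in res.atoms:
                serial += 1
                lines.append(_format_atom_line("ATOM", serial, atom, chain.id))
        serial += 1
        lines.append(f"{'TER':<6s}{serial:>5d}")
    for atom in s.ligands:
        serial += 1
        lines.append(_format_atom_line("HETATM", serial, atom, atom.chain_id))
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Sequence / alignment formats
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA (or A3M) into an ordered ``id -> sequence`` mapping.

    A3M-style lowercase insertion characters are uppercased on read; ``.``
    gap characters are normalized to ``-``. Duplicate ids are an error.
    """
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in out:
            raise ParseError(f"{path}: duplicate FASTA id {record.id!r}")
        out[record.id] = str(record.seq).replace(".", "-").upper()
    if not out:
        raise ParseError(f"{path}: no FASTA records")
    return out


def write_fasta(rows: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in rows.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass
class MSA:
    """A gapped multiple sequence alignment: ``rows`` maps id to sequence."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"MSA rows have unequal lengths: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    def column(self, j: int) -> dict[str, str]:
        return {name: seq[j] for name, seq in self.rows.items()}

    def subset(self, ids: Iterable[str]) -> "MSA":
        return MSA({i: self.rows[i] for i in ids})

    def ungapped(self, row_id: str) -> str:
        return self.rows[row_id].replace("-", "")


def read_msa(path: str | Path) -> MSA:
    return MSA(read_fasta(path))


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------


@dataclass
class PhyloNode:
    id: str
    parent: Optional[str]
    children: list[str]
    branch_length: float
    clade_label: Optional[str] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Phylogeny:
    """A rooted tree with named nodes and non-negative branch lengths."""

    def __init__(self, nodes: dict[str, PhyloNode], root_id: str):
        self.nodes = nodes
        self.root_id = root_id
        self._validate()

    def _validate(self) -> None:
        if self.root_id not in self.nodes:
            raise ValueError(f"root id {self.root_id!r} not among nodes")
        roots = [n for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1 or roots[0].id != self.root_id:
            raise ValueError("tree must have exactly one root")
        for n in self.nodes.values():
            if n.branch_length < 0:
                raise ValueError(f"node {n.id}: negative branch length {n.branch_length}")

    # -- traversal helpers -------------------------------------------------

    def preorder(self) -> Iterator[PhyloNode]:
        stack = [self.root_id]
        while stack:
            node = self.nodes[stack.pop()]
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[PhyloNode]:
        out = list(self.preorder())
        yield from reversed(out)

    def leaves(self) -> list[PhyloNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_ids(self) -> list[str]:
        return [n.id for n in self.leaves()]

    def path_to_root(self, node_id: str) -> list[str]:
        """Node ids from ``node_id`` up to (and including) the root."""
        path = [node_id]
        while self.nodes[path[-1]].parent is not None:
            path.append(self.nodes[path[-1]].parent)
        return path

    def mrca(self, leaf_ids: Iterable[str]) -> str:
        paths = [set(self.path_to_root(i)) for i in leaf_ids]
        common = set.intersection(*paths)
        # the deepest shared ancestor has the longest path back to the root
        return max(common, key=lambda i: len(self.path_to_root(i)))

    def subtree_ids(self, node_id: str) -> list[str]:
        out = []
        stack = [node_id]
        while stack:
            nid = stack.pop()
            out.append(nid)
            stack.extend(reversed(self.nodes[nid].children))
        return out

    def subtree_leaf_ids(self, node_id: str) -> list[str]:
        return [i for i in self.subtree_ids(node_id) if self.nodes[i].is_leaf]

    def clade_labels(self) -> dict[str, str]:
        return {n.id: n.clade_label for n in self.preorder() if n.clade_label is not None}

    # -- serialization -----------------------------------------------------

    def to_newick(self) -> str:
        def render(node_id: str) -> str:
            node = self.nodes[node_id]
            label = node.id
            if node.children:
                inner = ",".join(render(c) for c in node.children)
                body = f"({inner}){label}"
            else:
                body = label
            if node.parent is not None:
                body += f":{node.branch_length:g}"
            return body

        return render(self.root_id) + ";"


def _phylogeny_from_dendropy(tree: dendropy.Tree) -> Phylogeny:
    nodes: dict[str, PhyloNode] = {}
    auto_counter = 0
    ids: dict[int, str] = {}
    for dnode in tree.preorder_node_iter():
        if dnode.taxon is not None and dnode.taxon.label:
            nid = dnode.taxon.label
        elif dnode.label:
            nid = dnode.label
        else:
            nid = f"node{auto_counter}"
            auto_counter += 1
        if nid in nodes:
            raise ParseError(f"duplicate node id {nid!r} in tree")
        ids[id(dnode)] = nid
        parent = ids[id(dnode.parent_node)] if dnode.parent_node is not None else None
        bl = dnode.edge.length if dnode.edge.length is not None else 0.0
        if bl < 0:
            raise ParseError(f"node {nid!r}: negative branch length {bl}")
        nodes[nid] = PhyloNode(id=nid, parent=parent, children=[], branch_length=float(bl))
        if parent is not None:
            nodes[parent].children.append(nid)
    root_id = ids[id(tree.seed_node)]
    return Phylogeny(nodes, root_id)


def read_newick(source: str | Path) -> Phylogeny:
    """Read a rooted newick tree; internal labels become node ids.

    Unlabeled internal nodes receive deterministic ``node<i>`` ids in
    preorder. Accepts a path or a literal newick string.
    """
    text = None
    if isinstance(source, Path) or (isinstance(source, str) and not source.lstrip().startswith("(")):
        text = Path(source).read_text()
    else:
        text = str(source)
    tree = dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
        rooting="force-rooted",
    )
    return _phylogeny_from_dendropy(tree)


# ---------------------------------------------------------------------------
# Posterior tables
# ---------------------------------------------------------------------------


@dataclass
class PosteriorMatrix:
    """Sites × 20 ancestral posterior probabilities for one node.

    Rows are indexed by ungapped ancestral site (0-based), columns by
    :data:`AMINO_ACIDS` alphabetical order. Each row sums to 1.
    """

    node_id: str
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != len(AMINO_ACIDS):
            raise ValueError(f"posterior matrix must be sites × 20, got {self.probs.shape}")
        if np.any(self.probs < -1e-12) or np.any(self.probs > 1 + 1e-12):
            raise ValueError("posterior entries must lie in [0, 1]")
        sums = self.probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(f"posterior row {bad} sums to {sums[bad]:.6f}, not 1")

    @property
    def n_sites(self) -> int:
        return self.probs.shape[0]


def read_posterior_table(path: str | Path, node_id: Optional[str] = None) -> PosteriorMatrix:
    """Read a site-wise posterior probability table.

    Two tab/whitespace-separated dialects are accepted:

    * labeled: ``site  A:0.62  G:0.31  S:0.07`` (unlisted states are 0);
    * plain: 20 numeric columns in alphabetical amino-acid order, with an
      optional leading site-index column.

    Rows must sum to 1 within 1e-3; they are renormalized exactly on read.
    """
    path = Path(path)
    rows: list[np.ndarray] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        vec = np.zeros(len(AMINO_ACIDS))
        if any(":" in t for t in tokens[1:]) or (tokens and ":" in tokens[0]):
            data_tokens = tokens[1:] if ":" not in tokens[0] else tokens
            for t in data_tokens:
                if ":" not in t:
                    raise ParseError(f"{path}:{lineno}: expected AA:prob token, got {t!r}")
                aa, _, p = t.partition(":")
                if aa not in AA_INDEX:
                    raise ParseError(f"{path}:{lineno}: unknown amino acid {aa!r}")
                vec[AA_INDEX[aa]] = float(p)
        else:
            values = [float(t) for t in tokens]
            if len(values) == len(AMINO_ACIDS) + 1:
                values = values[1:]
            if len(values) != len(AMINO_ACIDS):
                raise ParseError(f"{path}:{lineno}: expected 20 probabilities, got {len(values)}")
            vec[:] = values
        total = vec.sum()
        if abs(total - 1.0) > 1e-3:
            raise ParseError(f"{path}:{lineno}: site {len(rows)} probabilities sum to {total:.4f}, not 1")
        rows.append(vec / total)
    if not rows:
        raise ParseError(f"{path}: no posterior rows")
    return PosteriorMatrix(node_id=node_id or path.stem, probs=np.array(rows))


def write_posterior_table(p: PosteriorMatrix, path: str | Path) -> None:
    """Write the plain 20-column dialect with a leading site-index column."""
    with open(path, "w") as fh:
        fh.write("# site\t" + "\t".join(AMINO_ACIDS) + "\n")
        for i, row in enumerate(p.probs):
            fh.write(str(i) + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# Structure preprocessing
# ---------------------------------------------------------------------------


def _chain_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of identical positions in a global alignment of two chains."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(seq_a, seq_b)[0]
    matches = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        matches += sum(1 for i, j in zip(range(a0, a1), range(b0, b1)) if seq_a[i] == seq_b[j])
    return matches / max(len(seq_a), len(seq_b))


def rename_chains_to_template(query: Structure, template: Structure) -> Structure:
    """Relabel query chains with the template chain ids of their best
    sequence-identity partners.

    The assignment is greedy on descending identity, with ties broken by
    input chain order, and must come out bijective. A query whose chain
    labels already match the template is returned unchanged in labeling.
    """
    if len(query.chains) != len(template.chains):
        raise ValueError(
            f"chain count mismatch: query {len(query.chains)} vs template {len(template.chains)}"
        )
    q_seqs = [c.sequence() for c in query.chains]
    t_seqs = [c.sequence() for c in template.chains]
    scored = []
    for qi, qs in enumerate(q_seqs):
        for ti, ts in enumerate(t_seqs):
            scored.append((-_chain_identity(qs, ts), qi, ti))
    scored.sort()
    q_assigned: dict[int, int] = {}
    t_taken: set[int] = set()
    for _neg, qi, ti in scored:
        if qi in q_assigned or ti in t_taken:
            continue
        q_assigned[qi] = ti
        t_taken.add(ti)
    if len(q_assigned) != len(query.chains):
        raise ValueError("chain mapping did not come out bijective")
    out = query.copy()
    for qi, chain in enumerate(out.chains):
        new_id = template.chains[q_assigned[qi]].id
        chain.id = new_id
        for r in chain.residues:
            for a in r.atoms:
                a.chain_id = new_id
    # keep template chain order
    order = {template.chains[q_assigned[qi]].id: q_assigned[qi] for qi in q_assigned}
    out.chains.sort(key=lambda c: order[c.id])
    return out


def trim_low_confidence(s: Structure, threshold: float = 70.0) -> Structure:
    """Remove low-confidence terminal residue runs from a predicted model.

    Residues are stripped inward from each chain terminus while their
    confidence (mean over atoms) is below ``threshold``; interior residues
    are never touched and retained coordinates and numbering are unchanged.
    A chain falling entirely below the threshold is dropped with a warning.
    """
    if not 0.0 <= threshold <= 100.0:
        raise ValueError(f"threshold {threshold} outside [0, 100]")
    if s.model_kind != "predicted":
        raise ValueError("confidence trimming applies to predicted models only")
    out = s.copy()
    kept_chains = []
    for chain in out.chains:
        lo, hi = 0, len(chain.residues)
        while lo < hi and chain.residues[lo].confidence < threshold:
            lo += 1
        while hi > lo and chain.residues[hi - 1].confidence < threshold:
            hi -= 1
        if lo == hi:
            logger.warning(
                "structure %s chain %s: all residues below confidence %.1f, chain removed",
                s.id,
                chain.id,
                threshold,
            )
            continue
        chain.residues = chain.residues[lo:hi]
        kept_chains.append(chain)
    out.chains = kept_chains
    return out


def structure_from_sequence_coords(
    structure_id: str,
    sequence: str,
    coords: np.ndarray,
    chain_id: str = "A",
    confidence: float = 90.0,
    residue_indices: Optional[list[int]] = None,
) -> Structure:
    """Build a Cα-only :class:`Structure` from a sequence and an n×3 array."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (len(sequence), 3):
        raise ValueError("coords must be len(sequence) × 3")
    chain = Chain(id=chain_id)
    for i, (aa, xyz) in enumerate(zip(sequence, coords)):
        idx = residue_indices[i] if residue_indices is not None else i + 1
        resname = seq3(aa).upper()
        chain.residues.append(
            Residue(
                index=idx,
                name=resname,
                atoms=[
                    Atom(
                        serial=i + 1,
                        name="CA",
                        element="C",
                        residue_index=idx,
                        residue_name=resname,
                        chain_id=chain_id,
                        coords=xyz,
                        confidence=confidence,
                    )
                ],
            )
        )
    return Structure(id=structure_id, model_kind="predicted", chains=[chain])
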