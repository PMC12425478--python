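"""Structural attributes mapped across the phylogeny.

Reimplemented equivalents of the attribute computations used downstream of
structure prediction: solvent-accessible surface area (Shrake–Rupley
quadrature), geometric descriptors, charged-residue composition,
intersubunit contact counts classified by residue chemistry, a
contact-based linear binding-affinity model, residue contact-network
summaries, and Gaussian-network-model normal modes.

Residue chemistry classes follow the contact-based affinity model's
convention: charged {D, E, K, R, H}, apolar {A, C, F, G, I, L, M, P, V, W},
polar the remainder {N, Q, S, T, Y}. The *charged fraction* attribute uses
the stricter {D, E, K, R} set (histidine excluded) by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core_io import Structure

logger = logging.getLogger(__name__)

#: van der Waals radii (Å) by element, used for SASA
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
    "SE": 1.90,
    "FE": 1.47,
    "MO": 1.45,
    "V": 1.53,
}

#: theoretical maximum SASA per residue (Å²), Tien et al.-style values,
#: used to convert absolute to relative accessibility
MAX_SASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

CHARGED_SET = set("DEKR")
CLASS_CHARGED = set("DEKRH")
CLASS_APOLAR = set("ACFGILMPVW")
CLASS_POLAR = set("NQSTY")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}

#: published contact-class linear affinity model (ΔG in kcal/mol):
#: weights on interface contact counts by class pair and on the apolar /
#: charged percentages of the non-interacting surface, plus an intercept
PRODIGY_COEFFICIENTS = {
    "ic_cc": -0.09459,
    "ic_ca": -0.10007,
    "ic_pp": 0.19577,
    "ic_pa": -0.22671,
    "nis_apolar": 0.18681,
    "nis_charged": 0.13810,
    "intercept": -15.9433,
}


def residue_class(one_letter: str) -> str:
    aa = one_letter.upper()
    if aa in CLASS_CHARGED:
        return "charged"
    if aa in CLASS_APOLAR:
        return "apolar"
    if aa in CLASS_POLAR:
        return "polar"
    return "polar"  # unknowns treated as polar, never dropped silently


@dataclass
class InterfaceContactCounts:
    """Interface residue–residue contact counts by unordered class pair."""

    cc: int = 0
    cp: int = 0
    ca: int = 0
    pp: int = 0
    pa: int = 0
    aa: int = 0
    cutoff: float = 5.5

    @property
    def total(self) -> int:
        return self.cc + self.cp + self.ca + self.pp + self.pa + self.aa


@dataclass
class NISComposition:
    """Class percentages of the non-interacting surface residues."""

    percent_apolar: float
    percent_charged: float
    percent_polar: float
    rel_sasa_cutoff: float = 0.05

    def __post_init__(self) -> None:
        total = self.percent_apolar + self.percent_charged + self.percent_polar
        if abs(total - 100.0) > 0.1:
            raise ValueError(f"NIS percentages sum to {total:.3f}, not 100")


@dataclass
class AttributeRecord:
    structure_id: str
    total_sasa: Optional[float] = None
    radius_of_gyration: Optional[float] = None
    charged_fraction: Optional[float] = None
    n_intersubunit_contacts: Optional[int] = None
    affinity_score: Optional[float] = None
    mean_slow_mode_fluctuation: Optional[float] = None


# ---------------------------------------------------------------------------
# SASA (Shrake–Rupley quadrature)
# ---------------------------------------------------------------------------


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def sasa(
    s: Structure, probe: float = 1.4, n_points: int = 960, radii: Optional[dict] = None
) -> tuple[np.ndarray, float]:
    """Per-atom and total solvent-accessible surface area in Å².

    Each atom is expanded by the probe radius and sampled with a fixed
    golden-spiral point set; a point is exposed when outside every
    neighboring expanded sphere. Deterministic by construction.
    """
    radii = {**VDW_RADII, **(radii or {})}
    atoms = list(s.atoms()) + list(s.ligands)
    if not atoms:
        raise ValueError("structure has no atoms")
    coords = np.array([a.coords for a in atoms])
    r_exp = np.empty(len(atoms))
    for i, a in enumerate(atoms):
        key = a.element.upper()
        if key not in radii:
            raise ValueError(f"no van der Waals radius for element {a.element!r}")
        r_exp[i] = radii[key] + probe
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_reach = 2 * r_exp.max()
    areas = np.zeros(len(atoms))
    for i in range(len(atoms)):
        pts = coords[i] + r_exp[i] * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], r_exp[i] + max_reach) if j != i]
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 > r_exp[j] ** 2
            if not exposed.any():
                break
        areas[i] = 4.0 * np.pi * r_exp[i] ** 2 * exposed.sum() / n_points
    return areas, float(areas.sum())


def residue_sasa(s: Structure, probe: float = 1.4, n_points: int = 960) -> dict[tuple[str, int, str], float]:
    """Per-residue SASA of the protein chains (ligand atoms still occlude)."""
    areas, _ = sasa(s, probe=probe, n_points=n_points)
    out: dict[tuple[str, int, str], float] = {}
    i = 0
    for chain in s.chains:
        for res in chain.residues:
            key = (chain.id, res.index, res.icode)
            out[key] = out.get(key, 0.0)
            for _atom in res.atoms:
                out[key] += areas[i]
                i += 1
    return out


# ---------------------------------------------------------------------------
# Geometry and composition
# ---------------------------------------------------------------------------


def radius_of_gyration(s: Structure, atoms: str = "ca") -> float:
    """Unweighted radius of gyration over Cα (default) or all atoms."""
    if atoms == "ca":
        coords = np.array([r.ca.coords for c in s.chains for r in c.residues if r.ca is not None])
    elif atoms == "all":
        coords = np.array([a.coords for a in s.atoms()])
    else:
        raise ValueError(f"atoms must be 'ca' or 'all', got {atoms!r}")
    if len(coords) == 0:
        raise ValueError("no atoms selected")
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))


def charged_fraction(sequences: list[str], charged: set[str] = frozenset(CHARGED_SET)) -> float:
    """Pooled fraction of charged residues over all subunit sequences.

    Non-standard letters are excluded from numerator and denominator with
    a warning.
    """
    charged = set(charged)
    n_charged = 0
    n_total = 0
    for seq in sequences:
        for aa in seq.upper():
            if aa not in THREE_TO_ONE.values():
                warnings.warn(f"non-standard residue letter {aa!r} excluded from charged fraction")
                continue
            n_total += 1
            if aa in charged:
                n_charged += 1
    if n_total == 0:
        raise ValueError("no standard residues in input")
    return n_charged / n_total


# ---------------------------------------------------------------------------
# Interfaces and affinity
# ---------------------------------------------------------------------------


def _heavy_atoms_by_residue(s: Structure, chain_ids: list[str]):
    out = []
    for cid in chain_ids:
        chain = s.chain(cid)
        for res in chain.residues:
            heavy = [a for a in res.atoms if a.element.upper() != "H"]
            if heavy:
                out.append(((cid, res.index, res.icode), THREE_TO_ONE.get(res.name.upper(), "X"), heavy))
    return out


def interface_contacts(
    s: Structure, group_a: list[str], group_b: list[str], cutoff: float = 5.5
) -> InterfaceContactCounts:
    """Count inter-group residue contacts, classified by residue chemistry.

    A residue pair across the two chain groups counts once when any pair of
    heavy atoms lies within ``cutoff`` Å. Symmetric in the two groups.
    """
    if not group_a or not group_b:
        raise ValueError("both chain groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("chain groups must be disjoint")
    res_a = _heavy_atoms_by_residue(s, group_a)
    res_b = _heavy_atoms_by_residue(s, group_b)
    coords_a = np.array([a.coords for _, _, atoms in res_a for a in atoms])
    coords_b = np.array([a.coords for _, _, atoms in res_b for a in atoms])
    idx_a = np.concatenate([[i] * len(atoms) for i, (_, _, atoms) in enumerate(res_a)])
    idx_b = np.concatenate([[i] * len(atoms) for i, (_, _, atoms) in enumerate(res_b)])
    tree_b = cKDTree(coords_b)
    pairs = tree_b.query_ball_point(coords_a, cutoff)
    contact_residue_pairs = {
        (int(idx_a[ai]), int(idx_b[bj])) for ai, hits in enumerate(pairs) for bj in hits
    }
    icc = InterfaceContactCounts(cutoff=cutoff)
    key_map = {
        frozenset(["charged"]): "cc",
        frozenset(["charged", "polar"]): "cp",
        frozenset(["charged", "apolar"]): "ca",
        frozenset(["polar"]): "pp",
        frozenset(["polar", "apolar"]): "pa",
        frozenset(["apolar"]): "aa",
    }
    for ia, ib in contact_residue_pairs:
        ca_class = residue_class(res_a[ia][1])
        cb_class = residue_class(res_b[ib][1])
        attr = key_map[frozenset([ca_class, cb_class])]
        setattr(icc, attr, getattr(icc, attr) + 1)
    return icc


def interface_residues(
    s: Structure, group_a: list[str], group_b: list[str], cutoff: float = 5.5
) -> set[tuple[str, int, str]]:
    """Residue keys participating in at least one inter-group contact."""
    res_a = _heavy_atoms_by_residue(s, group_a)
    res_b = _heavy_atoms_by_residue(s, group_b)
    coords_a = np.array([a.coords for _, _, atoms in res_a for a in atoms])
    coords_b = np.array([a.coords for _, _, atoms in res_b for a in atoms])
    idx_a = np.concatenate([[i] * len(atoms) for i, (_, _, atoms) in enumerate(res_a)])
    idx_b = np.concatenate([[i] * len(atoms) for i, (_, _, atoms) in enumerate(res_b)])
    tree_b = cKDTree(coords_b)
    hits = tree_b.query_ball_point(coords_a, cutoff)
    out: set[tuple[str, int, str]] = set()
    for ai, matched in enumerate(hits):
        if matched:
            out.add(res_a[int(idx_a[ai])][0])
            for bj in matched:
                out.add(res_b[int(idx_b[bj])][0])
    return out


def nis_composition(
    s: Structure,
    group_a: list[str],
    group_b: list[str],
    rel_sasa_cutoff: float = 0.05,
    contact_cutoff: float = 5.5,
    n_points: int = 960,
) -> NISComposition:
    """Chemistry composition of the non-interacting surface (NIS).

    NIS residues are solvent exposed on the assembled complex (relative
    SASA ≥ ``rel_sasa_cutoff``) and take part in no inter-group contact.
    """
    rsasa = residue_sasa(s, n_points=n_points)
    iface = interface_residues(s, group_a, group_b, cutoff=contact_cutoff)
    counts = {"charged": 0, "polar": 0, "apolar": 0}
    for chain in s.chains:
        for res in chain.residues:
            key = (chain.id, res.index, res.icode)
            max_ref = MAX_SASA.get(res.name.upper())
            if max_ref is None:
                continue
            if key in iface:
                continue
            if rsasa.get(key, 0.0) / max_ref < rel_sasa_cutoff:
                continue
            counts[residue_class(THREE_TO_ONE.get(res.name.upper(), "X"))] += 1
    n_nis = sum(counts.values())
    if n_nis == 0:
        raise ValueError("no non-interacting surface residues found")
    return NISComposition(
        percent_apolar=100.0 * counts["apolar"] / n_nis,
        percent_charged=100.0 * counts["charged"] / n_nis,
        percent_polar=100.0 * counts["polar"] / n_nis,
        rel_sasa_cutoff=rel_sasa_cutoff,
    )


def affinity_score(
    icc: InterfaceContactCounts,
    nis: NISComposition,
    coefficients: Optional[dict[str, float]] = None,
) -> float:
    """Linear contact-class binding-affinity score (ΔG-like, kcal/mol).

    Exactly linear in its features; lower means stronger predicted binding.
    """
    coefs = PRODIGY_COEFFICIENTS if coefficients is None else coefficients
    required = {"ic_cc", "ic_ca", "ic_pp", "ic_pa", "nis_apolar", "nis_charged", "intercept"}
    missing = required - set(coefs)
    if missing:
        raise ValueError(f"missing affinity coefficients: {sorted(missing)}")
    return (
        coefs["ic_cc"] * icc.cc
        + coefs["ic_ca"] * icc.ca
        + coefs["ic_pp"] * icc.pp
        + coefs["ic_pa"] * icc.pa
        + coefs["nis_apolar"] * nis.percent_apolar
        + coefs["nis_charged"] * nis.percent_charged
        + coefs["intercept"]
    )


# ---------------------------------------------------------------------------
# Residue networks and elastic-network modes
# ---------------------------------------------------------------------------


def _ca_records(s: Structure):
    out = []
    for ci, chain in enumerate(s.chains):
        for ri, res in enumerate(chain.residues):
            if res.ca is not None:
                out.append((ci, ri, res.ca.coords))
    return out


def contact_network_counts(s: Structure, cutoff: float = 6.5) -> dict[str, float]:
    """Residue contact-graph summary: nodes, edges, mean degree.

    Edges join residues whose Cα atoms lie within ``cutoff`` Å, excluding
    trivially bonded neighbors (sequence separation < 2 within a chain);
    inter-chain contacts always qualify.
    """
    records = _ca_records(s)
    if len(records) < 2:
        raise ValueError("need at least 2 residues")
    coords = np.array([xyz for _, _, xyz in records])
    tree = cKDTree(coords)
    edges = 0
    for i, j in tree.query_pairs(cutoff):
        ci, ri, _ = records[i]
        cj, rj, _ = records[j]
        if ci == cj and abs(ri - rj) < 2:
            continue
        edges += 1
    n = len(records)
    return {"nodes": n, "edges": edges, "mean_degree": 2.0 * edges / n}


def kirchhoff_matrix(s: Structure, cutoff: float = 7.5) -> np.ndarray:
    """Gaussian-network-model Kirchhoff (graph Laplacian) from Cα contacts."""
    records = _ca_records(s)
    n = len(records)
    coords = np.array([xyz for _, _, xyz in records])
    K = np.zeros((n, n))
    tree = cKDTree(coords)
    for i, j in tree.query_pairs(cutoff):
        K[i, j] = K[j, i] = -1.0
    np.fill_diagonal(K, -K.sum(axis=1))
    return K


def gnm_modes(s: Structure, cutoff: float = 7.5) -> tuple[np.ndarray, np.ndarray]:
    """GNM eigenvalues and per-residue slowest-mode squared fluctuations.

    The Kirchhoff matrix of a connected contact graph has exactly one ~0
    eigenvalue; fluctuations come from the slowest non-trivial mode,
    u₁ᵢ² / λ₁ (the dominant term of the pseudo-inverse diagonal).
    """
    K = kirchhoff_matrix(s, cutoff)
    n = K.shape[0]
    if n < 2:
        raise ValueError("GNM needs at least 2 residues")
    # connectivity check by BFS on the contact graph
    adj = K < 0
    seen = np.zeros(n, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        i = stack.pop()
        for j in np.nonzero(adj[i])[0]:
            if not seen[j]:
                seen[j] = True
                stack.append(int(j))
    if not seen.all():
        n_components = 1
        remaining = ~seen
        while remaining.any():
            n_components += 1
            start = int(np.nonzero(remaining)[0][0])
            comp_stack = [start]
            remaining[start] = False
            while comp_stack:
                i = comp_stack.pop()
                for j in np.nonzero(adj[i])[0]:
                    if remaining[j]:
                        remaining[j] = False
                        comp_stack.append(int(j))
        raise ValueError(f"contact graph disconnected at cutoff {cutoff} Å: {n_components} components")
    eigvals, eigvecs = np.linalg.eigh(K)
    lam1 = eigvals[1]
    u1 = eigvecs[:, 1]
    fluctuations = u1**2 / lam1
    return eigvals, fluctuations


# ---------------------------------------------------------------------------
# Attribute tables
# ---------------------------------------------------------------------------


def attribute_table(
    structures: list[Structure],
    groups: Optional[tuple[list[str], list[str]]] = None,
    contact_cutoff: float = 5.5,
    gnm_cutoff: float = 7.5,
    sasa_points: int = 240,
) -> pd.DataFrame:
    """One :class:`AttributeRecord` per structure, as a DataFrame.

    Individual attribute failures (e.g. no interface for a monomer) are
    recorded as missing values; the run continues.
    """
    records = []
    for s in structures:
        rec = AttributeRecord(structure_id=s.id)
        for name, fn in (
            ("total_sasa", lambda: sasa(s, n_points=sasa_points)[1]),
            ("radius_of_gyration", lambda: radius_of_gyration(s)),
            ("charged_fraction", lambda: charged_fraction(list(s.sequences().values()))),
        ):
            try:
                setattr(rec, name, fn())
            except (ValueError, KeyError) as exc:
                logger.warning("%s: %s failed: %s", s.id, name, exc)
        if groups is not None:
            try:
                icc = interface_contacts(s, groups[0], groups[1], cutoff=contact_cutoff)
                rec.n_intersubunit_contacts = icc.total
                nis = nis_composition(
                    s, groups[0], groups[1], contact_cutoff=contact_cutoff, n_points=sasa_points
                )
                rec.affinity_score = affinity_score(icc, nis)
            except (ValueError, KeyError) as exc:
                logger.warning("%s: interface attributes failed: %s", s.id, exc)
        try:
            _, fluct = gnm_modes(s, cutoff=gnm_cutoff)
            rec.mean_slow_mode_fluctuation = float(fluct.mean())
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("%s: GNM failed: %s", s.id, exc)
        records.append(rec)
    return pd.DataFrame([vars(r) for r in records]).set_index("structure_id")
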