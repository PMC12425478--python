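"""Residue correspondence, rigid superposition, and structure-similarity
metrics (RMSD, RMSD100, TM-score) for monomers and multimeric complexes.

Correspondence is sequence-guided: per chain, a global Needleman–Wunsch
alignment (BLOSUM62, affine gap open/extend 11/1) yields the residue
pairing, and chains are concatenated in template order. The TM-score
optimum is approximated by iterative superposition restricted to
well-fitting pairs, the standard refinement used by length-normalized
structural scores. The metrics are:

    RMSD       = sqrt( (1/N) Σ |x_i_ref − x_i|² )
    RMSD100    = RMSD / (1 + ln sqrt(L / 100))
    TM-score   = max over superpositions of
                 (1/L_ref) Σ_i 1 / (1 + (d_i / d0(L_ref))²)

with d0(L) = 1.24 (L − 15)^(1/3) − 1.8, floored at 0.5 Å.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.spatial.distance import cdist

from .core_io import Structure

logger = logging.getLogger(__name__)

#: residue key: (chain_id, residue_index, insertion_code)
ResidueKey = tuple[str, int, str]


@dataclass
class AlignedPair:
    """Residue correspondence between a reference and a query structure."""

    ref_id: str
    query_id: str
    pairs: list[tuple[ResidueKey, ResidueKey]]
    L_ref: int
    L_query: int
    low_coverage: bool = False

    @property
    def L(self) -> int:
        return len(self.pairs)


@dataclass
class SuperpositionResult:
    """Proper rigid-body transform mapping query coordinates onto reference."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def validate(self) -> None:
        r = self.rotation
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(r) - 1.0) > 1e-8:
            raise ValueError("rotation determinant is not +1")


# ---------------------------------------------------------------------------
# Correspondence
# ---------------------------------------------------------------------------


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    # end gaps are free: terminal extensions of one homolog must not drag
    # unrelated residues of the other into the correspondence
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older Biopython naming
        aligner.end_gap_score = 0.0
    return aligner


def _chain_residues_with_ca(structure: Structure, chain_id: str):
    """Residues of one chain that carry a Cα; missing-Cα residues are dropped
    from the correspondence with a logged warning."""
    chain = structure.chain(chain_id)
    kept = []
    for r in chain.residues:
        if r.ca is None:
            logger.warning(
                "structure %s chain %s residue %s%s has no CA; dropped from correspondence",
                structure.id,
                chain_id,
                r.index,
                r.icode,
            )
            continue
        kept.append(r)
    return kept


def sequence_correspondence(ref: Structure, query: Structure) -> AlignedPair:
    """Global-per-chain sequence alignment between two structures.

    Chains must already share a labeling convention (see
    :func:`nitroscape.core_io.rename_chains_to_template`); pairing is
    chain-by-chain, concatenated in reference chain order, and never
    crosses chains.
    """
    common = [cid for cid in ref.chain_ids if cid in query.chain_ids]
    if not common:
        raise ValueError(
            f"no mappable chains between {ref.id} ({ref.chain_ids}) and {query.id} ({query.chain_ids})"
        )
    aligner = _make_aligner()
    pairs: list[tuple[ResidueKey, ResidueKey]] = []
    L_ref = 0
    L_query = 0
    for cid in common:
        ref_res = _chain_residues_with_ca(ref, cid)
        query_res = _chain_residues_with_ca(query, cid)
        L_ref += len(ref_res)
        L_query += len(query_res)
        if not ref_res or not query_res:
            continue
        ref_seq = "".join(r.one_letter for r in ref_res)
        query_seq = "".join(r.one_letter for r in query_res)
        aln = aligner.align(ref_seq, query_seq)[0]
        for (a0, a1), (b0, b1) in zip(*aln.aligned):
            for i, j in zip(range(a0, a1), range(b0, b1)):
                pairs.append(((cid, ref_res[i].index, ref_res[i].icode), (cid, query_res[j].index, query_res[j].icode)))
    ap = AlignedPair(
        ref_id=ref.id,
        query_id=query.id,
        pairs=pairs,
        L_ref=L_ref,
        L_query=L_query,
        low_coverage=len(pairs) < 10,
    )
    if ap.low_coverage:
        logger.warning("correspondence %s vs %s has only %d aligned pairs", ref.id, query.id, ap.L)
    return ap


def _residue_lookup(structure: Structure) -> dict[ResidueKey, "object"]:
    out = {}
    for c in structure.chains:
        for r in c.residues:
            out[(c.id, r.index, r.icode)] = r
    return out


def _paired_coords(
    ref: Structure, query: Structure, ap: AlignedPair, atoms: str = "ca"
) -> tuple[np.ndarray, np.ndarray, list[ResidueKey]]:
    """Coordinate arrays for the aligned residues, plus the reference keys
    actually used (one per residue for ``ca``, repeated for ``all``)."""
    ref_lookup = _residue_lookup(ref)
    query_lookup = _residue_lookup(query)
    ref_xyz: list[np.ndarray] = []
    query_xyz: list[np.ndarray] = []
    used_keys: list[ResidueKey] = []
    for ref_key, query_key in ap.pairs:
        r_res, q_res = ref_lookup[ref_key], query_lookup[query_key]
        if atoms == "ca":
            names = ["CA"] if (r_res.ca is not None and q_res.ca is not None) else []
        elif atoms == "all":
            q_names = {a.name for a in q_res.atoms}
            names = [a.name for a in r_res.atoms if a.name in q_names]
        else:
            raise ValueError(f"atoms must be 'ca' or 'all', got {atoms!r}")
        if not names:
            logger.warning("no shared atoms for residue pair %s/%s; dropped", ref_key, query_key)
            continue
        for name in names:
            ref_xyz.append(r_res.atom(name).coords)
            query_xyz.append(q_res.atom(name).coords)
            used_keys.append(ref_key)
    return np.array(ref_xyz), np.array(query_xyz), used_keys


# ---------------------------------------------------------------------------
# Superposition and metrics
# ---------------------------------------------------------------------------


def kabsch_superpose(coords_ref: np.ndarray, coords_query: np.ndarray) -> SuperpositionResult:
    """Least-squares proper rotation + translation of query onto reference.

    Solved by SVD of the cross-covariance matrix with reflection correction
    (the determinant is forced to +1), the classic Kabsch construction.
    """
    P = np.asarray(coords_ref, dtype=float)
    Q = np.asarray(coords_query, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"coordinate arrays must share an n×3 shape, got {P.shape} vs {Q.shape}")
    n = P.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 points to superpose, got {n}")
    if not (np.all(np.isfinite(P)) and np.all(np.isfinite(Q))):
        raise ValueError("coordinates must be finite")
    p_mean, q_mean = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - p_mean, Q - q_mean
    if min(np.linalg.matrix_rank(Pc, tol=1e-9), np.linalg.matrix_rank(Qc, tol=1e-9)) < 2:
        raise ValueError("degenerate (collinear) point configuration")
    H = Qc.T @ Pc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = p_mean - R @ q_mean
    diff = Pc - Qc @ R.T
    rmsd_val = float(np.sqrt((diff**2).sum() / n))
    result = SuperpositionResult(rotation=R, translation=t, rmsd=rmsd_val, n_atoms=n)
    result.validate()
    return result


def rmsd(ref: Structure, query: Structure, ap: AlignedPair, atoms: str = "ca") -> float:
    """Superposition RMSD over the aligned residues (Cα by default)."""
    ref_xyz, query_xyz, _ = _paired_coords(ref, query, ap, atoms)
    if len(ref_xyz) < 3:
        raise ValueError(f"only {len(ref_xyz)} aligned atoms; need >= 3")
    return kabsch_superpose(ref_xyz, query_xyz).rmsd


def rmsd100(rmsd_value: float, L: int) -> float:
    """Length-normalized RMSD: RMSD / (1 + ln sqrt(L/100)).

    Corrects the alignment-size bias of raw RMSD; the denominator crosses
    zero near L ≈ 13, below which the normalization is undefined.
    """
    if L < 20:
        raise ValueError(f"alignment length {L} too short for RMSD100 (need >= 20)")
    denom = 1.0 + math.log(math.sqrt(L / 100.0))
    if denom <= 0:
        raise ValueError(f"RMSD100 denominator non-positive at L={L}")
    return rmsd_value / denom


def tm_d0(L_ref: int, floor: float = 0.5) -> float:
    """Size-dependent TM-score normalization distance d0(L)."""
    if L_ref < 20:
        raise ValueError(f"L_ref={L_ref} too short for a defined d0 (need >= 20)")
    return max(floor, 1.24 * (L_ref - 15) ** (1.0 / 3.0) - 1.8)


def _tm_from_distances(d: np.ndarray, L_ref: int, d0: float) -> float:
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / L_ref)


def tm_score(
    ref: Structure,
    query: Structure,
    ap: AlignedPair,
    normalize_by: str = "ref",
    superpose: bool = True,
    d_cut: float = 8.0,
    max_iter: int = 10,
    tol: float = 1e-4,
) -> float:
    """Length-normalized structural similarity in [0, 1].

    ``normalize_by`` selects the L_ref in the formula: ``ref`` (default),
    ``query``, or ``longer`` (the longer of the pair — used for symmetric
    pairwise matrices). With ``superpose=True`` the score is maximized by
    iterative superposition on pairs closer than ``d_cut`` Å; with
    ``superpose=False`` the coordinates are scored as given.
    """
    ref_xyz, query_xyz, _ = _paired_coords(ref, query, ap, "ca")
    if normalize_by == "ref":
        L_norm = ap.L_ref
    elif normalize_by == "query":
        L_norm = ap.L_query
    elif normalize_by == "longer":
        L_norm = max(ap.L_ref, ap.L_query)
    else:
        raise ValueError(f"normalize_by must be ref|query|longer, got {normalize_by!r}")
    d0 = tm_d0(L_norm)
    if not superpose:
        d = np.linalg.norm(ref_xyz - query_xyz, axis=1)
        return min(1.0, _tm_from_distances(d, L_norm, d0))
    sup = kabsch_superpose(ref_xyz, query_xyz)
    best = -np.inf
    for _ in range(max_iter):
        d = np.linalg.norm(ref_xyz - sup.apply(query_xyz), axis=1)
        score = _tm_from_distances(d, L_norm, d0)
        improved = score > best + tol
        best = max(best, score)
        keep = d < d_cut
        if not improved or keep.sum() < 3 or keep.all():
            break
        sup = kabsch_superpose(ref_xyz[keep], query_xyz[keep])
    return min(1.0, best)


def per_residue_deviation(ref: Structure, query: Structure, ap: AlignedPair) -> dict[ResidueKey, float]:
    """Cα–Cα distance per aligned residue after global Cα superposition,
    keyed by reference residue; unaligned residues are absent."""
    ref_xyz, query_xyz, keys = _paired_coords(ref, query, ap, "ca")
    if len(ref_xyz) < 3:
        raise ValueError("need >= 3 aligned residues")
    sup = kabsch_superpose(ref_xyz, query_xyz)
    d = np.linalg.norm(ref_xyz - sup.apply(query_xyz), axis=1)
    return {key: float(di) for key, di in zip(keys, d)}


def local_site_rmsd(
    ref: Structure,
    query: Structure,
    ap: AlignedPair,
    site_residues: list[ResidueKey],
    radius: float = 8.0,
) -> float:
    """Cα RMSD after local superposition of the residues surrounding a site.

    The selection is every aligned residue whose reference Cα lies within
    ``radius`` Å of any listed site residue Cα; the superposition is
    computed on that selection alone.
    """
    ref_lookup = _residue_lookup(ref)
    missing = [k for k in site_residues if k not in ref_lookup]
    if missing:
        raise ValueError(f"site residues absent from reference: {missing}")
    site_xyz = np.array([ref_lookup[k].ca.coords for k in site_residues])
    ref_xyz, query_xyz, keys = _paired_coords(ref, query, ap, "ca")
    dist_to_site = cdist(ref_xyz, site_xyz).min(axis=1)
    keep = dist_to_site <= radius
    if keep.sum() < 3:
        raise ValueError(f"local selection has {int(keep.sum())} residues; need >= 3")
    return kabsch_superpose(ref_xyz[keep], query_xyz[keep]).rmsd


def pairwise_matrix(
    structures: list[Structure],
    metric: str = "rmsd",
    atoms: str = "ca",
) -> pd.DataFrame:
    """All-vs-all symmetric metric matrix over a structure list.

    The diagonal is 0 for ``rmsd``/``rmsd100`` and 1 for ``tm``; TM-scores
    are normalized by the longer member of each pair so the matrix is
    symmetric by construction. Failed pairs are recorded as NaN, never as
    silent zeros.
    """
    if len(structures) < 2:
        raise ValueError("need at least 2 structures")
    if metric not in ("rmsd", "tm", "rmsd100"):
        raise ValueError(f"metric must be rmsd|tm|rmsd100, got {metric!r}")
    ids = [s.id for s in structures]
    n = len(structures)
    mat = np.full((n, n), np.nan)
    np.fill_diagonal(mat, 1.0 if metric == "tm" else 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                ap = sequence_correspondence(structures[i], structures[j])
                if metric == "tm":
                    value = tm_score(structures[i], structures[j], ap, normalize_by="longer")
                else:
                    value = rmsd(structures[i], structures[j], ap, atoms=atoms)
                    if metric == "rmsd100":
                        value = rmsd100(value, ap.L)
            except (ValueError, KeyError) as exc:
                logger.warning("pair (%s, %s) failed: %s", ids[i], ids[j], exc)
                continue
            mat[i, j] = mat[j, i] = value
    return pd.DataFrame(mat, index=ids, columns=ids)
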