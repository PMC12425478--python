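"""Ancestral sequence variants from site-wise posterior distributions.

Marginal ancestral sequence reconstruction yields, for each internal node,
a per-site posterior distribution over the 20 amino acids. From that
distribution this module derives the sequence set used for structure
prediction:

* ``ml`` — the maximum-likelihood sequence (per-site argmax);
* ``altall`` — the ML sequence with the *second* most probable state at
  every ambiguous site, where a site is ambiguous when its maximal
  posterior falls below a threshold (default 0.7);
* ``alt2``–``alt5`` — sequences drawn by sampling the full site posterior
  at each ambiguous site (unambiguous sites keep the ML state).

All ties are broken by alphabetical order of the one-letter codes, and all
sampling is reproducible from an explicit integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import AMINO_ACIDS, PosteriorMatrix


@dataclass
class VariantSet:
    """ML + alternative ancestral sequences for one node."""

    node_id: str
    ml: str
    altall: str
    alts: list[str]
    seed: int
    ambiguity_threshold: float

    @property
    def all_sequences(self) -> dict[str, str]:
        """FASTA-ready mapping using the ``<node>_ml/_altall/_alt<k>`` naming."""
        out = {f"{self.node_id}_ml": self.ml, f"{self.node_id}_altall": self.altall}
        for k, seq in enumerate(self.alts, start=2):
            out[f"{self.node_id}_alt{k}"] = seq
        return out


@dataclass
class PipelineCensus:
    """Study design counts for the structure-prediction bookkeeping."""

    n_extant: int
    n_ancestral_nodes: int
    n_alt_per_ancestor: int
    n_complexes_per_variant: int

    def __post_init__(self) -> None:
        for name in ("n_extant", "n_ancestral_nodes", "n_alt_per_ancestor", "n_complexes_per_variant"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")


def _check_matrix(p: PosteriorMatrix) -> None:
    if p.n_sites == 0:
        raise ValueError(f"posterior matrix for {p.node_id} has no sites")


def ml_sequence(p: PosteriorMatrix) -> str:
    """Per-site argmax sequence; ties go to the alphabetically first state."""
    _check_matrix(p)
    # argmax returns the first maximum; columns are alphabetical already
    idx = np.argmax(p.probs, axis=1)
    return "".join(AMINO_ACIDS[i] for i in idx)


def ambiguous_sites(p: PosteriorMatrix, threshold: float = 0.7) -> np.ndarray:
    """Boolean mask of sites whose maximal posterior is below ``threshold``."""
    return p.probs.max(axis=1) < threshold


def altall_sequence(p: PosteriorMatrix, threshold: float = 0.7) -> str:
    """Second-most-probable state at ambiguous sites, ML elsewhere."""
    _check_matrix(p)
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    order = np.argsort(-p.probs, axis=1, kind="stable")  # stable => alphabetical ties
    first, second = order[:, 0], order[:, 1]
    ambiguous = ambiguous_sites(p, threshold)
    choice = np.where(ambiguous, second, first)
    return "".join(AMINO_ACIDS[i] for i in choice)


def sample_variant_sequences(
    p: PosteriorMatrix, n: int, seed: int, threshold: float = 0.7
) -> list[str]:
    """Draw ``n`` sequences, sampling the full posterior at ambiguous sites.

    Unambiguous sites always carry the ML state; identical seeds give
    identical output.
    """
    _check_matrix(p)
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    ml = ml_sequence(p)
    ambiguous = ambiguous_sites(p, threshold)
    amb_idx = np.nonzero(ambiguous)[0]
    out = []
    for _ in range(n):
        chars = list(ml)
        for site in amb_idx:
            probs = p.probs[site]
            chars[site] = AMINO_ACIDS[rng.choice(len(AMINO_ACIDS), p=probs)]
        out.append("".join(chars))
    return out


def build_variant_set(
    p: PosteriorMatrix, seed: int, threshold: float = 0.7, n_sampled: int = 4
) -> VariantSet:
    """ML + altall + ``n_sampled`` posterior-sampled alternatives (default 4,
    for five alternatives per ancestor in total)."""
    return VariantSet(
        node_id=p.node_id,
        ml=ml_sequence(p),
        altall=altall_sequence(p, threshold),
        alts=sample_variant_sequences(p, n_sampled, seed, threshold),
        seed=seed,
        ambiguity_threshold=threshold,
    )


def census_counts(c: PipelineCensus) -> dict[str, int]:
    """Variant and structure totals implied by a study design.

    Each ancestral node contributes ``1 + n_alt_per_ancestor`` sequence
    variants; every variant has ``n_complexes_per_variant`` multimeric
    complexes predicted (e.g. the reductase homodimer and the catalytic
    heterotetramer).
    """
    n_ancestral_variants = c.n_ancestral_nodes * (1 + c.n_alt_per_ancestor)
    n_variants = c.n_extant + n_ancestral_variants
    return {
        "n_variants": n_variants,
        "n_structures": n_variants * c.n_complexes_per_variant,
        "n_extant_structures": c.n_extant * c.n_complexes_per_variant,
        "n_ancestral_structures": n_ancestral_variants * c.n_complexes_per_variant,
    }
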