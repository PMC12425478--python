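# Methods

This note records the models implemented in `nitroscape`, the parameter
choices baked into the defaults, and the limitations of the synthetic data.

## Variant enumeration from ASR posteriors

An ancestral reconstruction is represented as an L×20 posterior matrix over
the standard amino acids (alphabetical order). The maximum-likelihood (ML)
sequence takes the argmax at each site, breaking exact ties alphabetically.
A site is *ambiguous* when its maximum posterior is strictly below the
threshold (default 0.7; a site at exactly 0.7 is not ambiguous). The
"altall" variant substitutes the second-most-probable state at every
ambiguous site; additional alternatives are drawn by sampling the full
20-state posterior at ambiguous sites only, so every alternative differs
from the ML sequence only where the reconstruction is genuinely uncertain.

The study-design census is exact combinatorics: with `n_extant` extant
sequences, `n_anc` ancestral nodes, `k` alternatives per ancestor and `c`
predicted complexes per variant,
`n_variants = n_extant + n_anc·(1+k)` and `n_structures = c·n_variants`.

## Structure comparison

Residue correspondence is sequence-guided: chains of the query are first
mapped to template chains by best sequence identity, then each chain pair is
aligned globally (Needleman–Wunsch, BLOSUM62, gap open −11 / extend −1) with
**free end gaps**, so a terminal extension present in only one structure is
left unaligned rather than dragging unrelated residues into correspondence.
Per-chain alignments are concatenated in template chain order.

Superposition is the Kabsch algorithm via SVD, with the determinant forced
to +1 (proper rotations only; no reflections). From the superposed pairs:

- **RMSD** over Cα atoms (or all shared heavy atoms, matched by atom name
  within corresponding residues).
- **RMSD100** = RMSD / (1 + ln √(L/100)), a length normalization defined for
  L ≥ 20 (the denominator changes sign near L ≈ 14, so shorter alignments
  are rejected).
- **TM-score** with d0(L) = 1.24·(L−15)^⅓ − 1.8, floored at 0.5 Å, and
  iterative superposition refinement: re-superpose on the subset of pairs
  within 8 Å, up to 10 iterations or convergence. Normalization length is
  selectable (reference, query, or the longer of the two). A closed-form
  consequence used in testing: if every pair sits at distance exactly d0,
  the score is 0.5 when normalized by the alignment length.

Pairwise matrices over structure sets are symmetric with a zero (RMSD) or
unit (TM) diagonal; pairs that cannot be compared (e.g. alignments too short
for the metric) are reported as NaN rather than silently dropped.

## Structure-derived attributes

- **Solvent accessibility**: Shrake–Rupley with probe radius 1.4 Å and a
  golden-spiral point distribution (960 points per atom by default; 240 in
  bulk attribute tables for speed). For an isolated atom this converges to
  the analytic sphere area 4π(r+1.4)² to within ~2%. Relative accessibility
  uses the Tien et al. theoretical maximum per residue.
- **Charged surface fraction** counts {D,E,K,R} by default (histidine is
  configurable), over surface residues above a relative-accessibility
  cutoff.
- **Interface contacts** between chain groups use a heavy-atom distance
  cutoff (5.5 Å default) and classify residue pairs as
  charged/apolar/polar; the binding-affinity score is the linear
  contact-based model
  ΔG = −0.09459·CC − 0.10007·CA + 0.19577·PP − 0.22671·PA
  + 0.18681·%NIS_apolar + 0.13810·%NIS_charged − 15.9433,
  with non-interacting-surface (NIS) percentages computed from
  solvent-exposed residues outside the interface.
- **GNM**: Kirchhoff (connectivity) matrix from Cα contacts within 7.5 Å;
  slow-mode fluctuations from the first non-zero eigenpair. A disconnected
  contact graph has a degenerate zero eigenvalue and is rejected with an
  error naming the number of components. The 3-node path graph has the
  analytic spectrum {0, 1, 3}, and the eigenvalue sum always equals the
  matrix trace; both serve as internal checks.

## Phylogenetic analysis

Spearman correlation is computed from ranks (average ranks for ties) with a
permutation p-value. Structure-distance matrices are clustered by
average linkage; recovered partitions are scored against reference clade
labels with the adjusted Rand index (ARI).

Indel blocks are detected from per-column presence sets in the alignment:
adjacent columns are merged while their presence sets have Jaccard
similarity ≥ 0.9 or are nested, and blocks shorter than 5 columns are
discarded. Each block's presence/absence pattern at the leaves is pushed
onto the tree by Fitch parsimony (root ties resolve to absence, so a
pattern explicable as either a gain or a loss is called an insertion).
When ancestral sequence rows are available for *all* internal nodes, the
observed ancestral states override the parsimony reconstruction, which is
how progressive elongation (a block growing stepwise along a lineage) and
true deletions are distinguished. The length trajectory of a block along a
root-to-tip path reports the number of non-gap characters per node.

## Synthetic data generator

The generator plants a fully known ground truth:

- **Tree**: Yule (pure-birth) topology with exponential branch lengths
  (mean 0.05), 24 leaves and 4 clades by default; clades are carved by
  repeatedly splitting the largest internal subtree.
- **Sequences**: root of length 300, Poisson substitution process at rate
  0.5 per site per unit branch length with uniform replacement; expected
  identity after total time T follows
  p = 1/20 + (19/20)·e^(−(20/19)·r·T), which is verified against simulation.
- **Indels**: two one-shot insertions (lengths 60 and 55) and one
  progressive insertion growing 8 → 20 → 40 along three successive internal
  nodes of a clade; events are placed on distinct branches and recorded in
  the truth file with their blocks, branches and schedules.
- **Structures**: toy Cα helices (rise 1.5 Å, radius 2.3 Å, twist 100°,
  position 0 at the origin) with insertion regions rendered as radial loop
  bulges; clade-specific smoothed displacement fields (σ_inter = 1.5 Å) and
  per-node Gaussian jitter (σ_intra = 0.3 Å) make within-clade structures
  more similar than between-clade ones by construction (5× ratio). For two
  structures independently perturbed at σ, the expected RMSD is σ√6.
- **Posteriors**: ASR-style matrices that place the true state at high
  posterior everywhere except a controlled fraction (default 0.15) of
  ambiguous sites.
- **Planted attributes**: a node attribute with a target Spearman
  correlation ρ against root distance, via a Gaussian copula with
  ρ_gauss = 2·sin(π·ρ/6); |ρ| = 1 uses an exact monotone transform.

Sub-seeds for every component are derived from the master seed by CRC-32 of
a component label fed into `numpy.random.SeedSequence`, so all outputs are
reproducible and independent components are decoupled.

### What the synthetic data does and does not show

The generator demonstrates that the *analysis machinery* recovers what was
planted: insertion blocks on the correct branches with no spurious
deletions, exact progressive length trajectories, perfect clade recovery
from structure distances, and the sign (and approximate magnitude) of weak
planted depth correlations. It does **not** model real protein biophysics:
the helical toy structures have no side chains, packing, or secondary
structure variety; the substitution model is site-independent and
exchangeability-free; posterior matrices are manufactured, not inferred;
and attribute–depth correlations are planted directly rather than emerging
from structure. Quantities computed on synthetic data therefore validate
the code paths and statistical procedures, not any biological conclusion.

## Numerical choices

- All superpositions center coordinates before SVD; reflections are
  excluded by sign-correcting the smallest singular vector.
- Posterior rows are renormalized exactly on parse; rows deviating from
  unit sum by more than 0.01 are rejected.
- PDB output uses fixed-column formatting (coordinates %8.3f, B-factor
  %6.2f at columns 61–66); round-trips through the reader are exact to
  format precision.
- Seeds everywhere are integers < 2³¹; derived seeds come from labeled
  CRC-32 sub-seeding.

## Limitations

- The comparison pipeline assumes one-to-one chain correspondence; no
  support for homo-oligomer chain-assignment ambiguity beyond best-identity
  matching in template order.
- RMSD100 is undefined below 20 aligned residues and is rejected there.
- The affinity model is a fixed linear fit; it is used as a comparative
  score, not a calibrated free energy.
- GNM fluctuations use only the first non-zero mode.
- Indel detection assumes a trustworthy alignment; misalignment artifacts
  are not modeled or corrected.
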