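# nitroscape

Tools for studying the structural evolution of protein families along
phylogenies reconstructed by ancestral sequence resurrection (ASR).

When every node of a phylogeny — extant leaves and reconstructed ancestors
alike — has a predicted three-dimensional structure, structure itself becomes
an evolvable character that can be traced through time. `nitroscape`
implements the computational machinery for that kind of study:

- **Variant enumeration from ASR posteriors.** Maximum-likelihood ancestral
  sequences, the "altall" alternative (second-most-probable state at every
  ambiguously reconstructed site), and posterior-sampled alternatives, with a
  census of how many sequence variants and structure predictions a full study
  design implies.
- **Structure comparison.** Sequence-guided residue correspondence
  (Needleman–Wunsch, BLOSUM62, free end gaps), Kabsch superposition, RMSD,
  the length-normalized RMSD100, and TM-score with iterative superposition
  refinement — plus per-residue deviations and local site RMSD.
- **Structure-derived attributes.** Shrake–Rupley solvent accessibility,
  radius of gyration, charged surface fraction, interface contact counting
  with a linear contact-based binding-affinity score, residue contact
  networks, and Gaussian network model (GNM) slow-mode fluctuations.
- **Phylogenetic analysis of structural characters.** Root-to-node distances,
  Spearman correlation of attributes with phylogenetic depth (with a
  permutation test), average-linkage clustering of structure-distance
  matrices, clade-recovery scoring (adjusted Rand index), and insertion /
  deletion block detection with Fitch parsimony assignment of indel events to
  branches — including progressive, stepwise elongation along a lineage.
- **Synthetic data with planted ground truth.** A generator that simulates a
  birth-only phylogeny with clade structure, evolves sequences and toy
  helical structures along it, plants indel events (one-shot and
  progressive), manufactures ASR-style posterior matrices with a controlled
  fraction of ambiguous sites, and plants depth-correlated attributes at a
  chosen Spearman rho. Every planted quantity is written to a machine-readable
  truth file so recovery can be tested end to end.

All randomness is seeded and reproducible; rerunning any generator or
pipeline stage with the same seed yields byte-identical outputs.

## Worked example

Generate a synthetic dataset with planted ground truth (24 leaves, 4 clades,
three planted insertion events, one of them progressive):

```console
$ nitroscape synth --seed 42 --out demo
dataset written to demo
$ ls demo
msa.fasta  posteriors  structures  tree.nwk  truth.json
```

Compare two extant structures:

```console
$ nitroscape compare demo/structures/L000.pdb demo/structures/L005.pdb --metric rmsd
rmsd	0.7307	L=355
$ nitroscape compare demo/structures/L000.pdb demo/structures/L005.pdb --metric tm
tm	0.9889	L=355
```

Enumerate ancestral sequence variants (ML, altall, and four posterior
samples) for the root ancestor:

```console
$ nitroscape variants --posterior demo/posteriors/N000.tsv --seed 1 --out variants.fasta
6 sequences written to variants.fasta
$ head -1 variants.fasta
>N000_ml
```

Detect indel blocks in the alignment and assign each event to a branch by
Fitch parsimony:

```console
$ nitroscape indels --msa demo/msa.fasta --tree demo/tree.nwk --out events.tsv
3 events written to events.tsv
$ cat events.tsv
block_start	block_end	event_branch	direction
0	40	N004	insertion
190	245	N001	insertion
395	455	N006	insertion
```

These three blocks are exactly the planted events recorded in
`demo/truth.json`, on the correct branches, with no spurious deletions.

Or run the whole pipeline from a config file:

```console
$ cat run.yaml
outdir: run_out
seed: 42
synth:
  n_leaves: 12
  n_clades: 3
  root_length: 120
$ nitroscape run --config run.yaml
{
  "design": {
    "n_alt_per_ancestor": 5,
    "n_ancestral_nodes": 11,
    "n_complexes_per_variant": 1,
    "n_extant": 12
  },
  "n_ancestral_structures": 66,
  "n_extant_structures": 12,
  "n_structures": 78,
  "n_variants": 78
}
```

The run directory contains a `manifest.json` with a SHA-256 hash of every
output file; reruns with the same seed are hash-identical.

The same functionality is available as a Python API
(`nitroscape.core_io`, `nitroscape.asr_variants`, `nitroscape.struct_compare`,
`nitroscape.struct_attributes`, `nitroscape.phylo_evo`,
`nitroscape.synthetic_data`, `nitroscape.pipeline`).

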