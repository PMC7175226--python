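# structkit

A structural-bioinformatics toolkit: a macromolecular data model, a
filter-based high-throughput PDB reader/writer, sequence and FASTA
utilities, a geometry engine, hierarchical clustering of structure
ensembles, pairwise sequence alignment, and a "one task – one app"
command-line suite.

## Features

- **Data model** (`structkit.core_model`) — `Structure → Chain →
  Residue → PdbAtom` hierarchy with `Vec3` vector algebra, a monomer
  table (1/3-letter codes, aromatic ring definitions), CA-trace
  extraction with calcium/alpha-carbon disambiguation.
- **PDB I/O** (`structkit.pdb_io`) — fixed-column (wwPDB v3.3) parsing
  and writing, composable raw-line filters (`is_ca_filter`, name/chain/
  residue predicates combinable with `& | ~`) applied *before* parsing,
  gzip input, and a fast multi-model path that parses the first model
  only and swaps coordinates for chemically identical later models
  (with automatic fallback and warning on mismatch).
- **Sequences** (`structkit.sequence`) — chain sequences from
  structures, FASTA read/write, MSA column-frequency profiles with
  additive pseudocounts.
- **Geometry** (`structkit.calc_structural`) — signed torsion angles,
  phi/psi with Glycine/Proline/Pre-Proline/General classes, Kabsch
  (SVD, reflection-corrected) superposition and crmsd, all-pairs crmsd
  matrices, multi-model residue contact maps (CA or any-atom, strict
  `<` cutoff), aromatic-ring local reference frames and stacking
  descriptors (centroid distance, inter-plane angle, lateral offset).
- **Clustering** (`structkit.clustering`) — deterministic agglomerative
  clustering (single/complete/average linkage, lowest-index tie-break),
  cuts by `k` or height, medoid extraction, Newick export.
- **Alignments** (`structkit.alignments`) — Needleman–Wunsch global
  alignment with linear gaps or a substitution matrix, percent
  identity.
- **Fixtures** (`structkit.fixtures`) — seeded synthetic generators
  with ground truth: backbones built from target phi/psi internal
  coordinates, multi-model trajectories (rigid / noise / two-basin),
  aromatic ring pairs with prescribed stacking geometry, random
  protein-like files with ligands, ions and alt-locs.

## Command-line usage

All apps live under one entry point:

```sh
structkit read-pdb model.pdb                      # model/chain/residue/atom counts
structkit ca-only-multimodel a.pdb b.pdb -o m.pdb # merge CA-only models
structkit contact-map traj.pdb --cutoff 8         # contact counts over models
structkit pdb-to-fasta model.pdb                  # chain sequences as FASTA
structkit ramachandran model.pdb                  # phi/psi + class TSV
structkit rmsd a.pdb b.pdb                        # CA crmsd after superposition
structkit stacking model.pdb --cutoff 6.5         # aromatic ring pair table
structkit clust dist.txt -k 3 --newick t.nwk      # cluster matrix or PDB ensemble
structkit seqc in.fasta                           # sequence converter
structkit strc in.pdb --ca-only -o out.pdb        # structure converter
structkit bench                                   # six-task micro-benchmark
```

Outputs go to stdout by default; `-o` writes to a file. Errors produce
a one-line diagnostic and a non-zero exit status.

## Notes on conventions

- Alt-locs: by default only the first-encountered conformer per
  (residue, atom name) is kept; `keep_alt_locs=True` retains all.
- An atom is an alpha carbon only if its name strips to `CA` *and* its
  element field is carbon or blank — calcium ions never qualify.
- Contacts use strict `<` and by default exclude intra-chain pairs with
  sequence separation < 2.
- TRP ring frames use the six-membered ring, HIS the five-membered.
- Torsion angles follow the IUPAC sign convention in (−180°, 180°].
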