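# pbrefine

Protein Block (PB) based refinement of structurally variable regions (SVRs)
in pairwise structural alignments of homologous proteins.

Globally superposed homologous structures contain regions of high Cα
deviation that often hide *local* conformational similarity — e.g. a helix
that is merely displaced. `pbrefine` encodes each backbone as a string over
the 16-letter PB structural alphabet, splits a superposed pairwise alignment
into structurally conserved regions (SCRs: ≥ 3 contiguous residues with
Cα–Cα deviation < 3.0 Å) and SVRs, re-aligns each SVR's PB strings with an
affine-gap dynamic programme (gap open 10, extend 0.2, substitution matrix
scaled to [0, 10]), and reports per-SVR scores before and after refinement:

- **SAP** — mean raw substitution value over aligned PB pairs;
- **SCA** — the same including gap columns scored −3, normalized by length;
- classification *similar*/*dissimilar* at a SAP cutoff of −0.42
  (re-derivable with `calibrate_cutoff`);
- **SDM** — structural distance metric from a local Kabsch superposition of
  the (refined) residue equivalences, with RMS = rmsd / 24.97;
- gap statistics, a 16×16 PB-pair substitution-difference matrix, and the
  refined residue equivalences as aligned FASTA.

The shipped substitution matrix (`pbrefine/data/pb_substitution_standin.tsv`)
is a clearly-labeled **stand-in** derived from inter-prototype angular
distances; supply your own 16×16 matrix via `--matrix` for real analyses.

## CLI

```sh
# PB-encode one chain
pbrefine assign structure.pdb --chain A -o out.pb.fasta

# SCR/SVR segmentation of a pair (two-record aligned FASTA drives the columns)
pbrefine segment s1.pdb s2.pdb --alignment aln.fasta -o segments.tsv

# full refinement: SVR table TSV + JSON report + refined aligned FASTA
pbrefine refine s1.pdb s2.pdb --alignment aln.fasta \
    --matrix my_pb_matrix.tsv --out-prefix results/pair

# synthetic ground-truth fixtures (identical / displaced / conformational / indel)
pbrefine simulate --kind displaced --seed 7 --outdir fixtures/
```

Thresholds and penalties can be overridden with `--config file` holding flat
`key=value` lines (`deviation_cutoff`, `min_scr_length`, `gap_open`,
`gap_extend`, `end_gaps_penalized`, `gap_score`, `similarity_cutoff`,
`max_rmsd`, `w_equiv`, `w_rms`, `min_svr_aligned_pbs`).

## Python API

```python
from pbrefine import read_structure, default_matrix, refine_pair
from pbrefine.segmentation import alignment_from_fasta_strings

c1 = read_structure("s1.pdb", chain="A")
c2 = read_structure("s2.pdb", chain="A")
aln = alignment_from_fasta_strings(row1, row2)   # two aligned sequences
report = refine_pair(c1, c2, aln, default_matrix())
for r in report.svr_results:
    print(r.svr.column_range, r.after.classification, r.delta.d_sap, r.delta.d_sdm)
```

## Synthetic module

`pbrefine.synthetic` builds backbones from PB strings by NeRF-style
internal-to-Cartesian placement (ideal peptide geometry, ω = 180°; residue i
takes the central φ/ψ of its prototype) and provides rigid displacement,
conformational-swap and indel perturbations plus `make_pair_fixture`, which
writes two PDB files, the residue alignment and a truth record. Strings
drawn from the prototype-overlap transition graph round-trip exactly through
build → assign.

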