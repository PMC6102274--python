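# ppikit

Demarcation and analysis of protein–protein interaction interfaces from
multimeric PDB structures.

Structural biologists who want to know *which atoms actually touch* across a
protein–protein interface — rather than a residue-level approximation —
need an atom-specific distance criterion, a reproducible file format for the
resulting contact lists, and a way to reduce a large interface corpus to a
structurally non-redundant benchmark set. ppikit provides all three as a
library plus a `ppikit` command-line tool.

## The model

Two atoms *i*, *j* on **different** protein chains form an **atomic contact
pair (ACP)** when

```
d(i, j)  <  r_vdw(i) + r_vdw(j) + t
```

with `r_vdw` the element's van der Waals radius (bundled Bondi 1964 table:
C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, H 1.20, Se 1.90 Å; the table is
swappable) and `t = 1.0 Å` a tolerance absorbing coordinate error and
thermal motion. The inequality is strict, so the threshold is atom-type
specific: 4.40 Å for a carbon–carbon pair, 4.04 Å for N–O, and so on.

From there:

- **Interface (PPII)** — all ACPs between one unordered chain pair, stored
  as a `<chain1>_<chain2>_<PDBID>.int` file (chains in lexicographic order;
  `A_B_…` and `B_A_…` are the same interface and only the former exists).
- **Patch (PPIP)** — the atoms (and their residues) one chain contributes to
  an interface; every interface has exactly two patches.
- **Patch descriptors** — interacting-residue count; solvent-accessible
  surface area of the interacting residues (Shrake–Rupley, 1.4 Å probe,
  computed on the isolated chain); a hydrophobicity score summing a
  translocon-derived per-residue scale running from −0.60 (Ile, most
  hydrophobic) to 3.49 (Asp); and whole-chain sequence similarity between
  the two sides (global alignment, identities / alignment length), with
  interfaces at ≥ 75 % similarity classed homologous (homodimer-like).
- **Non-redundant subset (NRDB)** — label every interface with the unordered
  pair of SCOP superfamilies of its chains, keep only interfaces with more
  than 20 ACPs, and retain one maximum-ACP representative per superfamily
  pair.
- **Sequence clustering** — greedy incremental clustering of chain sequences
  at ≥ 90 % identity (longest sequence founds each cluster head), plus
  head-based homolog lookup for a query sequence.

Corpus eligibility mirrors the usual quality filters: X-ray structures at
resolution ≤ 2.5 Å, at least two protein chains, single-model files only.

## Worked example

The bundled generator emits valid PDB files with exact, precomputed contact
ground truth — handy both for testing and for trying the tool:

```
$ ppikit make-fixture --spec spec.json -o 9fix.pdb --truth truth.json
9fix.pdb: 170 ground-truth ACPs over 2 chain pairs

$ ppikit filter 9fix.pdb
9FIX: accept

$ ppikit interfaces 9fix.pdb -o out/
A_B_9FIX.int    86 ACPs
B_C_9FIX.int    84 ACPs

$ ppikit analyze out/ --pdb-dir pdbs -o summary.tsv
wrote 4 patch rows to summary.tsv
```

(`spec.json` here was `{"n_chains": 3, "atoms_per_chain": 32, "seed": 7,
"seqres_gap": true}` — a three-chain complex in which only adjacent chains
touch, so the A–C interface correctly does not appear.) The summary holds
one row per patch:

```
pdb_id  chain_pair  chain  residue_count  sasa_A2  hydrophobicity  similarity_pct  dimer_class   ...
9FIX    A_B         A      8              761.00   4.50            0.00            heterologous  ...
9FIX    A_B         B      8              763.81   9.80            0.00            heterologous  ...
```

Chain A's patch has 8 interacting residues exposing 761 Å² on the isolated
chain, a hydrophobicity sum of 4.50 (mildly hydrophobic on a scale where
lower means more hydrophobic), and 0 % sequence similarity to its partner —
a heterologous interface. Each `.int` file begins with a provenance header
(format version, tolerance, radius-table checksum, contact count) followed
by one tab-separated ACP per line with the inter-atomic distance; output is
byte-deterministic, so repeated runs produce identical files.

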