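# Methods

## Contact criterion

An atomic contact pair (ACP) joins two atoms on different protein chains
whose Euclidean distance is strictly less than the sum of their van der
Waals radii plus a tolerance `t` (default 1.0 Å). The tolerance compensates
for coordinate uncertainty at typical crystallographic resolution and for
thermal motion; `t = 0.5 Å` reproduces the tighter variant used elsewhere in
the literature and is available by parameter. The criterion is atom-type
specific through the radii, which is the point of the method: a blanket
5–6 Å sphere criterion is deliberately not the default (it can be emulated
by a user-supplied radius table if needed).

Radii are element-level Bondi (1964) values shipped as a two-column TSV
(C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, H 1.20, Se 1.90 Å; unknown elements
fall back to 1.70 Å with a logged warning). No distinction between carbon
types (carbonyl vs aliphatic) is made; a user table can override any of
this, and every `.int` file records a checksum of the table that produced
it. Candidate pairs come from a k-d tree queried at the conservative radius
`max r_a + max r_b + t`, followed by the exact per-pair check, so the result
is provably identical to all-pairs enumeration (and is tested to be, against
an independent brute-force oracle).

## Structure parsing and eligibility

The fixed-width PDB reader captures ATOM/HETATM, SEQRES, EXPDTA,
`REMARK   2 RESOLUTION.` and MODEL/ENDMDL records. Only the first model's
coordinates are kept; the total model count is retained so multi-model files
can be rejected. Waters are always discarded. Alternate locations collapse
to the highest-occupancy conformer (ties prefer altloc `A`, then blank).
Hydrogens are kept in the hierarchy but excluded from contact detection by
default, since ≤ 2.5 Å X-ray structures rarely resolve them; a flag restores
them. A chain counts as protein when it has at least one standard amino-acid
residue with coordinates (selenomethionine maps to Met); nucleic and
ligand-only chains never enter interface computation.

Corpus eligibility requires: X-ray experiment, resolution present and
≤ 2.5 Å (the bound is read inclusively and is configurable), ≥ 2 protein
chains, exactly one model. The filter never throws; it enumerates every
failed criterion. No attempt is made to separate crystallographic-packing
contacts from biological interfaces — very small patches (1–5 residues) may
be crystallization artefacts and should be treated with care downstream.

Residue roles relative to a patch partition each SEQRES position into
interacting / non-interacting / missing. The observed sequence is embedded
into SEQRES by a heavily mismatch-penalized global alignment; SEQRES
positions with no observed residue are "missing". Without SEQRES the roles
cover observed residues only and the result carries a flag.

## Patch descriptors

**SASA.** Shrake–Rupley with a 1.4 Å probe and a deterministic
Fibonacci-lattice point set (default 960 points per atom; fewer than 100 is
refused). The patch value is the per-residue SASA of the *isolated* chain
summed over interacting residues — the surface the patch devotes to binding
— rather than the area buried on complexation; the ΔSASA reading is exposed
via `delta=True` / `--delta-sasa` for users who want it. 960 points put the
single-atom discretization error well under 1 %, and doubling the count
moves patch values by < 1 % (tested).

**Hydrophobicity.** A plain sum of per-residue values over the patch's
interacting residues, on a translocon-derived scale spanning −0.60 (Ile) to
3.49 (Asp); lower sums mean more hydrophobic patches. A sum (not a mean) is
used because reported per-patch scores well above the scale maximum are only
consistent with accumulation over residues. Non-standard residues are
skipped with a warning.

**Similarity.** Whole observed-chain sequences are globally aligned
(match +1, mismatch 0, gap open −10, extend −0.5 — the scoring affects only
the alignment path) and similarity is 100 × identities / alignment length,
gaps included. Whole chains, not just patch residues, are compared: the
question answered is whether the interface is homodimer-like. Interfaces at
≥ 75 % similarity are classed homologous; 75.0 falls in the "75–100" bin.

**Bins.** Residue counts: 1–5, 6–20, 21–40, 41–60, >60. SASA (Å²): ≤1000,
1001–2000, 2001–3000, >3000. Hydrophobicity: ≤10, 11–20, 21+. Similarity
(%): [0,25), [25,50), [50,75), [75,100]. Counts are conserved and
percentages sum to 100 by construction.

## Non-redundant subset

Interfaces with 20 or fewer ACPs are dropped ("more than 20" read strictly
as ≥ 21). Each survivor is labelled with the canonicalized unordered pair of
its chains' SCOP superfamilies, parsed from a standard `dir.cla` file; a
chain whose domains span several superfamilies contributes its interface to
*every* pair in the Cartesian product, which maximizes the information the
subset retains (the alternative — one pair per interface — is not adopted).
Interfaces with an unclassified chain are excluded and logged. Per pair, the
representative is the interface with the most ACPs; ties break
lexicographically on (pdb_id, chain pair), making the build deterministic
under any input ordering.

## Sequence clustering

Greedy incremental clustering: sequences are processed longest-first (ties
by identifier); each joins the first existing cluster whose head it matches
at ≥ 90 % identity, else founds a new cluster. Identity is identities
divided by the shorter sequence's length, the convention of the classic
greedy tool; the k-mer pre-filter of that tool is not reproduced because
exact alignment against heads is affordable at the corpus sizes this
package targets. Homolog lookup aligns a query against cluster heads only.
"Similarity" is implemented as identity, not substitution-group similarity.

## Synthetic structures

The generator builds parallel extended strands: 4-atom backbones (N, CA, C,
O) at 3.8 Å residue spacing, chains offset by a configurable gap, seeded
uniform jitter per coordinate, real residue names and SEQRES records.
Coordinates are rounded to the PDB's 3-decimal precision *before* the
ground-truth pass, so the bundled all-pairs contact list agrees exactly with
what a re-parse of the file yields. Decoration flags inject altlocs (0.6/0.4
conformers), insertion codes, near- and far-field waters, three-model
copies, SEQRES-only tail residues and a nucleic chain.

What the generator does not emulate: real folds and side chains (backbone
only), crystal packing, B-factor structure, chain breaks mid-sequence, or
physically realistic residue contact preferences. Passing tests therefore
demonstrate the correctness of the demarcation and scoring machinery on
geometrically controlled inputs, not biological realism of any particular
value; descriptor magnitudes on real structures will differ (side chains
roughly double atom counts and contact counts).

Default generator conditions (two to three chains, 16–48 atoms per chain,
4 Å inter-chain gap, 0.15 Å jitter, 1.9 Å nominal resolution) are chosen so
adjacent chains form interfaces of a few dozen ACPs — the scale of a small
real interface — while all-pairs verification stays instantaneous.

## Numerical choices and degenerate inputs

- Strict `<` at the contact threshold; two carbons at exactly 4.40 Å are
  not in contact.
- ACP lists are sorted by (serial_a, serial_b) and distances printed to
  3 decimals, so `.int` output is byte-reproducible.
- Empty interfaces cannot be constructed; patch extraction of an empty
  interface raises.
- `.int` files carry atom identity, not geometry: atoms reconstructed from
  them hold placeholder coordinates and must not feed geometric analyses.
- An empty patch scores 0 hydrophobicity and produces no interacting
  positions in role maps.
- SASA of a fully caged atom is exactly 0 (all lattice points rejected).

## Known limitations

- mmCIF is not parsed; biological-assembly expansion and symmetry mates are
  out of scope, so interfaces present only in the assembly are missed.
- Contact typing (hydrogen bonds, salt bridges) and core/rim decomposition
  are not implemented.
- The SCOP parser handles the tab-separated `dir.cla` layout generically; it
  does not track classification-release bookkeeping.
- Sequence-level redundancy reduction (e.g. 30 % identity) is not part of
  the non-redundant build, which is purely structural.
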