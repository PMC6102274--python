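"""Seeded synthetic-structure generator with exact ground-truth contacts.

Structures are built as parallel extended peptide strands: each residue
contributes a 4-atom backbone (N, CA, C, O) spaced 3.8 Å along the strand,
chains are offset laterally by a controllable gap, and every coordinate can
carry seeded jitter.  Real residue names and SEQRES records are emitted so
the same files exercise hydrophobicity, SASA, alignment and role mapping.
The generator evaluates every inter-chain atom pair directly (all-pairs, the
shipped radius table) at generation time, so each file ships with the exact
contact list the pipeline is expected to recover.  Decoration flags inject
the awkward corners of real files: alternate locations, insertion codes,
waters, extra models, SEQRES-only (missing) residues and a nucleic chain.

Randomness enters only through the explicit seed: one spec + seed always
produces byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .contacts import VdwTable
from .structure_io import Atom, format_atom_line

__all__ = ["FixtureSpec", "FixtureSpecError", "GroundTruth", "make_structure",
           "two_atom_structure"]

# backbone atom template: (name, element, local offset in Å)
_BACKBONE = (
    ("N", "N", np.array([-1.20, 0.30, 0.10])),
    ("CA", "C", np.array([0.00, 0.00, 0.00])),
    ("C", "C", np.array([1.20, 0.35, -0.10])),
    ("O", "O", np.array([1.35, 1.55, -0.25])),
)
_RESIDUE_SPACING = 3.8  # Å between consecutive CA atoms along the strand

_STANDARD_NAMES = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR "
    "TRP TYR VAL").split()


class FixtureSpecError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    n_chains: int = 2
    atoms_per_chain: int = 16
    inter_chain_gap: float = 4.0
    jitter: float = 0.15
    seed: int = 0
    tolerance: float = 1.0
    pdb_id: str = "9FIX"
    resolution: Optional[float] = 1.90
    experiment_method: str = "X-RAY DIFFRACTION"
    residue_names: Optional[Tuple[Tuple[str, ...], ...]] = None  # per chain
    # decorations
    altloc: bool = False
    insertion_codes: bool = False
    water: bool = False
    multi_model: bool = False
    seqres_gap: bool = False
    nucleic_chain: bool = False

    def validate(self) -> None:
        if self.n_chains < 1:
            raise FixtureSpecError("n_chains must be >= 1")
        if self.atoms_per_chain < 1:
            raise FixtureSpecError("atoms_per_chain must be >= 1")
        if self.inter_chain_gap < 0 or self.jitter < 0 or self.tolerance < 0:
            raise FixtureSpecError("gap, jitter and tolerance must be non-negative")
        if self.jitter >= self.inter_chain_gap and self.n_chains > 1 and self.jitter > 0:
            raise FixtureSpecError("jitter must stay below the inter-chain gap")
        if self.multi_model and self.altloc:
            # the altloc ground truth is defined on model 1 only; combining the
            # two flags makes the hand-checkable expectations ambiguous
            raise FixtureSpecError("altloc and multi_model decorations are exclusive")
        if self.residue_names is not None:
            if len(self.residue_names) != self.n_chains:
                raise FixtureSpecError("residue_names must give one tuple per chain")
            for names in self.residue_names:
                unknown = [n for n in names if n not in _STANDARD_NAMES]
                if unknown:
                    raise FixtureSpecError(f"non-standard residue names: {unknown}")


@dataclass
class GroundTruth:
    """Exact expected contacts per unordered chain pair, as
    (serial_a, serial_b, distance) triples sorted by serials."""

    acps: Dict[Tuple[str, str], List[Tuple[int, int, float]]]
    tolerance: float

    @property
    def interface_pairs(self) -> List[Tuple[str, str]]:
        return sorted(k for k, v in self.acps.items() if v)

    @property
    def total_acps(self) -> int:
        return sum(len(v) for v in self.acps.values())


def _chain_residue_names(spec: FixtureSpec, rng: np.random.Generator,
                         chain_idx: int, n_residues: int) -> List[str]:
    if spec.residue_names is not None:
        names = list(spec.residue_names[chain_idx])
        if len(names) < n_residues:
            raise FixtureSpecError(
                f"chain {chain_idx}: {len(names)} residue names for "
                f"{n_residues} residues")
        return names[:n_residues]
    return [str(rng.choice(_STANDARD_NAMES)) for _ in range(n_residues)]


def make_structure(spec: FixtureSpec,
                   table: Optional[VdwTable] = None) -> Tuple[str, GroundTruth]:
    """Emit PDB text plus the exact all-pairs contact list for ``spec``."""
    spec.validate()
    table = table or VdwTable.bondi()
    rng = np.random.default_rng(spec.seed)

    serial = 0
    protein_atoms: List[Atom] = []       # contact-eligible, kept conformers
    extra_atoms: List[Atom] = []         # altloc B, waters, nucleic chain
    seqres: Dict[str, List[str]] = {}
    chain_ids = [chr(ord("A") + k) for k in range(spec.n_chains)]

    n_residues = -(-spec.atoms_per_chain // len(_BACKBONE))
    for k, chain_id in enumerate(chain_ids):
        names = _chain_residue_names(spec, rng, k, n_residues)
        seqres[chain_id] = list(names)
        atoms_left = spec.atoms_per_chain
        # insertion-code decoration on chain A: residue index 2 re-uses the
        # previous residue number with iCode 'A'
        keys: List[Tuple[int, str]] = []
        seq_num = 0
        for i in range(n_residues):
            if spec.insertion_codes and chain_id == "A" and i == 2 and seq_num >= 1:
                keys.append((seq_num, "A"))
            else:
                seq_num += 1
                keys.append((seq_num, ""))
        for i in range(n_residues):
            if atoms_left == 0:
                seqres[chain_id] = seqres[chain_id][:i]
                break
            res_seq, icode = keys[i]
            origin = np.array([i * _RESIDUE_SPACING, k * spec.inter_chain_gap,
                               0.6 * (k % 2)])
            for name, element, offset in _BACKBONE:
                if atoms_left == 0:
                    break
                # round to the PDB's 3-decimal precision BEFORE the truth pass,
                # so generated truth and re-parsed coordinates agree exactly
                pos = np.round(
                    origin + offset + rng.uniform(-spec.jitter, spec.jitter, 3), 3)
                serial += 1
                atom = Atom(serial=serial, name=name, element=element, altloc="",
                            residue_name=names[i], chain_id=chain_id,
                            residue_seq=res_seq, insertion_code=icode,
                            position=pos, occupancy=1.0, record_type="ATOM")
                if spec.altloc and chain_id == "A" and serial == 1:
                    # two conformers of the first atom: A at the true spot
                    # (occupancy 0.6, kept), B displaced (0.4, discarded)
                    atom = Atom(serial=serial, name=name, element=element,
                                altloc="A", residue_name=names[i],
                                chain_id=chain_id, residue_seq=res_seq,
                                insertion_code=icode, position=pos,
                                occupancy=0.60, record_type="ATOM")
                    serial += 1
                    extra_atoms.append(Atom(
                        serial=serial, name=name, element=element, altloc="B",
                        residue_name=names[i], chain_id=chain_id,
                        residue_seq=res_seq, insertion_code=icode,
                        position=pos + np.array([0.5, 0.0, 0.0]),
                        occupancy=0.40, record_type="ATOM"))
                protein_atoms.append(atom)
                atoms_left -= 1
        if spec.seqres_gap:
            # SEQRES-only tail residues: observed coordinates never appear
            seqres[chain_id] = seqres[chain_id] + ["GLY", "SER"]

    if spec.nucleic_chain:
        nuc_id = chr(ord("A") + spec.n_chains)
        seqres[nuc_id] = ["DA", "DA"]
        for i in range(2):
            origin = np.array([i * 6.0, -spec.inter_chain_gap, 0.0])
            for name, element, offset in (("P", "P", np.zeros(3)),
                                          ("O5'", "O", np.array([1.2, 0.4, 0.0])),
                                          ("C1'", "C", np.array([2.2, -0.5, 0.3]))):
                serial += 1
                extra_atoms.append(Atom(
                    serial=serial, name=name, element=element, altloc="",
                    residue_name="DA", chain_id=nuc_id, residue_seq=i + 1,
                    insertion_code="", position=origin + offset, occupancy=1.0,
                    record_type="ATOM"))
    if spec.water:
        mid_y = 0.5 * spec.inter_chain_gap if spec.n_chains > 1 else 3.0
        for i, pos in enumerate(
                [np.array([2.0, mid_y, 0.3]), np.array([-30.0, -30.0, 0.0])]):
            serial += 1
            extra_atoms.append(Atom(
                serial=serial, name="O", element="O", altloc="",
                residue_name="HOH", chain_id=chain_ids[0], residue_seq=900 + i,
                insertion_code="", position=pos, occupancy=1.0,
                record_type="HETATM"))

    truth = _ground_truth(protein_atoms, spec.tolerance, table)
    text = _render(spec, protein_atoms, extra_atoms, seqres)
    return text, truth


def _ground_truth(atoms: Sequence[Atom], tolerance: float,
                  table: VdwTable) -> GroundTruth:
    acps: Dict[Tuple[str, str], List[Tuple[int, int, float]]] = {}
    for i, a in enumerate(atoms):
        for b in atoms[i + 1:]:
            if a.chain_id == b.chain_id:
                continue
            dist = float(np.linalg.norm(a.position - b.position))
            if dist < table.radius(a.element) + table.radius(b.element) + tolerance:
                first, second = ((a, b) if a.chain_id < b.chain_id else (b, a))
                key = (first.chain_id, second.chain_id)
                acps.setdefault(key, []).append((first.serial, second.serial, dist))
    for key in acps:
        acps[key].sort()
    return GroundTruth(acps=acps, tolerance=tolerance)


def _render(spec: FixtureSpec, protein_atoms: Sequence[Atom],
            extra_atoms: Sequence[Atom],
            seqres: Dict[str, List[str]]) -> str:
    lines: List[str] = [
        f"HEADER    {'SYNTHETIC FIXTURE':<40}{'':12}{spec.pdb_id:>4}",
        f"EXPDTA    {spec.experiment_method}",
    ]
    if spec.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION.{spec.resolution:9.2f} ANGSTROMS.")
    for chain_id in sorted(seqres):
        names = seqres[chain_id]
        for i in range(0, len(names), 13):
            chunk = " ".join(f"{n:>3}" for n in names[i:i + 13])
            lines.append(
                f"SEQRES {i // 13 + 1:>3} {chain_id} {len(names):>4}  {chunk}")

    all_atoms = sorted(list(protein_atoms) + list(extra_atoms),
                       key=lambda a: a.serial)

    def coordinate_block(shift: float) -> List[str]:
        block = []
        for atom in all_atoms:
            if shift:
                atom = Atom(serial=atom.serial, name=atom.name,
                            element=atom.element, altloc=atom.altloc,
                            residue_name=atom.residue_name,
                            chain_id=atom.chain_id, residue_seq=atom.residue_seq,
                            insertion_code=atom.insertion_code,
                            position=atom.position + np.array([shift, 0.0, 0.0]),
                            occupancy=atom.occupancy, record_type=atom.record_type)
            block.append(format_atom_line(atom))
        return block

    if spec.multi_model:
        for m in range(1, 4):
            lines.append(f"MODEL     {m:>4}")
            lines.extend(coordinate_block(shift=100.0 * (m - 1)))
            lines.append("ENDMDL")
    else:
        lines.extend(coordinate_block(shift=0.0))
    lines.append("END")
    return "\n".join(lines) + "\n"


def two_atom_structure(distance: float, element: str = "C",
                       pdb_id: str = "9TWO") -> str:
    """Minimal two-chain file: one carbon-bearing glycine per chain, their CA
    atoms exactly ``distance`` apart -- the boundary-behaviour probe."""
    atoms = [
        Atom(serial=1, name="CA", element=element, altloc="", residue_name="GLY",
             chain_id="A", residue_seq=1, insertion_code="",
             position=np.zeros(3), occupancy=1.0, record_type="ATOM"),
        Atom(serial=2, name="CA", element=element, altloc="", residue_name="GLY",
             chain_id="B", residue_seq=1, insertion_code="",
             position=np.array([distance, 0.0, 0.0]), occupancy=1.0,
             record_type="ATOM"),
    ]
    lines = [
        f"HEADER    {'SYNTHETIC FIXTURE':<40}{'':12}{pdb_id:>4}",
        "EXPDTA    X-RAY DIFFRACTION",
        f"REMARK   2 RESOLUTION.{1.50:9.2f} ANGSTROMS.",
    ]
    lines.extend(format_atom_line(a) for a in atoms)
    lines.append("END")
    return "\n".join(lines) + "\n"
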