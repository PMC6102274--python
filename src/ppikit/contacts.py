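"""Atomic contact pairs, interfaces and patches.

Two atoms on different protein chains form an atomic contact pair (ACP) when
their separation is strictly less than the sum of their van der Waals radii
plus a tolerance (1 Å by default, absorbing coordinate error and thermal
motion).  The set of all ACPs between one unordered chain pair is an
interface (PPII); the atoms each chain contributes form that chain's patch
(PPIP).

Candidate pairs come from a k-d tree queried at the largest possible
threshold, followed by the exact per-pair radius check, so results are
identical to brute-force enumeration.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Atom, Chain, StructureModel

__all__ = [
    "VdwTable",
    "AtomContactPair",
    "Interface",
    "Patch",
    "contact_threshold",
    "find_acps",
    "build_interfaces",
    "extract_patches",
]

logger = logging.getLogger(__name__)


@dataclass
class VdwTable:
    """Per-element van der Waals radii in Å, with a fallback for elements the
    table does not list."""

    radius_by_element: Dict[str, float]
    default_radius: float = 1.70

    def __post_init__(self) -> None:
        self.radius_by_element = {k.upper(): float(v)
                                  for k, v in self.radius_by_element.items()}
        for elem, r in self.radius_by_element.items():
            if not 0.5 < r < 3.0:
                raise ValueError(f"implausible vdW radius {r} Å for {elem}")
        self._warned: Set[str] = set()

    @classmethod
    def bondi(cls) -> "VdwTable":
        """The bundled Bondi (1964) element radii."""
        text = resources.files("ppikit.data").joinpath("vdw_bondi.tsv").read_text()
        return cls._from_text(text)

    @classmethod
    def from_file(cls, path) -> "VdwTable":
        with open(path) as fh:
            return cls._from_text(fh.read())

    @classmethod
    def _from_text(cls, text: str) -> "VdwTable":
        radii = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            elem, value = line.split("\t")
            radii[elem.upper()] = float(value)
        return cls(radius_by_element=radii)

    def radius(self, element: str) -> float:
        element = element.upper()
        try:
            return self.radius_by_element[element]
        except KeyError:
            if element not in self._warned:
                logger.warning(
                    "element %s not in vdW table; using default radius %.2f Å",
                    element, self.default_radius)
                self._warned.add(element)
            return self.default_radius

    @property
    def max_radius(self) -> float:
        return max(self.radius_by_element.values())

    @property
    def checksum(self) -> str:
        canonical = ";".join(
            f"{e}={self.radius_by_element[e]:.4f}"
            for e in sorted(self.radius_by_element)) + f";default={self.default_radius:.4f}"
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class AtomContactPair:
    atom_a: Atom
    atom_b: Atom
    distance: float

    def __post_init__(self) -> None:
        if self.atom_a.chain_id == self.atom_b.chain_id:
            raise ValueError("ACP atoms must come from different chains")
        if self.distance <= 0:
            raise ValueError("ACP distance must be positive")

    def swapped(self) -> "AtomContactPair":
        return AtomContactPair(self.atom_b, self.atom_a, self.distance)


@dataclass
class Interface:
    pdb_id: str
    chain_pair: Tuple[str, str]
    acps: List[AtomContactPair]

    def __post_init__(self) -> None:
        a, b = self.chain_pair
        if not a < b:
            raise ValueError(f"chain_pair {self.chain_pair} not lexicographic")
        for acp in self.acps:
            if (acp.atom_a.chain_id, acp.atom_b.chain_id) != (a, b):
                raise ValueError("ACP chains do not match the interface chain pair")

    @classmethod
    def from_acps(cls, pdb_id: str, acps: Sequence[AtomContactPair]) -> "Interface":
        """Canonicalize: order the chain pair lexicographically and swap ACP
        members so atom_a always sits on the first chain."""
        if not acps:
            raise ValueError("cannot build an interface from zero ACPs")
        c1, c2 = acps[0].atom_a.chain_id, acps[0].atom_b.chain_id
        if c1 > c2:
            acps = [acp.swapped() for acp in acps]
            c1, c2 = c2, c1
        acps = sorted(acps, key=lambda p: (p.atom_a.serial, p.atom_b.serial))
        return cls(pdb_id=pdb_id, chain_pair=(c1, c2), acps=list(acps))

    @property
    def acp_count(self) -> int:
        return len(self.acps)


@dataclass
class Patch:
    """One chain's side of an interface: the atoms (and the residues they
    belong to) that appear in at least one ACP."""

    chain_id: str
    interacting_atoms: List[Atom]
    interacting_residues: FrozenSet[Tuple[int, str]] = field(init=False)

    def __post_init__(self) -> None:
        self.interacting_residues = frozenset(
            a.residue_key for a in self.interacting_atoms)

    @property
    def residue_count(self) -> int:
        return len(self.interacting_residues)


def contact_threshold(atom_a: Atom, atom_b: Atom, tolerance: float = 1.0,
                      table: Optional[VdwTable] = None) -> float:
    """Distance below which two atoms are in contact: r(a) + r(b) + tolerance."""
    if tolerance < 0:
        raise ValueError(f"tolerance must be non-negative, got {tolerance}")
    table = table or VdwTable.bondi()
    return table.radius(atom_a.element) + table.radius(atom_b.element) + tolerance


def _contact_atoms(chain: Chain, include_hetatm: bool,
                   include_hydrogens: bool) -> List[Atom]:
    atoms = []
    for res in chain.residues:
        if not (res.is_standard or include_hetatm):
            continue
        for atom in res.atoms:
            if atom.is_hydrogen and not include_hydrogens:
                continue
            atoms.append(atom)
    return atoms


def find_acps(chain_a: Chain, chain_b: Chain, tolerance: float = 1.0,
              table: Optional[VdwTable] = None, *,
              include_hetatm: bool = False,
              include_hydrogens: bool = False) -> List[AtomContactPair]:
    """All ACPs between two chains, sorted by (serial_a, serial_b).

    Non-protein residues and hydrogens are excluded by default; 2.5 Å crystal
    structures rarely resolve hydrogens, and ligands are not part of the
    protein-protein interface.
    """
    if tolerance < 0:
        raise ValueError(f"tolerance must be non-negative, got {tolerance}")
    if chain_a.chain_id == chain_b.chain_id:
        raise ValueError("find_acps requires two distinct chains")
    table = table or VdwTable.bondi()
    atoms_a = _contact_atoms(chain_a, include_hetatm, include_hydrogens)
    atoms_b = _contact_atoms(chain_b, include_hetatm, include_hydrogens)
    if not atoms_a or not atoms_b:
        return []
    coords_a = np.array([a.position for a in atoms_a])
    coords_b = np.array([b.position for b in atoms_b])
    radii_a = np.array([table.radius(a.element) for a in atoms_a])
    radii_b = np.array([table.radius(b.element) for b in atoms_b])
    # conservative candidate radius covers the largest possible threshold
    query_radius = radii_a.max() + radii_b.max() + tolerance
    tree_b = cKDTree(coords_b)
    candidates = tree_b.query_ball_point(coords_a, r=query_radius)
    acps: List[AtomContactPair] = []
    for i, neighbours in enumerate(candidates):
        if not neighbours:
            continue
        d = np.linalg.norm(coords_b[neighbours] - coords_a[i], axis=1)
        thr = radii_a[i] + radii_b[np.asarray(neighbours)] + tolerance
        for j, dist, t in zip(neighbours, d, thr):
            if dist < t:
                acps.append(AtomContactPair(atoms_a[i], atoms_b[j], float(dist)))
    acps.sort(key=lambda p: (p.atom_a.serial, p.atom_b.serial))
    return acps


def build_interfaces(model: StructureModel, tolerance: float = 1.0,
                     table: Optional[VdwTable] = None, min_acps: int = 1, *,
                     include_hetatm: bool = False,
                     include_hydrogens: bool = False) -> List[Interface]:
    """Deconvolute a multimer into its binary interfaces.

    One :class:`Interface` per unordered protein-chain pair with at least
    ``min_acps`` contacts; ``min_acps=21`` reproduces the non-redundant-subset
    precondition (interfaces with more than 20 ACPs).
    """
    table = table or VdwTable.bondi()
    chains = sorted(model.protein_chains, key=lambda c: c.chain_id)
    interfaces: List[Interface] = []
    for i in range(len(chains)):
        for j in range(i + 1, len(chains)):
            acps = find_acps(chains[i], chains[j], tolerance, table,
                             include_hetatm=include_hetatm,
                             include_hydrogens=include_hydrogens)
            if len(acps) >= min_acps and acps:
                interfaces.append(Interface.from_acps(model.pdb_id, acps))
    return interfaces


def extract_patches(interface: Interface) -> Tuple[Patch, Patch]:
    """The two patches of an interface: per chain, the atoms in >= 1 ACP."""
    if not interface.acps:
        raise ValueError("cannot extract patches from an empty interface")
    seen_a: Dict[int, Atom] = {}
    seen_b: Dict[int, Atom] = {}
    for acp in interface.acps:
        seen_a.setdefault(acp.atom_a.serial, acp.atom_a)
        seen_b.setdefault(acp.atom_b.serial, acp.atom_b)
    patch_a = Patch(interface.chain_pair[0],
                    [seen_a[s] for s in sorted(seen_a)])
    patch_b = Patch(interface.chain_pair[1],
                    [seen_b[s] for s in sorted(seen_b)])
    return patch_a, patch_b
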