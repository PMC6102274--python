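"""Patch-level descriptors: residue count, solvent accessibility, hydrophobicity,
inter-patch sequence similarity, and the binning used to profile them.

SASA follows Shrake-Rupley with a deterministic Fibonacci-lattice point set
and a 1.4 Å water probe, evaluated on the isolated chain (the partner removed)
so the number reads as the surface the patch devotes to binding.  The
hydrophobicity score is a plain sum of per-residue values on a
translocon-derived scale where isoleucine (-0.60) is the most and aspartate
(3.49) the least hydrophobic residue; lower patch totals therefore mean more
hydrophobic patches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .contacts import Interface, Patch, VdwTable, extract_patches
from .structure_io import Chain, THREE_TO_ONE

__all__ = [
    "HydrophobicityScale",
    "PatchSummary",
    "Interval",
    "BinSpec",
    "RESIDUE_BINS",
    "SASA_BINS",
    "HYDROPHOBICITY_BINS",
    "SIMILARITY_BINS",
    "hydrophobicity_score",
    "shrake_rupley",
    "patch_sasa",
    "chain_sasa",
    "sequence_identity_pct",
    "patch_similarity",
    "classify_dimer",
    "summarize_patch",
    "bin_distribution",
]

logger = logging.getLogger(__name__)


@dataclass
class HydrophobicityScale:
    score_by_residue: Dict[str, float]

    def __post_init__(self) -> None:
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.score_by_residue)
        if missing:
            raise ValueError(f"scale missing residues: {sorted(missing)}")

    @classmethod
    def hessa(cls) -> "HydrophobicityScale":
        """The bundled translocon (Hessa et al.) scale."""
        text = resources.files("ppikit.data").joinpath("hessa_scale.tsv").read_text()
        scores = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            aa, value = line.split("\t")
            scores[aa] = float(value)
        return cls(score_by_residue=scores)

    def score(self, one_letter: str) -> float:
        return self.score_by_residue[one_letter]


@dataclass
class PatchSummary:
    residue_count: int
    sasa: float
    hydrophobicity: float
    similarity_to_partner: float

    def __post_init__(self) -> None:
        if self.sasa < 0:
            raise ValueError("SASA cannot be negative")
        if not 0.0 <= self.similarity_to_partner <= 100.0:
            raise ValueError("similarity must lie in [0, 100]")


# ---------------------------------------------------------------------------
# hydrophobicity

def hydrophobicity_score(patch: Patch, chain: Chain,
                         scale: Optional[HydrophobicityScale] = None) -> float:
    """Sum of per-residue scale values over the patch's interacting residues.

    Non-standard residues that cannot be mapped to a one-letter code are
    skipped with a warning.
    """
    if patch.chain_id != chain.chain_id:
        raise ValueError(
            f"patch chain {patch.chain_id!r} does not match chain {chain.chain_id!r}")
    scale = scale or HydrophobicityScale.hessa()
    total = 0.0
    for key in sorted(patch.interacting_residues):
        res = chain.residue(key)
        one = THREE_TO_ONE.get(res.name)
        if one is None:
            logger.warning("skipping non-standard residue %s %s in hydrophobicity sum",
                           res.name, key)
            continue
        total += scale.score(one)
    return total


# ---------------------------------------------------------------------------
# SASA

def _fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set (golden-angle spiral)."""
    i = np.arange(n_points, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n_points
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = phi * i
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def shrake_rupley(coords: np.ndarray, radii: np.ndarray, probe: float = 1.4,
                  n_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area, Å².

    Test points are placed on each atom's solvent sphere (radius + probe) and
    rejected when inside any neighbour's solvent sphere; the accessible
    fraction scales the sphere area.
    """
    if n_points < 100:
        raise ValueError("n_points < 100 gives unacceptable discretization error")
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    sphere = _fibonacci_sphere(n_points)
    solvent_r = radii + probe
    out = np.zeros(n)
    if n == 0:
        return out
    tree = cKDTree(coords)
    max_reach = 2.0 * solvent_r.max()
    neighbour_lists = tree.query_ball_point(coords, r=max_reach)
    for i in range(n):
        pts = coords[i] + solvent_r[i] * sphere
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbour_lists[i]:
            if j == i:
                continue
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 >= solvent_r[j] ** 2
        out[i] = 4.0 * np.pi * solvent_r[i] ** 2 * accessible.mean()
    return out


def _sasa_atoms(chain: Chain):
    return [a for r in chain.residues if r.is_standard
            for a in r.atoms if not a.is_hydrogen]


def chain_sasa(chain: Chain, probe: float = 1.4, n_points: int = 960,
               table: Optional[VdwTable] = None,
               context: Optional[Sequence] = None) -> Dict[Tuple[int, str], float]:
    """Per-residue SASA of a chain; ``context`` atoms occlude but do not
    contribute area (used for the in-complex reading)."""
    table = table or VdwTable.bondi()
    atoms = _sasa_atoms(chain)
    extra = [a for a in (context or []) if not a.is_hydrogen]
    all_atoms = atoms + extra
    coords = np.array([a.position for a in all_atoms])
    radii = np.array([table.radius(a.element) for a in all_atoms])
    per_atom = shrake_rupley(coords, radii, probe=probe, n_points=n_points)
    per_res: Dict[Tuple[int, str], float] = {}
    for atom, area in zip(atoms, per_atom[:len(atoms)]):
        per_res[atom.residue_key] = per_res.get(atom.residue_key, 0.0) + float(area)
    return per_res


def patch_sasa(patch: Patch, chain: Chain, probe: float = 1.4,
               n_points: int = 960, table: Optional[VdwTable] = None,
               delta: bool = False, partner: Optional[Chain] = None) -> float:
    """SASA (Å²) summed over the patch's interacting residues.

    Default reading: the isolated chain, partner removed.  With
    ``delta=True`` (and ``partner`` given) the value is instead the area
    buried on complexation: isolated minus in-complex.
    """
    if patch.chain_id != chain.chain_id:
        raise ValueError(
            f"patch chain {patch.chain_id!r} does not match chain {chain.chain_id!r}")
    isolated = chain_sasa(chain, probe=probe, n_points=n_points, table=table)
    total = sum(isolated.get(key, 0.0) for key in patch.interacting_residues)
    if not delta:
        return total
    if partner is None:
        raise ValueError("delta SASA requires the partner chain")
    bound = chain_sasa(chain, probe=probe, n_points=n_points, table=table,
                       context=_sasa_atoms(partner))
    bound_total = sum(bound.get(key, 0.0) for key in patch.interacting_residues)
    return total - bound_total


# ---------------------------------------------------------------------------
# sequence similarity

def _global_aligner():
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def sequence_identity_pct(seq_a: str, seq_b: str,
                          denominator: str = "alignment") -> float:
    """Percent identity from one deterministic global alignment.

    ``denominator="alignment"`` divides by the alignment length including gap
    columns; ``"shorter"`` divides by the shorter sequence's length (the
    greedy-clustering convention).
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    alignment = _global_aligner().align(seq_a, seq_b)[0]
    identities = alignment.counts().identities
    if denominator == "alignment":
        denom = alignment.length
    elif denominator == "shorter":
        denom = min(len(seq_a), len(seq_b))
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return 100.0 * identities / denom


def patch_similarity(chain_a: Chain, chain_b: Chain) -> float:
    """Whole-chain sequence similarity between the two sides of an interface:
    100 x identical aligned positions / alignment length (gaps included)."""
    seq_a, seq_b = chain_a.observed_sequence, chain_b.observed_sequence
    if not seq_a or not seq_b:
        raise ValueError("both chains need at least one observed residue")
    return sequence_identity_pct(seq_a, seq_b, denominator="alignment")


# ---------------------------------------------------------------------------
# binning

@dataclass(frozen=True)
class Interval:
    label: str
    lo: float
    hi: float
    lo_inclusive: bool = True
    hi_inclusive: bool = False

    def contains(self, value: float) -> bool:
        above = value >= self.lo if self.lo_inclusive else value > self.lo
        below = value <= self.hi if self.hi_inclusive else value < self.hi
        return above and below


@dataclass(frozen=True)
class BinSpec:
    name: str
    intervals: Tuple[Interval, ...]

    def __post_init__(self) -> None:
        ivals = sorted(self.intervals, key=lambda iv: iv.lo)
        for prev, cur in zip(ivals, ivals[1:]):
            if cur.lo < prev.hi or (cur.lo == prev.hi
                                    and cur.lo_inclusive and prev.hi_inclusive):
                raise ValueError(f"bins overlap in {self.name}")

    def bin_of(self, value: float) -> str:
        for interval in self.intervals:
            if interval.contains(value):
                return interval.label
        raise ValueError(f"{self.name}: value {value} falls in no bin")

    @property
    def labels(self) -> List[str]:
        return [iv.label for iv in self.intervals]


_INF = float("inf")

RESIDUE_BINS = BinSpec("interacting residues", (
    Interval("1-5", 1, 5, True, True),
    Interval("6-20", 6, 20, True, True),
    Interval("21-40", 21, 40, True, True),
    Interval("41-60", 41, 60, True, True),
    Interval(">60", 60, _INF, False, False),
))

SASA_BINS = BinSpec("patch SASA (Å²)", (
    Interval("<=1000", -_INF, 1000, False, True),
    Interval("1001-2000", 1000, 2000, False, True),
    Interval("2001-3000", 2000, 3000, False, True),
    Interval(">3000", 3000, _INF, False, False),
))

HYDROPHOBICITY_BINS = BinSpec("hydrophobicity score", (
    Interval("<=10", -_INF, 10, False, True),
    Interval("11-20", 10, 20, False, True),
    Interval("21+", 20, _INF, False, False),
))

SIMILARITY_BINS = BinSpec("sequence similarity (%)", (
    Interval("0-25", 0, 25, True, False),
    Interval("25-50", 25, 50, True, False),
    Interval("50-75", 50, 75, True, False),
    Interval("75-100", 75, 100, True, True),
))

HOMOLOGY_THRESHOLD = 75.0


def classify_dimer(similarity: float) -> Tuple[str, str]:
    """Homologous (homodimer-like) at similarity >= 75, else heterologous;
    returns (class, similarity bin).  75 belongs to '75-100'."""
    label = "homologous" if similarity >= HOMOLOGY_THRESHOLD else "heterologous"
    return label, SIMILARITY_BINS.bin_of(similarity)


def summarize_patch(interface: Interface, which_side: int, chain: Chain,
                    partner: Chain,
                    scale: Optional[HydrophobicityScale] = None,
                    probe: float = 1.4, n_points: int = 960,
                    table: Optional[VdwTable] = None) -> PatchSummary:
    """All four descriptors for one side (0 or 1) of an interface."""
    if which_side not in (0, 1):
        raise ValueError("which_side must be 0 or 1")
    patch = extract_patches(interface)[which_side]
    return PatchSummary(
        residue_count=patch.residue_count,
        sasa=patch_sasa(patch, chain, probe=probe, n_points=n_points, table=table),
        hydrophobicity=hydrophobicity_score(patch, chain, scale=scale),
        similarity_to_partner=patch_similarity(chain, partner),
    )


def bin_distribution(values: Sequence[float], spec: BinSpec) -> Dict[str, Tuple[int, float]]:
    """Counts and percentages per bin; counts are conserved and percentages
    sum to 100."""
    values = list(values)
    if not values:
        raise ValueError("no patches")
    counts = {label: 0 for label in spec.labels}
    for v in values:
        counts[spec.bin_of(v)] += 1
    n = len(values)
    return {label: (c, 100.0 * c / n) for label, c in counts.items()}
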