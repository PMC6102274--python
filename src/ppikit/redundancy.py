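"""SCOP superfamily assignment and the non-redundant interface subset.

Every interface is labelled with the unordered pair of SCOP superfamilies of
its two chains; per superfamily pair, only the interface with the most atomic
contact pairs is kept, and interfaces with 20 or fewer contacts are dropped
beforehand.  A chain carrying several superfamily domains contributes its
interface to every pair in the Cartesian product.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Set, Tuple

from .contacts import Interface

__all__ = [
    "ScopAssignment",
    "SuperfamilyPair",
    "NrdbEntry",
    "ScopParseError",
    "parse_scop_cla",
    "assign_pairs",
    "build_nrdb",
]

logger = logging.getLogger(__name__)

SuperfamilyPair = Tuple[int, int]


class ScopParseError(ValueError):
    pass


@dataclass
class ScopAssignment:
    """(pdb_id lowercased, chain_id) -> set of superfamily ids.  A chain may
    carry several ids when its domains fall in different superfamilies."""

    by_chain: Dict[Tuple[str, str], Set[int]]

    def superfamilies(self, pdb_id: str, chain_id: str) -> Set[int]:
        return self.by_chain.get((pdb_id.lower(), chain_id), set())

    def __len__(self) -> int:
        return len(self.by_chain)


def parse_scop_cla(stream) -> ScopAssignment:
    """Parse a SCOP ``dir.cla`` classification file.

    Tab-separated columns: sid, pdb_id, chain:range, sccs, sunid, node list
    (``cl=...,cf=...,sf=...,...``).  Lines starting with '#' are comments.
    Chain ranges collapse to the bare chain id; the superfamily id comes from
    the ``sf=`` token.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    by_chain: Dict[Tuple[str, str], Set[int]] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise ScopParseError(f"line {lineno}: expected >= 6 tab-separated fields")
        pdb_id = fields[1].strip().lower()
        chain_field = fields[2].strip()
        sf_id: Optional[int] = None
        for token in fields[5].split(","):
            token = token.strip()
            if token.startswith("sf="):
                sf_id = int(token[3:])
                break
        if sf_id is None:
            raise ScopParseError(f"line {lineno}: no sf= token in node list")
        for part in chain_field.split(","):
            chain_id = part.split(":")[0].strip()
            if not chain_id or chain_id == "-":
                continue
            by_chain.setdefault((pdb_id, chain_id), set()).add(sf_id)
    return ScopAssignment(by_chain=by_chain)


def canonical_pair(a: int, b: int) -> SuperfamilyPair:
    return (a, b) if a <= b else (b, a)


def assign_pairs(interface: Interface, scop: ScopAssignment) -> List[SuperfamilyPair]:
    """Superfamily pairs for an interface: the canonicalized, deduplicated
    Cartesian product of the two chains' superfamily sets.  Empty (and logged)
    when either chain is unclassified."""
    c1, c2 = interface.chain_pair
    sfs1 = scop.superfamilies(interface.pdb_id, c1)
    sfs2 = scop.superfamilies(interface.pdb_id, c2)
    if not sfs1 or not sfs2:
        logger.info("interface %s %s_%s unclassified in SCOP; excluded",
                    interface.pdb_id, c1, c2)
        return []
    pairs = {canonical_pair(a, b) for a in sfs1 for b in sfs2}
    return sorted(pairs)


@dataclass
class NrdbEntry:
    superfamily_pair: SuperfamilyPair
    representative: Interface
    acp_count: int
    members: int

    def __post_init__(self) -> None:
        if self.representative.acp_count != self.acp_count:
            raise ValueError("acp_count does not match the representative")


def build_nrdb(interfaces: List[Interface], scop: ScopAssignment,
               min_acps: int = 21) -> List[NrdbEntry]:
    """One maximum-ACP representative interface per superfamily pair.

    Interfaces with fewer than ``min_acps`` contacts are dropped first (the
    default keeps interfaces with more than 20).  Ties on the ACP count break
    lexicographically on (pdb_id, chain_pair), so the build is deterministic
    under any input ordering.  An interface with multi-superfamily chains may
    represent several pairs.
    """
    surviving = [i for i in interfaces if i.acp_count >= min_acps]
    groups: Dict[SuperfamilyPair, List[Interface]] = {}
    for interface in surviving:
        for pair in assign_pairs(interface, scop):
            groups.setdefault(pair, []).append(interface)
    entries: List[NrdbEntry] = []
    for pair in sorted(groups):
        members = groups[pair]
        representative = min(
            members, key=lambda i: (-i.acp_count, i.pdb_id, i.chain_pair))
        entries.append(NrdbEntry(
            superfamily_pair=pair,
            representative=representative,
            acp_count=representative.acp_count,
            members=len(members),
        ))
    return entries
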