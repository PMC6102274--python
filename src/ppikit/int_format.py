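"""Reader/writer for the interface (``.int``) file dialect.

One file per interface, named ``<chain1>_<chain2>_<PDBID>.int`` with the
chain pair in lexicographic order (the interface between A and B is stored
once, never twice).  The header carries provenance; the body lists one atomic
contact pair per line with the inter-atomic distance.  Output is
byte-deterministic: rows are sorted by atom serials and distances are printed
to 3 decimals, so identical inputs always produce identical files.

Header (lines prefixed '#'): format version, pdb_id, chains, tolerance,
radii-table checksum, acp_count.  Body columns (tab-separated): serial_a,
name_a, resname_a, chain_a, resseq_a, icode_a, serial_b, name_b, resname_b,
chain_b, resseq_b, icode_b, distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .contacts import AtomContactPair, Interface
from .structure_io import Atom

__all__ = ["IntFile", "IntFormatError", "int_filename", "write_int", "read_int"]

FORMAT_LINE = "#format: ppikit-int v1"


class IntFormatError(ValueError):
    pass


@dataclass
class IntFile:
    interface: Interface
    tolerance: float
    radii_checksum: str

    @property
    def filename(self) -> str:
        return int_filename(self.interface)


def int_filename(interface: Interface) -> str:
    c1, c2 = interface.chain_pair
    return f"{c1}_{c2}_{interface.pdb_id.upper()}.int"


def _body_row(acp: AtomContactPair) -> str:
    a, b = acp.atom_a, acp.atom_b
    return "\t".join([
        str(a.serial), a.name, a.residue_name, a.chain_id,
        str(a.residue_seq), a.insertion_code or ".",
        str(b.serial), b.name, b.residue_name, b.chain_id,
        str(b.residue_seq), b.insertion_code or ".",
        f"{acp.distance:.3f}",
    ])


def write_int(interface: Interface, tolerance: float = 1.0,
              radii_checksum: str = "") -> str:
    """Serialize an interface; rows sorted by (serial_a, serial_b)."""
    acps = sorted(interface.acps,
                  key=lambda p: (p.atom_a.serial, p.atom_b.serial))
    lines = [
        FORMAT_LINE,
        f"#pdb_id: {interface.pdb_id.upper()}",
        f"#chains: {interface.chain_pair[0]}_{interface.chain_pair[1]}",
        f"#tolerance: {tolerance:.3f}",
        f"#radii_sha256: {radii_checksum or 'unknown'}",
        f"#acp_count: {len(acps)}",
    ]
    lines.extend(_body_row(acp) for acp in acps)
    return "\n".join(lines) + "\n"


def _atom_from_fields(serial: str, name: str, resname: str, chain: str,
                      resseq: str, icode: str) -> Atom:
    # .int files carry atom identity, not geometry: position/occupancy are
    # placeholders and must not be used downstream of a read.
    return Atom(
        serial=int(serial), name=name, element=name[0].upper() or "X",
        altloc="", residue_name=resname, chain_id=chain,
        residue_seq=int(resseq), insertion_code="" if icode == "." else icode,
        position=np.zeros(3), occupancy=1.0, record_type="ATOM",
    )


def read_int(text: str) -> IntFile:
    """Parse ``.int`` text; raises on header/body count mismatch or malformed
    rows (message names the row)."""
    header = {}
    acps: List[AtomContactPair] = []
    pdb_id: Optional[str] = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            if line == FORMAT_LINE:
                continue
            try:
                key, value = line[1:].split(":", 1)
            except ValueError:
                raise IntFormatError(f"line {lineno}: malformed header line")
            header[key.strip()] = value.strip()
            continue
        fields = line.split("\t")
        if len(fields) != 13:
            raise IntFormatError(
                f"line {lineno}: expected 13 tab-separated columns, got {len(fields)}")
        try:
            atom_a = _atom_from_fields(*fields[0:6])
            atom_b = _atom_from_fields(*fields[6:12])
            distance = float(fields[12])
        except (ValueError, TypeError) as exc:
            raise IntFormatError(f"line {lineno}: malformed body row: {exc}") from exc
        acps.append(AtomContactPair(atom_a, atom_b, distance))
    for key in ("pdb_id", "chains", "tolerance", "acp_count"):
        if key not in header:
            raise IntFormatError(f"missing header field #{key}")
    declared = int(header["acp_count"])
    if declared != len(acps):
        raise IntFormatError(
            f"header declares {declared} ACPs but body has {len(acps)}")
    if not acps:
        raise IntFormatError("empty interface file")
    interface = Interface.from_acps(header["pdb_id"], acps)
    expected_chains = tuple(header["chains"].split("_"))
    if interface.chain_pair != expected_chains:
        raise IntFormatError(
            f"header chains {expected_chains} do not match body {interface.chain_pair}")
    return IntFile(
        interface=interface,
        tolerance=float(header["tolerance"]),
        radii_checksum=header.get("radii_sha256", "unknown"),
    )
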