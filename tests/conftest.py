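import numpy as np
import pytest
from hypothesis import settings

from ppikit.contacts import AtomContactPair, VdwTable
from ppikit.structure_io import Atom

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bondi():
    return VdwTable.bondi()


def make_atom(serial, chain_id, position, element="C", name="CA",
              residue_name="GLY", residue_seq=1, insertion_code="",
              occupancy=1.0, altloc="", record_type="ATOM"):
    """Terse Atom constructor for hand-built geometries."""
    return Atom(serial=serial, name=name, element=element, altloc=altloc,
                residue_name=residue_name, chain_id=chain_id,
                residue_seq=residue_seq, insertion_code=insertion_code,
                position=np.asarray(position, dtype=float),
                occupancy=occupancy, record_type=record_type)


def brute_force_acps(chain_a, chain_b, tolerance, table):
    """Independent all-pairs contact oracle: plain double loop, no spatial
    index, no shared code with ppikit.contacts.find_acps internals."""
    pairs = []
    for res_a in chain_a.residues:
        if not res_a.is_standard:
            continue
        for atom_a in res_a.atoms:
            if atom_a.element in ("H", "D"):
                continue
            for res_b in chain_b.residues:
                if not res_b.is_standard:
                    continue
                for atom_b in res_b.atoms:
                    if atom_b.element in ("H", "D"):
                        continue
                    d = float(np.linalg.norm(atom_a.position - atom_b.position))
                    thr = (table.radius(atom_a.element)
                           + table.radius(atom_b.element) + tolerance)
                    if d < thr:
                        pairs.append((atom_a.serial, atom_b.serial, d))
    pairs.sort()
    return pairs


def acp_triples(acps):
    return sorted((p.atom_a.serial, p.atom_b.serial, p.distance) for p in acps)
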