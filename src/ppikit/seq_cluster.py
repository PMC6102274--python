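"""Greedy incremental sequence clustering at an identity threshold, with
head-based homolog lookup.

The procedure mirrors the classic greedy-incremental scheme: sequences are
visited longest-first, each joins the first existing cluster whose head it
matches at or above the threshold, otherwise it founds a new cluster as head.
Identity is identities divided by the shorter sequence's length.  The k-mer
pre-filter of the original tool is not reproduced; every comparison is an
exact global alignment, which is affordable at desk-scale corpora.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, NamedTuple, Sequence, Tuple

from .patch_analytics import sequence_identity_pct

__all__ = [
    "SeqRecord",
    "SeqCluster",
    "greedy_cluster",
    "find_homologs",
    "read_fasta",
    "write_fasta",
    "write_clstr",
    "parse_clstr",
    "clusters_to_tsv",
]


class SeqRecord(NamedTuple):
    id: str
    seq: str


@dataclass
class SeqCluster:
    head: SeqRecord
    members: List[Tuple[SeqRecord, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            self.members = [(self.head, 100.0)]

    @property
    def size(self) -> int:
        return len(self.members)


def _identity(a: str, b: str) -> float:
    return sequence_identity_pct(a, b, denominator="shorter")


def greedy_cluster(records: Sequence[SeqRecord],
                   threshold: float = 90.0) -> List[SeqCluster]:
    """Cluster sequences so every member matches its (longest-first) head at
    >= ``threshold`` percent identity.  Deterministic: processing order is
    descending length, ties broken by record id."""
    for rec in records:
        if not rec.seq:
            raise ValueError(f"record {rec.id!r} has an empty sequence")
    ordered = sorted(records, key=lambda r: (-len(r.seq), r.id))
    clusters: List[SeqCluster] = []
    for rec in ordered:
        placed = False
        for cluster in clusters:
            identity = _identity(rec.seq, cluster.head.seq)
            if identity >= threshold:
                cluster.members.append((rec, identity))
                placed = True
                break
        if not placed:
            clusters.append(SeqCluster(head=rec))
    return clusters


def find_homologs(query: str, clusters: Sequence[SeqCluster],
                  threshold: float = 90.0) -> List[Tuple[str, float]]:
    """Cluster heads matching the query at >= threshold identity, best first."""
    if not query:
        raise ValueError("query sequence is empty")
    hits = []
    for cluster in clusters:
        identity = _identity(query, cluster.head.seq)
        if identity >= threshold:
            hits.append((cluster.head.id, identity))
    hits.sort(key=lambda h: (-h[1], h[0]))
    return hits


# ---------------------------------------------------------------------------
# I/O

def read_fasta(path) -> List[SeqRecord]:
    from Bio import SeqIO

    return [SeqRecord(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[SeqRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), 60):
                fh.write(rec.seq[i:i + 60] + "\n")


def write_clstr(clusters: Sequence[SeqCluster]) -> str:
    """CD-HIT ``.clstr``-style text: '*' marks the head, members carry their
    identity to it."""
    lines: List[str] = []
    for idx, cluster in enumerate(clusters):
        lines.append(f">Cluster {idx}")
        for midx, (rec, identity) in enumerate(cluster.members):
            if rec.id == cluster.head.id:
                lines.append(f"{midx}\t{len(rec.seq)}aa, >{rec.id}... *")
            else:
                lines.append(f"{midx}\t{len(rec.seq)}aa, >{rec.id}... at {identity:.2f}%")
    return "\n".join(lines) + "\n"


def parse_clstr(text: str, sequences: dict) -> List[SeqCluster]:
    """Rebuild clusters from ``.clstr`` text; ``sequences`` maps id -> seq."""
    clusters: List[SeqCluster] = []
    pending: List[Tuple[str, float, bool]] = []

    def flush():
        if not pending:
            return
        head_id = next(i for i, _, is_head in pending if is_head)
        head = SeqRecord(head_id, sequences[head_id])
        members = [(SeqRecord(i, sequences[i]), ident) for i, ident, _ in pending]
        clusters.append(SeqCluster(head=head, members=members))

    for line in text.splitlines():
        if line.startswith(">Cluster"):
            flush()
            pending = []
        elif line.strip():
            _, rest = line.split("\t", 1)
            rec_id = rest.split(">")[1].split("...")[0]
            if rest.rstrip().endswith("*"):
                pending.append((rec_id, 100.0, True))
            else:
                identity = float(rest.rstrip().rstrip("%").rsplit(" ", 1)[1])
                pending.append((rec_id, identity, False))
    flush()
    return clusters


def clusters_to_tsv(clusters: Sequence[SeqCluster]) -> str:
    lines = ["cluster\tmember_id\tlength\tidentity_to_head\tis_head"]
    for idx, cluster in enumerate(clusters):
        for rec, identity in cluster.members:
            lines.append(f"{idx}\t{rec.id}\t{len(rec.seq)}\t{identity:.2f}\t"
                         f"{int(rec.id == cluster.head.id)}")
    return "\n".join(lines) + "\n"
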