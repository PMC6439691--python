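"""UMI family clustering and PCR-duplicate collapse.

Reads sharing alignment coordinates are clustered on their unique molecular
identifiers with the directional-adjacency rule: within one coordinate
bucket a UMI is absorbed into a higher-count UMI at Hamming distance
<= ``max_edit`` when ``count_child <= count_parent / 2 + 1``.  Each family
is then collapsed to a single consensus molecule (per-position majority
base, maximum member quality), which removes PCR duplicates and most
polymerase/sequencer substitution errors before pileup.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

_BASES = "ACGT"
# uint8 ASCII codes for A, C, G, T used by the vectorised consensus
_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(slots=True)
class UMIRead:
    """One aligned read (or read pair collapsed to its fragment sequence)."""

    read_id: str
    umi: str
    amplicon_id: str
    contig: str
    start: int
    seq: str
    qual: str  # phred+33
    mapq: int

    def __post_init__(self) -> None:
        if len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.read_id}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )


@dataclass
class UMIFamily:
    """Reads sharing (corrected UMI, alignment coordinates)."""

    umi: str
    amplicon_id: str
    contig: str
    start: int
    reads: list[UMIRead]
    has_n: bool = False
    consensus_seq: str | None = None
    consensus_qual: str | None = None
    member_umis: tuple[str, ...] = field(default_factory=tuple)

    @property
    def size(self) -> int:
        return len(self.reads)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("UMIs of unequal length")
    return sum(x != y for x, y in zip(a, b))


def _one_sub_variants(umi: str):
    """All strings at Hamming distance exactly 1, in deterministic
    (position, base) order."""
    for i in range(len(umi)):
        for b in _BASES:
            if b != umi[i]:
                yield umi[:i] + b + umi[i + 1 :]


def cluster_umis(counts: dict[str, int], max_edit: int = 1) -> list[list[str]]:
    """Directional-adjacency clustering of a UMI count table.

    Seeds are visited by (count descending, UMI lexicographic); from each
    seed a breadth-first search absorbs unassigned UMIs within Hamming
    distance ``max_edit`` of the current node whose count satisfies
    ``count_child <= count_node / 2 + 1``.  The canonical visiting order
    makes the partition independent of input order.
    """
    if max_edit < 0:
        raise ValueError("max_edit must be >= 0")
    order = sorted(counts, key=lambda u: (-counts[u], u))
    if max_edit == 0:
        return [[u] for u in order]

    umis = set(counts)
    assigned: set[str] = set()
    clusters: list[list[str]] = []
    for seed in order:
        if seed in assigned:
            continue
        group = [seed]
        assigned.add(seed)
        queue = [seed]
        while queue:
            node = queue.pop(0)
            if max_edit == 1:
                neighbours = (v for v in _one_sub_variants(node) if v in umis)
            else:
                neighbours = sorted(
                    v for v in umis if v not in assigned and hamming(node, v) <= max_edit
                )
            for nb in neighbours:
                if nb in assigned:
                    continue
                if counts[nb] <= counts[node] / 2 + 1:
                    assigned.add(nb)
                    group.append(nb)
                    queue.append(nb)
        clusters.append(group)
    return clusters


def group_umis(reads: list[UMIRead], max_edit: int = 1) -> list[UMIFamily]:
    """Partition reads into UMI families within (amplicon, contig, start)
    buckets.  Reads with ``N`` in the UMI are never merged: each distinct
    N-containing UMI forms its own flagged family.
    """
    buckets: dict[tuple[str, str, int], list[UMIRead]] = defaultdict(list)
    for r in reads:
        buckets[(r.amplicon_id, r.contig, r.start)].append(r)

    families: list[UMIFamily] = []
    for (amplicon_id, contig, start) in sorted(buckets):
        bucket = buckets[(amplicon_id, contig, start)]
        by_umi: dict[str, list[UMIRead]] = defaultdict(list)
        n_umis: dict[str, list[UMIRead]] = defaultdict(list)
        for r in bucket:
            if "N" in r.umi:
                n_umis[r.umi].append(r)
            else:
                by_umi[r.umi].append(r)
        for umi in sorted(n_umis):
            families.append(
                UMIFamily(umi, amplicon_id, contig, start, n_umis[umi], has_n=True,
                          member_umis=(umi,))
            )
        counts = {u: len(rs) for u, rs in by_umi.items()}
        for cluster in cluster_umis(counts, max_edit=max_edit):
            members: list[UMIRead] = []
            for u in cluster:
                members.extend(by_umi[u])
            families.append(
                UMIFamily(cluster[0], amplicon_id, contig, start, members,
                          member_umis=tuple(cluster))
            )
    return families


def _consensus(seqs: list[str], quals: list[str]) -> tuple[str, str]:
    """Per-position majority base, per-position maximum quality.

    A position with no unique majority (e.g. a 1-1 split in a two-read
    family) is ambiguous evidence and becomes ``N`` at quality 0, so it
    can never vote in the pileup."""
    if len(set(seqs)) == 1:
        if len(set(quals)) == 1:
            return seqs[0], quals[0]
        qarr = np.frombuffer("".join(quals).encode(), dtype=np.uint8)
        qmax = qarr.reshape(len(quals), -1).max(axis=0)
        return seqs[0], qmax.tobytes().decode()
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)
    tallies = np.stack([(arr == c).sum(axis=0) for c in _BASE_CODES])
    best = np.argmax(tallies, axis=0)
    top = tallies.max(axis=0)
    tie = (tallies == top).sum(axis=0) > 1
    cons = _BASE_CODES[best]
    qarr = np.frombuffer("".join(quals).encode(), dtype=np.uint8)
    qmax = qarr.reshape(len(quals), -1).max(axis=0)
    # no ACGT observed at all (all members N): keep N
    tie |= top == 0
    if tie.any():
        cons = np.where(tie, ord("N"), cons)
        qmax = np.where(tie, ord("!"), qmax)
    return cons.tobytes().decode(), qmax.tobytes().decode()


def dedup(families: list[UMIFamily], min_family_size: int = 1) -> list[UMIRead]:
    """Collapse each UMI family to one consensus read.

    Families smaller than ``min_family_size`` are dropped.  The consensus
    read inherits the family's coordinates and corrected UMI; its mapping
    quality is the maximum over members.
    """
    if min_family_size < 1:
        raise ValueError("min_family_size must be >= 1")
    out: list[UMIRead] = []
    for fam in families:
        if fam.size < min_family_size:
            continue
        seqs = [r.seq for r in fam.reads]
        quals = [r.qual for r in fam.reads]
        cons_seq, cons_qual = _consensus(seqs, quals)
        fam.consensus_seq = cons_seq
        fam.consensus_qual = cons_qual
        out.append(
            UMIRead(
                read_id=f"{fam.amplicon_id}:{fam.start}:{fam.umi}",
                umi=fam.umi,
                amplicon_id=fam.amplicon_id,
                contig=fam.contig,
                start=fam.start,
                seq=cons_seq,
                qual=cons_qual,
                mapq=max(r.mapq for r in fam.reads),
            )
        )
    return out
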