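"""Pileup construction and candidate-variant calling on consensus reads.

Calling is deliberately permissive: no allele-frequency threshold, a
minimum alternate read count of 2, and minimum base/mapping quality of 20.
Everything else — population frequency, cohort recurrence, dual-set
concordance, effect class, the VAF window — is the filter cascade's job
(see :mod:`chipcall.filtering`), so that each exclusion is auditable.

VAF is computed as alternate reads / (reference + alternate reads); at a
multi-allelic site each alternate allele gets its own call against the
same reference count.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .panel import SET_A, SET_B, AmpliconPanel
from .umi import UMIRead

logger = logging.getLogger(__name__)

_ALLELES = "ACGT"
_ALLELE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


def compute_vaf(alt_reads: int, ref_reads: int) -> float:
    """Variant allele fraction: alt / (ref + alt)."""
    if alt_reads < 0 or ref_reads < 0:
        raise ValueError("read counts must be non-negative")
    total = alt_reads + ref_reads
    if total == 0:
        raise ValueError("empty locus: ref + alt read count is zero")
    return alt_reads / total


@dataclass
class PileupColumn:
    """Allele counts at one site, tracked per amplicon set and combined."""

    contig: str
    position: int  # 0-based
    ref_base: str
    gene: str | None
    counts: dict[str, int]
    counts_by_set: dict[str, dict[str, int]]
    mean_mapq: float

    @property
    def depth(self) -> int:
        return sum(self.counts.values())

    def set_depth(self, set_label: str) -> int:
        return sum(self.counts_by_set.get(set_label, {}).values())


@dataclass
class VariantCall:
    """One candidate substitution with its evidence and audit trail."""

    contig: str
    position: int  # 0-based
    ref: str
    alt: str
    gene: str | None
    alt_reads: int
    ref_reads: int
    vaf: float
    set_counts: dict[str, tuple[int, int]]  # set_label -> (alt, total depth)
    mean_mapq: float
    patient_id: str | None = None
    effect: str | None = None
    pop_mafs: dict[str, float] = field(default_factory=dict)
    dbsnp_common: bool = False
    filters: list[str] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.position, self.ref, self.alt)

    @property
    def passed(self) -> bool:
        return not self.filters


def build_pileup(
    reads: list[UMIRead],
    panel: AmpliconPanel,
    min_base_quality: int = 20,
    min_mapping_quality: int = 20,
) -> list[PileupColumn]:
    """Column-wise allele counts from consensus reads.

    Bases with quality below ``min_base_quality`` are excluded from counts;
    reads with mapping quality below ``min_mapping_quality`` are excluded
    entirely.  Reads whose amplicon is not in the panel are skipped (the
    skip count is logged).  Counts are kept separately per amplicon set so
    the dual-set concordance filter can act later.
    """
    skipped = 0
    # (contig) -> per-set 4 x L count arrays, plus mapq accumulators
    per_contig: dict[str, dict[str, np.ndarray]] = {}
    mq_sum: dict[str, np.ndarray] = {}
    mq_n: dict[str, np.ndarray] = {}

    groups: dict[tuple[str, str, int, int], list[UMIRead]] = defaultdict(list)
    for r in reads:
        try:
            amp = panel.amplicon(r.amplicon_id)
        except KeyError:
            skipped += 1
            continue
        if r.mapq < min_mapping_quality:
            continue
        groups[(amp.set_label, r.contig, r.start, len(r.seq))].append(r)
    if skipped:
        logger.info("build_pileup: skipped %d reads overlapping no panel amplicon", skipped)

    min_q_byte = 33 + min_base_quality
    for (set_label, contig, start, length), grp in groups.items():
        if contig not in per_contig:
            clen = len(panel.reference[contig])
            per_contig[contig] = {
                SET_A: np.zeros((4, clen), dtype=np.int64),
                SET_B: np.zeros((4, clen), dtype=np.int64),
            }
            mq_sum[contig] = np.zeros(clen, dtype=np.float64)
            mq_n[contig] = np.zeros(clen, dtype=np.int64)
        seq = np.frombuffer("".join(r.seq for r in grp).encode(), dtype=np.uint8)
        seq = seq.reshape(len(grp), length)
        qual = np.frombuffer("".join(r.qual for r in grp).encode(), dtype=np.uint8)
        qual = qual.reshape(len(grp), length)
        ok = qual >= min_q_byte
        sl = slice(start, start + length)
        tgt = per_contig[contig][set_label]
        for i, code in enumerate(_ALLELE_CODES):
            tgt[i, sl] += ((seq == code) & ok).sum(axis=0)
        mapqs = np.array([r.mapq for r in grp], dtype=np.float64)
        mq_sum[contig][sl] += mapqs.sum()
        mq_n[contig][sl] += len(grp)

    columns: list[PileupColumn] = []
    for contig in sorted(per_contig):
        counts_a = per_contig[contig][SET_A]
        counts_b = per_contig[contig][SET_B]
        combined = counts_a + counts_b
        covered = np.nonzero(combined.sum(axis=0))[0]
        ref_seq = panel.reference[contig]
        for pos in covered:
            pos = int(pos)
            cdict = {_ALLELES[i]: int(combined[i, pos]) for i in range(4)}
            col = PileupColumn(
                contig=contig,
                position=pos,
                ref_base=ref_seq[pos],
                gene=panel.gene_at(contig, pos),
                counts=cdict,
                counts_by_set={
                    SET_A: {_ALLELES[i]: int(counts_a[i, pos]) for i in range(4)},
                    SET_B: {_ALLELES[i]: int(counts_b[i, pos]) for i in range(4)},
                },
                mean_mapq=float(mq_sum[contig][pos] / mq_n[contig][pos]),
            )
            columns.append(col)
    return columns


def call_variants(
    pileup: list[PileupColumn],
    min_alt_reads: int = 2,
    patient_id: str | None = None,
) -> list[VariantCall]:
    """Emit a candidate call for every non-reference allele whose combined
    count reaches ``min_alt_reads``.  No VAF bound is applied here."""
    if min_alt_reads < 1:
        raise ValueError("min_alt_reads must be >= 1")
    calls: list[VariantCall] = []
    for col in pileup:
        ref = col.ref_base
        ref_count = col.counts.get(ref, 0)
        for alt in _ALLELES:
            if alt == ref:
                continue
            alt_count = col.counts.get(alt, 0)
            if alt_count < min_alt_reads:
                continue
            set_counts = {}
            for label in (SET_A, SET_B):
                sc = col.counts_by_set.get(label, {})
                set_counts[label] = (sc.get(alt, 0), sum(sc.values()))
            calls.append(
                VariantCall(
                    contig=col.contig,
                    position=col.position,
                    ref=ref,
                    alt=alt,
                    gene=col.gene,
                    alt_reads=alt_count,
                    ref_reads=ref_count,
                    vaf=compute_vaf(alt_count, ref_count),
                    set_counts=set_counts,
                    mean_mapq=col.mean_mapq,
                    patient_id=patient_id,
                )
            )
    return calls
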