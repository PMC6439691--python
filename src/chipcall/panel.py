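"""Amplicon panel model.

The assay targets recurrently mutated clonal-hematopoiesis genes with a
dual-strand amplicon design: every variant-bearing region is covered by two
independent primer sets (``CAT_A`` and ``CAT_B``), so that a genuine somatic
variant must be observed in both sets while strand- or primer-specific
artifacts appear in only one.  Internally all coordinates are 0-based
half-open; conversion to 1-based happens only at VCF/TSV boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SET_A = "CAT_A"
SET_B = "CAT_B"
SET_LABELS = (SET_A, SET_B)

_BASES = "ACGT"


@dataclass(frozen=True)
class Amplicon:
    """One amplicon: a half-open interval on a panel contig, tagged with the
    gene it targets and the primer set it belongs to."""

    amplicon_id: str
    gene: str
    contig: str
    start: int
    end: int
    set_label: str

    def __post_init__(self) -> None:
        if self.set_label not in SET_LABELS:
            raise ValueError(
                f"amplicon {self.amplicon_id}: set_label must be one of "
                f"{SET_LABELS}, got {self.set_label!r}"
            )
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"amplicon {self.amplicon_id}: invalid interval "
                f"[{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def covers(self, contig: str, position: int) -> bool:
        return contig == self.contig and self.start <= position < self.end


class AmpliconPanel:
    """A set of amplicons plus the mini-reference they are defined on.

    Parameters
    ----------
    amplicons:
        Amplicon definitions.  Each targeted site must be covered by at
        least one ``CAT_A`` and one ``CAT_B`` amplicon for the dual-set
        concordance filter to be meaningful; :meth:`sets_covering` exposes
        which sets cover a given site.
    reference:
        Mapping contig name -> uppercase ACGT sequence.
    """

    def __init__(self, amplicons: list[Amplicon], reference: dict[str, str]):
        for amp in amplicons:
            if amp.contig not in reference:
                raise ValueError(f"amplicon {amp.amplicon_id}: unknown contig {amp.contig}")
            if amp.end > len(reference[amp.contig]):
                raise ValueError(
                    f"amplicon {amp.amplicon_id}: interval [{amp.start}, {amp.end}) "
                    f"exceeds contig {amp.contig} length {len(reference[amp.contig])}"
                )
        self.amplicons = list(amplicons)
        self.reference = dict(reference)
        self._by_id = {a.amplicon_id: a for a in self.amplicons}
        if len(self._by_id) != len(self.amplicons):
            raise ValueError("duplicate amplicon_id in panel")

    def __len__(self) -> int:
        return len(self.amplicons)

    def amplicon(self, amplicon_id: str) -> Amplicon:
        return self._by_id[amplicon_id]

    def amplicons_covering(self, contig: str, position: int) -> list[Amplicon]:
        return [a for a in self.amplicons if a.covers(contig, position)]

    def sets_covering(self, contig: str, position: int) -> set[str]:
        return {a.set_label for a in self.amplicons_covering(contig, position)}

    def gene_at(self, contig: str, position: int) -> str | None:
        for a in self.amplicons:
            if a.covers(contig, position):
                return a.gene
        return None

    def ref_base(self, contig: str, position: int) -> str:
        return self.reference[contig][position]

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.amplicons:
            seen.setdefault(a.gene, None)
        return list(seen)


DEFAULT_GENES = ("DNMT3A", "TET2", "ASXL1", "TP53")


def toy_panel(
    genes: tuple[str, ...] = DEFAULT_GENES,
    contig_length: int = 400,
    amplicon_length: int = 140,
    overlap_offset: int = 20,
    seed: int = 0,
) -> AmpliconPanel:
    """Build a desk-scale dual-set panel: one synthetic contig per gene and
    one amplicon per set, staggered so both sets share a central region.

    The shared region (where both sets cover) spans
    ``[100 + overlap_offset, 100 + amplicon_length)`` on each contig; spiked
    variants must fall inside it to survive dual-set filtering.
    """
    rng = np.random.default_rng(seed)
    reference: dict[str, str] = {}
    amplicons: list[Amplicon] = []
    for gene in genes:
        seq = "".join(rng.choice(list(_BASES), size=contig_length))
        reference[gene] = seq
        a_start = 100
        b_start = 100 + overlap_offset
        amplicons.append(
            Amplicon(f"{gene}_A", gene, gene, a_start, a_start + amplicon_length, SET_A)
        )
        amplicons.append(
            Amplicon(f"{gene}_B", gene, gene, b_start, b_start + amplicon_length, SET_B)
        )
    return AmpliconPanel(amplicons, reference)


def dual_set_region(panel: AmpliconPanel, gene: str) -> tuple[str, int, int]:
    """Return (contig, start, end) of the region of ``gene`` covered by both
    amplicon sets; raises if the gene lacks one of the sets."""
    amps = [a for a in panel.amplicons if a.gene == gene]
    a_amps = [a for a in amps if a.set_label == SET_A]
    b_amps = [a for a in amps if a.set_label == SET_B]
    if not a_amps or not b_amps:
        raise ValueError(f"gene {gene} lacks amplicons in one set")
    start = max(min(a.start for a in a_amps), min(b.start for b in b_amps))
    end = min(max(a.end for a in a_amps), max(b.end for b in b_amps))
    if start >= end:
        raise ValueError(f"gene {gene}: amplicon sets do not overlap")
    return a_amps[0].contig, start, end
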