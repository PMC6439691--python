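"""The variant filter cascade.

Candidate calls from the permissive caller are reduced to the clonal-
hematopoiesis call set by a fixed sequence of rules, each of which stamps
its tag on the first call it removes so the whole cascade is auditable:

=========  ==============================================================
tag        rule
=========  ==============================================================
POP_MAF    population minor allele frequency >= 5% in any of the three
           population databases (1000 Genomes / EVS / ExAC stand-ins)
MQ20       mean mapping quality < 20
RECUR8     same variant in >= 8% of patients in the cohort (technical
           artifact)
DUALSET    covered by < 100 reads in either amplicon set, or alternate
           support meeting the calling minimum in only one set
SETGAP     the site is covered by amplicons of only one set (panel-design
           gap, distinct from missing evidence)
DBSNP      flagged common (>= 1% population frequency) in dbSNP
EFFECT     predicted effect class LOW or MODIFIER
VAFWIN     VAF below the floor (0.02, or 0.005 for the low-clone-size
           analysis) or inside the germline band [0.45, 0.55]
=========  ==============================================================

Cohort recurrence is evaluated on pre-VAF-window candidates so that an
artifact recurring at any clonal size is caught.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .calling import VariantCall
from .panel import SET_A, SET_B, AmpliconPanel

EFFECT_CLASSES = ("HIGH", "MODERATE", "LOW", "MODIFIER")
MAF_SOURCES = ("KG1000", "EVS", "ExAC")

FLAG_POP_MAF = "POP_MAF"
FLAG_MQ = "MQ20"
FLAG_RECURRENCE = "RECUR8"
FLAG_DUAL_SET = "DUALSET"
FLAG_SET_GAP = "SETGAP"
FLAG_DBSNP = "DBSNP"
FLAG_EFFECT = "EFFECT"
FLAG_VAF_WINDOW = "VAFWIN"

CASCADE_ORDER = (
    FLAG_POP_MAF,
    FLAG_MQ,
    FLAG_RECURRENCE,
    FLAG_DUAL_SET,
    FLAG_DBSNP,
    FLAG_EFFECT,
    FLAG_VAF_WINDOW,
)


@dataclass
class FilterConfig:
    """Every threshold of the cascade in one validated object."""

    pop_maf_max: float = 0.05
    cohort_recurrence_max: float = 0.08
    map_quality_min: float = 20.0
    min_coverage_per_set: int = 100
    min_alt_per_set: int = 2
    dbsnp_common_maf: float = 0.01
    excluded_effects: frozenset = frozenset({"LOW", "MODIFIER"})
    vaf_min: float = 0.02
    low_vaf_floor: float = 0.005
    germline_band: tuple[float, float] = (0.45, 0.55)

    def __post_init__(self) -> None:
        lo, hi = self.germline_band
        if not (0 < self.low_vaf_floor < self.vaf_min < lo < hi < 1):
            raise ValueError(
                "require 0 < low_vaf_floor < vaf_min < germline_band.lower "
                "< germline_band.upper < 1"
            )
        for name in ("pop_maf_max", "cohort_recurrence_max", "dbsnp_common_maf"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.min_coverage_per_set < 1 or self.min_alt_per_set < 1:
            raise ValueError("per-set minimum counts must be >= 1")
        unknown = set(self.excluded_effects) - set(EFFECT_CLASSES)
        if unknown:
            raise ValueError(f"unknown effect classes: {sorted(unknown)}")


@dataclass(frozen=True)
class Annotation:
    pop_mafs: dict = field(default_factory=dict)  # source -> MAF
    dbsnp_common: bool = False
    effect: str = "HIGH"


_ABSENT = Annotation(pop_mafs={}, dbsnp_common=False, effect="HIGH")


class AnnotationTable:
    """Site annotations keyed by (contig, 0-based position, ref, alt).

    Lookups are total: an unannotated variant is treated as absent from the
    population databases (MAF 0, not dbSNP-common) with effect ``HIGH``.
    """

    def __init__(self, entries: dict[tuple[str, int, str, str], Annotation] | None = None):
        self._entries = dict(entries or {})

    def lookup(self, contig: str, position: int, ref: str, alt: str) -> Annotation:
        return self._entries.get((contig, position, ref, alt), _ABSENT)

    def __len__(self) -> int:
        return len(self._entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnnotationTable":
        """Load from TSV with columns contig, pos_1based, ref, alt,
        maf_kg1000, maf_evs, maf_exac, dbsnp_common, effect."""
        entries = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                key = (row["contig"], int(row["pos_1based"]) - 1, row["ref"], row["alt"])
                entries[key] = Annotation(
                    pop_mafs={
                        "KG1000": float(row["maf_kg1000"]),
                        "EVS": float(row["maf_evs"]),
                        "ExAC": float(row["maf_exac"]),
                    },
                    dbsnp_common=row["dbsnp_common"].strip() in ("1", "true", "True"),
                    effect=row["effect"],
                )
        return cls(entries)


def annotate_calls(calls: list[VariantCall], ann: AnnotationTable) -> None:
    """Attach population MAFs, dbSNP flag and effect class to each call."""
    for v in calls:
        a = ann.lookup(v.contig, v.position, v.ref, v.alt)
        v.pop_mafs = dict(a.pop_mafs)
        v.dbsnp_common = a.dbsnp_common
        v.effect = a.effect


# ---------------------------------------------------------------- predicates
# Each returns True when the call PASSES the rule.

def filter_population_maf(v: VariantCall, cfg: FilterConfig) -> bool:
    return not any(maf >= cfg.pop_maf_max for maf in v.pop_mafs.values())


def filter_mapping_quality(v: VariantCall, cfg: FilterConfig) -> bool:
    return v.mean_mapq >= cfg.map_quality_min


def filter_dbsnp(v: VariantCall, cfg: FilterConfig) -> bool:
    return not v.dbsnp_common


def filter_effect(v: VariantCall, cfg: FilterConfig) -> bool:
    effect = v.effect if v.effect is not None else "HIGH"
    return effect not in cfg.excluded_effects


def filter_annotation(v: VariantCall, cfg: FilterConfig) -> bool:
    """Combined annotation rule: dbSNP-common, excluded effect class, or low
    mapping quality all fail."""
    return filter_dbsnp(v, cfg) and filter_effect(v, cfg) and filter_mapping_quality(v, cfg)


def dual_set_status(v: VariantCall, cfg: FilterConfig,
                    panel: AmpliconPanel | None = None) -> str | None:
    """Return None when the dual-set rule passes, else the failing flag.

    ``SETGAP`` (site covered by amplicons of only one set) is reported when
    a panel is supplied and shows the design gap; otherwise insufficient
    evidence in either set fails as ``DUALSET``.
    """
    if panel is not None:
        sets = panel.sets_covering(v.contig, v.position)
        if sets != {SET_A, SET_B}:
            return FLAG_SET_GAP
    for label in (SET_A, SET_B):
        alt, depth = v.set_counts.get(label, (0, 0))
        if depth < cfg.min_coverage_per_set:
            return FLAG_DUAL_SET
        if alt < cfg.min_alt_per_set:
            return FLAG_DUAL_SET
    return None


def filter_dual_set(v: VariantCall, cfg: FilterConfig,
                    panel: AmpliconPanel | None = None) -> bool:
    return dual_set_status(v, cfg, panel) is None


def filter_vaf_window(v: VariantCall, cfg: FilterConfig,
                      vaf_floor: float | None = None) -> bool:
    """Pass iff VAF >= floor and outside the closed germline band."""
    floor = cfg.vaf_min if vaf_floor is None else vaf_floor
    lo, hi = cfg.germline_band
    if v.vaf < floor:
        return False
    return not (lo <= v.vaf <= hi)


def recurrent_keys(calls: list[VariantCall], cfg: FilterConfig,
                   cohort_size: int) -> set[tuple[str, int, str, str]]:
    """Variant keys carried by >= ``cohort_recurrence_max`` of the cohort's
    patients (distinct patients; ties at the threshold fail)."""
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    carriers: dict[tuple[str, int, str, str], set[str]] = {}
    for v in calls:
        if v.patient_id is None:
            raise ValueError("patient_id required for the recurrence rule")
        carriers.setdefault(v.key, set()).add(v.patient_id)
    return {
        key
        for key, pats in carriers.items()
        if len(pats) / cohort_size >= cfg.cohort_recurrence_max
    }


def filter_cohort_recurrence(calls: list[VariantCall], cfg: FilterConfig,
                             cohort_size: int) -> dict[tuple[str, int, str, str], bool]:
    """Per-key pass/fail for the recurrence rule (True = pass)."""
    bad = recurrent_keys(calls, cfg, cohort_size)
    return {v.key: v.key not in bad for v in calls}


# ------------------------------------------------------------------ cascade

def run_cascade(
    calls: list[VariantCall],
    ann: AnnotationTable,
    cfg: FilterConfig,
    cohort_size: int,
    vaf_floor: float | None = None,
    panel: AmpliconPanel | None = None,
) -> tuple[list[VariantCall], pd.DataFrame]:
    """Apply the full cascade in fixed order and return (survivors, audit).

    Each removed call carries its first failing rule's tag in
    ``call.filters``; the audit table lists per-rule removal counts which,
    together with the survivor count, sum to the input count.
    """
    annotate_calls(calls, ann)
    bad_keys = recurrent_keys(calls, cfg, cohort_size) if calls else set()

    removed = {flag: 0 for flag in CASCADE_ORDER}
    removed[FLAG_SET_GAP] = 0
    survivors: list[VariantCall] = []
    for v in calls:
        v.filters = []
        if not filter_population_maf(v, cfg):
            v.filters.append(FLAG_POP_MAF)
        elif not filter_mapping_quality(v, cfg):
            v.filters.append(FLAG_MQ)
        elif v.key in bad_keys:
            v.filters.append(FLAG_RECURRENCE)
        elif (flag := dual_set_status(v, cfg, panel)) is not None:
            v.filters.append(flag)
        elif not filter_dbsnp(v, cfg):
            v.filters.append(FLAG_DBSNP)
        elif not filter_effect(v, cfg):
            v.filters.append(FLAG_EFFECT)
        elif not filter_vaf_window(v, cfg, vaf_floor):
            v.filters.append(FLAG_VAF_WINDOW)
        if v.filters:
            removed[v.filters[0]] += 1
        else:
            survivors.append(v)

    rows = [
        {"rule": flag, "removed": removed[flag]}
        for flag in (*CASCADE_ORDER[:4], FLAG_SET_GAP, *CASCADE_ORDER[4:])
    ]
    rows.append({"rule": "PASS", "removed": len(survivors)})
    audit = pd.DataFrame(rows)
    audit["input_total"] = len(calls)
    return survivors, audit
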