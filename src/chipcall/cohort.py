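"""Patient-level clonal-hematopoiesis classification and summary tables.

A patient is a CHIP carrier when at least one variant survives the filter
cascade at the active VAF floor.  Clone size is summarised as the maximum
VAF over the patient's driver-gene (by default DNMT3A/TET2) calls and
discretised into dose bands for the clone-size/outcome analysis:

* ``none``            — no driver call above 0.005
* ``vaf_0.005_0.01``  — greater than 0.005 and below 0.01
* ``vaf_0.01_0.02``   — at least 0.01 and below 0.02
* ``vaf_ge_0.02``     — at least 0.02 (the conventional CHIP threshold)

Under the all-heterozygous model a clone at VAF v comprises 2v of
nucleated cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .calling import VariantCall

DRIVER_GENES = frozenset({"DNMT3A", "TET2"})

BAND_NONE = "none"
BAND_LOW = "vaf_0.005_0.01"
BAND_MID = "vaf_0.01_0.02"
BAND_HIGH = "vaf_ge_0.02"
BAND_ORDER = (BAND_NONE, BAND_LOW, BAND_MID, BAND_HIGH)


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Exact-arithmetic percentage rounded half-up to ``decimals`` places."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    q = Decimal(1).scaleb(-decimals)
    value = (Decimal(100) * Decimal(numerator) / Decimal(denominator)).quantize(
        q, rounding=ROUND_HALF_UP
    )
    return float(value)


def cell_fraction_from_vaf(vaf: float) -> float:
    """Fraction of nucleated cells carrying a heterozygous mutation at the
    given VAF: 2 * vaf.  Raises above 0.5, where the heterozygous model is
    violated."""
    if not 0 <= vaf <= 0.5:
        raise ValueError(
            f"vaf {vaf} outside [0, 0.5]: heterozygous single-clone model violated"
        )
    return 2.0 * vaf


@dataclass
class PatientRecord:
    """Clinical covariates, follow-up, and derived CHIP status."""

    patient_id: str
    age: float
    sex: str = "M"
    hypertension: bool = False
    hyperlipidemia: bool = False
    diabetes: bool = False
    smoking: bool = False
    nt_probnp: float | None = None
    shfm: float | None = None
    follow_up_years: float = 0.0
    died: bool = False
    rehosp: bool = False
    rehosp_time: float | None = None
    # derived
    chip_status: bool | None = None
    driver_genes: tuple[str, ...] = ()
    mutated_genes: tuple[str, ...] = ()
    n_mutations: int = 0
    max_driver_vaf: float | None = None
    vaf_band: str = BAND_NONE
    # simulator truth (None on real data)
    true_chip: bool | None = None
    true_max_driver_vaf: float | None = None

    def __post_init__(self) -> None:
        if self.follow_up_years < 0:
            raise ValueError(f"patient {self.patient_id}: negative follow-up")
        if self.rehosp_time is not None and self.rehosp_time > self.follow_up_years + 1e-9:
            raise ValueError(
                f"patient {self.patient_id}: rehospitalization after end of follow-up"
            )

    @property
    def composite_time(self) -> float:
        """Time to death or heart-failure rehospitalization, whichever first."""
        if self.rehosp and self.rehosp_time is not None:
            return min(self.rehosp_time, self.follow_up_years)
        return self.follow_up_years

    @property
    def composite_event(self) -> bool:
        return self.died or self.rehosp


def classify_patients(
    calls: list[VariantCall],
    patients: list[PatientRecord],
    vaf_floor: float = 0.02,
    driver_genes: frozenset[str] = DRIVER_GENES,
) -> list[PatientRecord]:
    """Derive per-patient CHIP status from cascade survivors.

    A patient is a carrier when at least one surviving call has
    VAF >= ``vaf_floor``; multi-mutation patients count once.  The maximum
    VAF over calls in ``driver_genes`` is recorded for dose banding.
    Raises when a call names a patient missing from the clinical table.
    """
    by_patient: dict[str, list[VariantCall]] = {}
    known = {p.patient_id for p in patients}
    for v in calls:
        if v.patient_id not in known:
            raise ValueError(f"call for unknown patient {v.patient_id!r}")
        by_patient.setdefault(v.patient_id, []).append(v)

    for p in patients:
        mine = [v for v in by_patient.get(p.patient_id, []) if v.vaf >= vaf_floor]
        p.chip_status = bool(mine)
        p.n_mutations = len(mine)
        genes = sorted({v.gene for v in mine if v.gene})
        p.mutated_genes = tuple(genes)
        p.driver_genes = tuple(g for g in genes if g in driver_genes)
        driver_vafs = [v.vaf for v in mine if v.gene in driver_genes]
        p.max_driver_vaf = max(driver_vafs) if driver_vafs else None
    return patients


def prevalence_by_age(
    patients: list[PatientRecord],
    decade_starts: tuple[int, ...] = (40, 50, 60, 70, 80),
) -> pd.DataFrame:
    """Carrier prevalence per age-decade bin.

    Returns a table with columns bin, carriers, n, percent (one decimal,
    half-up).  Patients outside every bin are omitted; bin counts therefore
    sum to the number of patients whose age falls in a listed decade.
    """
    rows = []
    for start in decade_starts:
        in_bin = [p for p in patients if start <= p.age < start + 10]
        n = len(in_bin)
        carriers = sum(1 for p in in_bin if p.chip_status)
        rows.append(
            {
                "bin": f"{start}-{start + 9}",
                "carriers": carriers,
                "n": n,
                "percent": percent(carriers, n) if n else 0.0,
            }
        )
    return pd.DataFrame(rows)


def gene_proportions(calls: list[VariantCall]) -> pd.Series:
    """Mutation count per gene over the surviving call set (mutations, not
    patients: a patient with two DNMT3A clones contributes two)."""
    counts: dict[str, int] = {}
    for v in calls:
        gene = v.gene or "unassigned"
        counts[gene] = counts.get(gene, 0) + 1
    return pd.Series(counts, dtype="int64").sort_values(ascending=False)


def assign_band(max_driver_vaf: float | None) -> str:
    if max_driver_vaf is None or max_driver_vaf <= 0.005:
        return BAND_NONE
    if max_driver_vaf < 0.01:
        return BAND_LOW
    if max_driver_vaf < 0.02:
        return BAND_MID
    return BAND_HIGH


def vaf_band_stratify(patients: list[PatientRecord]) -> list[PatientRecord]:
    """Assign each patient a clone-size band from the maximum driver VAF
    (set by :func:`classify_patients`, run at the 0.005 floor)."""
    for p in patients:
        p.vaf_band = assign_band(p.max_driver_vaf)
    return patients


def patients_to_frame(patients: list[PatientRecord]) -> pd.DataFrame:
    """Flatten patient records to a DataFrame (TSV-friendly)."""
    rows = []
    for p in patients:
        rows.append(
            {
                "patient_id": p.patient_id,
                "age": p.age,
                "sex": p.sex,
                "hypertension": int(p.hypertension),
                "hyperlipidemia": int(p.hyperlipidemia),
                "diabetes": int(p.diabetes),
                "smoking": int(p.smoking),
                "nt_probnp": p.nt_probnp,
                "shfm": p.shfm,
                "follow_up_years": p.follow_up_years,
                "died": int(p.died),
                "rehosp": int(p.rehosp),
                "rehosp_time": p.rehosp_time,
                "chip_status": None if p.chip_status is None else int(p.chip_status),
                "n_mutations": p.n_mutations,
                "mutated_genes": ",".join(p.mutated_genes),
                "max_driver_vaf": p.max_driver_vaf,
                "vaf_band": p.vaf_band,
                "true_chip": None if p.true_chip is None else int(p.true_chip),
            }
        )
    return pd.DataFrame(rows)
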