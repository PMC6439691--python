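"""Synthetic read and cohort generation with machine-readable truth.

Reads
-----
Each original DNA molecule of an amplicon gets a UMI drawn uniformly from
a pool (default the full 4^6 space of 6-mers) and is observed as a
geometric number of PCR duplicates (default mean 6.8, matching the
observed raw-to-consensus depth contraction of roughly 4282x to 630x).
Spiked variants are carried by a Binomial(molecules, true_vaf) subset of
molecules; sequencing substitution errors hit each read base independently
and a small fraction of read UMIs receive a single-base corruption so the
directional clustering stage has real work to do.

Cohorts
-------
Patients get truncated-normal ages, decade-binned CHIP carrier status
(calibrated to the observed prevalence rise with age: about 10% in the
50s, 21% in the 60s, 27% in the 70s), and exponential event times whose
hazard is baseline x HR^carrier (or band-specific HRs for clone-size
dose-response studies), with exponential-plus-administrative censoring
calibrated to a median follow-up near 4.4 years.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cohort import PatientRecord, assign_band, BAND_LOW, BAND_MID, BAND_HIGH
from .panel import AmpliconPanel
from .umi import UMIRead

_BASES = "ACGT"
_BASE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)

ORIGIN_SOMATIC = "somatic_clone"
ORIGIN_GERMLINE = "germline_het"

GERMLINE_BAND = (0.45, 0.55)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one spiked variant."""

    patient_id: str
    gene: str
    contig: str
    position: int  # 0-based
    ref: str
    alt: str
    true_vaf: float
    origin: str

    def __post_init__(self) -> None:
        if self.origin == ORIGIN_SOMATIC:
            if not 0 < self.true_vaf < 0.45:
                raise ValueError(
                    f"somatic_clone true_vaf must be in (0, 0.45), got {self.true_vaf}"
                )
        elif self.origin == ORIGIN_GERMLINE:
            lo, hi = GERMLINE_BAND
            if not lo <= self.true_vaf <= hi:
                raise ValueError(
                    f"germline_het true_vaf must be in [{lo}, {hi}], got {self.true_vaf}"
                )
        else:
            raise ValueError(f"unknown origin {self.origin!r}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")


def _umi_from_index(idx: np.ndarray, length: int) -> list[str]:
    """Map pool indices to UMI strings by base-4 digits."""
    digits = np.empty((idx.size, length), dtype=np.uint8)
    rem = idx.copy()
    for k in range(length - 1, -1, -1):
        digits[:, k] = rem % 4
        rem //= 4
    chars = _BASE_LUT[digits]
    return [row.tobytes().decode() for row in chars]


def simulate_reads(
    panel: AmpliconPanel,
    truth: list[TruthRecord],
    depth_per_set: int = 630,
    umi_length: int = 6,
    umi_pool_size: int = 4**6,
    error_rate: float = 1e-3,
    seed: int = 0,
    duplicate_mean: float = 6.8,
    umi_corruption_rate: float = 0.01,
    base_quality: int = 30,
    mapping_quality: int = 60,
) -> tuple[list[UMIRead], list[TruthRecord]]:
    """Simulate UMI-tagged amplicon reads with spiked variants.

    ``depth_per_set`` is the number of original molecules per amplicon
    (i.e. the target consensus depth contributed by each amplicon set);
    raw read depth is about ``duplicate_mean`` times higher.  Returns the
    reads and the truth table unchanged.
    """
    if depth_per_set < 1:
        raise ValueError("depth_per_set must be >= 1")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    if umi_pool_size < 1 or umi_pool_size > 4**umi_length:
        raise ValueError("umi_pool_size must be in [1, 4^umi_length]")
    somatic = [t for t in truth if t.origin == ORIGIN_SOMATIC]
    if somatic and error_rate > 0:
        min_vaf = min(t.true_vaf for t in somatic)
        if error_rate >= min_vaf / 5:
            raise ValueError(
                f"error_rate {error_rate} too high to resolve the smallest "
                f"spiked clone (true_vaf {min_vaf}); require error_rate < true_vaf / 5"
            )
    for t in truth:
        if not panel.amplicons_covering(t.contig, t.position):
            raise ValueError(
                f"truth variant at {t.contig}:{t.position} lies outside every panel amplicon"
            )
    if umi_pool_size < depth_per_set:
        warnings.warn(
            f"umi_pool_size {umi_pool_size} below molecule count {depth_per_set}: "
            "UMI collisions will merge distinct molecules",
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    reads: list[UMIRead] = []
    patient = truth[0].patient_id if truth else "sample"

    for amp in panel.amplicons:
        ref_seq = panel.reference[amp.contig][amp.start : amp.end]
        L = amp.length
        m = depth_per_set
        base = np.frombuffer(ref_seq.encode(), dtype=np.uint8)
        mol = np.tile(base, (m, 1))

        site_truth = [
            t for t in truth
            if t.contig == amp.contig and amp.start <= t.position < amp.end
        ]
        for t in site_truth:
            carriers = rng.random(m) < t.true_vaf
            mol[carriers, t.position - amp.start] = ord(t.alt)

        umi_idx = rng.integers(0, umi_pool_size, size=m)
        umis = _umi_from_index(umi_idx, umi_length)

        dup = rng.geometric(1.0 / duplicate_mean, size=m)
        read_mol = np.repeat(np.arange(m), dup)
        R = read_mol.size
        read_seq = mol[read_mol].copy()

        if error_rate > 0:
            n_err = rng.binomial(L, error_rate, size=R)
            total = int(n_err.sum())
            if total:
                err_read = np.repeat(np.arange(R), n_err)
                err_pos = rng.integers(0, L, size=total)
                old = read_seq[err_read, err_pos]
                old_code = np.searchsorted(_BASE_LUT, old)
                new_code = (old_code + rng.integers(1, 4, size=total)) % 4
                read_seq[err_read, err_pos] = _BASE_LUT[new_code]

        corrupt = rng.random(R) < umi_corruption_rate
        qual = chr(33 + base_quality) * L
        dup_counter: dict[int, int] = {}
        for r in range(R):
            mi = int(read_mol[r])
            k = dup_counter.get(mi, 0)
            dup_counter[mi] = k + 1
            umi = umis[mi]
            if corrupt[r]:
                pos = int(rng.integers(0, umi_length))
                nb = _BASES[(_BASES.index(umi[pos]) + int(rng.integers(1, 4))) % 4]
                umi = umi[:pos] + nb + umi[pos + 1 :]
            reads.append(
                UMIRead(
                    read_id=f"{patient}:{amp.amplicon_id}:{mi}:{k}",
                    umi=umi,
                    amplicon_id=amp.amplicon_id,
                    contig=amp.contig,
                    start=amp.start,
                    seq=read_seq[r].tobytes().decode(),
                    qual=qual,
                    mapq=mapping_quality,
                )
            )
    return reads, list(truth)


# ------------------------------------------------------------------ truth

def spike_truth(
    panel: AmpliconPanel,
    patient_id: str,
    somatic_sites: list[tuple[str, int, float]] | None = None,
    germline_sites: list[tuple[str, int, float]] | None = None,
) -> list[TruthRecord]:
    """Build truth records at explicit (contig, position, vaf) sites; the
    alternate allele is the reference base cycled by one (A->C->G->T->A)."""
    records = []
    for origin, sites in ((ORIGIN_SOMATIC, somatic_sites or []),
                          (ORIGIN_GERMLINE, germline_sites or [])):
        for contig, pos, vaf in sites:
            ref = panel.ref_base(contig, pos)
            alt = _BASES[(_BASES.index(ref) + 1) % 4]
            gene = panel.gene_at(contig, pos) or contig
            records.append(
                TruthRecord(patient_id, gene, contig, pos, ref, alt, vaf, origin)
            )
    return records


# ------------------------------------------------------------------ cohort

DEFAULT_PREVALENCE = {40: 0.05, 50: 0.10, 60: 0.209, 70: 0.266, 80: 0.30}


@dataclass
class CohortSpec:
    """Parameters of a simulated heart-failure cohort.

    Defaults are calibrated to the study conditions of a 200-patient
    chronic-heart-failure cohort: mean age 64 (SD 10.7), CHIP prevalence
    rising from 10% (ages 50-59) to 26.6% (70-79), baseline all-cause
    mortality hazard 0.06/year, carrier hazard ratio 2.1, and censoring
    giving a median follow-up near 4.4 years.
    """

    n_patients: int = 200
    age_mean: float = 64.0
    age_sd: float = 10.7
    age_range: tuple[float, float] = (40.0, 90.0)
    prevalence_by_age: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    hazard_ratio: float = 2.1
    baseline_hazard: float = 0.06  # deaths / year
    rehosp_hazard: float = 0.03   # HF rehospitalizations / year
    censoring_rate: float = 0.10  # exponential censoring, / year
    max_follow_up: float = 6.0    # administrative cut-off, years
    # clone-size dose-response mode: per-band hazard ratios for carriers
    band_hazard_ratios: dict[str, float] | None = None
    band_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.hazard_ratio <= 0 or self.baseline_hazard <= 0:
            raise ValueError("hazard ratio and baseline hazard must be positive")
        for k, v in self.prevalence_by_age.items():
            if not 0 <= v <= 1:
                raise ValueError(f"prevalence for bin {k} outside [0, 1]")
        if self.band_hazard_ratios is not None:
            missing = {BAND_LOW, BAND_MID, BAND_HIGH} - set(self.band_hazard_ratios)
            if missing:
                raise ValueError(f"band_hazard_ratios missing bands: {sorted(missing)}")


def _prevalence_for_age(spec: CohortSpec, age: float) -> float:
    decade = int(age // 10 * 10)
    if decade in spec.prevalence_by_age:
        return spec.prevalence_by_age[decade]
    keys = sorted(spec.prevalence_by_age)
    if not keys:
        return 0.0
    if decade < keys[0]:
        return spec.prevalence_by_age[keys[0]]
    return spec.prevalence_by_age[keys[-1]]


def simulate_cohort(spec: CohortSpec, seed: int | None = None) -> list[PatientRecord]:
    """Draw a cohort with truth CHIP labels and censored survival times."""
    if all(v == 0 for v in spec.prevalence_by_age.values()) and spec.hazard_ratio != 1:
        warnings.warn("all-zero prevalence with HR != 1: no carriers to estimate from",
                      stacklevel=2)
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    lo, hi = spec.age_range
    patients: list[PatientRecord] = []
    for i in range(spec.n_patients):
        age = float(np.clip(rng.normal(spec.age_mean, spec.age_sd), lo, hi))
        carrier = rng.random() < _prevalence_for_age(spec, age)

        hr = 1.0
        band = None
        true_vaf = None
        if carrier:
            if spec.band_hazard_ratios is not None:
                band = rng.choice([BAND_LOW, BAND_MID, BAND_HIGH], p=spec.band_probs)
                ranges = {
                    BAND_LOW: (0.005, 0.01),
                    BAND_MID: (0.01, 0.02),
                    BAND_HIGH: (0.02, 0.23),
                }[band]
                true_vaf = float(rng.uniform(*ranges))
                hr = spec.band_hazard_ratios[band]
            else:
                # clone sizes roughly log-uniform over the observed 0.02-0.23
                true_vaf = float(np.exp(rng.uniform(np.log(0.02), np.log(0.23))))
                hr = spec.hazard_ratio

        t_death = rng.exponential(1.0 / (spec.baseline_hazard * hr))
        t_rehosp = rng.exponential(1.0 / (spec.rehosp_hazard * hr))
        t_censor = min(rng.exponential(1.0 / spec.censoring_rate), spec.max_follow_up)

        follow_up = min(t_death, t_censor)
        died = t_death <= t_censor
        rehosp = t_rehosp <= follow_up
        nt = float(rng.lognormal(np.log(953.0), 1.2))
        p = PatientRecord(
            patient_id=f"P{i:04d}",
            age=age,
            sex="M" if rng.random() < 0.845 else "F",
            hypertension=bool(rng.random() < 0.80),
            hyperlipidemia=bool(rng.random() < 0.81),
            diabetes=bool(rng.random() < 0.36),
            smoking=bool(rng.random() < 0.65),
            nt_probnp=nt,
            shfm=float(rng.normal(0.4, 1.1)),
            follow_up_years=float(follow_up),
            died=bool(died),
            rehosp=bool(rehosp),
            rehosp_time=float(t_rehosp) if rehosp else None,
            true_chip=bool(carrier),
            true_max_driver_vaf=true_vaf,
        )
        p.vaf_band = assign_band(true_vaf)
        patients.append(p)
    return patients


# ---------------------------------------------- marrow / blood VAF pairs

def simulate_bm_blood_vafs(
    n: int = 23,
    noise_sd: float = 0.042,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired driver-clone VAF measurements in bone marrow and peripheral
    blood: blood VAF = marrow VAF + Gaussian measurement/compartment noise,
    floored at 0.  ``noise_sd`` 0.042 against log-uniform clone sizes on
    [0.02, 0.23] yields a Pearson correlation near 0.8."""
    rng = np.random.default_rng(seed)
    bm = np.exp(rng.uniform(np.log(0.02), np.log(0.23), size=n))
    blood = np.clip(bm + rng.normal(0.0, noise_sd, size=n), 0.0, 0.5)
    return bm, blood
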