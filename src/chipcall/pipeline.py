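"""End-to-end pipeline: simulate -> dedup -> call -> filter -> classify ->
survival, with a manifest that makes every run reproducible from (config,
seed)."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import __version__
from .calling import build_pileup, call_variants
from .cohort import classify_patients, prevalence_by_age, vaf_band_stratify
from .filtering import AnnotationTable, run_cascade
from .io import RunConfig, write_cohort_tsv, write_truth_tsv, write_vcf
from .panel import dual_set_region, toy_panel
from .simulate import (
    CohortSpec,
    ORIGIN_GERMLINE,
    ORIGIN_SOMATIC,
    simulate_cohort,
    simulate_reads,
    spike_truth,
)
from .survival import cox_ph, km_estimate, logrank_test
from .umi import dedup, group_umis

logger = logging.getLogger(__name__)

STAGES = ("simulate", "dedup", "call", "filter", "classify", "survival")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _spike_patient_truth(panel, patient_id, rng, clones, germline):
    genes = panel.genes
    somatic_sites = []
    germline_sites = []
    used: set[int] = set()
    for _ in range(clones):
        gene = genes[int(rng.integers(0, len(genes)))]
        contig, lo, hi = dual_set_region(panel, gene)
        pos = int(rng.integers(lo, hi))
        if pos in used:
            continue
        used.add(pos)
        somatic_sites.append((contig, pos, float(rng.uniform(0.02, 0.25))))
    for _ in range(germline):
        gene = genes[int(rng.integers(0, len(genes)))]
        contig, lo, hi = dual_set_region(panel, gene)
        pos = int(rng.integers(lo, hi))
        if pos in used:
            continue
        used.add(pos)
        germline_sites.append((contig, pos, float(rng.uniform(0.497, 0.503))))
    return spike_truth(panel, patient_id, somatic_sites, germline_sites)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on a simulated cohort and write outputs plus a
    manifest to ``config.out_dir``.  Returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    panel = toy_panel(genes=config.genes, seed=config.seed)
    manifest: dict = {
        "package": "chipcall",
        "version": __version__,
        "seed": config.seed,
        "stages": [],
    }

    def record_stage(name, t0, **counts):
        elapsed = time.perf_counter() - t0
        logger.info("stage %s done in %.2fs: %s", name, elapsed, counts)
        manifest["stages"].append({"stage": name, **counts})

    # --- simulate ---------------------------------------------------------
    t0 = time.perf_counter()
    spec = CohortSpec(n_patients=config.n_patients, seed=config.seed)
    patients = simulate_cohort(spec)
    truth_all = []
    reads_by_patient = {}
    for i, p in enumerate(patients):
        truth = _spike_patient_truth(
            panel, p.patient_id, rng, config.clones_per_patient, config.germline_per_patient
        )
        reads, _ = simulate_reads(
            panel,
            truth,
            depth_per_set=config.depth_per_set,
            umi_length=config.umi_length,
            umi_pool_size=config.umi_pool_size,
            error_rate=config.error_rate,
            seed=int(rng.integers(0, 2**31 - 1)),
            duplicate_mean=config.duplicate_mean,
            umi_corruption_rate=config.umi_corruption_rate,
        )
        truth_all.extend(truth)
        reads_by_patient[p.patient_id] = reads
    write_truth_tsv(truth_all, out / "truth.tsv")
    n_reads = sum(len(r) for r in reads_by_patient.values())
    record_stage("simulate", t0, patients=len(patients), truth_records=len(truth_all),
                 reads=n_reads)

    # --- dedup ------------------------------------------------------------
    t0 = time.perf_counter()
    consensus_by_patient = {}
    n_families = 0
    for pid, reads in reads_by_patient.items():
        fams = group_umis(reads, max_edit=config.max_edit)
        n_families += len(fams)
        consensus_by_patient[pid] = dedup(fams, min_family_size=config.min_family_size)
    record_stage("dedup", t0, raw_reads=n_reads, families=n_families,
                 consensus_reads=sum(len(c) for c in consensus_by_patient.values()))

    # --- call -------------------------------------------------------------
    t0 = time.perf_counter()
    all_calls = []
    for pid, cons in consensus_by_patient.items():
        pile = build_pileup(
            cons, panel,
            min_base_quality=config.min_base_quality,
            min_mapping_quality=config.min_mapping_quality,
        )
        all_calls.extend(call_variants(pile, min_alt_reads=config.min_alt_reads,
                                       patient_id=pid))
    record_stage("call", t0, candidates=len(all_calls))

    # --- filter -----------------------------------------------------------
    t0 = time.perf_counter()
    ann = (AnnotationTable.from_tsv(config.annotation_path)
           if config.annotation_path else AnnotationTable())
    survivors, audit = run_cascade(
        all_calls, ann, config.filter_config,
        cohort_size=config.n_patients, vaf_floor=config.vaf_floor, panel=panel,
    )
    write_vcf(all_calls, out / "calls.vcf", panel)
    write_vcf(survivors, out / "survivors.vcf", panel)
    audit.to_csv(out / "filter_audit.tsv", sep="\t", index=False)
    record_stage("filter", t0, input=len(all_calls), survivors=len(survivors))

    # --- classify ---------------------------------------------------------
    t0 = time.perf_counter()
    floor = config.vaf_floor if config.vaf_floor is not None else config.filter_config.vaf_min
    classify_patients(survivors, patients, vaf_floor=floor)
    vaf_band_stratify(patients)
    write_cohort_tsv(patients, out / "cohort.tsv")
    prevalence_by_age(patients).to_csv(out / "prevalence_by_age.tsv", sep="\t", index=False)
    n_carriers = sum(1 for p in patients if p.chip_status)
    record_stage("classify", t0, carriers=n_carriers, non_carriers=len(patients) - n_carriers)

    # --- survival ---------------------------------------------------------
    t0 = time.perf_counter()
    times = np.array([p.follow_up_years for p in patients])
    events = np.array([p.died for p in patients])
    carrier = np.array([bool(p.chip_status) for p in patients])
    report: dict = {"endpoint": "death", "n": len(patients),
                    "carriers": int(carrier.sum())}
    if 0 < carrier.sum() < len(patients) and events.any():
        km_carrier = km_estimate(times[carrier], events[carrier])
        km_non = km_estimate(times[~carrier], events[~carrier]) if events[~carrier].any() else None
        km_carrier.to_frame().to_csv(out / "km_carriers.tsv", sep="\t", index=False)
        if km_non is not None:
            km_non.to_frame().to_csv(out / "km_non_carriers.tsv", sep="\t", index=False)
        try:
            lr = logrank_test(carrier.astype(int), times, events)
            report["logrank"] = {"chi2": lr.statistic, "df": lr.df, "p": lr.p_value}
        except ValueError as exc:
            report["logrank"] = {"error": str(exc)}
        try:
            cox = cox_ph(carrier.astype(float)[:, None], times, events, names=["chip"])
            report["cox"] = {
                "hr": float(cox.hr[0]),
                "ci": [float(cox.ci_low[0]), float(cox.ci_high[0])],
                "p": float(cox.p[0]),
            }
        except Exception as exc:  # small demo cohorts may lack events
            report["cox"] = {"error": str(exc)}

    # truth-based sensitivity of the full pipeline
    somatic_q = [t for t in truth_all if t.origin == ORIGIN_SOMATIC and t.true_vaf >= floor]
    surv_keys = {(v.patient_id, v.contig, v.position, v.alt) for v in survivors}
    detected = sum(
        1 for t in somatic_q if (t.patient_id, t.contig, t.position, t.alt) in surv_keys
    )
    germline_surviving = sum(
        1 for t in truth_all if t.origin == ORIGIN_GERMLINE
        and (t.patient_id, t.contig, t.position, t.alt) in surv_keys
    )
    report["truth_recovery"] = {
        "qualifying_somatic": len(somatic_q),
        "detected": detected,
        "sensitivity": detected / len(somatic_q) if somatic_q else None,
        "germline_survivors": germline_surviving,
    }
    with open(out / "survival_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    record_stage("survival", t0, events=int(events.sum()))

    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
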