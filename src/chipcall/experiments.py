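"""Reproduction studies: calibrated simulations that exercise the whole
pipeline and measure how well it recovers known truth.

Each function builds its inputs from the package's own simulators at the
study conditions (cohort size 200, ~27% event rate, carrier hazard ratio
2.1, amplicon depth calibrated to the 4282x raw / 630x consensus medians),
runs the method under test, and returns plain-number summaries.  They are
what ``scripts/acceptance.py`` and the acceptance test suite call.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from .calling import build_pileup, call_variants
from .cohort import BAND_HIGH, BAND_LOW, BAND_MID, BAND_NONE
from .filtering import (
    FLAG_RECURRENCE,
    AnnotationTable,
    FilterConfig,
    run_cascade,
)
from .panel import AmpliconPanel, dual_set_region, toy_panel
from .simulate import (
    CohortSpec,
    ORIGIN_GERMLINE,
    ORIGIN_SOMATIC,
    simulate_bm_blood_vafs,
    simulate_cohort,
    simulate_reads,
    spike_truth,
)
from .survival import cox_ph, km_estimate, logrank_test
from .umi import dedup, group_umis

# a desk-scale stand-in for the 56-gene CHIP/myeloid panel
CHIP_PANEL_GENES = (
    "DNMT3A", "TET2", "ASXL1", "TP53", "KDM6A", "BCOR", "SF3B1", "CBLC",
    "JAK2", "SRSF2", "PPM1D", "GNB1", "IDH2", "RUNX1", "CBL", "CALR",
)


# ------------------------------------------------------------ UMI collapse

def umi_collapse_calibration(
    n_amplicons: int = 100,
    molecules: int = 630,
    duplicate_mean: float = 6.8,
    seed: int = 0,
) -> dict:
    """Raw vs consensus depth across amplicons at the calibrated duplicate
    rate; the per-amplicon medians mirror the assay's 4282x -> 630x
    contraction."""
    genes = tuple(f"G{i:03d}" for i in range(n_amplicons))
    full = toy_panel(genes=genes, seed=seed)
    amps = [a for a in full.amplicons if a.set_label == "CAT_A"]
    panel = AmpliconPanel(amps, full.reference)
    reads, _ = simulate_reads(
        panel, [], depth_per_set=molecules, duplicate_mean=duplicate_mean, seed=seed
    )
    families = group_umis(reads, max_edit=0)
    raw = Counter(r.amplicon_id for r in reads)
    cons = Counter(f.amplicon_id for f in families)
    raw_median = float(np.median([raw[a.amplicon_id] for a in amps]))
    cons_median = float(np.median([cons[a.amplicon_id] for a in amps]))
    return {
        "n_amplicons": n_amplicons,
        "raw_depth_median": raw_median,
        "consensus_depth_median": cons_median,
        "collapse_ratio": raw_median / cons_median,
    }


# --------------------------------------------------- filter truth recovery

def filter_truth_recovery(
    n_patients: int = 50,
    clones_per_patient: int = 3,
    depth_per_set: int = 800,
    duplicate_mean: float = 6.8,
    artifact_fraction: float = 0.2,
    artifact_vaf: float = 0.05,
    error_rate: float = 1e-3,
    genes: tuple[str, ...] = CHIP_PANEL_GENES,
    seed: int = 0,
) -> dict:
    """End-to-end cascade evaluation against simulator truth.

    Every patient gets ``clones_per_patient`` somatic clones (true VAF
    uniform on [0.02, 0.25]) and one private near-balanced germline het;
    a fixed-site technical artifact is spiked into ``artifact_fraction``
    of patients.  The full pipeline (reads -> consensus -> pileup -> calls
    -> cascade) is run per patient and compared with truth.
    """
    rng = np.random.default_rng(seed)
    panel = toy_panel(genes=genes, seed=seed)
    genes = panel.genes
    artifact_gene = genes[-1]
    art_contig, art_lo, art_hi = dual_set_region(panel, artifact_gene)
    artifact_pos = (art_lo + art_hi) // 2
    n_artifact = int(round(artifact_fraction * n_patients))

    cfg = FilterConfig()
    ann = AnnotationTable()
    all_calls = []
    truth_all = []
    for i in range(n_patients):
        pid = f"P{i:04d}"
        used = {artifact_pos}
        somatic = []
        for _ in range(clones_per_patient):
            gene = genes[int(rng.integers(0, len(genes)))]
            contig, lo, hi = dual_set_region(panel, gene)
            pos = int(rng.integers(lo, hi))
            if (contig, pos) in used or pos == artifact_pos:
                continue
            used.add((contig, pos))
            somatic.append((contig, pos, float(rng.uniform(0.02, 0.25))))
        if i < n_artifact:
            somatic.append((art_contig, artifact_pos, artifact_vaf))
        gene = genes[int(rng.integers(0, len(genes)))]
        contig, lo, hi = dual_set_region(panel, gene)
        pos = int(rng.integers(lo, hi))
        germline = [] if (contig, pos) in used or pos == artifact_pos else [
            (contig, pos, float(rng.uniform(0.497, 0.503)))
        ]
        truth = spike_truth(panel, pid, somatic, germline)
        reads, _ = simulate_reads(
            panel, truth, depth_per_set=depth_per_set, duplicate_mean=duplicate_mean,
            error_rate=error_rate, seed=int(rng.integers(0, 2**31 - 1)),
        )
        cons = dedup(group_umis(reads, max_edit=0))
        pile = build_pileup(cons, panel)
        all_calls.extend(call_variants(pile, patient_id=pid))
        truth_all.extend(truth)

    survivors, audit = run_cascade(
        all_calls, ann, cfg, cohort_size=n_patients, panel=panel
    )
    surv_keys = {(v.patient_id, v.contig, v.position, v.alt) for v in survivors}

    artifact_key = None
    for t in truth_all:
        if t.position == artifact_pos and t.contig == art_contig:
            artifact_key = (t.contig, t.position, t.ref, t.alt)
            break
    qualifying = [
        t for t in truth_all
        if t.origin == ORIGIN_SOMATIC and t.true_vaf >= cfg.vaf_min
        and not (t.contig == art_contig and t.position == artifact_pos)
    ]
    detected = sum(
        1 for t in qualifying
        if (t.patient_id, t.contig, t.position, t.alt) in surv_keys
    )
    germline_truth = [t for t in truth_all if t.origin == ORIGIN_GERMLINE]
    germline_survivors = sum(
        1 for t in germline_truth
        if (t.patient_id, t.contig, t.position, t.alt) in surv_keys
    )
    artifact_calls = [v for v in all_calls if artifact_key and v.key == artifact_key]
    artifact_truth_calls = [
        v for v in artifact_calls
        if int(v.patient_id[1:]) < n_artifact
    ]
    artifact_removed_by_recurrence = sum(
        1 for v in artifact_truth_calls if v.filters[:1] == [FLAG_RECURRENCE]
    )
    removed_total = int(audit.loc[audit["rule"] != "PASS", "removed"].sum())
    return {
        "n_patients": n_patients,
        "n_candidate_calls": len(all_calls),
        "n_survivors": len(survivors),
        "qualifying_clones": len(qualifying),
        "detected_clones": detected,
        "sensitivity": detected / len(qualifying) if qualifying else float("nan"),
        "germline_truths": len(germline_truth),
        "germline_survivors": germline_survivors,
        "artifact_calls": len(artifact_truth_calls),
        "artifact_removed_by_recurrence": artifact_removed_by_recurrence,
        "artifact_survivors": sum(
            1 for v in artifact_calls
            if (v.patient_id, v.contig, v.position, v.alt) in surv_keys
        ),
        "audit_conserved": removed_total + len(survivors) == len(all_calls),
        "audit": audit,
    }


# ------------------------------------------------------ survival recovery

def cox_recovery_study(
    n_seeds: int = 200,
    n_patients: int = 200,
    true_hr: float = 2.1,
    seed: int = 0,
) -> dict:
    """Fit the carrier Cox model on repeated simulated cohorts and measure
    estimate accuracy and 95% CI coverage for the true hazard ratio."""
    rng = np.random.default_rng(seed)
    beta_true = np.log(true_hr)
    betas, covered, within3 = [], 0, 0
    fitted = 0
    for _ in range(n_seeds):
        patients = simulate_cohort(
            CohortSpec(n_patients=n_patients, hazard_ratio=true_hr),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        x = np.array([float(p.true_chip) for p in patients])
        t = np.array([p.follow_up_years for p in patients])
        e = np.array([p.died for p in patients])
        if x.std() == 0 or e.sum() < 2:
            continue
        res = cox_ph(x[:, None], t, e, names=["chip"])
        fitted += 1
        betas.append(res.coef[0])
        if res.ci_low[0] <= true_hr <= res.ci_high[0]:
            covered += 1
        if abs(res.coef[0] - beta_true) <= 3 * res.se[0]:
            within3 += 1
    return {
        "n_seeds": fitted,
        "true_hr": true_hr,
        "mean_hr": float(np.exp(np.mean(betas))),
        "mean_beta": float(np.mean(betas)),
        "ci_coverage": covered / fitted,
        "frac_within_3se": within3 / fitted,
    }


def logrank_type1_study(
    n_seeds: int = 200,
    n_patients: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Rejection rate of the carrier log-rank test under no carrier effect
    (HR = 1); should sit near the nominal alpha."""
    rng = np.random.default_rng(seed)
    rejections = 0
    tested = 0
    for _ in range(n_seeds):
        patients = simulate_cohort(
            CohortSpec(n_patients=n_patients, hazard_ratio=1.0),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        x = np.array([int(p.true_chip) for p in patients])
        t = np.array([p.follow_up_years for p in patients])
        e = np.array([p.died for p in patients])
        if len(np.unique(x)) < 2 or not e.any():
            continue
        tested += 1
        if logrank_test(x, t, e).p_value < alpha:
            rejections += 1
    return {"n_seeds": tested, "alpha": alpha, "rejection_rate": rejections / tested}


_BAND_SCORE = {BAND_NONE: 0, BAND_LOW: 1, BAND_MID: 2, BAND_HIGH: 3}


def dose_response_study(
    n_seeds: int = 30,
    n_patients: int = 2000,
    band_hrs: tuple[float, float, float] = (1.5, 2.0, 3.0),
    horizon: float = 5.0,
    seed: int = 0,
) -> dict:
    """Clone-size dose-response machinery check.

    Cohorts are simulated with band-wise hazard ratios (non-carriers 1,
    then ``band_hrs`` for the three clone-size bands).  A run succeeds when
    Kaplan-Meier survival at ``horizon`` is monotone non-increasing across
    the ordered bands and the Cox trend test on the band score rejects at
    0.05."""
    rng = np.random.default_rng(seed)
    spec = CohortSpec(
        n_patients=n_patients,
        prevalence_by_age={40: 0.3, 50: 0.3, 60: 0.3, 70: 0.3, 80: 0.3},
        band_hazard_ratios={BAND_LOW: band_hrs[0], BAND_MID: band_hrs[1],
                            BAND_HIGH: band_hrs[2]},
    )
    successes = 0
    monotone_runs = 0
    trend_runs = 0
    for _ in range(n_seeds):
        patients = simulate_cohort(spec, seed=int(rng.integers(0, 2**31 - 1)))
        t = np.array([p.follow_up_years for p in patients])
        e = np.array([p.died for p in patients])
        score = np.array([_BAND_SCORE[p.vaf_band] for p in patients])
        surv_at = []
        for band_value in range(4):
            mask = score == band_value
            surv_at.append(km_estimate(t[mask], e[mask]).survival_at(horizon))
        monotone = all(surv_at[i] >= surv_at[i + 1] for i in range(3))
        trend = cox_ph(score.astype(float)[:, None], t, e, names=["band"]).p[0] < 0.05
        monotone_runs += monotone
        trend_runs += trend
        successes += monotone and trend
    return {
        "n_seeds": n_seeds,
        "band_hrs": (1.0, *band_hrs),
        "monotone_rate": monotone_runs / n_seeds,
        "trend_rate": trend_runs / n_seeds,
        "success_rate": successes / n_seeds,
    }


def bm_blood_correlation_study(n_reps: int = 100, n_pairs: int = 23, seed: int = 0) -> dict:
    """Mean Pearson correlation between paired bone-marrow and blood clone
    VAFs at the calibrated measurement noise."""
    from .survival import pearson_r

    rng = np.random.default_rng(seed)
    rs = []
    for _ in range(n_reps):
        bm, blood = simulate_bm_blood_vafs(n=n_pairs, seed=int(rng.integers(0, 2**31 - 1)))
        rs.append(pearson_r(bm, blood)[0])
    return {"n_reps": n_reps, "n_pairs": n_pairs, "mean_r": float(np.mean(rs))}
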