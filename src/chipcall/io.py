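"""Readers and writers for the formats the pipeline touches.

FASTQ carries the UMI as the final colon-delimited field of the read
header.  Aligned reads travel as a SAM-like TSV dialect (read_id, umi,
amplicon_id, contig, start_1based, mapq, seq, qual) — sufficient for an
amplicon assay where every read's placement is known.  Variant calls are
emitted as VCF v4.2 with per-rule FILTER tags.  Internal coordinates are
0-based half-open everywhere; conversion happens only here.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, fields as dc_fields
from pathlib import Path

import pandas as pd
import pysam
import yaml
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .calling import VariantCall
from .cohort import PatientRecord
from .filtering import FilterConfig
from .panel import SET_A, SET_B, AmpliconPanel
from .simulate import TruthRecord
from .umi import UMIRead

_COMPLEMENT = str.maketrans("ACGTN", "TACGN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ------------------------------------------------------------------ FASTQ

def write_fastq(reads: list[UMIRead], r1_path: str | Path, r2_path: str | Path | None = None) -> None:
    """Write reads as FASTQ; the UMI is the final colon field of the
    header.  When ``r2_path`` is given, R2 holds the reverse complement
    (amplicons are short enough for both mates to span the insert)."""
    with open(r1_path, "w") as r1:
        for r in reads:
            r1.write(f"@{r.read_id}:{r.umi}\n{r.seq}\n+\n{r.qual}\n")
    if r2_path is not None:
        with open(r2_path, "w") as r2:
            for r in reads:
                r2.write(f"@{r.read_id}:{r.umi}\n{revcomp(r.seq)}\n+\n{r.qual[::-1]}\n")


@dataclass
class FastqRead:
    read_id: str
    umi: str
    seq: str
    qual: str


def read_fastq(path: str | Path) -> list[FastqRead]:
    """Parse FASTQ, recovering the UMI from the header's final colon field.
    Malformed records raise with the offending record's ordinal."""
    out: list[FastqRead] = []
    with open(path) as fh:
        try:
            for i, (title, seq, qual) in enumerate(FastqGeneralIterator(fh), start=1):
                if len(seq) != len(qual):
                    raise ValueError(
                        f"record {i} (line ~{4 * i - 3}): sequence/quality length mismatch"
                    )
                name = title.split()[0]
                base, _, umi = name.rpartition(":")
                out.append(FastqRead(base, umi, seq, qual))
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ near record {len(out) + 1}: {exc}") from exc
    return out


# ----------------------------------------------------------- reads as TSV

_READS_COLUMNS = ["read_id", "umi", "amplicon_id", "contig", "start_1based", "mapq", "seq", "qual"]


def write_reads_tsv(reads: list[UMIRead], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (r.read_id, r.umi, r.amplicon_id, r.contig, r.start + 1, r.mapq, r.seq, r.qual)
            for r in reads
        ],
        columns=_READS_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_reads_tsv(path: str | Path) -> list[UMIRead]:
    df = pd.read_csv(path, sep="\t", dtype={"umi": str, "seq": str, "qual": str})
    missing = set(_READS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"reads TSV missing columns: {sorted(missing)}")
    return [
        UMIRead(
            read_id=str(row.read_id),
            umi=row.umi,
            amplicon_id=str(row.amplicon_id),
            contig=str(row.contig),
            start=int(row.start_1based) - 1,
            seq=row.seq,
            qual=row.qual,
            mapq=int(row.mapq),
        )
        for row in df.itertuples()
    ]


# ----------------------------------------------------------- truth/cohort

def write_truth_tsv(truth: list[TruthRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            (t.patient_id, t.gene, t.contig, t.position + 1, t.ref, t.alt, t.true_vaf, t.origin)
            for t in truth
        ],
        columns=["patient_id", "gene", "contig", "pos_1based", "ref", "alt", "true_vaf", "origin"],
    ).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str | Path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        TruthRecord(
            str(r.patient_id), str(r.gene), str(r.contig), int(r.pos_1based) - 1,
            str(r.ref), str(r.alt), float(r.true_vaf), str(r.origin),
        )
        for r in df.itertuples()
    ]


def write_cohort_tsv(patients: list[PatientRecord], path: str | Path) -> None:
    from .cohort import patients_to_frame

    patients_to_frame(patients).to_csv(path, sep="\t", index=False)


def read_cohort_tsv(path: str | Path) -> list[PatientRecord]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples():
        out.append(
            PatientRecord(
                patient_id=str(r.patient_id),
                age=float(r.age),
                sex=str(r.sex),
                hypertension=bool(r.hypertension),
                hyperlipidemia=bool(r.hyperlipidemia),
                diabetes=bool(r.diabetes),
                smoking=bool(r.smoking),
                nt_probnp=None if pd.isna(r.nt_probnp) else float(r.nt_probnp),
                shfm=None if pd.isna(r.shfm) else float(r.shfm),
                follow_up_years=float(r.follow_up_years),
                died=bool(r.died),
                rehosp=bool(r.rehosp),
                rehosp_time=None if pd.isna(r.rehosp_time) else float(r.rehosp_time),
                true_chip=None if pd.isna(r.true_chip) else bool(r.true_chip),
            )
        )
    return out


# -------------------------------------------------------------------- VCF

_INFO_DEFS = [
    ("GENE", "1", "String", "Gene symbol of the targeted region"),
    ("VAF", "1", "Float", "Variant allele fraction: alt / (ref + alt)"),
    ("SET_A_AD", "2", "Integer", "CAT_A amplicon set: alt count, total depth"),
    ("SET_B_AD", "2", "Integer", "CAT_B amplicon set: alt count, total depth"),
    ("EFFECT", "1", "String", "Predicted effect class"),
    ("PATIENT", "1", "String", "Patient identifier"),
    ("MEAN_MQ", "1", "Float", "Mean mapping quality of covering reads"),
]

_FILTER_DEFS = {
    "POP_MAF": "Population minor allele frequency >= 5% in a population database",
    "MQ20": "Mean mapping quality below 20",
    "RECUR8": "Variant recurs in >= 8% of cohort patients (technical artifact)",
    "DUALSET": "Insufficient coverage or alternate support in one amplicon set",
    "SETGAP": "Site covered by amplicons of only one set (panel-design gap)",
    "DBSNP": "Common (>=1%) polymorphism in dbSNP",
    "EFFECT": "Effect class LOW or MODIFIER",
    "VAFWIN": "VAF below floor or inside the germline band 0.45-0.55",
}

_REQUIRED_INFO = ("VAF", "SET_A_AD", "SET_B_AD")


def write_vcf(calls: list[VariantCall], path: str | Path, panel: AmpliconPanel) -> None:
    """Emit calls as VCF v4.2 (1-based positions) with per-rule FILTER tags."""
    header = pysam.VariantHeader()
    for contig, seq in panel.reference.items():
        header.contigs.add(contig, length=len(seq))
    for fid, number, ftype, desc in _INFO_DEFS:
        header.info.add(fid, number, ftype, desc)
    for fid, desc in _FILTER_DEFS.items():
        header.filters.add(fid, None, None, desc)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for v in sorted(calls, key=lambda c: (c.contig, c.position, c.alt)):
            rec = vf.new_record(
                contig=v.contig, start=v.position, stop=v.position + 1,
                alleles=(v.ref, v.alt),
            )
            rec.info["GENE"] = v.gene or "."
            rec.info["VAF"] = float(v.vaf)
            rec.info["SET_A_AD"] = tuple(v.set_counts.get(SET_A, (0, 0)))
            rec.info["SET_B_AD"] = tuple(v.set_counts.get(SET_B, (0, 0)))
            rec.info["EFFECT"] = v.effect or "HIGH"
            if v.patient_id:
                rec.info["PATIENT"] = v.patient_id
            rec.info["MEAN_MQ"] = float(v.mean_mapq)
            if v.filters:
                for tag in v.filters:
                    rec.filter.add(tag)
            else:
                rec.filter.add("PASS")
            vf.write(rec)


def read_vcf(path: str | Path) -> list[VariantCall]:
    """Read calls back (positions to 0-based); missing required INFO keys
    raise naming the key and record."""
    out: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            for key in _REQUIRED_INFO:
                if key not in rec.info:
                    raise ValueError(
                        f"missing required INFO key {key} at {rec.contig}:{rec.pos}"
                    )
            alt = rec.alts[0]
            a_ad = tuple(int(x) for x in rec.info["SET_A_AD"])
            b_ad = tuple(int(x) for x in rec.info["SET_B_AD"])
            filters = [f for f in rec.filter.keys() if f != "PASS"]
            alt_reads = a_ad[0] + b_ad[0]
            vaf = float(rec.info["VAF"])
            ref_reads = round(alt_reads / vaf) - alt_reads if vaf > 0 else 0
            out.append(
                VariantCall(
                    contig=rec.contig,
                    position=rec.start,
                    ref=rec.ref,
                    alt=alt,
                    gene=rec.info.get("GENE"),
                    alt_reads=alt_reads,
                    ref_reads=ref_reads,
                    vaf=vaf,
                    set_counts={SET_A: a_ad, SET_B: b_ad},
                    mean_mapq=float(rec.info.get("MEAN_MQ", 60.0)),
                    patient_id=rec.info.get("PATIENT"),
                    effect=rec.info.get("EFFECT"),
                    filters=filters,
                )
            )
    return out


# ------------------------------------------------------------- run config

@dataclass
class RunConfig:
    """Validated configuration for an end-to-end run."""

    out_dir: str = "chipcall_run"
    seed: int = 0
    n_patients: int = 20
    genes: tuple[str, ...] = ("DNMT3A", "TET2", "ASXL1", "TP53")
    depth_per_set: int = 300
    duplicate_mean: float = 6.8
    error_rate: float = 1e-3
    umi_length: int = 6
    umi_pool_size: int = 4**6
    umi_corruption_rate: float = 0.01
    max_edit: int = 0  # 6-bp UMIs saturate at amplicon depth; see docs/methods.md
    min_family_size: int = 1
    min_base_quality: int = 20
    min_mapping_quality: int = 20
    min_alt_reads: int = 2
    vaf_floor: float | None = None
    clones_per_patient: int = 2
    germline_per_patient: int = 1
    log_level: str = "INFO"
    annotation_path: str | None = None
    filter_config: FilterConfig = dc_field(default_factory=FilterConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config must be a YAML mapping")
        fc_raw = raw.pop("filter_config", {})
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        fc_known = {f.name for f in dc_fields(FilterConfig)}
        fc_unknown = set(fc_raw) - fc_known
        if fc_unknown:
            raise ValueError(f"unknown filter_config keys: {sorted(fc_unknown)}")
        if "excluded_effects" in fc_raw:
            fc_raw["excluded_effects"] = frozenset(fc_raw["excluded_effects"])
        if "germline_band" in fc_raw:
            fc_raw["germline_band"] = tuple(fc_raw["germline_band"])
        if "genes" in raw:
            raw["genes"] = tuple(raw["genes"])
        return cls(filter_config=FilterConfig(**fc_raw), **raw)
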