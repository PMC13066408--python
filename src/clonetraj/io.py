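"""Readers and writers for cohort-level files.

Formats (all UTF-8, tab-separated; coordinates 1-based inclusive):

* variant tables — TSV with the documented header, or VCF 4.x with
  ``AD``/``DP`` FORMAT fields (sample names encode patient/timepoint as
  ``<patient>:<timepoint>``);
* CNV segments — SEG-like TSV;
* clinical tables — one row per patient;
* clone trees — JSON, ``schema_version`` 1 (see docs/formats.md).

The detection threshold defaults to a 10% VAF; a 1% sensitivity mode is
available by passing ``vaf_threshold=0.01``.
"""

from __future__ import annotations

import json
import logging
import math
import os
from pathlib import Path

import pandas as pd

from .datatypes import (
    ClinicalRecord,
    CloneTreeDocument,
    CnvSegment,
    FormatError,
    ValidationError,
    VariantCall,
)

log = logging.getLogger("clonetraj.io")

DEFAULT_VAF_THRESHOLD = 0.10
SENSITIVE_VAF_THRESHOLD = 0.01

VARIANT_COLUMNS = [
    "patient_id", "sample_id", "timepoint", "chrom", "pos", "ref", "alt",
    "gene", "protein_change", "vaf", "depth", "alt_reads",
]
_VARIANT_REQUIRED = ["patient_id", "sample_id", "timepoint", "chrom", "pos",
                     "ref", "alt", "gene", "vaf", "depth"]

SEGMENT_COLUMNS = [
    "patient_id", "sample_id", "timepoint", "chrom", "start", "end",
    "cn", "loh", "baf", "logr", "fraction",
]
_SEGMENT_REQUIRED = ["patient_id", "sample_id", "timepoint", "chrom",
                     "start", "end", "cn", "loh"]

CLINICAL_COLUMNS = [
    "patient_id", "entity", "age_group", "age_years", "relapsed",
    "time_to_event_days", "event_observed", "sample_timepoints",
]
_CLINICAL_REQUIRED = CLINICAL_COLUMNS[:-1]


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{what}: missing required column {col!r}")


def _parse_bool(x) -> bool:
    if isinstance(x, bool):
        return x
    s = str(x).strip().lower()
    if s in ("true", "1", "yes", "t"):
        return True
    if s in ("false", "0", "no", "f"):
        return False
    raise ValidationError(f"cannot parse boolean value {x!r}")


def _optional_float(x) -> float | None:
    if x is None or (isinstance(x, float) and math.isnan(x)) or str(x).strip() in ("", "NA", "."):
        return None
    return float(x)


# ---------------------------------------------------------------------------
# variants

def read_variant_table(path: str | os.PathLike, dialect: str = "tsv",
                       vaf_threshold: float = DEFAULT_VAF_THRESHOLD) -> list[VariantCall]:
    """Read somatic small-variant calls, keeping calls with
    ``vaf >= vaf_threshold`` (inclusive, mirroring the panel's detection
    threshold). Rows below threshold are counted and logged.
    """
    if dialect == "tsv":
        calls = _read_variants_tsv(path)
    elif dialect == "vcf":
        calls = _read_variants_vcf(path)
    else:
        raise ValueError(f"unknown variant dialect {dialect!r}")
    kept = [c for c in calls if c.vaf >= vaf_threshold]
    n_dropped = len(calls) - len(kept)
    if n_dropped:
        log.info("read_variant_table(%s): %d calls below VAF threshold %.3g dropped",
                 path, n_dropped, vaf_threshold)
    return kept


def _read_variants_tsv(path) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, _VARIANT_REQUIRED, "variant table")
    calls: list[VariantCall] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        try:
            vaf = float(row.vaf) if str(row.vaf).strip() != "" else None
            depth = int(float(row.depth))
            alt_reads = None
            if "alt_reads" in df.columns and str(row.alt_reads).strip() != "":
                alt_reads = int(float(row.alt_reads))
            if vaf is not None and not 0.0 <= vaf <= 1.0:
                raise ValidationError(f"vaf outside [0,1]: {vaf}")
            # reads are the primary evidence when both are present
            if alt_reads is not None:
                vaf_from_reads = alt_reads / depth
                if vaf is None:
                    vaf = vaf_from_reads
                elif abs(vaf - vaf_from_reads) > 0.5 / depth:
                    log.warning(
                        "variant table line %d: vaf column %.4f disagrees with "
                        "alt_reads/depth %.4f; using read counts", i, vaf, vaf_from_reads)
                    vaf = vaf_from_reads
            if vaf is None:
                raise ValidationError("neither vaf nor alt_reads/depth present")
            calls.append(VariantCall(
                patient_id=row.patient_id,
                sample_id=row.sample_id,
                timepoint=int(float(row.timepoint)),
                chrom=str(row.chrom),
                pos=int(float(row.pos)),
                ref=row.ref,
                alt=row.alt,
                gene=row.gene,
                protein_change=getattr(row, "protein_change", "") or "",
                vaf=vaf,
                depth=depth,
                alt_reads=alt_reads,
            ))
        except ValidationError as e:
            raise ValidationError(f"variant table line {i}: {e}") from None
        except (TypeError, ValueError) as e:
            raise FormatError(f"variant table line {i}: {e}") from None
    return calls


def _read_variants_vcf(path) -> list[VariantCall]:
    from cyvcf2 import VCF  # local import: only the VCF dialect needs it

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    calls: list[VariantCall] = []
    for rec in vcf:
        gene = rec.INFO.get("GENE") or rec.INFO.get("gene") or ""
        prot = rec.INFO.get("PROTEIN_CHANGE") or ""
        ad = rec.format("AD")
        dp = rec.format("DP")
        if ad is None or dp is None:
            raise FormatError(f"VCF record {rec.CHROM}:{rec.POS} lacks AD/DP FORMAT fields")
        for si, sample in enumerate(samples):
            depth = int(dp[si][0]) if dp[si][0] >= 0 else 0
            alt_reads = int(ad[si][1]) if ad.shape[1] > 1 and ad[si][1] >= 0 else 0
            if depth <= 0:
                continue
            if ":" in sample:
                patient_id, tp_s = sample.rsplit(":", 1)
                timepoint = int(tp_s)
            else:
                patient_id, timepoint = sample, 0
            calls.append(VariantCall(
                patient_id=patient_id,
                sample_id=sample,
                timepoint=timepoint,
                chrom=str(rec.CHROM),
                pos=int(rec.POS),
                ref=rec.REF,
                alt=rec.ALT[0] if rec.ALT else "",
                gene=gene,
                protein_change=prot,
                vaf=alt_reads / depth,
                depth=depth,
                alt_reads=alt_reads,
            ))
    return calls


def write_variant_table(calls: list[VariantCall], path) -> None:
    rows = [{
        "patient_id": c.patient_id, "sample_id": c.sample_id,
        "timepoint": c.timepoint, "chrom": c.chrom, "pos": c.pos,
        "ref": c.ref, "alt": c.alt, "gene": c.gene,
        "protein_change": c.protein_change,
        "vaf": f"{c.vaf:.6g}", "depth": c.depth,
        "alt_reads": "" if c.alt_reads is None else c.alt_reads,
    } for c in calls]
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# CNV segments

def read_cnv_segments(path) -> list[CnvSegment]:
    """Read SEG-like CNV segments, sorted by (patient, sample, chrom, start)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, _SEGMENT_REQUIRED, "CNV segment table")
    segs: list[CnvSegment] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            segs.append(CnvSegment(
                patient_id=row.patient_id,
                sample_id=row.sample_id,
                timepoint=int(float(row.timepoint)),
                chrom=str(row.chrom),
                start=int(float(row.start)),
                end=int(float(row.end)),
                cn=int(float(row.cn)),
                loh=_parse_bool(row.loh),
                baf=_optional_float(getattr(row, "baf", None)),
                logr=_optional_float(getattr(row, "logr", None)),
                fraction=_optional_float(getattr(row, "fraction", None)),
            ))
        except ValidationError as e:
            raise ValidationError(f"CNV segment table line {i}: {e}") from None
        except (TypeError, ValueError) as e:
            raise FormatError(f"CNV segment table line {i}: {e}") from None
    segs.sort(key=lambda s: (s.patient_id, s.sample_id, s.chrom, s.start))
    return segs


def write_cnv_segments(segs: list[CnvSegment], path) -> None:
    rows = [{
        "patient_id": s.patient_id, "sample_id": s.sample_id,
        "timepoint": s.timepoint, "chrom": s.chrom, "start": s.start,
        "end": s.end, "cn": s.cn, "loh": str(s.loh).lower(),
        "baf": "" if s.baf is None else f"{s.baf:.6g}",
        "logr": "" if s.logr is None else f"{s.logr:.6g}",
        "fraction": "" if s.fraction is None else f"{s.fraction:.6g}",
    } for s in segs]
    pd.DataFrame(rows, columns=SEGMENT_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# clinical

def read_clinical_table(path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, _CLINICAL_REQUIRED, "clinical table")
    records: list[ClinicalRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        pid = row.patient_id
        if pid in seen:
            raise ValidationError(f"clinical table line {i}: duplicate patient_id {pid!r}")
        seen.add(pid)
        tps_raw = getattr(row, "sample_timepoints", "")
        tps = [int(t) for t in str(tps_raw).split(",") if str(t).strip() != ""]
        try:
            records.append(ClinicalRecord(
                patient_id=pid,
                entity=row.entity,
                age_group=row.age_group,
                age_years=float(row.age_years),
                relapsed=_parse_bool(row.relapsed),
                time_to_event_days=float(row.time_to_event_days),
                event_observed=_parse_bool(row.event_observed),
                sample_timepoints=tps,
            ))
        except ValidationError as e:
            raise ValidationError(f"clinical table line {i}: {e}") from None
        except (TypeError, ValueError) as e:
            raise FormatError(f"clinical table line {i}: {e}") from None
    return records


def write_clinical_table(records: list[ClinicalRecord], path) -> None:
    rows = [{
        "patient_id": r.patient_id, "entity": r.entity, "age_group": r.age_group,
        "age_years": f"{r.age_years:.6g}", "relapsed": str(r.relapsed).lower(),
        "time_to_event_days": f"{r.time_to_event_days:.6g}",
        "event_observed": str(r.event_observed).lower(),
        "sample_timepoints": ",".join(str(t) for t in r.sample_timepoints),
    } for r in records]
    pd.DataFrame(rows, columns=CLINICAL_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# clone trees

def write_tree_json(tree: CloneTreeDocument, path) -> None:
    d = tree.to_dict()  # validates (refuses cycles / self-parents)
    Path(path).write_text(json.dumps(d, indent=1, sort_keys=True), encoding="utf-8")


def read_tree_json(path) -> CloneTreeDocument:
    d = json.loads(Path(path).read_text(encoding="utf-8"))
    return CloneTreeDocument.from_dict(d)
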