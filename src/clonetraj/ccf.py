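"""Cancer cell fraction (CCF) estimation.

The package integrates small variants and copy-number events on the CCF
scale. For a small variant with allele frequency ``v`` observed in a
sample of purity ``rho``, at a locus of tumor copy number ``n_t``
(normal copy number ``n_n``, usually 2) mutated on ``m`` copies, the
expected VAF given the CCF ``phi`` is

    v = phi * m * rho / (rho * n_t + (1 - rho) * n_n)

so the point estimate is the linear inversion, clamped to [0, 1]. For
array CNVs, the mirrored B-allele frequency of the affected segment is
inverted under the class-specific allele model (hemizygous deletion,
copy-neutral LOH, single-copy gain) to a tumor-cell fraction ``f``,
which already lives on the CCF scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .datatypes import CnvSegment, VariantCall

#: a raw CCF above this value is reported as a model violation
MODEL_VIOLATION_THRESHOLD = 1.1


class PurityError(ValueError):
    """No usable purity information for a sample."""


class SignalError(ValueError):
    """A CNV segment carries neither BAF nor an explicit fraction."""


@dataclass
class PurityEstimate:
    sample_id: str
    rho: float
    method: str  # "from_metadata" | "from_vaf"

    def __post_init__(self) -> None:
        if not 0.0 < self.rho <= 1.0:
            raise ValueError(f"purity must be in (0,1], got {self.rho}")


@dataclass
class CcfEstimate:
    event_id: str
    ccf: float
    ci_low: float
    ci_high: float
    multiplicity: int
    local_cn: int
    purity: float
    raw_ccf: float
    model_violation: bool = False


def vaf_coefficient(purity: float, local_cn: int, multiplicity: int = 1,
                    normal_cn: int = 2) -> float:
    """Linear factor ``c`` such that expected VAF = ``c * ccf``."""
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity must be in (0,1], got {purity}")
    if multiplicity < 1:
        raise ValueError("multiplicity must be >= 1")
    denom = purity * local_cn + (1.0 - purity) * normal_cn
    if denom <= 0:
        raise ValueError("degenerate locus: zero expected copies")
    return multiplicity * purity / denom


def expected_vaf(ccf: float, purity: float, local_cn: int,
                 multiplicity: int = 1, normal_cn: int = 2) -> float:
    """Forward model: expected VAF of a variant at CCF ``ccf``."""
    return vaf_coefficient(purity, local_cn, multiplicity, normal_cn) * ccf


def estimate_purity(calls: list[VariantCall], override: float | None = None,
                    sample_id: str = "") -> PurityEstimate:
    """Purity from CN-neutral variant calls, or a metadata override.

    Without an override: ``rho = min(1, 95th percentile of 2*VAF)`` over
    the supplied CN-neutral calls — a deep-panel heuristic anchored on
    clonal heterozygous variants.
    """
    if override is not None:
        return PurityEstimate(sample_id=sample_id, rho=float(override),
                              method="from_metadata")
    if not calls:
        raise PurityError("no CN-neutral calls and no purity override")
    vafs = np.array([c.vaf for c in calls], dtype=float)
    rho = float(min(1.0, np.percentile(2.0 * vafs, 95)))
    sid = sample_id or calls[0].sample_id
    return PurityEstimate(sample_id=sid, rho=max(rho, 1e-6), method="from_vaf")


def implied_purity_fraction(segment: CnvSegment) -> float | None:
    """rho*f implied by a segment's mirrored BAF under its class model.

    Because rho >= rho*f for any event, the maximum over a sample's
    events (including 2*VAF of CN-neutral variants) is a purity estimate
    that is exact in the noise-free limit whenever any event is clonal.
    """
    if segment.baf is None:
        return None
    b = min(segment.baf, 1.0 - segment.baf)
    cls = segment.cnv_class
    if cls == "del":
        rf = (1.0 - 2.0 * b) / (1.0 - b) if b < 1.0 else 0.0
    elif cls == "LOH":
        rf = 1.0 - 2.0 * b
    else:  # dup
        rf = (1.0 / b) - 2.0 if b > 0 else 1.0
    return float(min(1.0, max(0.0, rf)))


def compute_snv_ccf(vaf: float, purity: float, local_cn: int = 2,
                    normal_cn: int = 2, multiplicity: int = 1,
                    depth: int | None = None, alt_reads: int | None = None,
                    event_id: str = "", alpha: float = 0.05) -> CcfEstimate:
    """Invert the VAF forward model to a CCF with a Wilson interval.

    When read counts are given, a Wilson confidence interval on the VAF
    is propagated through the linear map; otherwise the interval
    degenerates to the point estimate. Raw CCFs above
    ``MODEL_VIOLATION_THRESHOLD`` raise the model-violation flag.
    """
    if not 0.0 <= vaf <= 1.0:
        raise ValueError(f"vaf outside [0,1]: {vaf}")
    c = vaf_coefficient(purity, local_cn, multiplicity, normal_cn)
    raw = vaf / c
    ccf = float(min(1.0, max(0.0, raw)))
    if depth is not None:
        if alt_reads is None:
            alt_reads = int(round(vaf * depth))
        lo, hi = proportion_confint(alt_reads, depth, alpha=alpha, method="wilson")
        ci_low = float(min(1.0, max(0.0, lo / c)))
        ci_high = float(min(1.0, max(0.0, hi / c)))
    else:
        ci_low = ci_high = ccf
    return CcfEstimate(
        event_id=event_id, ccf=ccf, ci_low=ci_low, ci_high=ci_high,
        multiplicity=multiplicity, local_cn=local_cn, purity=purity,
        raw_ccf=raw, model_violation=raw > MODEL_VIOLATION_THRESHOLD,
    )


class MultiplicityError(ValueError):
    """Variant sits inside a homozygous deletion; multiplicity undefined."""


def estimate_multiplicity(vaf: float, purity: float, local_cn: int) -> int:
    """Pick the mutated copy number 1..local_cn whose implied CCF is
    closest to the feasible [0,1] range; ties break toward m=1."""
    if local_cn < 1:
        raise MultiplicityError(
            "variant inside homozygous deletion (local_cn=0): flagged for review")
    best_m, best_penalty = 1, None
    for m in range(1, local_cn + 1):
        raw = vaf / vaf_coefficient(purity, local_cn, m)
        penalty = max(0.0, raw - 1.0) + max(0.0, -raw)
        if best_penalty is None or penalty < best_penalty - 1e-12:
            best_m, best_penalty = m, penalty
    return best_m


def cnv_fraction(segment: CnvSegment, purity: float,
                 event_id: str = "", baf_sd: float | None = None) -> CcfEstimate:
    """Tumor-cell fraction of a CNV from its mirrored BAF.

    Class-specific inversions of the allele-signal forward model
    (``simulate.cnv_signal_expectations`` is the matching forward map):

    * one-copy deletion:   f = (1 - 2 BAF) / (rho (1 - BAF))
    * copy-neutral LOH:    f = (1 - 2 BAF) / rho
    * one-copy gain:       f = (1 / BAF - 2) / rho

    An explicit ``fraction`` on the segment passes through unchanged.
    When logR is also present, the logR-implied fraction is reported via
    ``raw_ccf`` diagnostics only through the clamped estimate; BAF wins.
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity must be in (0,1], got {purity}")
    if segment.fraction is not None:
        f = float(segment.fraction)
        return CcfEstimate(event_id=event_id, ccf=f, ci_low=f, ci_high=f,
                           multiplicity=1, local_cn=segment.cn, purity=purity,
                           raw_ccf=f)
    if segment.baf is None:
        raise SignalError(
            f"segment {segment.chrom}:{segment.start}-{segment.end} has neither "
            "BAF nor an explicit fraction")
    b = min(segment.baf, 1.0 - segment.baf)  # mirrored BAF
    cls = segment.cnv_class
    if cls == "del":
        raw = (1.0 - 2.0 * b) / (purity * (1.0 - b))
    elif cls == "LOH":
        raw = (1.0 - 2.0 * b) / purity
    else:  # dup
        raw = ((1.0 / b) - 2.0) / purity if b > 0 else 1.0 / purity
    f = float(min(1.0, max(0.0, raw)))
    ci_low = ci_high = f
    if baf_sd is not None:
        # delta-method interval from the array noise level
        db = 1e-6
        seg_hi = _fraction_from_baf(min(b + db, 0.5), cls, purity)
        slope = abs(seg_hi - raw) / db
        half = 1.96 * slope * baf_sd
        ci_low = float(min(1.0, max(0.0, raw - half)))
        ci_high = float(min(1.0, max(0.0, raw + half)))
    return CcfEstimate(event_id=event_id, ccf=f, ci_low=ci_low, ci_high=ci_high,
                       multiplicity=1, local_cn=segment.cn, purity=purity,
                       raw_ccf=raw, model_violation=raw > MODEL_VIOLATION_THRESHOLD)


def _fraction_from_baf(b: float, cls: str, purity: float) -> float:
    if cls == "del":
        return (1.0 - 2.0 * b) / (purity * (1.0 - b))
    if cls == "LOH":
        return (1.0 - 2.0 * b) / purity
    return ((1.0 / b) - 2.0) / purity if b > 0 else 1.0 / purity
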