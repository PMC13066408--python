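"""Cohort-level mutational-landscape statistics.

Covers burden summaries, age associations of mutated genes (rank-sum with
BH adjustment), age-normalized mutation-density curves (ratio of Gaussian
KDEs with a shared bandwidth), exploratory mutual exclusivity (Fisher
exact on 2x2 tables, unadjusted), length-weighted CNV frequency tracks
over fixed genome bins, and event co-occurrence rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import genome
from .datatypes import ClinicalRecord, CnvSegment, VariantCall
from .trajectories import bh_adjust


# ---------------------------------------------------------------------------
# gene x patient matrix

def gene_matrix(variants: list[VariantCall], clinical: list[ClinicalRecord],
                primary_only: bool = True) -> tuple[pd.DataFrame, pd.Series]:
    """Boolean genes x patients mutation matrix plus patient -> subgroup.

    ``primary_only`` restricts to each patient's earliest timepoint."""
    by_patient: dict[str, set[str]] = {r.patient_id: set() for r in clinical}
    primary_tp = {}
    for c in variants:
        primary_tp[c.patient_id] = min(primary_tp.get(c.patient_id, c.timepoint),
                                       c.timepoint)
    for c in variants:
        if c.patient_id not in by_patient:
            continue
        if primary_only and c.timepoint != primary_tp[c.patient_id]:
            continue
        by_patient[c.patient_id].add(c.gene)
    genes = sorted({g for gs in by_patient.values() for g in gs})
    patients = [r.patient_id for r in clinical]
    mat = pd.DataFrame(
        [[g in by_patient[p] for p in patients] for g in genes],
        index=genes, columns=patients, dtype=bool)
    subgroups = pd.Series({r.patient_id: r.subgroup for r in clinical},
                          name="subgroup")
    return mat, subgroups


# ---------------------------------------------------------------------------
# burden

def mutation_burden_summary(variants: list[VariantCall],
                            clinical: list[ClinicalRecord],
                            segments: list[CnvSegment] | None = None
                            ) -> pd.DataFrame:
    """Per-subgroup mean and sd of events per patient (primary samples).

    Rows are subgroups; columns report small-variant and (when segments
    are given) CNV counts. Subgroups without patients are omitted. A
    single-patient subgroup reports sd 0 with ``degenerate_sd=True``."""
    sub_of = {r.patient_id: r.subgroup for r in clinical}
    primary_tp: dict[str, int] = {}
    for c in variants:
        primary_tp[c.patient_id] = min(primary_tp.get(c.patient_id, c.timepoint),
                                       c.timepoint)
    for s in segments or []:
        primary_tp[s.patient_id] = min(primary_tp.get(s.patient_id, s.timepoint),
                                       s.timepoint)

    var_counts = {r.patient_id: 0 for r in clinical}
    for c in variants:
        if c.patient_id in var_counts and c.timepoint == primary_tp.get(c.patient_id, 0):
            var_counts[c.patient_id] += 1
    cnv_counts = {r.patient_id: 0 for r in clinical}
    for s in segments or []:
        if s.patient_id in cnv_counts and s.timepoint == primary_tp.get(s.patient_id, 0):
            cnv_counts[s.patient_id] += 1

    rows = []
    for sg in sorted({r.subgroup for r in clinical}):
        pids = [p for p, g in sub_of.items() if g == sg]
        if not pids:
            continue
        v = np.array([var_counts[p] for p in pids], dtype=float)
        row = {
            "subgroup": sg, "n_patients": len(pids),
            "variant_mean": float(v.mean()),
            "variant_sd": float(v.std(ddof=1)) if len(pids) > 1 else 0.0,
            "degenerate_sd": len(pids) == 1,
        }
        if segments is not None:
            s = np.array([cnv_counts[p] for p in pids], dtype=float)
            row["cnv_mean"] = float(s.mean())
            row["cnv_sd"] = float(s.std(ddof=1)) if len(pids) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("subgroup")


# ---------------------------------------------------------------------------
# age associations

def gene_age_association(matrix: pd.DataFrame, ages: pd.Series,
                         min_freq: float = 0.05) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum of age between mutated and wild-type
    patients, per gene mutated in >= ``min_freq`` of the tested patients;
    BH adjustment across tested genes. Genes mutated in all or no
    patients are skipped with a note."""
    patients = [p for p in matrix.columns if p in ages.index]
    rows = []
    tested_idx = []
    for gene in matrix.index:
        mask = matrix.loc[gene, patients].to_numpy()
        freq = mask.mean()
        note = ""
        p_val = np.nan
        if freq < min_freq:
            note = "below frequency filter"
        elif mask.all() or not mask.any():
            note = "mutated in all or no patients"
        else:
            a = ages[patients].to_numpy()[mask]
            b = ages[patients].to_numpy()[~mask]
            p_val = float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                             method="auto").pvalue)
            tested_idx.append(len(rows))
        rows.append({"gene": gene, "n_mutated": int(mask.sum()),
                     "frequency": float(freq), "p_value": p_val, "note": note})
    df = pd.DataFrame(rows).set_index("gene")
    df["p_adjusted"] = np.nan
    if tested_idx:
        adj = bh_adjust(df.iloc[tested_idx]["p_value"].to_numpy())
        df.iloc[tested_idx, df.columns.get_loc("p_adjusted")] = adj
    return df


@dataclass
class AgeDensityCurve:
    label: str
    grid: np.ndarray
    density: np.ndarray          # mutated-age KDE / baseline KDE
    bandwidth: float
    supported: np.ndarray        # False where baseline fell below the floor


def age_density_curve(mutated_ages, all_ages, grid=None,
                      bandwidth: float | None = None,
                      label: str = "") -> AgeDensityCurve:
    """Mutation density normalized for the baseline age distribution.

    Gaussian KDE of the mutated patients' ages divided pointwise by a
    Gaussian KDE of all ages, both using the same absolute bandwidth
    (Silverman's rule on the baseline by default). The baseline is floored
    at 1e-6 of its maximum; grid points below the floor are flagged."""
    mutated = np.asarray(mutated_ages, dtype=float)
    baseline = np.asarray(all_ages, dtype=float)
    if len(mutated) < 2:
        raise ValueError("need >= 2 mutated patients for a density curve")
    if grid is None:
        grid = np.linspace(baseline.min(), baseline.max(), 200)
    grid = np.asarray(grid, dtype=float)
    kde_all = stats.gaussian_kde(baseline, bw_method="silverman")
    bw_abs = bandwidth if bandwidth is not None else \
        float(kde_all.factor * baseline.std(ddof=1))
    kde_all = stats.gaussian_kde(baseline, bw_method=bw_abs / baseline.std(ddof=1))
    kde_mut = stats.gaussian_kde(mutated, bw_method=bw_abs / mutated.std(ddof=1))
    base = kde_all(grid)
    mut = kde_mut(grid)
    floor = 1e-6 * base.max()
    supported = base >= floor
    density = mut / np.maximum(base, floor)
    return AgeDensityCurve(label=label, grid=grid, density=density,
                           bandwidth=bw_abs, supported=supported)


# ---------------------------------------------------------------------------
# mutual exclusivity

@dataclass
class ExclusivityResult:
    gene_a: str
    gene_b: str
    n11: int  # both mutated
    n10: int  # A only
    n01: int  # B only
    n00: int  # neither
    odds_ratio: float
    or_infinite: bool
    p_value: float
    subgroup: str = ""


def mutual_exclusivity(matrix: pd.DataFrame, gene_a: str, gene_b: str,
                       patients: list[str] | None = None,
                       subgroup: str = "") -> ExclusivityResult:
    """Sample odds ratio and two-sided Fisher exact p for a gene pair.

    Reported unadjusted (exploratory). OR = 0 when the genes never
    co-occur; an infinite OR (n11>0 with an empty discordant cell) is
    flagged rather than returned as a number."""
    if patients is None:
        patients = list(matrix.columns)
    if not patients:
        raise ValueError("empty patient set")
    a = matrix.loc[gene_a, patients].to_numpy()
    b = matrix.loc[gene_b, patients].to_numpy()
    n11 = int((a & b).sum())
    n10 = int((a & ~b).sum())
    n01 = int((~a & b).sum())
    n00 = int((~a & ~b).sum())
    or_infinite = False
    if n11 == 0:
        odds = 0.0
    elif n10 * n01 == 0:
        odds = float("inf")
        or_infinite = True
    else:
        odds = (n11 * n00) / (n10 * n01)
    p = float(stats.fisher_exact([[n11, n10], [n01, n00]],
                                 alternative="two-sided")[1])
    return ExclusivityResult(gene_a, gene_b, n11, n10, n01, n00,
                             odds, or_infinite, p, subgroup)


# ---------------------------------------------------------------------------
# CNV frequency tracks

@dataclass
class CnvFrequencyTrack:
    """Per-bin, per-class fraction of patients with an overlapping CNV."""

    bin_size: int
    build: str
    n_patients: int
    subgroup: str
    # (chrom, class) -> frequency per bin
    frequencies: dict[tuple[str, str], np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        table = genome.arm_table(self.build)
        for (chrom, cls), freq in sorted(self.frequencies.items()):
            length = table[chrom][0]
            for i, f in enumerate(freq):
                if f > 0:
                    rows.append({
                        "chrom": chrom,
                        "start": i * self.bin_size + 1,
                        "end": min((i + 1) * self.bin_size, length),
                        "class": cls,
                        "subgroup": self.subgroup,
                        "frequency": float(f),
                    })
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "class",
                                           "subgroup", "frequency"])


CNV_CLASSES = ("del", "LOH", "dup")


def cnv_frequency_track(segments: list[CnvSegment], patients: list[str],
                        bin_size: int = 1_000_000, build: str = "GRCh38",
                        subgroup: str = "") -> CnvFrequencyTrack:
    """Fraction of patients with >= 1 overlapping segment per 1 Mb bin and
    CNV class. A patient counts once per bin regardless of how the
    covering segments are split."""
    if not patients:
        raise ValueError("empty patient set")
    table = genome.arm_table(build)
    pset = set(patients)
    counts: dict[tuple[str, str], np.ndarray] = {}
    seen: dict[tuple[str, str, str], np.ndarray] = {}  # (patient, chrom, cls)
    for s in segments:
        if s.patient_id not in pset:
            continue
        chrom = genome.normalize_chrom(s.chrom)
        if chrom not in table:
            raise KeyError(f"unknown chromosome {s.chrom!r} for build {build}")
        n_bins = int(np.ceil(table[chrom][0] / bin_size))
        cls = s.cnv_class
        key = (s.patient_id, chrom, cls)
        if key not in seen:
            seen[key] = np.zeros(n_bins, dtype=bool)
        lo = (s.start - 1) // bin_size
        hi = (s.end - 1) // bin_size
        seen[key][lo:hi + 1] = True
    for (pid, chrom, cls), mask in seen.items():
        ckey = (chrom, cls)
        if ckey not in counts:
            counts[ckey] = np.zeros(len(mask), dtype=float)
        counts[ckey] += mask
    freqs = {k: v / len(patients) for k, v in counts.items()}
    return CnvFrequencyTrack(bin_size=bin_size, build=build,
                             n_patients=len(patients), subgroup=subgroup,
                             frequencies=freqs)


def arm_weighted_frequency(track: CnvFrequencyTrack, chrom: str, arm: str,
                           cnv_class: str) -> float:
    """Length-weighted mean bin frequency over a chromosome arm (or the
    whole chromosome with ``arm=''``)."""
    chrom = genome.normalize_chrom(chrom)
    table = genome.arm_table(track.build)
    length, cen = table[chrom]
    if arm == "p":
        lo_bp, hi_bp = 1, cen
    elif arm == "q":
        lo_bp, hi_bp = cen + 1, length
    elif arm == "":
        lo_bp, hi_bp = 1, length
    else:
        raise ValueError(f"arm must be 'p', 'q' or '', got {arm!r}")
    n_bins = int(np.ceil(length / track.bin_size))
    freq = track.frequencies.get((chrom, cnv_class), np.zeros(n_bins))
    starts = np.arange(n_bins, dtype=float) * track.bin_size + 1
    ends = np.minimum(starts + track.bin_size - 1, length)
    overlap = np.maximum(0.0, np.minimum(ends, hi_bp) - np.maximum(starts, lo_bp) + 1)
    if overlap.sum() == 0:
        return 0.0
    return float(np.average(freq, weights=overlap))


# ---------------------------------------------------------------------------
# co-occurrence

def cooccurrence_rate(events_by_patient: dict[str, set[str]], event_a: str,
                      event_b: str, patients: list[str] | None = None) -> float:
    """Fraction of the patient set harboring both events (any clone, any
    sample of the primary disease)."""
    if patients is None:
        patients = sorted(events_by_patient)
    if not patients:
        return 0.0
    hits = sum(1 for p in patients
               if event_a in events_by_patient.get(p, set())
               and event_b in events_by_patient.get(p, set()))
    return hits / len(patients)
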