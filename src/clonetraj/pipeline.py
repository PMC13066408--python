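"""End-to-end pipeline: (simulate or ingest) -> purity/CCF -> clone trees
-> trajectories & nested levels -> landscape statistics -> survival model.

Per-patient failures (e.g. contradictory phasing constraints) are
isolated: the patient is logged and skipped, cohort statistics run on
the successful subset, and the counts are recorded in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import ccf as ccf_mod
from . import io, landscape, outcomes, simulate, trajectories, trees
from .datatypes import CnvSegment, SUBGROUPS, VariantCall

log = logging.getLogger("clonetraj.pipeline")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Validated run configuration; unknown keys are rejected."""

    out_dir: str
    variants: str | None = None
    segments: str | None = None
    clinical: str | None = None
    simulate: dict | None = None          # SimConfig fields
    vaf_threshold: float = io.DEFAULT_VAF_THRESHOLD
    epsilon: float | None = None          # None = depth-scaled default
    n_perm: int = 2000
    seed: int = 0
    genome_build: str = "GRCh38"
    max_clusters: int = 6
    marker_gene: str = "NOTCH1"

    _KNOWN = ("out_dir", "variants", "segments", "clinical", "simulate",
              "vaf_threshold", "epsilon", "n_perm", "seed", "genome_build",
              "max_clusters", "marker_gene")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - set(cls._KNOWN)
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        if "out_dir" not in raw:
            raise PipelineError("config requires out_dir")
        return cls(**raw)

    def validate_inputs(self) -> None:
        if self.simulate is None:
            for name in ("variants", "segments", "clinical"):
                p = getattr(self, name)
                if p is None:
                    raise PipelineError(f"config requires {name} (or a simulate block)")
                if not Path(p).exists():
                    raise PipelineError(f"{name} file not found: {p}")
        if not 0.0 <= self.vaf_threshold <= 1.0:
            raise PipelineError("vaf_threshold must be in [0,1]")

    def sim_config(self) -> simulate.SimConfig:
        d = dict(self.simulate or {})
        d.setdefault("seed", self.seed)
        return simulate.SimConfig(**d)


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    n_patients: int
    n_trees: int
    failed_patients: list[str]
    checksums: dict[str, str]
    started: float
    finished: float

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "version": self.version,
            "seed": self.seed,
            "n_patients": self.n_patients,
            "n_trees": self.n_trees,
            "failed_patients": list(self.failed_patients),
            "checksums": dict(sorted(self.checksums.items())),
            "started": self.started,
            "finished": self.finished,
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# observation assembly

def _segment_overlaps(seg: CnvSegment, chrom: str, pos: int) -> bool:
    from .genome import normalize_chrom
    return (normalize_chrom(seg.chrom) == normalize_chrom(chrom)
            and seg.start <= pos <= seg.end)


def build_observations(calls: list[VariantCall], segments: list[CnvSegment],
                       purity: dict[int, float], timepoints: list[int],
                       build: str = "GRCh38", baf_sd: float = 0.02,
                       fallback_depth: int = 500
                       ) -> tuple[list[trees.EventObservation], dict[str, str]]:
    """Assemble per-event CCF-scale observations for one patient.

    Small variants keyed by gene (position-disambiguated on collision);
    CNVs keyed by their trajectory label. Timepoints where a known event
    was not observed contribute a zero-alt pseudo-observation at the
    typical depth. Returns ``(observations, labels)`` where ``labels``
    maps event ids to trajectory labels.
    """
    median_depth: dict[int, float] = {}
    for tp in timepoints:
        depths = [c.depth for c in calls if c.timepoint == tp]
        median_depth[tp] = float(np.median(depths)) if depths else float(fallback_depth)

    # --- small variants ---------------------------------------------------
    by_locus: dict[tuple, dict[int, VariantCall]] = {}
    for c in calls:
        key = (c.gene, c.chrom, c.pos, c.ref, c.alt)
        by_locus.setdefault(key, {})[c.timepoint] = c
    gene_counts: dict[str, int] = {}
    for key in by_locus:
        gene_counts[key[0]] = gene_counts.get(key[0], 0) + 1

    observations: list[trees.EventObservation] = []
    labels: dict[str, str] = {}
    for key, per_tp in sorted(by_locus.items()):
        gene, chrom, pos, _, _ = key
        event_id = gene if gene_counts[gene] == 1 else f"{gene}@{pos}"
        ob = trees.EventObservation(event_id=event_id, kind="snv")
        for tp in timepoints:
            rho = purity[tp]
            call = per_tp.get(tp)
            # local copy number from an overlapping segment at this timepoint
            n_t, seg_here = 2, None
            for s in segments:
                if s.timepoint == tp and _segment_overlaps(s, chrom, pos):
                    seg_here = s
                    n_t = s.cn
                    break
            if n_t == 0:
                n_t = 2  # homozygous-deletion conflict: fall back, flag upstream
            if call is not None:
                alt = call.alt_reads if call.alt_reads is not None \
                    else call.vaf * call.depth
                m = ccf_mod.estimate_multiplicity(call.vaf, rho, n_t)
                ob.alt[tp] = float(alt)
                ob.depth[tp] = float(call.depth)
                ob.coeff[tp] = ccf_mod.vaf_coefficient(rho, n_t, m)
            else:
                ob.alt[tp] = 0.0
                ob.depth[tp] = median_depth[tp]
                ob.coeff[tp] = ccf_mod.vaf_coefficient(rho, 2, 1)
        observations.append(ob)
        labels[event_id] = gene

    # --- CNVs ---------------------------------------------------------------
    by_cnv: dict[tuple, dict[int, CnvSegment]] = {}
    for s in segments:
        lab = trajectories.cnv_event_label(s, build=build)
        by_cnv.setdefault((lab, s.chrom, s.start, s.end), {})[s.timepoint] = s
    for (lab, chrom, start, end), per_tp in sorted(by_cnv.items()):
        event_id = lab
        if event_id in labels or any(o.event_id == event_id for o in observations):
            event_id = f"{lab}@{start}"
        ob = trees.EventObservation(event_id=event_id, kind="cnv")
        for tp in timepoints:
            seg = per_tp.get(tp)
            if seg is not None:
                est = ccf_mod.cnv_fraction(seg, purity[tp], event_id=event_id,
                                           baf_sd=baf_sd)
                ob.f_hat[tp] = est.ccf
                ob.f_sd[tp] = max((est.ci_high - est.ci_low) / 3.92, 0.01)
            else:
                ob.f_hat[tp] = 0.0
                ob.f_sd[tp] = 0.05
        observations.append(ob)
        labels[event_id] = lab
    return observations, labels


def reconstruct_patient(patient_id: str, calls: list[VariantCall],
                        segments: list[CnvSegment],
                        purity_override: float | None = None,
                        build: str = "GRCh38", max_k: int = 6, seed: int = 0,
                        eps: float | None = None,
                        baf_sd: float = 0.02) -> trees.CloneTreeResult:
    """Purity -> CCF observations -> clone tree for one patient.

    Purity per timepoint from CN-neutral calls (outside any aberrant
    segment at that timepoint) unless overridden."""
    if not calls and not segments:
        raise trees.ReconstructionError(f"{patient_id}: no events")
    timepoints = sorted({c.timepoint for c in calls}
                        | {s.timepoint for s in segments})
    purity: dict[int, float] = {}
    for tp in timepoints:
        if purity_override is not None:
            purity[tp] = float(purity_override)
            continue
        # any clonal event bounds the purity from below: take the largest
        # implied rho*phi over CN-neutral variants (2*VAF) and CNV signals
        candidates = [2.0 * c.vaf for c in calls
                      if c.timepoint == tp and not any(
                          s.timepoint == tp and _segment_overlaps(s, c.chrom, c.pos)
                          for s in segments)]
        for s in segments:
            if s.timepoint == tp:
                rf = ccf_mod.implied_purity_fraction(s)
                if rf is not None:
                    candidates.append(rf)
        purity[tp] = float(min(1.0, max(candidates))) if candidates else 1.0
        purity[tp] = max(purity[tp], 0.05)
    observations, labels = build_observations(calls, segments, purity,
                                              timepoints, build=build,
                                              baf_sd=baf_sd)
    result = trees.reconstruct(observations, patient_id=patient_id,
                               max_k=max_k, seed=seed, eps=eps)
    result.tree = trajectories.label_events(result.tree, labels, build=build)
    return result


# ---------------------------------------------------------------------------
# full run

def run_pipeline(config: PipelineConfig) -> RunManifest:
    started = _time.time()
    config.validate_inputs()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree_dir = out / "trees"
    tree_dir.mkdir(exist_ok=True)

    # --- stage 0: inputs ---------------------------------------------------
    if config.simulate is not None:
        sim_dir = out / "cohort"
        paths = simulate.simulate_cohort(config.sim_config(), sim_dir, force=True)
        variants_path, segments_path, clinical_path = (
            paths["variants"], paths["segments"], paths["clinical"])
    else:
        variants_path, segments_path, clinical_path = (
            config.variants, config.segments, config.clinical)

    detected = io.read_variant_table(variants_path, vaf_threshold=config.vaf_threshold)
    all_calls = io.read_variant_table(variants_path, vaf_threshold=0.0)
    segments = io.read_cnv_segments(segments_path)
    clinical = io.read_clinical_table(clinical_path)
    if not clinical:
        raise PipelineError("clinical table is empty")

    detected_keys = {(c.patient_id, c.gene, c.chrom, c.pos) for c in detected}
    # quantify detected events at every timepoint (force-called)
    quant = [c for c in all_calls
             if (c.patient_id, c.gene, c.chrom, c.pos) in detected_keys]

    calls_by_patient: dict[str, list[VariantCall]] = {}
    for c in quant:
        calls_by_patient.setdefault(c.patient_id, []).append(c)
    segs_by_patient: dict[str, list[CnvSegment]] = {}
    for s in segments:
        segs_by_patient.setdefault(s.patient_id, []).append(s)

    # --- stage 1: per-patient reconstruction --------------------------------
    results: dict[str, trees.CloneTreeResult] = {}
    failed: list[str] = []
    for rec in clinical:
        pid = rec.patient_id
        pcalls = calls_by_patient.get(pid, [])
        psegs = segs_by_patient.get(pid, [])
        if not pcalls and not psegs:
            log.warning("%s: no events, skipped", pid)
            failed.append(pid)
            continue
        try:
            res = reconstruct_patient(pid, pcalls, psegs, build=config.genome_build,
                                      max_k=config.max_clusters, seed=config.seed,
                                      eps=config.epsilon)
        except trees.ReconstructionError as e:
            log.warning("%s: reconstruction failed (%s)", pid, e)
            failed.append(pid)
            continue
        results[pid] = res
        io.write_tree_json(res.tree, tree_dir / f"{pid}.json")
        if res.ambiguous:
            log.warning("%s: %d co-optimal trees", pid, res.n_co_optimal)
    if not results:
        raise PipelineError("zero successfully reconstructed trees")

    ambiguity = pd.DataFrame(
        [{"patient_id": pid, "n_candidates": r.n_candidates,
          "n_co_optimal": r.n_co_optimal, "epsilon": r.epsilon,
          "violation": r.violation} for pid, r in sorted(results.items())])
    ambiguity.to_csv(out / "ambiguity.tsv", sep="\t", index=False)

    # --- stage 2: trajectories + nested levels ------------------------------
    sub_of = {r.patient_id: r.subgroup for r in clinical}
    traj_frames = []
    nested_rows = []
    for sg in SUBGROUPS:
        sg_trees = [r.tree for pid, r in sorted(results.items())
                    if sub_of.get(pid) == sg]
        if not sg_trees:
            continue
        df = trajectories.test_cohort_trajectories(
            sg_trees, subgroup=sg, n_perm=config.n_perm, seed=config.seed,
            strict=False)
        if len(df):
            traj_frames.append(df)
        nl_tree = trajectories.weighted_nested_level(sg_trees, "tree", subgroup=sg)
        nested_rows.append({"subgroup": sg, "scope": "tree", "labels": "",
                            "value": nl_tree.value, "n": nl_tree.n})
        chr9_labels = {"del_in_9p", "LOH_in_9p", "del9", "LOH9"}
        try:
            nl_cls = trajectories.weighted_nested_level(
                sg_trees, "event_class", labels=chr9_labels, subgroup=sg)
            nested_rows.append({"subgroup": sg, "scope": "event_class",
                                "labels": "chr9 del/LOH", "value": nl_cls.value,
                                "n": nl_cls.n})
        except ValueError:
            pass
    traj_df = pd.concat(traj_frames, ignore_index=True) if traj_frames \
        else pd.DataFrame()
    if len(traj_df):
        traj_df = traj_df.drop(columns=["labels"])
    traj_df.to_csv(out / "trajectories.tsv", sep="\t", index=False)
    pd.DataFrame(nested_rows).to_csv(out / "nested_levels.tsv", sep="\t", index=False)

    # --- stage 3: landscape --------------------------------------------------
    matrix, subgroups = landscape.gene_matrix(detected, clinical)
    landscape.mutation_burden_summary(detected, clinical, segments).to_csv(
        out / "burden.tsv", sep="\t")
    ages = pd.Series({r.patient_id: r.age_years for r in clinical})
    if len(matrix):
        landscape.gene_age_association(matrix, ages).to_csv(
            out / "age_association.tsv", sep="\t")
    track_frames = []
    for sg in SUBGROUPS:
        pids = [r.patient_id for r in clinical if r.subgroup == sg]
        if not pids:
            continue
        track = landscape.cnv_frequency_track(segments, pids,
                                              build=config.genome_build,
                                              subgroup=sg)
        frame = track.to_frame()
        if len(frame):
            track_frames.append(frame)
    (pd.concat(track_frames, ignore_index=True) if track_frames
     else pd.DataFrame()).to_csv(out / "cnv_track.tsv", sep="\t", index=False)

    # --- stage 4: survival ----------------------------------------------------
    records = []
    for rec in clinical:
        res = results.get(rec.patient_id)
        if res is None:
            continue
        try:
            cov = outcomes.notch_wt_fraction(res.tree, min(res.tree.timepoints),
                                             marker_gene=config.marker_gene)
        except ValueError:
            continue
        records.append(outcomes.SurvivalRecord(
            patient_id=rec.patient_id, covariate=cov,
            time=rec.time_to_event_days, event=rec.event_observed,
            strata=rec.subgroup))
    pd.DataFrame([{
        "patient_id": r.patient_id, "covariate": r.covariate, "time": r.time,
        "event": r.event, "strata": r.strata} for r in records]).to_csv(
        out / "survival_records.tsv", sep="\t", index=False)
    survival_report: dict = {"n": len(records)}
    try:
        fit = outcomes.fit_cox_ph(records)
        survival_report.update({
            "beta": fit.beta, "hr": fit.hr, "ci_low": fit.ci_low,
            "ci_high": fit.ci_high, "p_value": fit.p_value,
            "n_events": fit.n_events,
            "hazard_increase_percent_per_point": fit.hazard_increase_percent(),
        })
    except (ValueError, outcomes.SeparationError) as e:
        survival_report["error"] = str(e)
    (out / "survival.json").write_text(
        json.dumps(survival_report, indent=1, sort_keys=True), encoding="utf-8")

    # --- manifest ---------------------------------------------------------------
    checksums = {}
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            checksums[str(p.relative_to(out))] = _sha256(p)
    manifest = RunManifest(
        config_hash=hashlib.sha256(
            json.dumps({k: getattr(config, k) for k in config._KNOWN},
                       sort_keys=True, default=str).encode()).hexdigest()[:16],
        version=__version__,
        seed=config.seed,
        n_patients=len(clinical),
        n_trees=len(results),
        failed_patients=failed,
        checksums=checksums,
        started=started,
        finished=_time.time(),
    )
    (out / "manifest.json").write_text(
        json.dumps(manifest.to_dict(), indent=1, sort_keys=True), encoding="utf-8")
    return manifest
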