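"""Synthetic T-ALL/T-LBL cohort generator.

Emulates the statistical structure the downstream analysis assumes:

* four subgroups (pediatric/adult x T-ALL/T-LBL);
* per-patient truth clone trees of 1-8 clones over 1-4 timepoints, with
  gene and CNV event labels and subtree-inclusive CCFs obeying the sum
  rule exactly (founding clone CCF = 1);
* panel-NGS read noise (Poisson depth around 500x, binomial alt reads at
  the expected VAF) and SNP-array noise (Gaussian BAF / logR around the
  class-specific allele model);
* relapse outcomes whose log hazard is linear in the NOTCH1-wild-type
  tumor fraction (default slope ln(1.032) per percentage point) with
  independent exponential censoring.

Label placement is exchangeable across tree slots when no trajectory
bias applies (the patient's label multiset is drawn first, then assigned
by a uniform permutation), so within-patient label-shuffle permutation
tests are exactly calibrated on unbiased cohorts. A trajectory bias
(source, target, multiplier) re-places the target label with extra
weight on slots strictly descendant of the source's node; multiplier 1
reduces to the uniform null.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import genome, io, outcomes, trees
from .datatypes import (
    ClinicalRecord,
    CloneNode,
    CloneTreeDocument,
    CnvSegment,
    SUBGROUPS,
    VariantCall,
)


class ConfigError(ValueError):
    pass


@dataclass
class EventSpec:
    label: str
    kind: str  # "gene" | "cnv"
    weight: float = 1.0
    subgroup_weights: dict[str, float] = field(default_factory=dict)

    def weight_for(self, subgroup: str) -> float:
        return self.subgroup_weights.get(subgroup, self.weight)


@dataclass
class TrajectoryBias:
    source: str
    target: str
    multiplier: float
    subgroups: tuple[str, ...] | None = None  # None = all subgroups

    def applies(self, subgroup: str) -> bool:
        return self.subgroups is None or subgroup in self.subgroups


def default_vocabulary() -> list[EventSpec]:
    """Gene and CNV labels mirroring the recurrently altered loci of
    T-lymphoblastic neoplasia panels."""
    return [
        EventSpec("NOTCH1", "gene", 3.0),
        EventSpec("PHF6", "gene", 1.2),
        EventSpec("FBXW7", "gene", 1.0),
        EventSpec("PTEN", "gene", 0.8),
        EventSpec("BCL11B", "gene", 0.6),
        EventSpec("USP7", "gene", 0.5),
        EventSpec("KMT2D", "gene", 0.5),
        EventSpec("TP53", "gene", 0.4),
        EventSpec("del_in_9p", "cnv", 1.5),
        EventSpec("LOH_in_9p", "cnv", 1.5),
        EventSpec("dup_in_9p", "cnv", 0.5),
        EventSpec("dup20", "cnv", 0.5,
                  subgroup_weights={"pediatric T-LBL": 1.2}),
        EventSpec("del_in_6q", "cnv", 0.4),
    ]


def default_bias() -> list[TrajectoryBias]:
    """Chromosome-9p LOH preceding NOTCH1 mutation, enriched in the
    pediatric subgroups."""
    ped = ("pediatric T-ALL", "pediatric T-LBL")
    return [TrajectoryBias("LOH_in_9p", "NOTCH1", 10.0, ped)]


@dataclass
class SimConfig:
    """Cohort-level simulation parameters; see docs/methods.md for the
    rationale behind each default."""

    n_patients: int | dict[str, int] = 10  # per subgroup
    seed: int = 0
    clones_per_tree: tuple[int, int] = (1, 8)
    timepoints_per_patient: tuple[int, int] = (1, 4)
    root_events: tuple[int, int] = (1, 3)
    subclone_events: tuple[int, int] = (1, 2)
    event_vocabulary: list[EventSpec] = field(default_factory=default_vocabulary)
    trajectory_bias: list[TrajectoryBias] = field(default_factory=default_bias)
    mean_depth: int = 500
    purity_range: tuple[float, float] = (0.5, 1.0)
    baf_sd: float = 0.02
    logr_sd: float = 0.05
    hazard_beta: float = math.log(1.032)  # per percentage point
    baseline_hazard: float = 5e-4         # events per day at covariate 0
    censoring_rate: float = 5e-4          # per day
    min_ccf_gap: float = 0.15             # L-inf separation between clones
    require_identifiable: bool = False
    noise: bool = True

    def validate(self) -> None:
        for name in ("clones_per_tree", "timepoints_per_patient",
                     "root_events", "subclone_events"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ConfigError(f"{name} range {lo}..{hi} is empty or invalid")
        if self.clones_per_tree[1] > 8:
            raise ConfigError("clones_per_tree upper bound is 8")
        if self.timepoints_per_patient[1] > 4:
            raise ConfigError("timepoints_per_patient upper bound is 4")
        if not self.event_vocabulary:
            raise ConfigError("event vocabulary is empty")
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigError("purity_range must lie within (0,1]")
        if self.mean_depth < 1 or self.baf_sd <= 0 or self.logr_sd <= 0:
            raise ConfigError("noise parameters must be positive")
        if self.baseline_hazard <= 0 or self.censoring_rate < 0:
            raise ConfigError("hazard parameters must be positive")

    def n_for(self, subgroup: str) -> int:
        if isinstance(self.n_patients, dict):
            return int(self.n_patients.get(subgroup, 0))
        return int(self.n_patients)

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["event_vocabulary"] = [asdict(e) for e in self.event_vocabulary]
        d["trajectory_bias"] = [
            {**asdict(b), "subgroups": list(b.subgroups) if b.subgroups else None}
            for b in self.trajectory_bias
        ]
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_jsonable(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class TruthRecord:
    patient_id: str
    subgroup: str
    tree: CloneTreeDocument
    purity: dict[int, float]               # per timepoint
    kinds: dict[str, str]                  # event label -> gene | cnv
    covariate: float                       # NOTCH1-WT fraction at diagnosis, %
    age_years: float = 0.0
    event_time: float | None = None
    event_observed: bool | None = None


# ---------------------------------------------------------------------------
# tree simulation

def _draw_topology(n: int, rng) -> list[int]:
    """Random recursive tree: node 0 is the founder, each later node picks
    a uniform parent among the earlier ones."""
    return [-1] + [int(rng.integers(0, i)) for i in range(1, n)]


def _draw_ccfs(parents: list[int], n_tp: int, rng, min_gap: float,
               max_tries: int = 80) -> np.ndarray | None:
    """CCF matrix (clones x timepoints) satisfying the sum rule exactly:
    founder = 1, each node's children split a Dirichlet share of the
    parent's CCF (one share left unassigned so strict subclonality is
    typical). Rejects draws whose clones are not separated by ``min_gap``
    (L-inf over timepoints) or never reach ``min_gap`` anywhere; the
    caller shrinks the tree when no separated configuration is found."""
    n = len(parents)
    children: list[list[int]] = [[] for _ in range(n)]
    for i, p in enumerate(parents):
        if p >= 0:
            children[p].append(i)
    eye_big = np.eye(n) * 10.0
    for _ in range(max_tries):
        ccf = np.zeros((n, n_tp))
        ccf[0] = 1.0
        for node in range(n):  # parents precede children
            kids = children[node]
            if not kids:
                continue
            g = rng.gamma(1.0, size=(n_tp, len(kids) + 1))
            shares = g[:, :-1] / g.sum(axis=1, keepdims=True)
            ccf[kids, :] = shares.T * ccf[node][None, :]
        if n > 1:
            diffs = np.abs(ccf[:, None, :] - ccf[None, :, :]).max(axis=2) + eye_big
            if diffs.min() < min_gap or (ccf[1:].max(axis=1) < min_gap).any():
                continue
        return ccf
    return None


def _truth_parent_unique(parents: list[int], ccf: np.ndarray) -> bool:
    """True iff the truth tree is the unique sum-rule-consistent tree on
    the true clone CCFs (pure enumeration; no inference involved)."""
    pvecs = trees.enumerate_parent_vectors(ccf, eps=1e-9)
    return len(pvecs) == 1 and list(pvecs[0]) == parents


def _weighted_sample_without_replacement(labels, weights, k, rng):
    """Exponential-race sampling: weighted without replacement."""
    keys = rng.exponential(1.0, size=len(labels)) / np.asarray(weights)
    order = np.argsort(keys, kind="stable")
    return [labels[i] for i in order[:k]]


def _place_labels(labels: list[str], slots: list[int], parents: list[int],
                  biases: list[TrajectoryBias], rng) -> list[str]:
    """Assign the drawn labels to node slots.

    Uniform permutation first (exchangeable null), then each applicable
    bias jointly re-places its (source, target) labels on an ordered slot
    pair drawn with weight ``multiplier`` when the source slot's node is
    a strict ancestor of the target slot's node and weight 1 otherwise.
    Multiplier 1 therefore reduces exactly to the uniform null."""
    assert len(labels) == len(slots)
    placed = [labels[i] for i in rng.permutation(len(labels))]
    L = len(slots)
    if L < 2:
        return placed

    def strict_descendant(node: int, anc: int) -> bool:
        cur = parents[node]
        while cur != -1:
            if cur == anc:
                return True
            cur = parents[cur]
        return False

    for bias in biases:
        if bias.source not in placed or bias.target not in placed:
            continue
        pairs = [(s1, s2) for s1 in range(L) for s2 in range(L) if s1 != s2]
        w = np.array([bias.multiplier
                      if strict_descendant(slots[s2], slots[s1]) else 1.0
                      for s1, s2 in pairs])
        s1, s2 = pairs[int(rng.choice(len(pairs), p=w / w.sum()))]
        i_a = placed.index(bias.source)
        placed[i_a], placed[s1] = placed[s1], placed[i_a]
        i_b = placed.index(bias.target)
        placed[i_b], placed[s2] = placed[s2], placed[i_b]
    return placed


def simulate_tree(config: SimConfig, subgroup: str, rng,
                  patient_id: str = "P0") -> TruthRecord:
    """Draw one patient's truth: topology, CCFs, events, purity."""
    config.validate()
    if subgroup not in SUBGROUPS:
        raise ConfigError(f"unknown subgroup {subgroup!r}")
    vocab = config.event_vocabulary
    biases = [b for b in config.trajectory_bias if b.applies(subgroup)]

    lo, hi = config.clones_per_tree
    n_clones = int(rng.integers(lo, hi + 1))
    n_tp = int(rng.integers(config.timepoints_per_patient[0],
                            config.timepoints_per_patient[1] + 1))
    day_grid = np.arange(180, 1320, 30)
    extra = sorted(rng.choice(day_grid, size=n_tp - 1, replace=False)) if n_tp > 1 else []
    timepoints = [0] + [int(d) for d in extra]

    ccf = None
    parents: list[int] = []
    for attempt in range(40):  # shrink the tree if the gap cannot be met
        parents = _draw_topology(n_clones, rng)
        n_tries = 30 if config.require_identifiable else 1
        for _ in range(n_tries):
            ccf = _draw_ccfs(parents, n_tp, rng, config.min_ccf_gap)
            if ccf is not None and config.require_identifiable \
                    and not _truth_parent_unique(parents, ccf):
                ccf = None
            if ccf is not None:
                break
        if ccf is not None:
            break
        if n_clones > 1 and rng.uniform() < 0.5:
            n_clones -= 1
    if ccf is None:
        # degenerate fallback: single clone is always valid
        n_clones, parents = 1, [-1]
        ccf = np.ones((1, n_tp))

    # events per clone, capped by the vocabulary size
    counts = [int(rng.integers(config.root_events[0], config.root_events[1] + 1))]
    counts += [int(rng.integers(config.subclone_events[0],
                                config.subclone_events[1] + 1))
               for _ in range(n_clones - 1)]
    total = sum(counts)
    while total > len(vocab):
        for i in range(n_clones - 1, -1, -1):
            if counts[i] > 1 and total > len(vocab):
                counts[i] -= 1
                total -= 1
        if max(counts) == 1:
            break
    total = min(sum(counts), len(vocab))

    weights = [max(e.weight_for(subgroup), 1e-9) for e in vocab]
    labels = _weighted_sample_without_replacement(
        [e.label for e in vocab], weights, total, rng)
    slots: list[int] = []
    for node, cnt in enumerate(counts):
        slots.extend([node] * cnt)
    slots = slots[:total]
    placed = _place_labels(labels, slots, parents, biases, rng)

    events_by_node: dict[int, list[str]] = {i: [] for i in range(n_clones)}
    for label, node in zip(placed, slots):
        events_by_node[node].append(label)

    nodes = []
    for i in range(n_clones):
        nodes.append(CloneNode(
            node_id=f"C{i + 1}",
            parent_id=None if parents[i] == -1 else f"C{parents[i] + 1}",
            events=sorted(events_by_node[i]),
            ccf_by_timepoint={tp: float(ccf[i, j]) for j, tp in enumerate(timepoints)},
        ))
    doc = CloneTreeDocument(patient_id=patient_id, nodes=nodes,
                            timepoints=timepoints)
    doc.validate()

    kinds = {e.label: e.kind for e in vocab}
    purity = {tp: float(rng.uniform(*config.purity_range)) for tp in timepoints}
    covariate = outcomes.notch_wt_fraction(doc, 0)
    age_group = subgroup.split(" ")[0]
    age = float(rng.uniform(1.5, 17.9) if age_group == "pediatric"
                else rng.uniform(18.0, 65.0))
    return TruthRecord(patient_id=patient_id, subgroup=subgroup, tree=doc,
                       purity=purity,
                       kinds={l: kinds[l] for l in placed},
                       covariate=covariate, age_years=age)


# ---------------------------------------------------------------------------
# observation forward models

def expected_vaf_for(ccf_value: float, purity: float) -> float:
    """Forward model for a heterozygous diploid small variant."""
    return ccf_value * purity / (purity * 2.0 + (1.0 - purity) * 2.0)


def cnv_signal_expectations(cnv_class: str, purity: float, fraction: float
                            ) -> tuple[float, float]:
    """Noise-free (BAF, logR) for a CNV class at tumor-cell fraction f."""
    rf = purity * fraction
    if cnv_class == "del":
        return (1.0 - rf) / (2.0 - rf), math.log2((2.0 - rf) / 2.0)
    if cnv_class == "LOH":
        return (1.0 - rf) / 2.0, 0.0
    if cnv_class == "dup":
        return 1.0 / (2.0 + rf), math.log2((2.0 + rf) / 2.0)
    raise ValueError(f"unknown CNV class {cnv_class!r}")


def _label_cnv_class(label: str) -> str:
    if label.startswith("del"):
        return "del"
    if label.startswith("LOH"):
        return "LOH"
    if label.startswith("dup"):
        return "dup"
    raise ValueError(f"cannot infer CNV class from label {label!r}")


def simulate_reads(truth: TruthRecord, config: SimConfig, rng,
                   noise: bool | None = None) -> list[VariantCall]:
    """Panel-NGS observations of the truth's small variants."""
    noise = config.noise if noise is None else noise
    calls: list[VariantCall] = []
    ev2node = truth.tree.event_nodes()
    for label, kind in truth.kinds.items():
        if kind != "gene":
            continue
        chrom, pos = genome.GENE_LOCI.get(label, ("1", 1_000_000))
        node = truth.tree.node(ev2node[label])
        for tp in truth.tree.timepoints:
            phi = node.ccf_by_timepoint.get(tp, 0.0)
            rho = truth.purity[tp]
            v = expected_vaf_for(phi, rho)
            if v >= 1.0:
                raise RuntimeError("inconsistent truth: expected VAF >= 1")
            if noise:
                depth = max(int(rng.poisson(config.mean_depth)), 20)
                alt = int(rng.binomial(depth, v))
                vaf = alt / depth
            else:
                depth, alt, vaf = config.mean_depth, None, v
            calls.append(VariantCall(
                patient_id=truth.patient_id,
                sample_id=f"{truth.patient_id}:T{tp}",
                timepoint=tp, chrom=chrom, pos=pos, ref="A", alt="T",
                gene=label, vaf=vaf, depth=depth, alt_reads=alt,
            ))
    return calls


#: below this fraction a CNV is invisible to the array and not emitted
CNV_DETECTION_FLOOR = 0.02


def simulate_cnv_signal(truth: TruthRecord, config: SimConfig, rng,
                        noise: bool | None = None) -> list[CnvSegment]:
    """SNP-array observations (BAF/logR) of the truth's CNV events."""
    noise = config.noise if noise is None else noise
    segs: list[CnvSegment] = []
    ev2node = truth.tree.event_nodes()
    for label, kind in truth.kinds.items():
        if kind != "cnv":
            continue
        cls = _label_cnv_class(label)
        chrom, start, end = genome.CNV_REGIONS.get(label, ("1", 1, 10_000_000))
        node = truth.tree.node(ev2node[label])
        for tp in truth.tree.timepoints:
            f = node.ccf_by_timepoint.get(tp, 0.0)
            rho = truth.purity[tp]
            if f * rho < CNV_DETECTION_FLOOR:
                continue
            baf, logr = cnv_signal_expectations(cls, rho, f)
            if noise:
                baf = float(np.clip(baf + rng.normal(0.0, config.baf_sd), 0.0, 1.0))
                logr = float(logr + rng.normal(0.0, config.logr_sd))
            cn = {"del": 1, "LOH": 2, "dup": 3}[cls]
            segs.append(CnvSegment(
                patient_id=truth.patient_id,
                sample_id=f"{truth.patient_id}:T{tp}",
                timepoint=tp, chrom=chrom, start=start, end=end,
                cn=cn, loh=(cls == "LOH"), baf=baf, logr=logr,
            ))
    return segs


def simulate_outcomes(truths: list[TruthRecord], config: SimConfig, rng
                      ) -> list[ClinicalRecord]:
    """Relapse times with log hazard linear in the NOTCH1-WT fraction."""
    records: list[ClinicalRecord] = []
    for t in truths:
        rate = config.baseline_hazard * math.exp(config.hazard_beta * t.covariate)
        event_time = rng.exponential(1.0 / rate)
        if config.censoring_rate > 0:
            censor_time = rng.exponential(1.0 / config.censoring_rate)
        else:
            censor_time = math.inf
        observed = bool(event_time <= censor_time)
        time = max(float(min(event_time, censor_time)), 0.5)
        t.event_time = time
        t.event_observed = observed
        age_group, entity = t.subgroup.split(" ", 1)
        records.append(ClinicalRecord(
            patient_id=t.patient_id, entity=entity, age_group=age_group,
            age_years=t.age_years, relapsed=observed,
            time_to_event_days=time, event_observed=observed,
            sample_timepoints=list(t.tree.timepoints),
        ))
    return records


# ---------------------------------------------------------------------------
# cohort assembly

@dataclass
class CohortData:
    truths: list[TruthRecord]
    variants: list[VariantCall]
    segments: list[CnvSegment]
    clinical: list[ClinicalRecord]


def _patient_rng(seed: int, sg_idx: int, p_idx: int):
    return np.random.default_rng(np.random.SeedSequence([seed, sg_idx, p_idx]))


def generate_cohort(config: SimConfig) -> CohortData:
    """Simulate a full cohort in memory; per-patient RNG substreams keep
    existing patients unchanged when the cohort grows."""
    config.validate()
    truths: list[TruthRecord] = []
    variants: list[VariantCall] = []
    segments: list[CnvSegment] = []
    for sg_idx, subgroup in enumerate(SUBGROUPS):
        n = config.n_for(subgroup)
        for p_idx in range(n):
            rng = _patient_rng(config.seed, sg_idx, p_idx)
            pid = f"UPN{sg_idx + 1}{p_idx + 1:03d}"
            truth = simulate_tree(config, subgroup, rng, patient_id=pid)
            variants.extend(simulate_reads(truth, config, rng))
            segments.extend(simulate_cnv_signal(truth, config, rng))
            truths.append(truth)
    outcome_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 99991]))
    clinical = simulate_outcomes(truths, config, outcome_rng)
    return CohortData(truths, variants, segments, clinical)


def truth_to_dict(t: TruthRecord) -> dict:
    return {
        "patient_id": t.patient_id,
        "subgroup": t.subgroup,
        "tree": t.tree.to_dict(),
        "purity": {str(k): v for k, v in t.purity.items()},
        "kinds": t.kinds,
        "covariate": t.covariate,
        "age_years": t.age_years,
        "event_time": t.event_time,
        "event_observed": t.event_observed,
    }


def simulate_cohort(config: SimConfig, out_dir, force: bool = False) -> dict:
    """Write a simulated cohort to disk (variant/SEG/clinical TSVs, truth
    JSON, manifest). Refuses to overwrite an existing non-empty directory
    unless ``force`` is set. Byte-identical for a fixed config."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(
            f"output directory {out} exists and is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config)
    paths = {
        "variants": out / "variants.tsv",
        "segments": out / "segments.tsv",
        "clinical": out / "clinical.tsv",
        "truth": out / "truth.json",
        "manifest": out / "manifest.json",
    }
    io.write_variant_table(cohort.variants, paths["variants"])
    io.write_cnv_segments(cohort.segments, paths["segments"])
    io.write_clinical_table(cohort.clinical, paths["clinical"])
    paths["truth"].write_text(json.dumps(
        [truth_to_dict(t) for t in cohort.truths], indent=1, sort_keys=True),
        encoding="utf-8")
    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_patients": {sg: config.n_for(sg) for sg in SUBGROUPS},
        "files": sorted(p.name for k, p in paths.items() if k != "manifest"),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=1, sort_keys=True),
                                 encoding="utf-8")
    return {k: str(v) for k, v in paths.items()}
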