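"""Ordered evolutionary trajectories and the weighted nested-level statistic.

A trajectory is an ordered tuple of 2-3 event labels acquired along a
strict ancestor -> descendant chain of a clone tree (any strict ancestor
counts, not only the parent; events on the same node have unknowable
order and contribute no pair). Cohort-level support is the number of
patients whose tree contains the trajectory.

Enrichment is tested against a within-patient label-shuffle null: each
permutation redistributes a patient's event labels over its tree nodes,
preserving the topology and the number of labels per node, so the test
asks whether the observed ordering is more conserved than label placement
alone explains. p-values use the add-one permutation estimator and are
Benjamini-Hochberg adjusted within one subgroup and trajectory length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import genome
from .datatypes import CloneTreeDocument, CnvSegment, NORMAL_NODE_ID

MIN_FREQ_LEN2 = 0.10
MIN_FREQ_LEN3 = 0.05


# ---------------------------------------------------------------------------
# event labelling

def cnv_event_label(segment: CnvSegment, build: str = "GRCh38",
                    arm_fraction: float = 0.9) -> str:
    """Label a CNV segment ``del_in_9p`` / ``LOH_in_9p`` style when >= 90%
    of it lies in one chromosome arm, else chromosome-scale (``dup20``)."""
    cls = segment.cnv_class
    chrom = genome.normalize_chrom(segment.chrom)
    arm = genome.arm_of(chrom, segment.start, segment.end, build=build,
                        arm_fraction=arm_fraction)
    if arm is None:
        return f"{cls}{chrom}"
    return f"{cls}_in_{chrom}{arm}"


def label_events(tree: CloneTreeDocument,
                 event_info: dict[str, object] | None = None,
                 build: str = "GRCh38") -> CloneTreeDocument:
    """Relabel a tree's events for trajectory analysis.

    ``event_info`` maps raw event ids either to a gene symbol (str) or to
    the event's :class:`CnvSegment`; ids without an entry are kept as-is
    (already labels). Duplicate labels within one node collapse.
    """
    new_nodes = []
    for n in tree.nodes:
        labels: list[str] = []
        for e in n.events:
            info = (event_info or {}).get(e, e)
            if isinstance(info, CnvSegment):
                lab = cnv_event_label(info, build=build)
            else:
                lab = str(info)
            if lab not in labels:
                labels.append(lab)
        new_nodes.append(type(n)(node_id=n.node_id, parent_id=n.parent_id,
                                 events=labels,
                                 ccf_by_timepoint=dict(n.ccf_by_timepoint)))
    return CloneTreeDocument(patient_id=tree.patient_id, nodes=new_nodes,
                             timepoints=list(tree.timepoints))


# ---------------------------------------------------------------------------
# extraction

def extract_trajectories(tree: CloneTreeDocument, max_len: int = 3
                         ) -> set[tuple[str, ...]]:
    """Distinct ordered label tuples along strict ancestor chains."""
    nodes = [n for n in tree.malignant_nodes() if n.events]
    out: set[tuple[str, ...]] = set()
    anc = {(a.node_id, b.node_id): tree.is_strict_ancestor(a.node_id, b.node_id)
           for a in nodes for b in nodes}
    for a in nodes:
        for b in nodes:
            if a.node_id == b.node_id or not anc[(a.node_id, b.node_id)]:
                continue
            for e1 in a.events:
                for e2 in b.events:
                    out.add((e1, e2))
            if max_len >= 3:
                for c in nodes:
                    if c.node_id in (a.node_id, b.node_id):
                        continue
                    if not anc[(b.node_id, c.node_id)]:
                        continue
                    for e1 in a.events:
                        for e2 in b.events:
                            for e3 in c.events:
                                out.add((e1, e2, e3))
    return out


@dataclass
class Trajectory:
    labels: tuple[str, ...]
    support: int
    subgroup: str
    frequency: float


@dataclass
class TrajectoryResult:
    trajectory: tuple[str, ...]
    support: int
    p_value: float
    p_adjusted: float
    n_permutations: int
    seed: int


def trajectory_frequencies(trees: list[CloneTreeDocument], subgroup: str = "",
                           min_freq2: float = MIN_FREQ_LEN2,
                           min_freq3: float = MIN_FREQ_LEN3) -> list[Trajectory]:
    """Cohort trajectories retained at the inclusive frequency filters
    (>= 10% of patients for length 2, >= 5% for length 3)."""
    if not trees:
        raise ValueError("need at least one tree")
    counts: dict[tuple[str, ...], int] = {}
    for t in trees:
        for traj in extract_trajectories(t):
            counts[traj] = counts.get(traj, 0) + 1
    n = len(trees)
    out = []
    for traj, c in sorted(counts.items()):
        freq = c / n
        cut = min_freq2 if len(traj) == 2 else min_freq3
        if freq >= cut:
            out.append(Trajectory(traj, c, subgroup, freq))
    return out


# ---------------------------------------------------------------------------
# permutation machinery

class _PermEngine:
    """Joint within-patient label-shuffle null for a cohort of trees.

    One set of ``n_perm`` shuffles is drawn per tree; supports of every
    pair (and optionally triple) of labels are accumulated jointly so an
    arbitrary number of trajectories can be tested on the same null.
    """

    def __init__(self, trees: list[CloneTreeDocument], n_perm: int, rng,
                 extra_labels: tuple[str, ...] = (), with_triples: bool = True):
        self.n_perm = n_perm
        self.n_trees = len(trees)
        labels = sorted({e for t in trees for n in t.malignant_nodes()
                         for e in n.events} | set(extra_labels))
        self.vocab = {lab: i for i, lab in enumerate(labels)}
        V = len(self.vocab)
        self.V = V
        self.with_triples = with_triples
        self.obs_pairs: dict[int, int] = {}
        self.obs_triples: dict[int, int] = {}
        self.null_pairs = np.zeros((n_perm, V * V), dtype=np.int32)
        self.null_triples = (np.zeros((n_perm, V * V * V), dtype=np.int32)
                             if with_triples else None)
        if with_triples and n_perm * V ** 3 > 4e8:
            raise MemoryError("label vocabulary too large for the joint "
                              "triple-support null; test pairs only")
        for t in trees:
            self._add_tree(t, rng)

    def _add_tree(self, tree: CloneTreeDocument, rng) -> None:
        nodes = [n for n in tree.malignant_nodes() if n.events]
        if not nodes:
            return
        nid = {n.node_id: i for i, n in enumerate(nodes)}
        k = len(nodes)
        anc = np.zeros((k, k), dtype=bool)
        for a in nodes:
            for b in nodes:
                if a.node_id != b.node_id:
                    anc[nid[a.node_id], nid[b.node_id]] = \
                        tree.is_strict_ancestor(a.node_id, b.node_id)
        slots_node: list[int] = []
        slots_label: list[int] = []
        for n in nodes:
            for e in n.events:
                slots_node.append(nid[n.node_id])
                slots_label.append(self.vocab[e])
        L = len(slots_label)
        slot_node = np.array(slots_node)
        labels = np.array(slots_label)
        pi, pj = np.nonzero(anc[slot_node][:, slot_node])
        V = self.V

        # observed supports (distinct per patient)
        if len(pi):
            codes = np.unique(labels[pi] * V + labels[pj])
            for c in codes:
                self.obs_pairs[int(c)] = self.obs_pairs.get(int(c), 0) + 1
        trip_idx = None
        if self.with_triples and len(pi):
            pair_mask = anc[slot_node][:, slot_node]
            trips = []
            for a in range(L):
                for b in range(L):
                    if not pair_mask[a, b]:
                        continue
                    for c in range(L):
                        if pair_mask[b, c]:
                            trips.append((a, b, c))
            if trips:
                trip_idx = np.array(trips)
                codes = np.unique(labels[trip_idx[:, 0]] * V * V
                                  + labels[trip_idx[:, 1]] * V
                                  + labels[trip_idx[:, 2]])
                for c in codes:
                    self.obs_triples[int(c)] = self.obs_triples.get(int(c), 0) + 1

        if L < 2 or not len(pi):
            # still consume randomness deterministically per tree
            rng.permuted(np.tile(labels, (self.n_perm, 1)), axis=1)
            return
        perms = rng.permuted(np.tile(labels, (self.n_perm, 1)), axis=1)
        pair_codes = perms[:, pi] * V + perms[:, pj]  # (n_perm, P)
        keys = (np.arange(self.n_perm)[:, None] * (V * V) + pair_codes).ravel()
        self.null_pairs.ravel()[np.unique(keys)] += 1
        if self.with_triples and trip_idx is not None and len(trip_idx):
            t_codes = (perms[:, trip_idx[:, 0]] * V * V
                       + perms[:, trip_idx[:, 1]] * V
                       + perms[:, trip_idx[:, 2]])
            keys = (np.arange(self.n_perm)[:, None] * (V ** 3) + t_codes).ravel()
            self.null_triples.ravel()[np.unique(keys)] += 1

    def _code(self, traj: tuple[str, ...]) -> int | None:
        idx = [self.vocab.get(lab) for lab in traj]
        if any(i is None for i in idx):
            return None
        if len(traj) == 2:
            return idx[0] * self.V + idx[1]
        return idx[0] * self.V * self.V + idx[1] * self.V + idx[2]

    def observed_support(self, traj: tuple[str, ...]) -> int:
        code = self._code(traj)
        if code is None:
            return 0
        src = self.obs_pairs if len(traj) == 2 else self.obs_triples
        return src.get(code, 0)

    def p_value(self, traj: tuple[str, ...]) -> float:
        obs = self.observed_support(traj)
        code = self._code(traj)
        if code is None:
            null = np.zeros(self.n_perm, dtype=int)
        elif len(traj) == 2:
            null = self.null_pairs[:, code]
        else:
            if self.null_triples is None:
                raise ValueError("engine built without triple support")
            null = self.null_triples[:, code]
        return float((1 + int((null >= obs).sum())) / (1 + self.n_perm))


def _check_n_perm(n_perm: int, strict: bool) -> None:
    if n_perm < 100:
        msg = f"n_perm={n_perm} is too small for meaningful p-values"
        if strict:
            raise ValueError(msg + " (strict mode)")
        warnings.warn(msg, stacklevel=3)


def trajectory_permutation_test(trees: list[CloneTreeDocument],
                                trajectory: tuple[str, ...],
                                n_perm: int = 10000, seed: int = 0,
                                strict: bool = True) -> TrajectoryResult:
    """Permutation p-value for one trajectory (no multiplicity adjustment;
    p_adjusted echoes the raw p)."""
    _check_n_perm(n_perm, strict)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7001]))
    engine = _PermEngine(trees, n_perm, rng, extra_labels=tuple(trajectory),
                         with_triples=len(trajectory) == 3)
    p = engine.p_value(tuple(trajectory))
    return TrajectoryResult(tuple(trajectory), engine.observed_support(tuple(trajectory)),
                            p, p, n_perm, seed)


def test_cohort_trajectories(trees: list[CloneTreeDocument], subgroup: str = "",
                             n_perm: int = 10000, seed: int = 0,
                             min_freq2: float = MIN_FREQ_LEN2,
                             min_freq3: float = MIN_FREQ_LEN3,
                             strict: bool = True) -> pd.DataFrame:
    """Frequency-filter, permutation-test and BH-adjust all trajectories
    of one subgroup cohort. Returns a tidy frame sorted by adjusted p."""
    _check_n_perm(n_perm, strict)
    retained = trajectory_frequencies(trees, subgroup, min_freq2, min_freq3)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7001]))
    need_triples = any(len(t.labels) == 3 for t in retained)
    engine = _PermEngine(trees, n_perm, rng, with_triples=need_triples)
    rows = []
    for t in retained:
        rows.append({
            "trajectory": " -> ".join(t.labels),
            "labels": t.labels,
            "length": len(t.labels),
            "subgroup": subgroup,
            "support": t.support,
            "frequency": t.frequency,
            "p_value": engine.p_value(t.labels),
        })
    df = pd.DataFrame(rows, columns=["trajectory", "labels", "length", "subgroup",
                                     "support", "frequency", "p_value"])
    if len(df):
        adj = np.ones(len(df))
        for ln in df["length"].unique():
            m = df["length"] == ln
            adj[m.to_numpy()] = bh_adjust(df.loc[m, "p_value"].to_numpy())
        df["p_adjusted"] = adj
        df["n_permutations"] = n_perm
        df["seed"] = seed
        df = df.sort_values(["p_adjusted", "p_value", "trajectory"],
                            kind="stable").reset_index(drop=True)
    else:
        df["p_adjusted"] = []
        df["n_permutations"] = []
        df["seed"] = []
    return df


def fixed_list_pvalues(trees: list[CloneTreeDocument],
                       trajectories: list[tuple[str, ...]],
                       n_perm: int = 199, seed: int = 0) -> dict[tuple[str, ...], float]:
    """Permutation p-values for an a-priori trajectory list (no frequency
    selection) — the calibration entry point."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7001]))
    extra = tuple({lab for t in trajectories for lab in t})
    with_triples = any(len(t) == 3 for t in trajectories)
    engine = _PermEngine(trees, n_perm, rng, extra_labels=extra,
                         with_triples=with_triples)
    return {tuple(t): engine.p_value(tuple(t)) for t in trajectories}


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# nested levels

def nested_levels(tree: CloneTreeDocument) -> dict[str, int]:
    """1-based acquisition depth of every event (founding clone = 1)."""
    depths = tree.depths()
    return {e: depths[nid] for e, nid in tree.event_nodes().items()}


def tree_nested_level(tree: CloneTreeDocument) -> int:
    """Depth of the deepest clone (founding clone = 1)."""
    depths = tree.depths()
    vals = [d for nid, d in depths.items() if nid != NORMAL_NODE_ID]
    return max(vals) if vals else 0


@dataclass
class NestedLevelResult:
    scope: str   # "tree" | "event_class"
    value: float
    subgroup: str
    n: int
    weighting: str


def weighted_nested_level(trees: list[CloneTreeDocument], scope: str,
                          labels: set[str] | None = None,
                          subgroup: str = "") -> NestedLevelResult:
    """Cohort nested-level statistic.

    ``scope='event_class'``: mean acquisition level over all occurrences
    of the given labels, each occurrence weighted equally.
    ``scope='tree'``: mean tree depth over patients, each patient weighted
    by its number of events.
    """
    if not trees:
        raise ValueError("need at least one tree")
    if scope == "event_class":
        if not labels:
            raise ValueError("event_class scope needs a label set")
        levels = []
        for t in trees:
            lv = nested_levels(t)
            levels.extend(v for e, v in lv.items() if e in labels)
        if not levels:
            raise ValueError(f"no occurrences of {sorted(labels)} in the cohort")
        return NestedLevelResult("event_class", float(np.mean(levels)), subgroup,
                                 len(levels), "each occurrence weighted equally")
    if scope == "tree":
        num = 0.0
        den = 0.0
        for t in trees:
            n_events = sum(len(n.events) for n in t.malignant_nodes())
            num += tree_nested_level(t) * n_events
            den += n_events
        if den == 0:
            raise ValueError("cohort trees carry no events")
        return NestedLevelResult("tree", num / den, subgroup, len(trees),
                                 "patients weighted by event count")
    raise ValueError(f"unknown scope {scope!r}")
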