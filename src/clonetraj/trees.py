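"""Clone-tree reconstruction from CCF-scaled events.

The reconstruction proceeds in four stages:

1. **Clustering** — events are grouped by a binomial/Gaussian mixture over
   CCF space, fitted by EM for k = 1..max_k with deterministic restarts;
   k is selected by BIC and near-duplicate clusters are merged.
2. **Enumeration** — all rooted trees on the clusters (with an implicit
   healthy-cell root) are enumerated; only trees satisfying the sum rule
   at every timepoint are kept.
3. **Constraints** — allele-phasing constraints (same-gene variants known
   to sit on different alleles, or on the same allele) remove impossible
   topologies.
4. **Selection** — minimal total sum-rule violation, then fewest leaves
   (parsimony prefers linear evolution), then lexicographic parent
   vector; the number of equally consistent trees is reported as the
   ambiguity.

Clone CCFs are subtree-inclusive, so the sum rule reads: at every
timepoint, the CCFs of a clone's children may not exceed the parent's
CCF (up to a depth-scaled tolerance ``eps``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .datatypes import CloneNode, CloneTreeDocument, NORMAL_NODE_ID

MAX_CLUSTERS = 8


class ReconstructionError(RuntimeError):
    """No sum-rule-consistent tree could be built for this patient."""

    def __init__(self, message: str, near_miss: "CloneTreeDocument | None" = None):
        super().__init__(message)
        self.near_miss = near_miss


@dataclass
class EventObservation:
    """Per-event measurements across the patient's timepoint grid.

    SNVs carry read counts plus the linear coefficient ``coeff`` mapping
    CCF to expected VAF (purity/copy-number/multiplicity correction, see
    :mod:`clonetraj.ccf`); CNVs carry a fraction estimate with a Gaussian
    uncertainty.
    """

    event_id: str
    kind: str  # "snv" | "cnv"
    alt: dict[int, float] = field(default_factory=dict)
    depth: dict[int, float] = field(default_factory=dict)
    coeff: dict[int, float] = field(default_factory=dict)
    f_hat: dict[int, float] = field(default_factory=dict)
    f_sd: dict[int, float] = field(default_factory=dict)

    def timepoints(self) -> list[int]:
        src = self.alt if self.kind == "snv" else self.f_hat
        return sorted(src)

    def naive_ccf(self, tp: int) -> float:
        if self.kind == "snv":
            d = self.depth[tp] * self.coeff[tp]
            return float(np.clip(self.alt[tp] / d if d > 0 else 0.0, 0.0, 1.0))
        return float(np.clip(self.f_hat[tp], 0.0, 1.0))


@dataclass
class EventCluster:
    cluster_id: str
    members: list[str]
    mean_ccf: dict[int, float]
    dispersion: dict[int, float]


@dataclass
class PhasingConstraint:
    """Allelic relation between 2-3 events of one gene, inferred from
    read pairs covering nearby positions (default window 150 bp)."""

    events: tuple[str, ...]
    relation: str  # "different_allele" | "same_allele"
    gene: str = ""
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.relation not in ("different_allele", "same_allele"):
            raise ValueError(f"unknown phasing relation {self.relation!r}")
        if not 2 <= len(self.events) <= 3:
            raise ValueError("phasing constraints cover 2-3 events")


# ---------------------------------------------------------------------------
# clustering

def _prepare_arrays(observations: list[EventObservation], timepoints: list[int]):
    E, T = len(observations), len(timepoints)
    tp_idx = {tp: j for j, tp in enumerate(timepoints)}
    A = np.zeros((E, T)); D = np.zeros((E, T)); C = np.ones((E, T))
    F = np.zeros((E, T)); SD = np.ones((E, T))
    M = np.zeros((E, T))
    is_snv = np.zeros(E, dtype=bool)
    naive = np.zeros((E, T))
    for i, ob in enumerate(observations):
        is_snv[i] = ob.kind == "snv"
        for tp in ob.timepoints():
            j = tp_idx[tp]
            M[i, j] = 1.0
            if ob.kind == "snv":
                A[i, j] = ob.alt[tp]
                D[i, j] = ob.depth[tp]
                C[i, j] = ob.coeff[tp]
            else:
                F[i, j] = ob.f_hat[tp]
                SD[i, j] = max(ob.f_sd.get(tp, 0.05), 1e-3)
            naive[i, j] = ob.naive_ccf(tp)
    return A, D, C, F, SD, M, is_snv, naive


def _loglik_matrix(phi, A, D, C, F, SD, M, is_snv):
    """Per-event, per-cluster log-likelihood. phi: (K, T)."""
    phi = np.clip(phi, 0.0, 1.0)
    V = np.clip(C[:, None, :] * phi[None, :, :], 1e-9, 1.0 - 1e-9)  # (E,K,T)
    ll_snv = A[:, None, :] * np.log(V) + (D - A)[:, None, :] * np.log1p(-V)
    ll_cnv = -0.5 * ((F[:, None, :] - phi[None, :, :]) / SD[:, None, :]) ** 2 \
        - np.log(SD[:, None, :])
    ll = np.where(is_snv[:, None, None], ll_snv, ll_cnv)
    return (ll * M[:, None, :]).sum(axis=2)


def _mstep_phi(w, a, d, c, f, sd, m, snv_mask, init):
    """Maximize the weighted 1-D CCF likelihood at one timepoint by
    damped Newton. All vectors are per-event at this timepoint."""
    w = w * m
    snv = snv_mask & (w > 0) & (d > 0)
    cnv = (~snv_mask) & (w > 0)
    if not snv.any() and not cnv.any():
        return init
    phi = float(np.clip(init, 1e-6, 1.0 - 1e-6))
    for _ in range(30):
        v = np.clip(c[snv] * phi, 1e-9, 1.0 - 1e-9)
        g = float(np.sum(w[snv] * (a[snv] / phi - (d[snv] - a[snv]) * c[snv] / (1.0 - v))))
        h = float(np.sum(w[snv] * (-a[snv] / phi ** 2
                                   - (d[snv] - a[snv]) * (c[snv] / (1.0 - v)) ** 2)))
        g += float(np.sum(w[cnv] * (f[cnv] - phi) / sd[cnv] ** 2))
        h -= float(np.sum(w[cnv] / sd[cnv] ** 2))
        if h >= -1e-12:
            break
        step = np.clip(-g / h, -0.2, 0.2)
        new = float(np.clip(phi + step, 1e-6, 1.0 - 1e-6))
        if abs(new - phi) < 1e-12:
            phi = new
            break
        phi = new
    return phi


def cluster_ccf(observations: list[EventObservation], max_k: int = 6,
                seed: int = 0, merge_tol: float = 0.05,
                n_restarts: int = 10) -> tuple[list[EventCluster], dict[str, str]]:
    """Cluster events in CCF space with a binomial-likelihood mixture.

    Returns ``(clusters, assignment)`` where ``assignment`` maps event id
    to cluster id. Deterministic given ``seed``: restarts use
    quantile-based initializations with seeded jitter, and ties in the
    hard assignment break toward the lower cluster index.
    """
    if not observations:
        raise ValueError("need at least one event")
    timepoints = sorted({tp for ob in observations for tp in ob.timepoints()})
    A, D, C, F, SD, M, is_snv, naive = _prepare_arrays(observations, timepoints)
    E, T = len(observations), len(timepoints)
    max_k = min(max_k, E)

    with np.errstate(invalid="ignore"):
        scalar = np.where(M.sum(1) > 0, (naive * M).sum(1) / np.maximum(M.sum(1), 1), 0.5)

    def run_em(k: int, phi0: np.ndarray):
        phi = phi0.copy()
        logpi = np.full(k, -np.log(k))
        prev = -np.inf
        for _ in range(150):
            ll_ek = _loglik_matrix(phi, A, D, C, F, SD, M, is_snv) + logpi[None, :]
            mx = ll_ek.max(axis=1, keepdims=True)
            lse = mx[:, 0] + np.log(np.exp(ll_ek - mx).sum(axis=1))
            total = float(lse.sum())
            R = np.exp(ll_ek - lse[:, None])
            pi = np.clip(R.mean(axis=0), 1e-9, None)
            logpi = np.log(pi / pi.sum())
            for kk in range(k):
                for j in range(T):
                    phi[kk, j] = _mstep_phi(R[:, kk], A[:, j], D[:, j], C[:, j],
                                            F[:, j], SD[:, j], M[:, j], is_snv,
                                            init=phi[kk, j])
            if abs(total - prev) < 1e-8 * (1.0 + abs(total)):
                prev = total
                break
            prev = total
        ll_ek = _loglik_matrix(phi, A, D, C, F, SD, M, is_snv) + logpi[None, :]
        mx = ll_ek.max(axis=1, keepdims=True)
        total = float((mx[:, 0] + np.log(np.exp(ll_ek - mx).sum(axis=1))).sum())
        return total, phi, ll_ek

    best = None  # (bic, k, phi, ll_ek)
    order = np.argsort(scalar, kind="stable")
    for k in range(1, max_k + 1):
        best_k = None
        for r in range(n_restarts):
            rng = np.random.default_rng(np.random.SeedSequence([seed, k, r]))
            if r == 0 or E < k:
                # scalar quantiles of the per-event mean CCF
                q = (np.arange(k) + 1.0) / (k + 1.0)
                centers = np.quantile(scalar[order], q)
                phi0 = np.clip(centers[:, None] * np.ones((k, T)), 1e-4, 1 - 1e-4)
            else:
                # seed clusters on actual event CCF profiles, which also
                # separates clones whose means cross between timepoints
                rows = rng.choice(E, size=k, replace=False)
                jitter = rng.normal(0.0, 0.01, size=(k, T))
                phi0 = np.clip(naive[rows] + jitter, 1e-4, 1.0 - 1e-4)
            total, phi, ll_ek = run_em(k, phi0)
            if best_k is None or total > best_k[0] + 1e-12:
                best_k = (total, phi, ll_ek)
        total, phi, ll_ek = best_k
        bic = -2.0 * total + (k * T + (k - 1)) * np.log(max(E, 2))
        if best is None or bic < best[0] - 1e-9:
            best = (bic, k, phi, ll_ek)

    _, k, phi, ll_ek = best
    assign = np.argmax(ll_ek, axis=1)

    # collapse clusters closer than merge_tol (L-inf over timepoints)
    groups = [[i] for i in range(k) if (assign == i).any()]
    means = [phi[g[0]].copy() for g in groups]

    def refit_mean(member_rows: list[int]) -> np.ndarray:
        w = np.zeros(E)
        w[member_rows] = 1.0
        out = np.zeros(T)
        for j in range(T):
            init = float(np.average(naive[member_rows, j],
                                    weights=np.maximum(M[member_rows, j], 1e-9)))
            out[j] = _mstep_phi(w, A[:, j], D[:, j], C[:, j], F[:, j], SD[:, j],
                                M[:, j], is_snv, init=np.clip(init, 1e-6, 1 - 1e-6))
        return out

    merged = True
    while merged and len(groups) > 1:
        merged = False
        for i, j in itertools.combinations(range(len(groups)), 2):
            if np.max(np.abs(means[i] - means[j])) < merge_tol:
                groups[i] = groups[i] + groups[j]
                del groups[j], means[j]
                rows = [e for e in range(E) if assign[e] in groups[i]]
                means[i] = refit_mean(rows)
                merged = True
                break

    # stable ordering: descending CCF profile
    def sort_key(idx):
        return tuple(-means[idx][j] for j in range(T))

    order2 = sorted(range(len(groups)), key=sort_key)
    clusters: list[EventCluster] = []
    assignment: dict[str, str] = {}
    for rank, gi in enumerate(order2, start=1):
        rows = [e for e in range(E) if assign[e] in groups[gi]]
        cid = f"K{rank}"
        member_ids = [observations[e].event_id for e in rows]
        mean_ccf = {tp: float(means[gi][j]) for j, tp in enumerate(timepoints)}
        disp = {tp: float(np.std(naive[rows, j])) for j, tp in enumerate(timepoints)}
        clusters.append(EventCluster(cid, member_ids, mean_ccf, disp))
        for m_id in member_ids:
            assignment[m_id] = cid
    return clusters, assignment


# ---------------------------------------------------------------------------
# enumeration

def enumerate_parent_vectors(ccf: np.ndarray, eps: float,
                             cap: int = 2_000_000) -> list[tuple[int, ...]]:
    """All rooted trees on K clusters under an implicit normal root.

    ``ccf`` is (K, T); entry ``parent[i] = -1`` attaches cluster i to the
    normal root (capacity 1 at every timepoint). Enumerates every parent
    assignment, pruning partial assignments whose children already
    overflow a parent's CCF, and drops cyclic assignments. Result order
    is (fewest leaves, lexicographic parent vector).
    """
    K, T = ccf.shape
    if K > MAX_CLUSTERS:
        raise ValueError(
            f"{K} clusters exceed the enumeration cap of {MAX_CLUSTERS}; "
            "raise the cluster merge threshold")
    feasible = []
    for i in range(K):
        opts = [-1]
        for j in range(K):
            if j != i and np.all(ccf[j] >= ccf[i] - eps):
                opts.append(j)
        feasible.append(opts)

    cap_arr = np.vstack([np.ones(T), ccf])  # row 0 = normal root
    csum = np.zeros((K + 1, T))
    parent = [0] * K
    out: list[tuple[int, ...]] = []
    counter = [0]

    def acyclic(pvec) -> bool:
        for s in range(K):
            seen = set()
            cur = s
            while cur != -1:
                if cur in seen:
                    return False
                seen.add(cur)
                cur = pvec[cur]
        return True

    def rec(i: int) -> None:
        if i == K:
            pvec = tuple(parent)
            if acyclic(pvec):
                out.append(pvec)
            return
        for p in feasible[i]:
            counter[0] += 1
            if counter[0] > cap:
                raise RuntimeError("tree enumeration exceeded safety cap")
            csum[p + 1] += ccf[i]
            if np.all(csum[p + 1] <= cap_arr[p + 1] + eps):
                parent[i] = p
                rec(i + 1)
            csum[p + 1] -= ccf[i]

    rec(0)

    def n_leaves(pvec) -> int:
        parents = set(pvec)
        return sum(1 for i in range(K) if i not in parents)

    out.sort(key=lambda pv: (n_leaves(pv), pv))
    return out


def tree_from_parent_vector(clusters: list[EventCluster], pvec: tuple[int, ...],
                            patient_id: str, timepoints: list[int]) -> CloneTreeDocument:
    """Materialize a parent vector over clusters as a clone-tree document.

    A single top-level cluster becomes the root; multiple top-level
    clusters hang under a virtual ``NORMAL`` node."""
    top = [i for i, p in enumerate(pvec) if p == -1]
    nodes: list[CloneNode] = []
    monoclonal = len(top) == 1
    if not monoclonal:
        nodes.append(CloneNode(NORMAL_NODE_ID, None, [],
                               {tp: 1.0 for tp in timepoints}))
    for i, cl in enumerate(clusters):
        if pvec[i] == -1:
            parent = None if monoclonal else NORMAL_NODE_ID
        else:
            parent = clusters[pvec[i]].cluster_id
        nodes.append(CloneNode(
            node_id=cl.cluster_id,
            parent_id=parent,
            events=list(cl.members),
            ccf_by_timepoint={tp: min(1.0, max(0.0, cl.mean_ccf[tp]))
                              for tp in timepoints},
        ))
    doc = CloneTreeDocument(patient_id=patient_id, nodes=nodes,
                            timepoints=list(timepoints))
    doc.validate()
    return doc


def enumerate_trees(clusters: list[EventCluster], eps: float,
                    patient_id: str = "", timepoints: list[int] | None = None
                    ) -> list[CloneTreeDocument]:
    """All sum-rule-consistent rooted trees on the clusters."""
    if timepoints is None:
        timepoints = sorted(clusters[0].mean_ccf)
    ccf = np.array([[cl.mean_ccf[tp] for tp in timepoints] for cl in clusters])
    pvecs = enumerate_parent_vectors(ccf, eps)
    return [tree_from_parent_vector(clusters, pv, patient_id, timepoints)
            for pv in pvecs]


# ---------------------------------------------------------------------------
# sum rule

def check_sum_rule(doc: CloneTreeDocument, eps: float):
    """True iff children's CCFs never exceed the parent's (within eps) and
    the root stays at or below 1 + eps. Violations are listed with
    their magnitudes."""
    violations = []
    for n in doc.nodes:
        kids = doc.children(n.node_id)
        if not kids:
            continue
        for tp in doc.timepoints:
            total = sum(k.ccf_by_timepoint.get(tp, 0.0) for k in kids)
            capacity = n.ccf_by_timepoint.get(tp, 0.0)
            if total > capacity + eps:
                violations.append({"node": n.node_id, "timepoint": tp,
                                   "excess": total - capacity})
    root = doc.root
    for tp in doc.timepoints:
        ccf = root.ccf_by_timepoint.get(tp, 0.0)
        if ccf > 1.0 + eps:
            violations.append({"node": root.node_id, "timepoint": tp,
                               "excess": ccf - 1.0})
    return len(violations) == 0, violations


def total_violation(doc: CloneTreeDocument) -> float:
    """Total positive sum-rule excess across nodes and timepoints."""
    _, v = check_sum_rule(doc, eps=0.0)
    return float(sum(item["excess"] for item in v))


# ---------------------------------------------------------------------------
# phasing constraints

def apply_phasing_constraints(candidates: list[CloneTreeDocument],
                              constraints: list[PhasingConstraint] | None,
                              n_alleles: int = 2) -> list[CloneTreeDocument]:
    """Filter candidate trees against allelic constraints.

    Events that are pairwise on *different* alleles cannot all travel on
    one lineage once they outnumber the locus's allele count (no copy
    gain -> 2 alleles): any root-to-leaf path carrying more than
    ``n_alleles`` mutually-incompatible events is impossible. Events on
    the *same* allele must be collinear (one lineage). An empty result
    means the constraints ruled out every candidate; callers should
    report this as a diagnostic.
    """
    if not constraints:
        return list(candidates)
    diff_pairs: set[frozenset[str]] = set()
    same_pairs: list[tuple[str, str]] = []
    constrained: set[str] = set()
    for c in constraints:
        for a, b in itertools.combinations(c.events, 2):
            if c.relation == "different_allele":
                diff_pairs.add(frozenset((a, b)))
                constrained.update((a, b))
            else:
                same_pairs.append((a, b))

    def ok(doc: CloneTreeDocument) -> bool:
        ev2node = doc.event_nodes()
        for a, b in same_pairs:
            if a in ev2node and b in ev2node:
                na, nb = ev2node[a], ev2node[b]
                if not (na == nb or doc.is_strict_ancestor(na, nb)
                        or doc.is_strict_ancestor(nb, na)):
                    return False
        present = [e for e in constrained if e in ev2node]
        if len(present) > n_alleles:
            parents = doc.parent_map()
            leaves = [n.node_id for n in doc.nodes if not doc.children(n.node_id)]
            for leaf in leaves:
                path = set()
                cur: str | None = leaf
                while cur is not None:
                    path.add(cur)
                    cur = parents[cur]
                on_path = [e for e in present if ev2node[e] in path]
                for combo in itertools.combinations(on_path, n_alleles + 1):
                    if all(frozenset(p) in diff_pairs
                           for p in itertools.combinations(combo, 2)):
                        return False
        return True

    return [doc for doc in candidates if ok(doc)]


# ---------------------------------------------------------------------------
# end-to-end reconstruction

def default_epsilon(observations: list[EventObservation],
                    floor: float = 0.05) -> float:
    """Sum-rule tolerance: max(floor, 2 x mean Wilson CI half-width of the
    events' CCFs) so the tolerance scales with sequencing depth."""
    halves = []
    for ob in observations:
        for tp in ob.timepoints():
            if ob.kind == "snv":
                d = ob.depth[tp]
                if d <= 0:
                    continue
                lo, hi = proportion_confint(min(ob.alt[tp], d), d, alpha=0.05,
                                            method="wilson")
                c = max(ob.coeff[tp], 1e-9)
                halves.append((hi - lo) / 2.0 / c)
            else:
                halves.append(1.96 * ob.f_sd.get(tp, 0.05))
    if not halves:
        return floor
    return max(floor, 2.0 * float(np.mean(halves)))


@dataclass
class CloneTreeResult:
    """Selected clone tree plus the ambiguity of the selection."""

    tree: CloneTreeDocument
    assignments: dict[str, str]          # event id -> node id
    clusters: list[EventCluster]
    n_candidates: int
    n_co_optimal: int
    epsilon: float
    violation: float

    @property
    def ambiguous(self) -> bool:
        return self.n_co_optimal > 1

    def nested_levels(self) -> dict[str, int]:
        depths = self.tree.depths()
        return {e: depths[n] for e, n in self.tree.event_nodes().items()}

    def relation(self, event_a: str, event_b: str) -> str:
        """'ancestor', 'descendant', 'same' or 'parallel' for two events."""
        ev = self.tree.event_nodes()
        na, nb = ev[event_a], ev[event_b]
        if na == nb:
            return "same"
        if self.tree.is_strict_ancestor(na, nb):
            return "ancestor"
        if self.tree.is_strict_ancestor(nb, na):
            return "descendant"
        return "parallel"

    def summary(self) -> str:
        lines = [
            f"Clone tree: {self.tree.patient_id}",
            f"  clones: {len(self.tree.malignant_nodes())}   "
            f"timepoints: {len(self.tree.timepoints)}",
            f"  sum-rule tolerance eps = {self.epsilon:.4f}   "
            f"total violation = {self.violation:.3g}",
            f"  candidate trees: {self.n_candidates}   "
            f"co-optimal: {self.n_co_optimal}"
            + ("   (AMBIGUOUS)" if self.ambiguous else ""),
        ]
        depths = self.tree.depths()
        for n in sorted(self.tree.nodes, key=lambda x: depths[x.node_id]):
            ccfs = ", ".join(f"t{tp}={n.ccf_by_timepoint.get(tp, 0):.2f}"
                             for tp in self.tree.timepoints)
            lines.append(f"  [{n.node_id}] level {depths[n.node_id]} "
                         f"parent={n.parent_id or '-'} events={n.events} ({ccfs})")
        return "\n".join(lines)

    def plot(self, ax=None):
        from .plot import plot_tree
        return plot_tree(self.tree, ax=ax)


class CloneTreeModel:
    """Model object wrapping per-patient clone-tree reconstruction.

    Parameters
    ----------
    observations
        CCF-scale event measurements across the patient's timepoints.
    constraints
        Optional allele-phasing constraints for same-gene variants.
    """

    def __init__(self, observations: list[EventObservation],
                 constraints: list[PhasingConstraint] | None = None,
                 patient_id: str = "", n_alleles: int = 2):
        if not observations:
            raise ValueError("need at least one event with a CCF estimate")
        self.observations = observations
        self.constraints = constraints or []
        self.patient_id = patient_id
        self.n_alleles = n_alleles

    def fit(self, max_k: int = 6, seed: int = 0,
            eps: float | None = None) -> CloneTreeResult:
        obs = self.observations
        timepoints = sorted({tp for ob in obs for tp in ob.timepoints()})
        clusters, assignment = cluster_ccf(obs, max_k=max_k, seed=seed)
        if eps is None:
            eps = default_epsilon(obs)

        candidates: list[CloneTreeDocument] = []
        used_eps = eps
        for mult in (1, 2, 4, 8):
            used_eps = eps * mult
            candidates = enumerate_trees(clusters, used_eps,
                                         patient_id=self.patient_id,
                                         timepoints=timepoints)
            if candidates:
                break
        if not candidates:
            near = _greedy_chain(clusters, self.patient_id, timepoints)
            raise ReconstructionError(
                f"no sum-rule-consistent tree at eps up to {used_eps:.3f}",
                near_miss=near)

        kept = apply_phasing_constraints(candidates, self.constraints,
                                         n_alleles=self.n_alleles)
        if not kept:
            raise ReconstructionError(
                "phasing constraints eliminated all sum-rule-consistent trees "
                f"({len(candidates)} candidates before filtering)")

        viols = [total_violation(doc) for doc in kept]
        vmin = min(viols)
        co_optimal = [doc for doc, v in zip(kept, viols) if v <= vmin + 1e-12]
        # kept is already ordered (fewest leaves, lexicographic), so the
        # first co-optimal tree is the selection.
        selected = co_optimal[0]
        ev2node = {}
        for n in selected.nodes:
            for e in n.events:
                ev2node[e] = n.node_id
        return CloneTreeResult(
            tree=selected,
            assignments=ev2node,
            clusters=clusters,
            n_candidates=len(kept),
            n_co_optimal=len(co_optimal),
            epsilon=used_eps,
            violation=vmin,
        )


def _greedy_chain(clusters, patient_id, timepoints) -> CloneTreeDocument:
    """Best-effort linear tree (CCF-descending chain) used as the
    near-miss diagnostic when no candidate passes the sum rule."""
    pvec = tuple(-1 if i == 0 else i - 1 for i in range(len(clusters)))
    return tree_from_parent_vector(clusters, pvec, patient_id, timepoints)


def reconstruct(observations: list[EventObservation],
                constraints: list[PhasingConstraint] | None = None,
                patient_id: str = "", max_k: int = 6, seed: int = 0,
                eps: float | None = None, n_alleles: int = 2) -> CloneTreeResult:
    """Cluster -> enumerate -> constrain -> select, in one call."""
    model = CloneTreeModel(observations, constraints, patient_id, n_alleles)
    return model.fit(max_k=max_k, seed=seed, eps=eps)
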