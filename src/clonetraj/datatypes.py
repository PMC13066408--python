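"""Core domain types shared across the package.

The central container is :class:`CloneTreeDocument`, a rooted clone tree
whose nodes carry the genomic events acquired by that clone and the
clone's cancer cell fraction (CCF) at each sampled timepoint. CCFs use
the subtree-inclusive convention: a clone's CCF is the fraction of tumor
cells carrying all of its events, so every descendant is counted in its
ancestors' CCFs and the sum rule (children's CCFs cannot exceed the
parent's) applies directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

ENTITIES = ("T-ALL", "T-LBL")
AGE_GROUPS = ("pediatric", "adult")
SUBGROUPS = tuple(f"{a} {e}" for a in AGE_GROUPS for e in ENTITIES)

#: node_id of the implicit healthy-cell root inserted when a candidate
#: tree has more than one founding malignant clone.
NORMAL_NODE_ID = "NORMAL"


class ValidationError(ValueError):
    """A record violates a domain invariant."""


class FormatError(ValueError):
    """An input file does not match the documented layout."""


@dataclass
class VariantCall:
    """One somatic SNV/indel observation in one sample."""

    patient_id: str
    sample_id: str
    timepoint: int
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    vaf: float
    depth: int
    alt_reads: int | None = None
    protein_change: str = ""

    def __post_init__(self) -> None:
        if self.timepoint < 0:
            raise ValidationError(f"timepoint must be >= 0, got {self.timepoint}")
        if self.pos < 1:
            raise ValidationError(f"pos must be 1-based positive, got {self.pos}")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValidationError(f"vaf outside [0,1]: {self.vaf}")
        if self.depth < 1:
            raise ValidationError(f"depth must be positive, got {self.depth}")
        if self.alt_reads is not None:
            if self.alt_reads < 0 or self.alt_reads > self.depth:
                raise ValidationError(
                    f"alt_reads {self.alt_reads} outside [0, depth={self.depth}]"
                )
        if not self.gene:
            raise ValidationError("gene symbol must be nonempty for panel variants")


@dataclass
class CnvSegment:
    """One copy-number / LOH segment in one sample.

    ``cn`` is the integer copy-number class (0-4); copy-neutral LOH is
    ``cn == 2`` with ``loh=True``. ``fraction`` is the subclonal cell
    fraction when known; ``baf`` / ``logr`` carry the raw array signal.
    """

    patient_id: str
    sample_id: str
    timepoint: int
    chrom: str
    start: int
    end: int
    cn: int
    loh: bool = False
    baf: float | None = None
    logr: float | None = None
    fraction: float | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"bad segment coordinates {self.chrom}:{self.start}-{self.end}"
            )
        if self.cn not in (0, 1, 2, 3, 4):
            raise ValidationError(f"cn must be in 0..4, got {self.cn}")
        if self.loh and self.cn != 2:
            raise ValidationError("loh=True requires cn=2 (copy-neutral LOH)")
        if self.baf is not None and not 0.0 <= self.baf <= 1.0:
            raise ValidationError(f"baf outside [0,1]: {self.baf}")
        if self.fraction is not None and not 0.0 <= self.fraction <= 1.0:
            raise ValidationError(f"fraction outside [0,1]: {self.fraction}")

    @property
    def cnv_class(self) -> str:
        """'del' (CN 0-1), 'LOH' (CN 2 + allelic loss) or 'dup' (CN 3-4)."""
        if self.cn <= 1:
            return "del"
        if self.cn == 2:
            if not self.loh:
                raise ValidationError("cn=2 without LOH is copy-neutral normal")
            return "LOH"
        return "dup"


@dataclass
class ClinicalRecord:
    """Per-patient clinical annotation and outcome."""

    patient_id: str
    entity: str
    age_group: str
    age_years: float
    relapsed: bool
    time_to_event_days: float
    event_observed: bool
    sample_timepoints: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.entity not in ENTITIES:
            raise ValidationError(f"unknown entity {self.entity!r}")
        if self.age_group not in AGE_GROUPS:
            raise ValidationError(f"unknown age_group {self.age_group!r}")
        if self.age_years < 0:
            raise ValidationError("age_years must be non-negative")
        if self.time_to_event_days <= 0:
            raise ValidationError("time_to_event_days must be positive")
        if self.relapsed and not self.event_observed:
            raise ValidationError("relapsed=True requires event_observed=True")

    @property
    def subgroup(self) -> str:
        return f"{self.age_group} {self.entity}"


@dataclass
class CloneNode:
    node_id: str
    parent_id: str | None  # None marks the root
    events: list[str] = field(default_factory=list)
    ccf_by_timepoint: dict[int, float] = field(default_factory=dict)


@dataclass
class CloneTreeDocument:
    """Rooted clone tree with per-timepoint CCFs.

    A virtual ``NORMAL`` root (empty event list, CCF 1.0) is present only
    when the reconstruction could not settle on a single founding clone.
    """

    patient_id: str
    nodes: list[CloneNode]
    timepoints: list[int]

    # -- structure helpers -------------------------------------------------

    def node(self, node_id: str) -> CloneNode:
        for n in self.nodes:
            if n.node_id == node_id:
                return n
        raise KeyError(node_id)

    @property
    def root(self) -> CloneNode:
        roots = [n for n in self.nodes if n.parent_id is None]
        if len(roots) != 1:
            raise ValidationError(f"tree must have exactly one root, found {len(roots)}")
        return roots[0]

    def children(self, node_id: str) -> list[CloneNode]:
        return [n for n in self.nodes if n.parent_id == node_id]

    def parent_map(self) -> dict[str, str | None]:
        return {n.node_id: n.parent_id for n in self.nodes}

    def is_strict_ancestor(self, a: str, b: str) -> bool:
        """True iff node ``a`` is a strict ancestor of node ``b``."""
        parents = self.parent_map()
        cur = parents.get(b)
        while cur is not None:
            if cur == a:
                return True
            cur = parents.get(cur)
        return False

    def malignant_nodes(self) -> list[CloneNode]:
        return [n for n in self.nodes if n.node_id != NORMAL_NODE_ID]

    def depths(self) -> dict[str, int]:
        """1-based depth from the founding malignant clone.

        Children of a virtual NORMAL root are level 1; the NORMAL node
        itself is assigned level 0 and excluded from malignant depth.
        """
        parents = self.parent_map()
        out: dict[str, int] = {}

        def depth(nid: str) -> int:
            if nid in out:
                return out[nid]
            if nid == NORMAL_NODE_ID:
                out[nid] = 0
            else:
                p = parents[nid]
                if p is None or p == NORMAL_NODE_ID:
                    out[nid] = 1
                else:
                    out[nid] = depth(p) + 1
            return out[nid]

        for n in self.nodes:
            depth(n.node_id)
        return out

    def event_nodes(self) -> dict[str, str]:
        """Map event label -> node_id where it was acquired."""
        out: dict[str, str] = {}
        for n in self.nodes:
            for e in n.events:
                out.setdefault(e, n.node_id)
        return out

    def validate(self) -> None:
        ids = [n.node_id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise ValidationError("node_ids must be unique")
        id_set = set(ids)
        roots = 0
        for n in self.nodes:
            if n.parent_id is None:
                roots += 1
            else:
                if n.parent_id == n.node_id:
                    raise ValidationError(f"node {n.node_id} is its own parent")
                if n.parent_id not in id_set:
                    raise ValidationError(
                        f"node {n.node_id} references unknown parent {n.parent_id}"
                    )
            for tp, ccf in n.ccf_by_timepoint.items():
                if not 0.0 <= ccf <= 1.0 + 1e-12:
                    raise ValidationError(
                        f"CCF outside [0,1] at node {n.node_id}, timepoint {tp}: {ccf}"
                    )
        if roots != 1:
            raise ValidationError(f"tree must have exactly one root, found {roots}")
        # acyclicity: walk to root from every node
        parents = self.parent_map()
        for nid in ids:
            seen = set()
            cur: str | None = nid
            while cur is not None:
                if cur in seen:
                    raise ValidationError(f"cyclic parent references at {cur}")
                seen.add(cur)
                cur = parents[cur]

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        self.validate()
        return {
            "schema_version": 1,
            "patient_id": self.patient_id,
            "timepoints": list(self.timepoints),
            "nodes": [
                {
                    "node_id": n.node_id,
                    "parent_id": n.parent_id,
                    "events": list(n.events),
                    "ccf_by_timepoint": {str(k): v for k, v in n.ccf_by_timepoint.items()},
                }
                for n in self.nodes
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CloneTreeDocument":
        if d.get("schema_version") != 1:
            raise FormatError(f"unsupported tree schema_version: {d.get('schema_version')}")
        doc = cls(
            patient_id=d["patient_id"],
            timepoints=[int(t) for t in d["timepoints"]],
            nodes=[
                CloneNode(
                    node_id=n["node_id"],
                    parent_id=n["parent_id"],
                    events=list(n["events"]),
                    ccf_by_timepoint={int(k): float(v) for k, v in n["ccf_by_timepoint"].items()},
                )
                for n in d["nodes"]
            ],
        )
        doc.validate()
        return doc
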