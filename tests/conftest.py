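import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from clonetraj.datatypes import CloneNode, CloneTreeDocument


def make_tree(patient_id: str, spec: list[tuple[str, str | None, list[str], dict]],
              timepoints: list[int] | None = None) -> CloneTreeDocument:
    """Build a tree from (node_id, parent_id, events, ccf_by_timepoint) rows."""
    nodes = [CloneNode(nid, parent, list(events), dict(ccfs))
             for nid, parent, events, ccfs in spec]
    tps = timepoints if timepoints is not None else sorted(
        {tp for _, _, _, ccfs in spec for tp in ccfs})
    doc = CloneTreeDocument(patient_id=patient_id, nodes=nodes, timepoints=tps)
    doc.validate()
    return doc


@pytest.fixture
def chain_tree():
    """Linear tree A(e1) -> B(e2) -> C(e3), one timepoint."""
    return make_tree("chain", [
        ("A", None, ["e1"], {0: 1.0}),
        ("B", "A", ["e2"], {0: 0.6}),
        ("C", "B", ["e3"], {0: 0.3}),
    ])


@pytest.fixture
def star_tree():
    """Root(e1) with two leaf children (e2), (e3)."""
    return make_tree("star", [
        ("A", None, ["e1"], {0: 1.0}),
        ("B", "A", ["e2"], {0: 0.5}),
        ("C", "A", ["e3"], {0: 0.3}),
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def relation_map(doc: CloneTreeDocument) -> dict[tuple[str, str], str]:
    """Pairwise event relations (ancestor/descendant/same/parallel)."""
    ev = doc.event_nodes()
    labs = sorted(ev)
    out = {}
    for i, a in enumerate(labs):
        for b in labs[i + 1:]:
            na, nb = ev[a], ev[b]
            if na == nb:
                rel = "same"
            elif doc.is_strict_ancestor(na, nb):
                rel = "anc"
            elif doc.is_strict_ancestor(nb, na):
                rel = "desc"
            else:
                rel = "par"
            out[(a, b)] = rel
    return out
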