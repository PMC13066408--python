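"""Minimal clone-tree and CCF-dynamics plots (cosmetic helpers)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402

from .datatypes import CloneTreeDocument


def plot_tree(tree: CloneTreeDocument, ax=None, timepoint: int | None = None):
    """Node-link diagram; marker area scales with CCF at ``timepoint``
    (default: first timepoint)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    tp = timepoint if timepoint is not None else tree.timepoints[0]
    depths = tree.depths()
    by_depth: dict[int, list] = {}
    for n in tree.nodes:
        by_depth.setdefault(depths[n.node_id], []).append(n)
    pos = {}
    for d, nodes in by_depth.items():
        for i, n in enumerate(sorted(nodes, key=lambda x: x.node_id)):
            pos[n.node_id] = (i - (len(nodes) - 1) / 2.0, -d)
    for n in tree.nodes:
        if n.parent_id is not None:
            x0, y0 = pos[n.parent_id]
            x1, y1 = pos[n.node_id]
            ax.plot([x0, x1], [y0, y1], "-", color="0.6", zorder=1)
    for n in tree.nodes:
        x, y = pos[n.node_id]
        ccf = n.ccf_by_timepoint.get(tp, 0.0)
        ax.scatter([x], [y], s=200 * max(ccf, 0.04) + 20, zorder=2)
        label = n.node_id if not n.events else f"{n.node_id}\n" + ",".join(n.events[:3])
        ax.annotate(label, (x, y), textcoords="offset points", xytext=(8, 0),
                    fontsize=7)
    ax.set_axis_off()
    ax.set_title(f"{tree.patient_id} (CCF at t={tp})")
    return ax


def plot_ccf_dynamics(tree: CloneTreeDocument, ax=None):
    """Per-clone CCF over timepoints (line plot)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    for n in tree.malignant_nodes():
        ys = [n.ccf_by_timepoint.get(tp, 0.0) for tp in tree.timepoints]
        ax.plot(tree.timepoints, ys, "o-", label=n.node_id)
    ax.set_xlabel("days since diagnosis")
    ax.set_ylabel("CCF")
    ax.set_ylim(-0.02, 1.05)
    ax.legend(fontsize=7)
    ax.set_title(tree.patient_id)
    return ax
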