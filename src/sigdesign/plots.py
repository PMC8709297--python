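"""Plotting helpers for benchmark results: RMSD box plots per objective,
proximity cumulative-frequency curves, and t-SNE scatter plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .benchmark import BenchmarkResult, ObjectiveResult

_KIND_COLORS = {
    "design": "tab:blue",
    "random": "tab:red",
    "top100": "gold",
    "same_indication": "tab:purple",
}


def plot_rmsd_boxes(result: BenchmarkResult, path: str | Path) -> None:
    """Grouped box plots of design/control RMSD distributions per objective.

    Whiskers at 1.5*IQR, outliers as dots."""
    objectives = list(result.per_objective)
    kinds = ["design", "random", "top100", "same_indication"]
    fig, ax = plt.subplots(figsize=(max(8, 0.8 * len(objectives)), 5))
    width = 0.18
    for k, kind in enumerate(kinds):
        data, positions = [], []
        for i, oid in enumerate(objectives):
            dist = result.per_objective[oid].rmsd_distributions.get(kind)
            if dist:
                data.append(dist)
                positions.append(i + (k - 1.5) * width)
        if not data:
            continue
        bp = ax.boxplot(
            data, positions=positions, widths=width, whis=1.5,
            patch_artist=True, flierprops={"markersize": 2},
        )
        for patch in bp["boxes"]:
            patch.set_facecolor(_KIND_COLORS[kind])
        ax.plot([], [], color=_KIND_COLORS[kind], label=kind)
    ax.set_xticks(range(len(objectives)))
    ax.set_xticklabels(objectives, rotation=90, fontsize=7)
    ax.set_ylabel("signature RMSD to objective")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_proximity_curves(
    proximities_by_subset: dict[str, list[float]], path: str | Path
) -> None:
    """Cumulative-frequency curves of pooled proximity values per subset."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, values in proximities_by_subset.items():
        v = np.sort(np.asarray(values))
        ax.plot(v, np.arange(1, v.size + 1) / v.size, label=name)
    ax.set_xlabel("proximity (relative gain vs naive control)")
    ax.set_ylabel("cumulative frequency")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_tsne(objective_result: ObjectiveResult, path: str | Path) -> None:
    """t-SNE scatter of objective, designs, and controls for one objective."""
    if objective_result.tsne is None:
        raise ValueError("benchmark was run without include_tsne")
    df = objective_result.tsne
    oid = objective_result.objective_id
    design_ids = {
        d.record.compound_id for d in objective_result.design_set.designs
    }
    control_ids = {
        kind: {c.compound_id for c in ctl.compounds}
        for kind, ctl in objective_result.controls.items()
    }
    fig, ax = plt.subplots(figsize=(6, 5))
    for _, row in df.iterrows():
        cid = row["compound_id"]
        if cid == oid:
            continue
        if cid in design_ids:
            color, marker = _KIND_COLORS["design"], "o"
        else:
            color, marker = "gray", "."
            for kind, ids in control_ids.items():
                if cid in ids:
                    color, marker = _KIND_COLORS[kind], "s"
                    break
        ax.scatter(row["x"], row["y"], c=color, marker=marker, s=12)
    obj_row = df[df["compound_id"] == oid].iloc[0]
    ax.scatter(obj_row["x"], obj_row["y"], c="black", marker="*", s=160, label=oid)
    ax.set_title(f"t-SNE of interaction signatures: {oid}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
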