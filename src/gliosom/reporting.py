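"""Figure rendering for a completed pipeline run.

Produces the standard visual summaries of the two-level clustering:
component-plane grids with inter-class borderlines, per-subject tumor label
overlays with label-fraction pie charts, per-label box-whisker plots of the
log-ratio features by genotype, and radar charts of each class centroid's
normalized channel values.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .features import LabelRatioFeatureTable
from .som import SOMModel, ProtoclusterPartition, component_planes, load_model


def plot_component_planes(
    som: SOMModel,
    partition: ProtoclusterPartition | None,
    channel_names,
    path: Path,
) -> None:
    planes, borders = component_planes(som, partition)
    n = planes.shape[0]
    fig, axes = plt.subplots(2, (n + 1) // 2, figsize=(3.2 * ((n + 1) // 2), 6.4))
    for c, ax in zip(range(n), axes.ravel()):
        im = ax.imshow(planes[c], cmap="viridis")
        ax.set_title(channel_names[c])
        ax.set_xticks([])
        ax.set_yticks([])
        fig.colorbar(im, ax=ax, shrink=0.8)
        if borders is not None:
            hi, hj = np.nonzero(borders["horizontal"])
            for i, j in zip(hi, hj):
                ax.plot([j - 0.5, j + 0.5], [i + 0.5, i + 0.5], "r-", lw=0.8)
            vi, vj = np.nonzero(borders["vertical"])
            for i, j in zip(vi, vj):
                ax.plot([j + 0.5, j + 0.5], [i - 0.5, i + 0.5], "r-", lw=0.8)
    for ax in axes.ravel()[n:]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_label_overlay(label_map: np.ndarray, K: int, subject_id: str, path: Path) -> None:
    """Mid-axial label painting plus the label-fraction pie chart."""
    mid = label_map.shape[2] // 2
    nz = np.argwhere(label_map > 0)
    if len(nz):
        mid = int(round(nz[:, 2].mean()))
    sl = label_map[:, :, mid]
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 4))
    cmap = plt.get_cmap("tab20", K + 1)
    ax1.imshow(np.ma.masked_equal(sl.T, 0), cmap=cmap, vmin=1, vmax=K, origin="lower")
    ax1.set_title(f"{subject_id} labels (slice {mid})")
    counts = np.bincount(label_map[label_map > 0], minlength=K + 1)[1:]
    present = counts > 0
    ax2.pie(counts[present],
            labels=[str(k + 1) for k in range(K) if present[k]],
            colors=[cmap(k) for k in range(K) if present[k]])
    ax2.set_title("label fractions")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_label_boxplots(table: LabelRatioFeatureTable, path: Path) -> None:
    geno = np.asarray(table.genotype)
    fig, ax = plt.subplots(figsize=(1.0 * table.K + 2, 4))
    positions, data, colors = [], [], []
    for k in range(table.K):
        data.append(table.log_ratios[k, geno == "wildtype"])
        data.append(table.log_ratios[k, geno == "mutant"])
        positions += [3 * k, 3 * k + 1]
        colors += ["tab:red", "tab:blue"]
    bp = ax.boxplot(data, positions=positions, widths=0.8, patch_artist=True)
    for patch, color in zip(bp["boxes"], colors):
        patch.set_facecolor(color)
    ax.set_xticks([3 * k + 0.5 for k in range(table.K)])
    ax.set_xticklabels([str(k + 1) for k in range(table.K)])
    ax.set_xlabel("label")
    ax.set_ylabel("log10(p + 1e-2)")
    ax.set_title("label log-ratios: wild-type (red) vs mutant (blue)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_radar_charts(partition: ProtoclusterPartition, channel_names, path: Path) -> None:
    K = partition.K
    angles = np.linspace(0, 2 * np.pi, len(channel_names), endpoint=False)
    ncols = min(K, 4)
    nrows = (K + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 3 * nrows),
                             subplot_kw={"projection": "polar"})
    axes = np.atleast_1d(axes).ravel()
    for k in range(K):
        ax = axes[k]
        vals = partition.centroids[k]
        ax.plot(np.r_[angles, angles[0]], np.r_[vals, vals[0]])
        ax.fill(np.r_[angles, angles[0]], np.r_[vals, vals[0]], alpha=0.25)
        ax.set_xticks(angles)
        ax.set_xticklabels(channel_names, fontsize=7)
        ax.set_title(f"label {k + 1}", fontsize=9)
    for ax in axes[K:]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_report(run_dir: str | Path, k: int | None = None) -> Path:
    """Render all figures for a completed run directory.

    Raises FileNotFoundError listing any missing stage outputs.
    """
    run_dir = Path(run_dir)
    model_path = run_dir / "cluster" / "som_model.npz"
    summary_path = run_dir / "summary.json"
    missing = [str(p) for p in (model_path, summary_path) if not p.exists()]
    if missing:
        raise FileNotFoundError(f"missing stage outputs: {', '.join(missing)}")
    summary = json.loads(summary_path.read_text())
    channel_names = summary["config"].get("channel_subset") or [
        "cet1", "t2", "flair", "adc", "rcbv", "fdopa"
    ]
    som, partitions = load_model(model_path)
    k = k or summary["best_k"]["auc"]
    if k not in partitions:
        raise FileNotFoundError(f"no partition for K={k} in the model archive")
    table_path = run_dir / "features" / f"label_ratios_k{k}.csv"
    if not table_path.exists():
        raise FileNotFoundError(f"missing stage outputs: {table_path}")
    table = LabelRatioFeatureTable.from_csv(table_path)

    out = run_dir / "report"
    out.mkdir(exist_ok=True)
    plot_component_planes(som, partitions[k], channel_names, out / "component_planes.png")
    plot_label_boxplots(table, out / f"label_boxplots_k{k}.png")
    plot_radar_charts(partitions[k], channel_names, out / f"radar_k{k}.png")
    return out
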