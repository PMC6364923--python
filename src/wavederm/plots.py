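"""Diagnostic figures: AUC vs. wavelet number, kernel averages, SV counts."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

_KERNEL_MARKERS = {"gaussian": "s", "linear": "^", "polynomial": "o"}


def auc_vs_wavelet(grid, out_dir: Path) -> list[Path]:
    """One panel per resolution: AUC against the wavelet catalogue number."""
    df = grid.to_frame()
    paths = []
    for res, sub in df.groupby("resolution"):
        fig, ax = plt.subplots(figsize=(7, 4))
        for kernel, line in sub.groupby("kernel"):
            line = line.sort_values("wavelet_id")
            ax.plot(
                line.wavelet_id,
                line.auc,
                marker=_KERNEL_MARKERS.get(kernel, "x"),
                label=kernel,
            )
        ax.set_xlabel("wavelet number")
        ax.set_ylabel("AUC")
        ax.set_title(f"resolution {res}")
        ax.set_ylim(0.0, 1.05)
        ax.legend()
        path = Path(out_dir) / f"auc_vs_wavelet_{res}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    return paths


def average_auc_bars(avg: pd.DataFrame, path: Path) -> Path:
    """Per-kernel average AUC (mean over wavelet ids) by resolution."""
    fig, ax = plt.subplots(figsize=(6, 4))
    pivot = avg.pivot(index="resolution", columns="kernel", values="mean_auc")
    pivot.plot.bar(ax=ax, rot=0)
    ax.set_ylabel("average AUC over wavelet ids")
    ax.set_ylim(0.0, 1.05)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return Path(path)


def support_vector_counts(cell_results: dict, path: Path) -> Path:
    """Mean support-vector count per wavelet id, split by kernel/resolution."""
    rows = [
        {
            "wavelet_id": wid,
            "resolution": res,
            "kernel": kernel,
            "n_sv": r.mean_n_support_vectors,
        }
        for (wid, res, kernel), r in cell_results.items()
    ]
    df = pd.DataFrame(rows)
    fig, ax = plt.subplots(figsize=(7, 4))
    for (kernel, res), sub in df.groupby(["kernel", "resolution"]):
        sub = sub.sort_values("wavelet_id")
        ax.plot(
            sub.wavelet_id,
            sub.n_sv,
            marker=_KERNEL_MARKERS.get(kernel, "x"),
            alpha=0.7,
            label=f"{kernel}/{res}",
        )
    ax.set_xlabel("wavelet number")
    ax.set_ylabel("mean support vectors per fold")
    ax.legend(fontsize=7)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return Path(path)
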