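"""Biplot export for the response-specific component model.

Each sample gets a score scatter (PC1 vs PC2) with per-marker loading
vectors (length = loading norm = the marker's importance; the angle between
two vectors reflects the markers' correlation, 180 degrees = negative),
the pooled-control benchmark ellipse and the sample's own ellipse. The
numbers behind every plot — loadings, explained fractions, per-sample
overlap fractions — are also written as delimited tables so the figures
are fully reproducible from text.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.patches import Ellipse

from .flood import BenchmarkRegion, FloodResults


def _ellipse_artist(region: BenchmarkRegion, **kwargs) -> Ellipse:
    eigval, eigvec = np.linalg.eigh(region.shape)
    # axis half-lengths: sqrt(eigenvalue * squared-radius threshold)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    angle = float(np.degrees(np.arctan2(eigvec[1, 0], eigvec[0, 0])))
    width, height = 2.0 * np.sqrt(eigval * region.threshold)
    return Ellipse(
        xy=tuple(region.center), width=width, height=height, angle=angle,
        fill=False, **kwargs,
    )


def export_biplot(
    results: FloodResults,
    per_sample: dict,
    out_dir: str | Path,
    loading_scale: float | None = None,
) -> dict[str, Path]:
    """Write per-sample biplots plus the underlying delimited tables.

    Returns a mapping of artefact names to paths. ``per_sample`` is the
    mapping produced by :func:`floodcyto.flood.flood_from_records`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artefacts: dict[str, Path] = {}

    loadings = pd.DataFrame(
        results.response_loadings,
        index=list(results.markers),
        columns=[f"PC{i + 1}" for i in range(results.k_r)],
    )
    loadings.index.name = "marker"
    loadings_path = out_dir / "response_loadings.tsv"
    loadings.to_csv(loadings_path, sep="\t")
    artefacts["loadings"] = loadings_path

    explained = pd.DataFrame(
        {
            "component": [f"PC{i + 1}" for i in range(results.k_r)],
            "explained_fraction": results.explained_fractions,
        }
    )
    explained_path = out_dir / "explained_fractions.tsv"
    explained.to_csv(explained_path, sep="\t", index=False)
    artefacts["explained"] = explained_path

    rows = []
    for (subject, time_label), entry in per_sample.items():
        rows.append(
            {
                "subject": subject,
                "time": time_label,
                "n_cells": entry["scores"].shape[0],
                "control_overlap": entry["overlap"],
            }
        )
    overlap_path = out_dir / "sample_overlap.tsv"
    pd.DataFrame(rows).to_csv(overlap_path, sep="\t", index=False)
    artefacts["overlap"] = overlap_path

    if loading_scale is None:
        span = max(
            float(np.abs(entry["scores"]).max()) for entry in per_sample.values()
        )
        norms = np.linalg.norm(results.response_loadings, axis=1)
        loading_scale = 0.7 * span / max(norms.max(), 1e-12)

    for (subject, time_label), entry in per_sample.items():
        fig, ax = plt.subplots(figsize=(5, 5))
        s = entry["scores"]
        ax.hexbin(s[:, 0], s[:, 1], gridsize=60, cmap="Blues", mincnt=1)
        ax.add_patch(_ellipse_artist(results.benchmark, color="cyan", lw=1.8))
        if "benchmark" in entry:
            colour = "navy" if time_label == "morning_d1" else "red"
            ax.add_patch(_ellipse_artist(entry["benchmark"], color=colour, lw=1.5))
        for i, marker in enumerate(results.markers):
            vx, vy = results.response_loadings[i, :2] * loading_scale
            ax.annotate(
                "", xy=(vx, vy), xytext=(0, 0),
                arrowprops=dict(arrowstyle="->", color="black", lw=1.0),
            )
            ax.text(vx * 1.08, vy * 1.08, marker, fontsize=7, ha="center")
        ev = results.explained_fractions
        ax.set_xlabel(f"PC1 ({ev[0] * 100:.0f}% response-specific variance)")
        ax.set_ylabel(
            f"PC2 ({ev[1] * 100:.0f}%)" if len(ev) > 1 else "PC2"
        )
        ax.set_title(f"{subject} {time_label}")
        fig.tight_layout()
        fig_path = out_dir / f"biplot_{subject}_{time_label}.png"
        fig.savefig(fig_path, dpi=120)
        plt.close(fig)
        artefacts[f"biplot_{subject}_{time_label}"] = fig_path
    return artefacts
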