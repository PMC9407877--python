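"""Diagnostic plots: scatter cloud + boundary points + fitted curve."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .constraint import BoundaryPointSet, ConstraintCurve
from .synthgen import ScatterCloud

__all__ = ["plot_constraint"]


def plot_constraint(
    cloud: ScatterCloud,
    points: BoundaryPointSet,
    curve: ConstraintCurve,
    path: str | Path,
    max_points: int = 5000,
) -> Path:
    """One pair-year panel: cloud, per-bin boundary points, fitted curve,
    and (for hump fits) the threshold marker."""
    fig, ax = plt.subplots(figsize=(5, 4))
    n = len(cloud)
    if n > max_points:
        idx = np.linspace(0, n - 1, max_points).astype(int)
        ax.plot(cloud.x[idx], cloud.y[idx], ".", ms=2, color="#4878a8", alpha=0.3)
    else:
        ax.plot(cloud.x, cloud.y, ".", ms=2, color="#4878a8", alpha=0.3)
    ax.plot(points.x_mid, points.y_q, "o", ms=4, color="black", label="boundary")
    xs = np.linspace(cloud.x.min(), cloud.x.max(), 200)
    ax.plot(xs, curve.predict(xs), "-", color="crimson", label=f"{curve.form} (R²={curve.r2:.2f})")
    if curve.form == "hump" and curve.threshold_x is not None:
        ax.plot([curve.threshold_x], [curve.threshold_y], "k^", ms=8, label="threshold")
    a, b = cloud.pair_label.split("_") if "_" in cloud.pair_label else (cloud.pair_label, "")
    ax.set_xlabel(a)
    ax.set_ylabel(b)
    title = cloud.pair_label if cloud.year is None else f"{cloud.pair_label} {cloud.year}"
    ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
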