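"""Constraint-line extraction by quantile segmentation.

The x-axis of an ES-pair scatter cloud is cut into equal-width bins, a
high empirical quantile of y is taken per bin (linear-interpolation
convention), and a curve is least-squares fitted to those boundary
points: a quadratic hump with its vertex as the threshold, or an
exponential decay y = b * k**x. ``auto`` fits both and keeps the higher
R². R² is always computed on the boundary points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import FormMismatchError, InsufficientDataError, InvalidInputError
from .esmodels import ESLayer
from .synthgen import LandUseMap, ScatterCloud

logger = logging.getLogger(__name__)

__all__ = [
    "BoundaryPointSet",
    "ConstraintCurve",
    "extract_boundary",
    "fit_constraint",
    "run_pairs",
    "DEFAULT_PAIRS",
    "DEFAULT_FORM_MAP",
]

#: The six ES pairs analysed, "A_B" with A constraining (x) and B responding (y).
DEFAULT_PAIRS = ("NPP_SC", "NPP_WY", "FP_NPP", "FP_WY", "FP_SC", "WY_SC")

#: Functional form fitted per pair; SC->FP is exponential, the rest hump.
DEFAULT_FORM_MAP: dict[str, str] = {"SC_FP": "exponential"}

MIN_BOUNDARY_POINTS = 5


@dataclass
class BoundaryPointSet:
    """Upper-quantile boundary points of a scatter cloud."""

    pair_label: str
    bin_edges: np.ndarray
    x_mid: np.ndarray
    y_q: np.ndarray
    quantile: float
    min_points: int
    bins_dropped: int
    year: int | None = None

    def __len__(self) -> int:
        return self.x_mid.size


@dataclass
class ConstraintCurve:
    """Fitted boundary curve and its characteristic values."""

    pair_label: str
    form: str  # "hump" or "exponential"
    params: dict[str, float]
    r2: float
    threshold_x: float | None = None  # hump vertex location
    threshold_y: float | None = None  # hump vertex height
    k: float | None = None  # exponential decay base
    b: float | None = None  # exponential intercept (value at x = 0)
    year: int | None = None
    n_points: int = 0

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.form == "hump":
            p = self.params
            return p["a2"] * x**2 + p["a1"] * x + p["a0"]
        return self.b * np.power(self.k, x)


def extract_boundary(
    cloud: ScatterCloud,
    n_bins: int = 50,
    quantile: float = 0.99,
    min_points: int = 10,
) -> BoundaryPointSet:
    """One upper-quantile boundary point per sufficiently populated x bin.

    Bins with fewer than ``min_points`` observations are dropped and
    counted; fewer than five retained bins raises
    :class:`InsufficientDataError`.
    """
    if not 0.0 < quantile <= 1.0:
        raise InvalidInputError(f"quantile must lie in (0, 1], got {quantile}")
    if n_bins < 1 or min_points < 1:
        raise InvalidInputError("n_bins and min_points must be >= 1")

    x, y = cloud.x, cloud.y
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    # right-inclusive last bin so the max point is not orphaned
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)

    mids, yq = [], []
    dropped = 0
    for b in range(n_bins):
        sel = idx == b
        count = int(sel.sum())
        if count < min_points:
            dropped += 1
            continue
        mids.append(0.5 * (edges[b] + edges[b + 1]))
        yq.append(float(np.quantile(y[sel], quantile, method="linear")))
    if len(mids) < MIN_BOUNDARY_POINTS:
        raise InsufficientDataError(
            f"only {len(mids)} boundary bins retained (need >= {MIN_BOUNDARY_POINTS})"
        )
    return BoundaryPointSet(
        pair_label=cloud.pair_label,
        bin_edges=edges,
        x_mid=np.asarray(mids),
        y_q=np.asarray(yq),
        quantile=quantile,
        min_points=min_points,
        bins_dropped=dropped,
        year=cloud.year,
    )


def _r2(y: np.ndarray, y_hat: np.ndarray) -> float:
    ss_res = float(((y - y_hat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot <= 0:
        return 1.0 if ss_res <= 1e-24 else 0.0
    return max(0.0, min(1.0, 1.0 - ss_res / ss_tot))


def _fit_hump(points: BoundaryPointSet) -> ConstraintCurve:
    a2, a1, a0 = np.polyfit(points.x_mid, points.y_q, 2)
    if a2 >= 0 or abs(a2) < 1e-12:
        raise FormMismatchError(
            f"hump fit rejected for {points.pair_label}: quadratic coefficient {a2:.3g} is not negative"
        )
    tx = -a1 / (2.0 * a2)
    ty = a0 - a1**2 / (4.0 * a2)
    y_hat = a2 * points.x_mid**2 + a1 * points.x_mid + a0
    return ConstraintCurve(
        pair_label=points.pair_label,
        form="hump",
        params={"a2": float(a2), "a1": float(a1), "a0": float(a0)},
        r2=_r2(points.y_q, y_hat),
        threshold_x=float(tx),
        threshold_y=float(ty),
        year=points.year,
        n_points=len(points),
    )


def _fit_exponential(points: BoundaryPointSet) -> ConstraintCurve:
    if np.any(points.y_q <= 0):
        raise InvalidInputError(
            f"exponential fit for {points.pair_label} requires positive boundary y"
        )
    slope, intercept = np.polyfit(points.x_mid, np.log(points.y_q), 1)
    k = float(np.exp(slope))
    b = float(np.exp(intercept))
    y_hat = b * k**points.x_mid
    return ConstraintCurve(
        pair_label=points.pair_label,
        form="exponential",
        params={"k": k, "b": b},
        r2=_r2(points.y_q, y_hat),
        k=k,
        b=b,
        year=points.year,
        n_points=len(points),
    )


def fit_constraint(points: BoundaryPointSet, form: str = "auto") -> ConstraintCurve:
    """Least-squares constraint curve through the boundary points.

    ``hump`` is a quadratic (vertex = threshold, quadratic coefficient must
    be negative); ``exponential`` is y = b * k**x fitted by log-linear
    regression; ``auto`` tries both and keeps the higher R².
    """
    if len(points) < MIN_BOUNDARY_POINTS:
        raise InsufficientDataError(
            f"{len(points)} boundary points (need >= {MIN_BOUNDARY_POINTS})"
        )
    if form == "hump":
        return _fit_hump(points)
    if form == "exponential":
        return _fit_exponential(points)
    if form != "auto":
        raise InvalidInputError(f"unknown form {form!r}")
    candidates: list[ConstraintCurve] = []
    for fitter in (_fit_hump, _fit_exponential):
        try:
            candidates.append(fitter(points))
        except (FormMismatchError, InvalidInputError) as exc:
            logger.debug("auto fit: %s", exc)
    if not candidates:
        raise FormMismatchError(f"no admissible form for {points.pair_label}")
    return max(candidates, key=lambda c: c.r2)


@dataclass
class PairConfig:
    """Knobs for :func:`run_pairs`; every output row records them."""

    n_bins: int = 50
    quantile: float = 0.99
    min_points: int = 10
    sample_n: int = 10_000
    form_map: dict[str, str] = dc_field(default_factory=lambda: dict(DEFAULT_FORM_MAP))
    default_form: str = "hump"


def build_cloud(
    layers: Mapping[str, ESLayer],
    pair: str,
    landuse: LandUseMap | None = None,
    sample_n: int = 10_000,
    rng: np.random.Generator | None = None,
    year: int | None = None,
) -> ScatterCloud:
    """Co-located (x, y) samples for one pair; FP pairs restricted to cropland."""
    a, b = pair.split("_")
    xa = np.asarray(layers[a].values, dtype=float)
    yb = np.asarray(layers[b].values, dtype=float)
    valid = np.isfinite(xa) & np.isfinite(yb)
    if "FP" in (a, b):
        if landuse is None:
            raise InvalidInputError("FP pairs need a land-use map for the cropland mask")
        valid &= landuse.mask("cropland")
    xv, yv = xa[valid], yb[valid]
    if rng is not None and xv.size > sample_n:
        take = rng.choice(xv.size, size=sample_n, replace=False)
        xv, yv = xv[take], yv[take]
    return ScatterCloud(pair_label=pair, x=xv, y=yv, year=year)


def run_pairs(
    es_layers: Mapping[int, Mapping[str, ESLayer]],
    pairs: tuple[str, ...] = DEFAULT_PAIRS,
    landuse_by_year: Mapping[int, LandUseMap] | None = None,
    config: PairConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit one constraint curve per (year, pair); failures become missing rows.

    Returns a tidy frame with columns year, pair, form, a2/a1/a0 or k/b,
    r2, threshold_x, threshold_y, n_points, status.
    """
    config = config or PairConfig()
    rows = []
    for year in sorted(es_layers):
        layers = es_layers[year]
        lu = landuse_by_year.get(year) if landuse_by_year else None
        # per-(year, pair) child seed keeps results independent of pair order
        for j, pair in enumerate(pairs):
            rng = np.random.default_rng(np.random.SeedSequence((seed, year, j)))
            form = config.form_map.get(pair, config.default_form)
            record: dict = {"year": year, "pair": pair, "form": form, "status": "ok"}
            try:
                cloud = build_cloud(
                    layers, pair, landuse=lu, sample_n=config.sample_n, rng=rng, year=year
                )
                points = extract_boundary(
                    cloud, config.n_bins, config.quantile, config.min_points
                )
                curve = fit_constraint(points, form)
            except (InsufficientDataError, FormMismatchError, InvalidInputError) as exc:
                logger.warning("%s %s: %s", year, pair, exc)
                record.update(status="missing", error=str(exc))
                rows.append(record)
                continue
            record.update(
                form=curve.form,
                r2=curve.r2,
                threshold_x=curve.threshold_x,
                threshold_y=curve.threshold_y,
                k=curve.k,
                b=curve.b,
                n_points=curve.n_points,
                bins_dropped=points.bins_dropped,
                n_bins=config.n_bins,
                quantile=config.quantile,
                sample_n=config.sample_n,
            )
            record.update({name: curve.params.get(name) for name in ("a2", "a1", "a0")})
            rows.append(record)
    return pd.DataFrame(rows)
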