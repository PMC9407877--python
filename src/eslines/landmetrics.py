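"""Landscape composition shares and five configuration metrics.

Patches are maximal connected components of equal-class cells (8-connected
by default). Metrics follow the standard landscape-level raster
definitions:

* SHDI  = -sum p_i ln p_i
* LSI   = 0.25 * E* / sqrt(A), E* = total edge incl. the landscape boundary
* CONTAG from the double-count class-adjacency matrix, boundary excluded
* PD    = patches per 100 ha
* PAFRAC = 2 / slope of OLS regression of ln(area) on ln(perimeter)

Undefined metrics (CONTAG with one class, PAFRAC with < 10 patches) are
returned as None, never silently zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import InvalidParameterError
from .synthgen import CLASS_CODES, LandUseMap

logger = logging.getLogger(__name__)

__all__ = [
    "PatchSet",
    "LandscapeMetrics",
    "label_patches",
    "compute_composition",
    "compute_configuration",
    "perimeter_area_fractal_dimension",
    "metrics_for_year",
]

MIN_PATCHES_FOR_PAFRAC = 10


@dataclass
class PatchSet:
    """Labelled patch raster plus per-patch area/perimeter records."""

    labels: np.ndarray  # patch ids 1..n
    table: pd.DataFrame  # patch_id, class_code, area_m2, perimeter_m
    connectivity: int
    cell_size: float

    @property
    def n_patches(self) -> int:
        return len(self.table)


@dataclass
class LandscapeMetrics:
    year: int | None
    composition: dict[str, float]  # class name -> % of landscape
    pafrac: float | None
    lsi: float
    contag: float | None
    shdi: float
    pd: float


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    raise InvalidParameterError(f"connectivity must be 4 or 8, got {connectivity}")


def label_patches(landuse: LandUseMap, connectivity: int = 8) -> PatchSet:
    """Label maximal same-class connected components and measure them.

    Perimeters count exposed cell-edge length, including edges on the
    landscape boundary.
    """
    struct = _structure(connectivity)
    classes = landuse.classes
    cell = landuse.grid.cell_size

    labels = np.zeros(classes.shape, dtype=np.int32)
    records: list[tuple[int, int]] = []  # (patch_id, class_code)
    offset = 0
    for code in sorted(np.unique(classes)):
        lab, n = ndimage.label(classes == code, structure=struct)
        labels[lab > 0] = lab[lab > 0] + offset
        records.extend((offset + i, int(code)) for i in range(1, n + 1))
        offset += n

    n_patches = offset
    areas = np.bincount(labels.ravel(), minlength=n_patches + 1)[1:] * cell * cell

    # exposed-edge counting per patch (class boundaries + landscape boundary)
    edge_counts = np.zeros(n_patches + 1, dtype=np.int64)
    h_diff = classes[:, :-1] != classes[:, 1:]
    np.add.at(edge_counts, labels[:, :-1][h_diff], 1)
    np.add.at(edge_counts, labels[:, 1:][h_diff], 1)
    v_diff = classes[:-1, :] != classes[1:, :]
    np.add.at(edge_counts, labels[:-1, :][v_diff], 1)
    np.add.at(edge_counts, labels[1:, :][v_diff], 1)
    for border in (labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]):
        np.add.at(edge_counts, border, 1)
    perimeters = edge_counts[1:] * cell

    table = pd.DataFrame(
        {
            "patch_id": [r[0] for r in records],
            "class_code": [r[1] for r in records],
            "area_m2": areas,
            "perimeter_m": perimeters,
        }
    )
    return PatchSet(labels=labels, table=table, connectivity=connectivity, cell_size=cell)


def perimeter_area_fractal_dimension(
    areas_m2: np.ndarray, perimeters_m: np.ndarray, min_patches: int = MIN_PATCHES_FOR_PAFRAC
) -> float | None:
    """PAFRAC = 2 / slope of the OLS regression of ln(area) on ln(perimeter).

    Returns None (undefined) with fewer than ``min_patches`` patches or a
    degenerate regression.
    """
    areas = np.asarray(areas_m2, dtype=float)
    perims = np.asarray(perimeters_m, dtype=float)
    if areas.size < min_patches:
        logger.info("only %d patches (< %d): PAFRAC undefined", areas.size, min_patches)
        return None
    ln_a, ln_p = np.log(areas), np.log(perims)
    if np.ptp(ln_p) < 1e-12:
        logger.warning("all patch perimeters equal; PAFRAC undefined")
        return None
    slope = stats.linregress(ln_p, ln_a).slope
    return float(2.0 / slope) if abs(slope) > 1e-12 else None


def compute_composition(landuse: LandUseMap) -> dict[str, float]:
    """Per-class share of the landscape in percent (sums to 100)."""
    n = landuse.classes.size
    return {
        name: 100.0 * float(np.count_nonzero(landuse.classes == code)) / n
        for name, code in CLASS_CODES.items()
    }


def _adjacency_matrix(classes: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Double-count 4-neighbour class adjacencies, landscape boundary excluded."""
    index = {c: i for i, c in enumerate(codes)}
    m = len(codes)
    g = np.zeros((m, m))
    mapped = np.vectorize(index.get)(classes)
    for a, b in (
        (mapped[:, :-1], mapped[:, 1:]),
        (mapped[:-1, :], mapped[1:, :]),
    ):
        np.add.at(g, (a.ravel(), b.ravel()), 1)
        np.add.at(g, (b.ravel(), a.ravel()), 1)
    return g


def compute_configuration(
    patches: PatchSet, landuse: LandUseMap, year: int | None = None
) -> LandscapeMetrics:
    """The five configuration metrics plus composition for one landscape."""
    classes = landuse.classes
    cell = landuse.grid.cell_size
    total_area_m2 = classes.size * cell * cell
    total_area_ha = total_area_m2 / 1e4

    composition = compute_composition(landuse)
    shares = np.array([v / 100.0 for v in composition.values() if v > 0])

    shdi = float(-(shares * np.log(shares)).sum())

    # total edge incl. boundary, counted once
    internal = int((classes[:, :-1] != classes[:, 1:]).sum()) + int(
        (classes[:-1, :] != classes[1:, :]).sum()
    )
    boundary = 2 * (classes.shape[0] + classes.shape[1])
    e_star = (internal + boundary) * cell
    lsi = float(0.25 * e_star / math.sqrt(total_area_m2))

    pd_metric = float(patches.n_patches / total_area_ha * 100.0)

    codes = np.unique(classes)
    if codes.size < 2:
        contag = None
    else:
        g = _adjacency_matrix(classes, codes)
        p_i = np.array([np.count_nonzero(classes == c) / classes.size for c in codes])
        row_sums = g.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.where(row_sums > 0, g / row_sums, 0.0)
        terms = p_i[:, None] * q
        nz = terms > 0
        entropy = float((terms[nz] * np.log(terms[nz])).sum())
        contag = float((1.0 + entropy / (2.0 * math.log(codes.size))) * 100.0)

    pafrac = perimeter_area_fractal_dimension(
        patches.table["area_m2"].to_numpy(), patches.table["perimeter_m"].to_numpy()
    )

    return LandscapeMetrics(
        year=year,
        composition=composition,
        pafrac=pafrac,
        lsi=lsi,
        contag=contag,
        shdi=shdi,
        pd=pd_metric,
    )


def metrics_for_year(
    landuse: LandUseMap, year: int | None = None, connectivity: int = 8
) -> LandscapeMetrics:
    """Convenience wrapper: label patches then compute all metrics."""
    return compute_configuration(label_patches(landuse, connectivity), landuse, year=year)


def metrics_to_row(metrics: LandscapeMetrics) -> dict[str, float | None]:
    """Flatten a LandscapeMetrics into one CSV row (class shares then metrics)."""
    row: dict[str, float | None] = {"year": metrics.year}
    for name in CLASS_CODES:
        row[f"{name}_pct"] = metrics.composition[name]
    row.update(
        pafrac=metrics.pafrac,
        lsi=metrics.lsi,
        contag=metrics.contag,
        shdi=metrics.shdi,
        pd=metrics.pd,
    )
    return row
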