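"""Synthetic input generation.

Every downstream stage of the pipeline is exercised against rasters and
scatter clouds produced here, with known statistical structure: land-use
mosaics with tunable composition and clumping, spatially autocorrelated
climate/NDVI surfaces with imposed interannual trends, a DEM whose relief
is concentrated in a central ridge, and ES-pair scatter clouds whose upper
boundary is an analytic hump or exponential curve.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError
from .grids import GridSpec

logger = logging.getLogger(__name__)

__all__ = [
    "CLASS_CODES",
    "CLASS_NAMES",
    "LandUseMap",
    "ForcingStack",
    "ZoneMap",
    "ScatterCloud",
    "generate_landscape",
    "generate_dem",
    "generate_soil",
    "generate_forcing",
    "generate_zones",
    "generate_constrained_cloud",
]

#: Land-use class codes used throughout the pipeline.
CLASS_CODES: dict[str, int] = {
    "cropland": 1,
    "forest": 2,
    "grassland": 3,
    "water": 4,
    "urban": 5,
    "unused": 6,
}
CLASS_NAMES: dict[int, str] = {v: k for k, v in CLASS_CODES.items()}

#: Fraction of annual precipitation falling in each calendar month.
#: Summer (Jun-Aug) carries 70% of the annual total.
MONTHLY_PPT_WEIGHTS = np.array(
    [0.30 / 9] * 5 + [0.70 / 3] * 3 + [0.30 / 9] * 4
)

#: Seasonal multipliers for monthly solar radiation (mean 1, peak in June).
MONTHLY_SOL_WEIGHTS = 1.0 + 0.45 * np.cos(2 * np.pi * (np.arange(12) - 5.5) / 12.0)
MONTHLY_SOL_WEIGHTS = MONTHLY_SOL_WEIGHTS / MONTHLY_SOL_WEIGHTS.mean()


@dataclass
class LandUseMap:
    """Integer raster of land-use codes 1..6 plus its grid geometry."""

    grid: GridSpec
    classes: np.ndarray

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes)
        if self.classes.shape != self.grid.shape:
            raise InvalidParameterError(
                f"class raster shape {self.classes.shape} != grid {self.grid.shape}"
            )
        valid = np.isin(self.classes, list(CLASS_CODES.values()))
        if not valid.all():
            bad = np.unique(self.classes[~valid])
            raise InvalidParameterError(f"unknown land-use codes: {bad.tolist()}")

    def mask(self, name: str) -> np.ndarray:
        return self.classes == CLASS_CODES[name]

    def fractions(self) -> dict[int, float]:
        """Realized per-class cell fractions (sum to 1 exactly)."""
        n = self.classes.size
        return {
            code: float(np.count_nonzero(self.classes == code)) / n
            for code in CLASS_CODES.values()
        }


@dataclass
class ForcingStack:
    """One year of gridded forcing.

    ``ppt`` is the annual total (mm yr-1) with a fixed monthly
    decomposition ``ppt_monthly`` (12, rows, cols); ``sol`` is monthly
    (MJ m-2 mo-1); soil holds sand/silt/clay/oc percentage rasters.
    """

    year: int
    grid: GridSpec
    ppt: np.ndarray
    ppt_monthly: np.ndarray
    tem: np.ndarray
    sol: np.ndarray
    ndvi: np.ndarray
    dem: np.ndarray
    soil: dict[str, np.ndarray]
    pop: np.ndarray
    gdp: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.ppt < 0):
            raise InvalidParameterError("ppt must be non-negative")
        if np.any(self.ndvi < -1) or np.any(self.ndvi > 1):
            raise InvalidParameterError("ndvi must lie in [-1, 1]")
        tex = self.soil["sand"] + self.soil["silt"] + self.soil["clay"]
        if np.any(np.abs(tex - 100.0) > 1.0):
            raise InvalidParameterError("sand+silt+clay must sum to 100 +/- 1")


@dataclass
class ZoneMap:
    """Administrative zones plus the per-zone total food production (t)."""

    grid: GridSpec
    zones: np.ndarray
    yield_table: dict[int, float]

    def __post_init__(self) -> None:
        ids = np.unique(self.zones)
        missing = [int(z) for z in ids if int(z) not in self.yield_table]
        if missing:
            raise InvalidParameterError(f"zones missing from yield_table: {missing}")


@dataclass
class ScatterCloud:
    """Paired (x, y) samples for one ES pair; label is 'A_B' with A on x."""

    pair_label: str
    x: np.ndarray
    y: np.ndarray
    year: int | None = None
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1 or self.x.size < 1:
            raise InvalidParameterError("x and y must be 1-D arrays of equal length >= 1")
        if np.isnan(self.x).any() or np.isnan(self.y).any():
            raise InvalidParameterError("scatter cloud must not contain NaN")

    def __len__(self) -> int:
        return self.x.size


def _smooth_field(
    rng: np.random.Generator, shape: tuple[int, int], sigma: float
) -> np.ndarray:
    """Standardized (mean 0, sd 1) spatially autocorrelated Gaussian field."""
    raw = rng.standard_normal(shape)
    if sigma > 0:
        raw = ndimage.gaussian_filter(raw, sigma=sigma, mode="reflect")
    sd = raw.std()
    if sd < 1e-12:
        return np.zeros(shape)
    return (raw - raw.mean()) / sd


def generate_landscape(
    spec: GridSpec,
    class_proportions: Mapping[int | str, float],
    clumping: float = 0.5,
    seed: int = 0,
) -> LandUseMap:
    """Generate a land-use mosaic with target composition and clumping.

    A rank-carved autocorrelated field: cells are ranked by a smoothed
    Gaussian random field and the rank order is cut into contiguous
    slices sized exactly by the requested proportions, one slice per
    class (classes placed in a seed-shuffled order). ``clumping`` in
    [0, 1] maps to the smoothing length, so 0 gives salt-and-pepper and
    1 gives large coherent patches; realized composition is exact up to
    integer rounding for any grid size.
    """
    props = {
        (CLASS_CODES[k] if isinstance(k, str) else int(k)): float(v)
        for k, v in class_proportions.items()
    }
    unknown = set(props) - set(CLASS_CODES.values())
    if unknown:
        raise InvalidParameterError(f"unknown class codes in proportions: {sorted(unknown)}")
    if any(v < 0 for v in props.values()):
        raise InvalidParameterError("class proportions must be non-negative")
    total = sum(props.values())
    if abs(total - 1.0) > 1e-9:
        raise InvalidParameterError(f"class proportions must sum to 1, got {total}")
    if not 0.0 <= clumping <= 1.0:
        raise InvalidParameterError(f"clumping must lie in [0, 1], got {clumping}")

    rng = np.random.default_rng(seed)
    n = spec.n_cells
    codes = sorted(props)
    # integer cell targets summing exactly to n (largest-remainder rounding)
    raw = np.array([props[c] * n for c in codes])
    targets = np.floor(raw).astype(int)
    short = n - targets.sum()
    if short > 0:
        order = np.argsort(-(raw - np.floor(raw)))
        targets[order[:short]] += 1

    sigma = 8.0 * clumping
    field = rng.standard_normal(spec.shape)
    if sigma > 0:
        field = ndimage.gaussian_filter(field, sigma=sigma, mode="reflect")
    # tiny white-noise tie-breaker keeps ranks unique after heavy smoothing
    field = field + 1e-9 * rng.standard_normal(spec.shape)

    code_order = np.array(codes, dtype=np.int16)
    rng.shuffle(code_order)
    shuffled_targets = [targets[codes.index(int(c))] for c in code_order]
    pool = np.repeat(code_order, shuffled_targets)

    out = np.empty(n, dtype=np.int16)
    out[np.argsort(field, axis=None, kind="stable")] = pool
    return LandUseMap(grid=spec, classes=out.reshape(spec.shape))


def generate_dem(
    spec: GridSpec,
    seed: int = 0,
    base_relief: float = 60.0,
    ridge_height: float = 800.0,
    ridge_width_frac: float = 0.18,
    smooth_sigma: float = 6.0,
) -> np.ndarray:
    """Smoothed random relief plus a Gaussian ridge in the grid centre."""
    rng = np.random.default_rng(seed)
    dem = base_relief * _smooth_field(rng, spec.shape, smooth_sigma)
    rr, cc = np.mgrid[0 : spec.n_rows, 0 : spec.n_cols]
    r0, c0 = (spec.n_rows - 1) / 2.0, (spec.n_cols - 1) / 2.0
    w = ridge_width_frac * max(spec.n_rows, spec.n_cols)
    dem = dem + ridge_height * np.exp(-(((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * w * w)))
    return dem - dem.min() + 20.0


def generate_soil(spec: GridSpec, seed: int = 0) -> dict[str, np.ndarray]:
    """Sand/silt/clay percentage rasters (sum 100) plus organic carbon (%)."""
    rng = np.random.default_rng(seed)
    logits = {
        "sand": 0.30 * _smooth_field(rng, spec.shape, 5.0) + np.log(40.0),
        "silt": 0.30 * _smooth_field(rng, spec.shape, 5.0) + np.log(35.0),
        "clay": 0.30 * _smooth_field(rng, spec.shape, 5.0) + np.log(25.0),
    }
    raw = {k: np.exp(v) for k, v in logits.items()}
    denom = raw["sand"] + raw["silt"] + raw["clay"]
    soil = {k: 100.0 * v / denom for k, v in raw.items()}
    soil["oc"] = np.clip(0.9 + 0.35 * _smooth_field(rng, spec.shape, 5.0), 0.05, None)
    return soil


def _require_params(params: Mapping[str, float] | None, mean: float, sd: float) -> dict:
    out = {"mean": mean, "sd": sd, "spatial_gradient": 0.0, "trend": 0.0}
    if params:
        out.update({k: float(v) for k, v in params.items()})
    if out["sd"] < 0:
        raise InvalidParameterError(f"sd must be >= 0, got {out['sd']}")
    return out


def generate_forcing(
    spec: GridSpec,
    years: Sequence[int],
    ppt_params: Mapping[str, float] | None = None,
    tem_params: Mapping[str, float] | None = None,
    sol_params: Mapping[str, float] | None = None,
    ndvi_coupling: float = 0.6,
    seed: int = 0,
    smooth_sigma: float = 5.0,
) -> list[ForcingStack]:
    """Generate one :class:`ForcingStack` per year.

    Each params mapping accepts ``mean``, ``sd`` (spatial noise sd),
    ``spatial_gradient`` (relative west-east tilt) and ``trend`` (per-year
    drift of the mean). NDVI is coupled to the same-year precipitation
    anomaly with weight ``ndvi_coupling``; the DEM, soil, and the spatial
    gradient pattern are shared across years.
    """
    years = list(years)
    if not years:
        raise InvalidParameterError("years must be non-empty")
    ppt_p = _require_params(ppt_params, mean=750.0, sd=120.0)
    tem_p = _require_params(tem_params, mean=12.0, sd=1.5)
    sol_p = _require_params(sol_params, mean=45.0, sd=3.0)
    if ppt_p["mean"] <= 0:
        raise InvalidParameterError("ppt mean must be > 0")

    rng = np.random.default_rng(seed)
    dem = generate_dem(spec, seed=int(rng.integers(2**31)))
    soil = generate_soil(spec, seed=int(rng.integers(2**31)))
    # standardized west-east gradient pattern, mean 0
    grad = np.linspace(-0.5, 0.5, spec.n_cols)[None, :] * np.ones(spec.shape)
    pop_field = _smooth_field(rng, spec.shape, smooth_sigma)
    gdp_field = _smooth_field(rng, spec.shape, smooth_sigma)

    stacks: list[ForcingStack] = []
    for i, year in enumerate(years):
        ppt_anom = _smooth_field(rng, spec.shape, smooth_sigma)
        ppt = (
            ppt_p["mean"]
            + ppt_p["trend"] * i
            + ppt_p["spatial_gradient"] * ppt_p["mean"] * grad
            + ppt_p["sd"] * ppt_anom
        )
        ppt = np.clip(ppt, 0.0, None)
        ppt_monthly = ppt[None, :, :] * MONTHLY_PPT_WEIGHTS[:, None, None]

        tem = (
            tem_p["mean"]
            + tem_p["trend"] * i
            + tem_p["spatial_gradient"] * abs(tem_p["mean"]) * grad
            + tem_p["sd"] * _smooth_field(rng, spec.shape, smooth_sigma)
        )
        sol_annual = np.clip(
            sol_p["mean"]
            + sol_p["trend"] * i
            + sol_p["spatial_gradient"] * sol_p["mean"] * grad
            + sol_p["sd"] * _smooth_field(rng, spec.shape, smooth_sigma),
            0.0,
            None,
        )
        sol = sol_annual[None, :, :] * MONTHLY_SOL_WEIGHTS[:, None, None]

        ppt_sd = ppt.std()
        ppt_z = (ppt - ppt.mean()) / ppt_sd if ppt_sd > 1e-12 else np.zeros(spec.shape)
        noise = _smooth_field(rng, spec.shape, smooth_sigma)
        ndvi = np.clip(
            0.5 + 0.22 * ndvi_coupling * ppt_z + 0.22 * (1.0 - abs(ndvi_coupling)) * noise,
            -1.0,
            1.0,
        )

        pop = np.exp(1.0 + 1.2 * pop_field) * (1.02**i)
        gdp = pop * 120.0 * np.exp(0.4 * gdp_field) * (1.08**i)

        stacks.append(
            ForcingStack(
                year=int(year),
                grid=spec,
                ppt=ppt,
                ppt_monthly=ppt_monthly,
                tem=tem,
                sol=sol,
                ndvi=ndvi,
                dem=dem,
                soil=soil,
                pop=pop,
                gdp=gdp,
            )
        )
    return stacks


def generate_zones(
    spec: GridSpec, n_zone_rows: int = 2, n_zone_cols: int = 2
) -> np.ndarray:
    """Block partition of the grid into n_zone_rows x n_zone_cols zones (ids 1..k)."""
    if n_zone_rows < 1 or n_zone_cols < 1:
        raise InvalidParameterError("zone grid must be at least 1x1")
    ri = np.minimum(
        (np.arange(spec.n_rows) * n_zone_rows) // spec.n_rows, n_zone_rows - 1
    )
    ci = np.minimum(
        (np.arange(spec.n_cols) * n_zone_cols) // spec.n_cols, n_zone_cols - 1
    )
    return (ri[:, None] * n_zone_cols + ci[None, :] + 1).astype(np.int32)


def hump_boundary(x: np.ndarray, x_star: float, y_star: float, width: float) -> np.ndarray:
    """Analytic hump boundary y* - ((x - x*)/width)^2."""
    return y_star - ((np.asarray(x, dtype=float) - x_star) / width) ** 2


def exponential_boundary(x: np.ndarray, k: float, b: float) -> np.ndarray:
    """Analytic exponential boundary b * k**x."""
    return b * np.power(k, np.asarray(x, dtype=float))


def generate_constrained_cloud(
    n: int,
    form: str,
    params: Mapping[str, float],
    noise_exponent: float = 3.0,
    x_range: tuple[float, float] = (0.0, 10.0),
    seed: int = 0,
    pair_label: str | None = None,
) -> ScatterCloud:
    """Scatter cloud whose true upper boundary is a known analytic curve.

    Points are drawn as ``y = f(x) * U**noise_exponent`` with
    ``U ~ Uniform(0, 1)``, so every point lies on or below the boundary
    ``f`` and the boundary is approached as n grows. ``form`` is ``hump``
    (params ``x_star``, ``y_star``, ``width``) or ``exponential``
    (params ``k``, ``b``).
    """
    if n < 100:
        raise InvalidParameterError(f"n must be >= 100, got {n}")
    if noise_exponent <= 0:
        raise InvalidParameterError("noise_exponent must be > 0")
    lo, hi = float(x_range[0]), float(x_range[1])
    if not hi > lo:
        raise InvalidParameterError(f"empty x_range {x_range}")

    rng = np.random.default_rng(seed)
    x = rng.uniform(lo, hi, size=n)

    if form == "hump":
        x_star, y_star = float(params["x_star"]), float(params["y_star"])
        width = float(params["width"])
        if width <= 0:
            raise InvalidParameterError(f"hump width must be > 0, got {width}")
        edge = min(hump_boundary(np.array([lo, hi]), x_star, y_star, width))
        if edge <= 0:
            raise InvalidParameterError(
                "hump boundary must stay positive over x_range; shrink x_range or widen the hump"
            )
        f = hump_boundary(x, x_star, y_star, width)
        truth = {"form": "hump", "x_star": x_star, "y_star": y_star, "width": width}
    elif form == "exponential":
        k, b = float(params["k"]), float(params["b"])
        if k <= 0:
            raise InvalidParameterError(f"exponential k must be > 0, got {k}")
        if b <= 0:
            raise InvalidParameterError(f"exponential b must be > 0, got {b}")
        f = exponential_boundary(x, k, b)
        truth = {"form": "exponential", "k": k, "b": b}
    else:
        raise InvalidParameterError(f"unknown cloud form {form!r}")

    u = rng.uniform(0.0, 1.0, size=n)
    y = f * u**noise_exponent
    return ScatterCloud(
        pair_label=pair_label or form,
        x=x,
        y=y,
        truth={**truth, "noise_exponent": noise_exponent, "x_range": (lo, hi)},
    )
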