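"""The four ecosystem-service models.

* NPP — light-use-efficiency (CASA-style) monthly product of absorbed
  radiation and realized efficiency, summed to an annual total.
* FP — zone-level grain totals allocated to cropland cells proportionally
  to NDVI, conserving each zone's total exactly.
* SC — RUSLE potential-minus-actual erosion with the usual factor
  closures (monthly erosivity R, EPIC erodibility K, slope-length LS,
  cover C, practice P).
* WY — annual Budyko-curve water balance: WY = (1 - AET/PPT) * PPT with
  the one-parameter evaporation curve and w = AWC*Z/PPT + 1.25.

All closures are parameterized through the dataclasses below so tests can
pin every constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np

from .errors import IncompleteForcingError, InvalidInputError
from .synthgen import CLASS_CODES, ForcingStack, LandUseMap, ZoneMap

logger = logging.getLogger(__name__)

__all__ = [
    "ESLayer",
    "CasaParams",
    "RusleParams",
    "RusleFactors",
    "WaterYieldParams",
    "monthly_npp",
    "compute_npp",
    "compute_fp",
    "compute_rusle_factors",
    "compute_sc",
    "compute_wy",
    "compute_all_services",
]

SERVICES = ("NPP", "FP", "SC", "WY")


@dataclass
class ESLayer:
    """One year's raster of one service. Units: t ha-1 (NPP/FP/SC), mm (WY)."""

    service: str
    year: int
    values: np.ndarray
    units: str


# ---------------------------------------------------------------------------
# NPP
# ---------------------------------------------------------------------------

#: Fixed phenology multipliers turning the annual NDVI surface into a
#: monthly one (peak growing season in summer).
PHENOLOGY_WEIGHTS = np.array(
    [0.30, 0.35, 0.50, 0.70, 0.90, 1.00, 1.00, 0.95, 0.80, 0.60, 0.40, 0.30]
)


def _default_eps_max() -> dict[int, float]:
    # g C MJ-1, per land-use class; zero over water/urban
    return {1: 0.56, 2: 0.69, 3: 0.54, 4: 0.0, 5: 0.0, 6: 0.30}


@dataclass
class CasaParams:
    ndvi_min: float = 0.05
    ndvi_max: float = 0.95
    fpar_max: float = 0.95
    eps_max: dict[int, float] = dc_field(default_factory=_default_eps_max)
    topt: float = 20.0
    t_sens: float = 0.003
    water_stress_min: float = 0.5
    ppt_ref: float = 800.0


def monthly_npp(apar: np.ndarray | float, eps: np.ndarray | float) -> np.ndarray | float:
    """One month's NPP in g C m-2: APAR (MJ m-2) times efficiency (g C MJ-1)."""
    return np.asarray(apar) * np.asarray(eps)


def _class_lookup(table: dict[int, float], classes: np.ndarray) -> np.ndarray:
    lut = np.zeros(max(CLASS_CODES.values()) + 1)
    for code, v in table.items():
        lut[code] = v
    return lut[classes]


def compute_npp(
    forcing: ForcingStack, landuse: LandUseMap, params: CasaParams | None = None
) -> ESLayer:
    """Annual NPP (t ha-1) from monthly solar radiation and NDVI phenology.

    FPAR is linear in NDVI between ``ndvi_min`` and ``ndvi_max`` (capped at
    ``fpar_max``) and forced to zero on water/urban cells; APAR = SOL *
    FPAR * 0.5; efficiency is eps_max(class) scaled by temperature and
    water stress. Annual g C m-2 converts to t ha-1 by the factor 0.01.
    """
    params = params or CasaParams()
    if forcing.sol.ndim != 3 or forcing.sol.shape[0] != 12:
        raise IncompleteForcingError(
            f"solar radiation must have 12 monthly bands, got shape {forcing.sol.shape}"
        )
    classes = landuse.classes
    eps_max = _class_lookup(params.eps_max, classes)
    t_stress = np.clip(1.0 - params.t_sens * (forcing.tem - params.topt) ** 2, 0.0, 1.0)
    w_stress = params.water_stress_min + (1.0 - params.water_stress_min) * np.clip(
        forcing.ppt / params.ppt_ref, 0.0, 1.0
    )
    eps = eps_max * t_stress * w_stress

    vegetated = ~(landuse.mask("water") | landuse.mask("urban"))
    npp_g = np.zeros(landuse.grid.shape)
    for m in range(12):
        ndvi_m = np.clip(forcing.ndvi * PHENOLOGY_WEIGHTS[m], -1.0, 1.0)
        fpar = np.clip(
            (ndvi_m - params.ndvi_min) / (params.ndvi_max - params.ndvi_min), 0.0, 1.0
        ) * params.fpar_max
        fpar = np.where(vegetated, fpar, 0.0)
        apar = forcing.sol[m] * fpar * 0.5
        npp_g += monthly_npp(apar, eps)
    return ESLayer("NPP", forcing.year, npp_g * 0.01, "t ha-1")


# ---------------------------------------------------------------------------
# FP
# ---------------------------------------------------------------------------


def compute_fp(
    ndvi: np.ndarray,
    landuse: LandUseMap,
    zones: ZoneMap,
    year: int = 0,
    per_hectare: bool = False,
) -> ESLayer:
    """Allocate each zone's grain total to its cropland cells by NDVI share.

    FP_i = NDVI_i / sum(NDVI over cropland in zone) * Gsum(zone); zero off
    cropland. With ``per_hectare=False`` values are tonnes per cell so each
    zone's allocation sums exactly to Gsum; with ``per_hectare=True`` they
    are divided by the cell area in hectares.
    """
    cropland = landuse.mask("cropland")
    ndvi_pos = np.where(cropland & (ndvi > 0), ndvi, 0.0)
    fp = np.zeros(landuse.grid.shape)
    for zone_id, gsum in zones.yield_table.items():
        zmask = zones.zones == zone_id
        s = ndvi_pos[zmask].sum()
        if s <= 0:
            logger.warning("zone %s has no cropland NDVI; FP set to 0 there", zone_id)
            continue
        fp[zmask] = ndvi_pos[zmask] / s * gsum
    if per_hectare:
        return ESLayer("FP", year, fp / landuse.grid.cell_area_ha, "t ha-1")
    return ESLayer("FP", year, fp, "t")


# ---------------------------------------------------------------------------
# SC (RUSLE)
# ---------------------------------------------------------------------------


def _default_p_table() -> dict[int, float]:
    return {1: 0.35, 2: 1.0, 3: 1.0, 4: 0.0, 5: 0.0, 6: 1.0}


@dataclass
class RusleParams:
    c_floor: float = 0.01  # C at full vegetation cover
    ndvi_soil: float = 0.05
    ndvi_veg: float = 0.90
    p_table: dict[int, float] = dc_field(default_factory=_default_p_table)
    k_si: float = 0.1317  # US-customary K -> SI conversion
    ls_ref_length: float = 22.13  # m


@dataclass
class RusleFactors:
    R: np.ndarray
    K: np.ndarray
    LS: np.ndarray
    C: np.ndarray
    P: np.ndarray


def rainfall_erosivity(ppt_monthly: np.ndarray) -> np.ndarray:
    """Monthly Wischmeier erosivity: R = sum 1.735 * 10^(1.5 log10(p^2/P) - 0.8188)."""
    p = np.asarray(ppt_monthly, dtype=float)
    annual = p.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where((annual > 0) & (p > 0), p**2 / annual, np.nan)
        terms = 1.735 * 10 ** (1.5 * np.log10(ratio) - 0.8188)
    return np.nansum(np.where(np.isfinite(terms), terms, 0.0), axis=0)


def epic_erodibility(
    sand: np.ndarray, silt: np.ndarray, clay: np.ndarray, oc: np.ndarray, k_si: float = 0.1317
) -> np.ndarray:
    """EPIC soil-erodibility closure from texture percentages and organic carbon."""
    san, sil, cla, c = (np.asarray(a, dtype=float) for a in (sand, silt, clay, oc))
    sn1 = 1.0 - san / 100.0
    k = (
        (0.2 + 0.3 * np.exp(-0.0256 * san * (1.0 - sil / 100.0)))
        * (sil / np.clip(cla + sil, 1e-9, None)) ** 0.3
        * (1.0 - 0.25 * c / (c + np.exp(3.72 - 2.95 * c)))
        * (1.0 - 0.7 * sn1 / (sn1 + np.exp(-5.51 + 22.9 * sn1)))
    )
    return k_si * k


def slope_from_dem(dem: np.ndarray, cell_size: float) -> np.ndarray:
    """Maximum downslope gradient (rise/run) to the 8 neighbours."""
    dem = np.asarray(dem, dtype=float)
    padded = np.pad(dem, 1, mode="edge")
    best = np.zeros_like(dem)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            nb = padded[1 + dr : 1 + dr + dem.shape[0], 1 + dc : 1 + dc + dem.shape[1]]
            dist = cell_size * np.hypot(dr, dc)
            best = np.maximum(best, (dem - nb) / dist)
    return np.clip(best, 0.0, None)


def ls_factor(dem: np.ndarray, cell_size: float, ref_length: float = 22.13) -> np.ndarray:
    """RUSLE LS from slope: L = (lambda/22.13)^m with m = beta/(1+beta), McCool S."""
    grad = slope_from_dem(dem, cell_size)
    theta = np.arctan(grad)
    sin_t = np.sin(theta)
    beta = (sin_t / 0.0896) / (3.0 * sin_t**0.8 + 0.56)
    m = beta / (1.0 + beta)
    length = (cell_size / ref_length) ** m
    steep = np.where(grad < 0.09, 10.8 * sin_t + 0.03, 16.8 * sin_t - 0.5)
    ls = length * steep
    if np.all(grad == 0):
        logger.info("flat DEM: LS at its minimum value everywhere")
    return ls


def compute_rusle_factors(
    forcing: ForcingStack,
    landuse: LandUseMap,
    dem: np.ndarray | None = None,
    soil: dict[str, np.ndarray] | None = None,
    params: RusleParams | None = None,
) -> RusleFactors:
    """All five RUSLE factor rasters for one year."""
    params = params or RusleParams()
    dem = forcing.dem if dem is None else dem
    soil = forcing.soil if soil is None else soil
    r = rainfall_erosivity(forcing.ppt_monthly)
    k = epic_erodibility(soil["sand"], soil["silt"], soil["clay"], soil["oc"], params.k_si)
    ls = ls_factor(dem, landuse.grid.cell_size, params.ls_ref_length)
    fc = np.clip(
        (forcing.ndvi - params.ndvi_soil) / (params.ndvi_veg - params.ndvi_soil), 0.0, 1.0
    )
    c = params.c_floor**fc  # 1 at bare soil, c_floor at full cover
    p = _class_lookup(params.p_table, landuse.classes)
    return RusleFactors(R=r, K=k, LS=ls, C=c, P=p)


def compute_sc(factors: RusleFactors, year: int = 0) -> ESLayer:
    """Soil conservation = potential minus actual erosion: R*K*LS*(1 - C*P)."""
    for name in ("R", "K", "LS", "C", "P"):
        arr = getattr(factors, name)
        if np.any(np.asarray(arr) < 0):
            raise InvalidInputError(f"RUSLE factor {name} contains negative values")
    for name in ("C", "P"):
        if np.any(np.asarray(getattr(factors, name)) > 1):
            raise InvalidInputError(f"RUSLE factor {name} exceeds 1")
    ap = factors.R * factors.K * factors.LS
    sc = ap * (1.0 - factors.C * factors.P)
    return ESLayer("SC", year, sc, "t ha-1")


# ---------------------------------------------------------------------------
# WY (Budyko)
# ---------------------------------------------------------------------------


def _default_kc_table() -> dict[int, float]:
    return {1: 0.65, 2: 1.0, 3: 0.65, 4: 1.0, 5: 0.30, 6: 0.20}


@dataclass
class WaterYieldParams:
    kc_table: dict[int, float] = dc_field(default_factory=_default_kc_table)
    z: float = 7.5  # seasonal constant
    awc: np.ndarray | None = None  # mm; estimated from soil if absent
    et0: np.ndarray | None = None  # mm yr-1; estimated from tem/sol if absent
    root_depth_mm: float = 1000.0

    def __post_init__(self) -> None:
        if self.z <= 0:
            raise InvalidInputError(f"Z must be > 0, got {self.z}")
        if any(v < 0 for v in self.kc_table.values()):
            raise InvalidInputError("Kc values must be >= 0")


def estimate_et0(tem: np.ndarray, sol: np.ndarray) -> np.ndarray:
    """Annual reference ET (mm) by an Oudin-style radiation-temperature rule.

    Monthly ET0 = SOL_m * (TEM + 5) / 24.5, floored at zero; SOL_m in
    MJ m-2 mo-1, TEM in degrees C.
    """
    monthly = np.clip(
        np.asarray(sol) * (np.asarray(tem)[None, :, :] + 5.0) / 24.5, 0.0, None
    )
    return monthly.sum(axis=0)


def estimate_awc(soil: dict[str, np.ndarray], root_depth_mm: float = 1000.0) -> np.ndarray:
    """Available water capacity (mm) from a simple texture pedotransfer rule."""
    frac = np.clip(
        0.05 + 0.0015 * soil["clay"] + 0.0009 * soil["silt"] + 0.01 * soil["oc"], 0.02, 0.30
    )
    return frac * root_depth_mm


def budyko_aet_ratio(pet_over_ppt: np.ndarray, w: np.ndarray) -> np.ndarray:
    """One-parameter evaporation curve: AET/PPT = 1 + r - (1 + r^w)^(1/w)."""
    r = np.asarray(pet_over_ppt, dtype=float)
    w = np.asarray(w, dtype=float)
    return 1.0 + r - (1.0 + r**w) ** (1.0 / w)


def compute_wy(
    forcing: ForcingStack, landuse: LandUseMap, params: WaterYieldParams | None = None
) -> ESLayer:
    """Annual water yield (mm): WY = (1 - AET/PPT) * PPT, clipped to [0, PPT].

    Cells with PPT = 0 yield 0 by convention (logged).
    """
    params = params or WaterYieldParams()
    et0 = params.et0 if params.et0 is not None else estimate_et0(forcing.tem, forcing.sol)
    awc = (
        params.awc
        if params.awc is not None
        else estimate_awc(forcing.soil, params.root_depth_mm)
    )
    kc = _class_lookup(params.kc_table, landuse.classes)
    pet = kc * et0

    ppt = forcing.ppt
    wet = ppt > 0
    if not wet.all():
        logger.info("%d cells with PPT = 0: WY set to 0 there", int((~wet).sum()))
    safe_ppt = np.where(wet, ppt, np.nan)
    w = awc * params.z / safe_ppt + 1.25
    aet_ratio = budyko_aet_ratio(pet / safe_ppt, w)
    wy = np.where(wet, (1.0 - aet_ratio) * safe_ppt, 0.0)
    wy = np.clip(np.nan_to_num(wy, nan=0.0), 0.0, np.where(wet, ppt, 0.0))
    return ESLayer("WY", forcing.year, wy, "mm")


# ---------------------------------------------------------------------------
# convenience
# ---------------------------------------------------------------------------


def compute_all_services(
    forcing: ForcingStack,
    landuse: LandUseMap,
    zones: ZoneMap,
    casa: CasaParams | None = None,
    rusle: RusleParams | None = None,
    wy_params: WaterYieldParams | None = None,
) -> dict[str, ESLayer]:
    """All four ES layers for one year, keyed by service name."""
    factors = compute_rusle_factors(forcing, landuse, params=rusle)
    return {
        "NPP": compute_npp(forcing, landuse, casa),
        "FP": compute_fp(forcing.ndvi, landuse, zones, year=forcing.year, per_hectare=True),
        "SC": compute_sc(factors, year=forcing.year),
        "WY": compute_wy(forcing, landuse, wy_params),
    }
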