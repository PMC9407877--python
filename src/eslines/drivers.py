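"""Driver attribution of characteristic-value change.

A documented stand-in for proprietary "automatic linear modelling":
standardize the year-by-driver matrix, forward-stepwise selection by
AICc with a VIF collinearity guard and a cap on retained terms, then a
Shapley (averaged-over-orderings sequential sum of squares) decomposition
of explained variance normalized to 1, and accuracy = adjusted R2 * 100
floored at 0. The interaction model adds all socioeconomic x
landscape-configuration products to the candidate set and reports the
selected interactions separately.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .errors import AlignmentError, InsufficientDataError
from .dynamics import FeatureSeries, significance_flag
from .synthgen import CLASS_CODES, ForcingStack

logger = logging.getLogger(__name__)

__all__ = [
    "DriverMatrix",
    "AttributionResult",
    "SelectionConfig",
    "build_driver_matrix",
    "fit_model0",
    "fit_model1",
]

SOCIO_TERMS = ("GDP", "POP")
CONFIG_TERMS = ("PAFRAC", "LSI", "CONTAG", "SHDI", "PD")

#: Column order of the assembled matrix: climate, vegetation, six
#: composition shares, five configuration metrics, two socioeconomic.
DRIVER_COLUMNS = (
    ("PPT", "TEM", "NDVI")
    + tuple(f"AREA_{name.upper()}" for name in CLASS_CODES)
    + CONFIG_TERMS
    + SOCIO_TERMS
)


@dataclass
class DriverMatrix:
    """Standardized year-by-driver table plus back-transformation parameters."""

    data: pd.DataFrame  # standardized, indexed by year
    means: pd.Series
    sds: pd.Series
    dropped: list[str]

    @property
    def years(self) -> np.ndarray:
        return self.data.index.to_numpy()


@dataclass
class TermResult:
    term: str
    coefficient: float
    p_value: float
    flag: str
    importance: float
    is_interaction: bool


@dataclass
class AttributionResult:
    response: str
    model_id: int
    terms: list[TermResult]
    accuracy: float  # adjusted R2 * 100, floored at 0

    @property
    def term_names(self) -> list[str]:
        return [t.term for t in self.terms]

    def importances(self) -> dict[str, float]:
        return {t.term: t.importance for t in self.terms}


def build_driver_matrix(
    forcings: list[ForcingStack],
    metrics_rows: list[dict] | pd.DataFrame,
) -> DriverMatrix:
    """Assemble and standardize the year-by-driver matrix.

    Climate/NDVI/population/GDP enter as annual spatial means; composition
    and configuration come from the landscape-metrics rows (as produced by
    :func:`eslines.landmetrics.metrics_to_row`). Years must match across
    sources; near-constant columns are excluded with a log entry.
    """
    met = pd.DataFrame(metrics_rows) if not isinstance(metrics_rows, pd.DataFrame) else metrics_rows
    met = met.set_index(met["year"].astype(int))
    f_years = sorted(f.year for f in forcings)
    m_years = sorted(met.index)
    if f_years != m_years:
        missing = sorted(set(f_years).symmetric_difference(m_years))
        raise AlignmentError(f"forcing and metrics years differ; unmatched: {missing}")

    rows = {}
    for f in sorted(forcings, key=lambda s: s.year):
        m = met.loc[f.year]
        row = {
            "PPT": float(f.ppt.mean()),
            "TEM": float(f.tem.mean()),
            "NDVI": float(f.ndvi.mean()),
            "GDP": float(f.gdp.mean()),
            "POP": float(f.pop.mean()),
        }
        for name in CLASS_CODES:
            row[f"AREA_{name.upper()}"] = float(m[f"{name}_pct"])
        for metric in CONFIG_TERMS:
            row[metric] = float(m[metric.lower()]) if pd.notna(m[metric.lower()]) else np.nan
        rows[f.year] = row
    raw = pd.DataFrame.from_dict(rows, orient="index")[list(DRIVER_COLUMNS)]
    raw.index.name = "year"

    means = raw.mean()
    sds = raw.std(ddof=1)
    dropped = [c for c in raw.columns if not np.isfinite(sds[c]) or sds[c] < 1e-12]
    if dropped:
        logger.info("dropping near-constant/undefined driver columns: %s", dropped)
    kept = [c for c in raw.columns if c not in dropped]
    z = (raw[kept] - means[kept]) / sds[kept]
    return DriverMatrix(data=z, means=means[kept], sds=sds[kept], dropped=dropped)


@dataclass
class SelectionConfig:
    max_terms: int = 6
    vif_cap: float = 10.0
    min_aicc_drop: float = 6.0  # required AICc improvement for a term to enter


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Coefficients (with intercept prepended) and residual sum of squares."""
    design = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return beta, float(resid @ resid)


def _aicc(n: int, rss: float, n_params: int) -> float:
    # n_params counts intercept + slopes; +1 for the error variance
    k = n_params + 1
    if n - k - 1 <= 0:
        return np.inf
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _vif_ok(X: np.ndarray, cap: float) -> bool:
    """True if no column of X (>=2 cols) exceeds the VIF cap."""
    if X.shape[1] < 2:
        return True
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        _, rss = _ols(X[:, j], others)
        tss = float(((X[:, j] - X[:, j].mean()) ** 2).sum())
        if tss <= 0:
            return False
        r2 = 1.0 - rss / tss
        if r2 >= 1.0 - 1.0 / cap:  # VIF = 1/(1-R2) > cap
            return False
    return True


def _r2_of(y: np.ndarray, X: np.ndarray) -> float:
    _, rss = _ols(y, X)
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - rss / tss if tss > 0 else 0.0


def _shapley_importance(y: np.ndarray, X: pd.DataFrame) -> dict[str, float]:
    """Share of explained variance per term, averaged over entry orderings.

    Exact enumeration over subsets (term counts are capped small), then
    normalized to sum to 1.
    """
    terms = list(X.columns)
    p = len(terms)
    r2_cache: dict[frozenset, float] = {frozenset(): 0.0}
    for r in range(1, p + 1):
        for sub in itertools.combinations(terms, r):
            r2_cache[frozenset(sub)] = _r2_of(y, X[list(sub)].to_numpy())
    import math

    contrib = dict.fromkeys(terms, 0.0)
    for t in terms:
        rest = [u for u in terms if u != t]
        for r in range(0, p):
            weight = math.factorial(r) * math.factorial(p - r - 1) / math.factorial(p)
            for sub in itertools.combinations(rest, r):
                s = frozenset(sub)
                contrib[t] += weight * (r2_cache[s | {t}] - r2_cache[s])
    total = sum(contrib.values())
    if total <= 0:
        return dict.fromkeys(terms, 1.0 / p)
    return {t: max(v, 0.0) / total for t, v in contrib.items()}


def _renormalize(imp: dict[str, float]) -> dict[str, float]:
    s = sum(imp.values())
    return {k: v / s for k, v in imp.items()} if s > 0 else imp


def _forward_stepwise(
    y: np.ndarray, X: pd.DataFrame, config: SelectionConfig
) -> list[str]:
    n = len(y)
    selected: list[str] = []
    best_aicc = _aicc(n, float(((y - y.mean()) ** 2).sum()), 1)
    while len(selected) < config.max_terms:
        # perfect fit: nothing left to explain
        if selected and _r2_of(y, X[selected].to_numpy()) > 1.0 - 1e-12:
            break
        best_term, best_candidate_aicc = None, best_aicc
        for term in X.columns:
            if term in selected:
                continue
            cols = selected + [term]
            Xc = X[cols].to_numpy()
            if not _vif_ok(Xc, config.vif_cap):
                logger.debug("VIF guard skips %s", term)
                continue
            _, rss = _ols(y, Xc)
            a = _aicc(n, rss, len(cols) + 1)
            if a < best_candidate_aicc - 1e-12:
                best_term, best_candidate_aicc = term, a
        if best_term is None or best_aicc - best_candidate_aicc < config.min_aicc_drop:
            break
        selected.append(best_term)
        best_aicc = best_candidate_aicc
    return selected


def _fit(
    response_name: str,
    y_series: FeatureSeries,
    X: pd.DataFrame,
    model_id: int,
    interaction_terms: set[str],
    config: SelectionConfig,
) -> AttributionResult:
    y_map = y_series.values
    years = [int(t) for t in X.index if int(t) in y_map]
    if len(years) < 8:
        raise InsufficientDataError(f"need >= 8 usable years, got {len(years)}")
    if len(years) < len(X.index):
        logger.info(
            "%s: %d of %d years usable", response_name, len(years), len(X.index)
        )
    X = X.loc[years]
    y_raw = np.array([y_map[t] for t in years], dtype=float)
    sd = y_raw.std(ddof=1)
    if sd < 1e-12:
        logger.warning("constant response %s: empty model", response_name)
        return AttributionResult(response_name, model_id, [], 0.0)
    y = (y_raw - y_raw.mean()) / sd

    selected = _forward_stepwise(y, X, config)
    if not selected:
        logger.warning("no term passed selection for %s", response_name)
        return AttributionResult(response_name, model_id, [], 0.0)

    Xs = X[selected]
    beta, rss = _ols(y, Xs.to_numpy())
    n, k = len(y), len(selected)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss
    adj = 1.0 - (1.0 - r2) * (n - 1) / max(n - k - 1, 1)
    accuracy = float(np.clip(adj * 100.0, 0.0, 100.0))

    # coefficient t-tests on the final model
    dof = max(n - k - 1, 1)
    sigma2 = rss / dof
    design = np.column_stack([np.ones(n), Xs.to_numpy()])
    cov = sigma2 * np.linalg.pinv(design.T @ design)
    se = np.sqrt(np.clip(np.diag(cov), 1e-300, None))
    from scipy import stats as sps

    tvals = beta / se
    pvals = 2.0 * sps.t.sf(np.abs(tvals), dof)

    importance = _renormalize(_shapley_importance(y, Xs))
    terms = [
        TermResult(
            term=t,
            coefficient=float(beta[i + 1]),
            p_value=float(pvals[i + 1]),
            flag=significance_flag(float(pvals[i + 1])),
            importance=float(importance[t]),
            is_interaction=t in interaction_terms,
        )
        for i, t in enumerate(selected)
    ]
    return AttributionResult(response_name, model_id, terms, accuracy)


def fit_model0(
    y: FeatureSeries,
    X: DriverMatrix,
    config: SelectionConfig | None = None,
) -> AttributionResult:
    """Main-effects attribution: stepwise OLS of the standardized response
    on the standardized driver columns."""
    config = config or SelectionConfig()
    name = f"{y.pair_label}:{y.feature}"
    return _fit(name, y, X.data, model_id=0, interaction_terms=set(), config=config)


def fit_model1(
    y: FeatureSeries,
    X: DriverMatrix,
    config: SelectionConfig | None = None,
    socio_terms: tuple[str, ...] = SOCIO_TERMS,
    config_terms: tuple[str, ...] = CONFIG_TERMS,
) -> AttributionResult:
    """Attribution with socioeconomic x landscape-configuration interactions.

    Candidate set = all main effects plus every socio x configuration
    product of standardized columns (products re-standardized); selection,
    importance and accuracy rules are those of the main-effects model.
    """
    config = config or SelectionConfig()
    data = X.data.copy()
    interactions: set[str] = set()
    for s in socio_terms:
        for c in config_terms:
            if s not in data.columns or c not in data.columns:
                continue
            name = f"{s}x{c}"
            prod = data[s] * data[c]
            psd = prod.std(ddof=1)
            if psd < 1e-12:
                continue
            data[name] = (prod - prod.mean()) / psd
            interactions.add(name)
    name = f"{y.pair_label}:{y.feature}"
    return _fit(name, y, data, model_id=1, interaction_terms=interactions, config=config)


def attribution_to_rows(result: AttributionResult) -> list[dict]:
    """Flatten an AttributionResult for the attribution CSV."""
    if not result.terms:
        return [
            {
                "response": result.response,
                "model": result.model_id,
                "term": None,
                "coefficient": None,
                "star": None,
                "importance": None,
                "interaction": None,
                "accuracy": result.accuracy,
            }
        ]
    return [
        {
            "response": result.response,
            "model": result.model_id,
            "term": t.term,
            "coefficient": t.coefficient,
            "star": t.flag,
            "importance": t.importance,
            "interaction": t.is_interaction,
            "accuracy": result.accuracy,
        }
        for t in result.terms
    ]
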