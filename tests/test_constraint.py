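import numpy as np
import pytest

from eslines.constraint import (
    BoundaryPointSet,
    PairConfig,
    build_cloud,
    extract_boundary,
    fit_constraint,
    run_pairs,
)
from eslines.errors import (
    FormMismatchError,
    InsufficientDataError,
    InvalidInputError,
)
from eslines.esmodels import ESLayer
from eslines.grids import GridSpec
from eslines.synthgen import ScatterCloud, generate_constrained_cloud


def points_on(x: np.ndarray, y: np.ndarray, pair="T_T") -> BoundaryPointSet:
    return BoundaryPointSet(
        pair_label=pair,
        bin_edges=np.array([]),
        x_mid=np.asarray(x, dtype=float),
        y_q=np.asarray(y, dtype=float),
        quantile=0.99,
        min_points=1,
        bins_dropped=0,
    )


class TestExtractBoundary:
    def test_degenerate_cloud_boundary_is_the_cloud(self):
        x = np.linspace(0, 10, 2000)
        cloud = ScatterCloud("Y_X", x, x.copy())
        bps = extract_boundary(cloud, n_bins=10, quantile=0.999, min_points=10)
        spacing = 10.0 / 10  # one within-bin x spacing
        assert np.all(np.abs(bps.y_q - bps.x_mid) <= spacing)

    def test_hump_cloud_peak_recovered(self):
        cloud = generate_constrained_cloud(
            10_000, "hump", {"x_star": 5.0, "y_star": 10.0, "width": 1.0},
            x_range=(2.0, 8.0), seed=0,
        )
        bps = extract_boundary(cloud, n_bins=50, quantile=0.99, min_points=10)
        assert 9.5 <= bps.y_q.max() <= 10.0

    def test_gapped_cloud_drops_bins(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.uniform(0, 3, 3000), rng.uniform(7, 10, 3000)])
        cloud = ScatterCloud("A_B", x, rng.uniform(0, 1, x.size))
        bps = extract_boundary(cloud, n_bins=20, quantile=0.99, min_points=10)
        assert bps.bins_dropped >= 1
        assert len(bps) + bps.bins_dropped == 20

    def test_too_few_bins_retained(self):
        rng = np.random.default_rng(2)
        cloud = ScatterCloud("A_B", rng.uniform(0, 1, 30), rng.uniform(0, 1, 30))
        with pytest.raises(InsufficientDataError):
            extract_boundary(cloud, n_bins=50, quantile=0.99, min_points=10)

    def test_x_mid_strictly_increasing(self):
        cloud = generate_constrained_cloud(
            5000, "hump", {"x_star": 5.0, "y_star": 10.0, "width": 1.0},
            x_range=(2.0, 8.0), seed=3,
        )
        bps = extract_boundary(cloud, 30, 0.99, 10)
        assert (np.diff(bps.x_mid) > 0).all()


class TestFitConstraint:
    def test_exact_quadratic_recovery(self):
        x = np.linspace(2, 8, 20)
        curve = fit_constraint(points_on(x, 10 - (x - 5) ** 2), form="hump")
        assert curve.threshold_x == pytest.approx(5.0, abs=1e-9)
        assert curve.threshold_y == pytest.approx(10.0, abs=1e-9)
        assert curve.r2 == pytest.approx(1.0)

    def test_exact_exponential_recovery(self):
        x = np.linspace(0, 3000, 40)
        curve = fit_constraint(points_on(x, 8.0 * 0.9995**x), form="exponential")
        assert curve.k == pytest.approx(0.9995, abs=1e-6)
        assert curve.b == pytest.approx(8.0, abs=1e-6)
        assert curve.r2 == pytest.approx(1.0)

    def test_exponential_b_is_value_at_zero(self):
        x = np.linspace(0, 100, 10)
        curve = fit_constraint(points_on(x, 6.5 * 0.999**x), form="exponential")
        assert curve.predict(np.array([0.0]))[0] == pytest.approx(curve.b)

    def test_hump_recovery_through_pipeline(self):
        cloud = generate_constrained_cloud(
            10_000, "hump", {"x_star": 5.0, "y_star": 10.0, "width": 1.0},
            x_range=(2.0, 8.0), seed=42,
        )
        bps = extract_boundary(cloud, 50, 0.99, 10)
        curve = fit_constraint(bps, form="hump")
        assert abs(curve.threshold_x - 5.0) <= 0.25

    def test_upward_quadratic_rejected(self):
        x = np.linspace(0, 10, 20)
        with pytest.raises(FormMismatchError, match="hump"):
            fit_constraint(points_on(x, (x - 5) ** 2), form="hump")

    def test_flat_quadratic_rejected(self):
        x = np.linspace(0, 10, 20)
        with pytest.raises(FormMismatchError):
            fit_constraint(points_on(x, 2 * x + 1), form="hump")

    def test_nonpositive_y_rejected_for_exponential(self):
        x = np.linspace(0, 10, 20)
        with pytest.raises(InvalidInputError):
            fit_constraint(points_on(x, x - 5.0), form="exponential")

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_constraint(points_on([1, 2, 3], [1, 2, 3]), form="hump")

    def test_auto_prefers_better_form(self):
        x = np.linspace(2, 8, 30)
        hump = fit_constraint(points_on(x, 10 - (x - 5) ** 2), form="auto")
        assert hump.form == "hump"
        xe = np.linspace(0, 3000, 30)
        expo = fit_constraint(points_on(xe, 8 * 0.999**xe), form="auto")
        assert expo.form == "exponential"

    def test_vertex_ratio_invariant_to_x_rescale(self):
        x = np.linspace(2, 8, 30)
        y = 10 - (x - 5) ** 2 + 0.05 * np.sin(x)
        c1 = fit_constraint(points_on(x, y), form="hump")
        c2 = fit_constraint(points_on(10 * x, y), form="hump")
        assert c2.threshold_x / 10 == pytest.approx(c1.threshold_x, rel=1e-9)
        assert c2.r2 == pytest.approx(c1.r2, rel=1e-9)

    def test_boundary_dominance_of_fitted_curve(self):
        q = 0.99
        cloud = generate_constrained_cloud(
            20_000, "hump", {"x_star": 5.0, "y_star": 10.0, "width": 1.0},
            noise_exponent=2.0, x_range=(2.0, 8.0), seed=11,
        )
        curve = fit_constraint(extract_boundary(cloud, 50, q, 10), form="hump")
        frac_below = np.mean(cloud.y <= curve.predict(cloud.x) + 1e-9)
        assert frac_below >= q - 0.02


def layers_from_cloud(seed: int, x_star: float = 4.0) -> dict[str, ESLayer]:
    """Two co-registered rasters whose scatter has a known hump boundary."""
    n = 80
    cloud = generate_constrained_cloud(
        n * n, "hump", {"x_star": x_star, "y_star": 10.0, "width": 2.5},
        x_range=(1.0, 7.0), seed=seed,
    )
    return {
        "NPP": ESLayer("NPP", 2000, cloud.x.reshape(n, n), "t ha-1"),
        "WY": ESLayer("WY", 2000, cloud.y.reshape(n, n), "mm"),
    }


class TestRunPairs:
    def test_cardinality_and_determinism(self):
        layers = layers_from_cloud(seed=5)
        es = {2000: layers, 2001: layers}
        cfg = PairConfig(n_bins=30, min_points=5, sample_n=4000)
        df = run_pairs(es, pairs=("NPP_WY",), config=cfg, seed=9)
        assert len(df) == 2
        ok = df[df["status"] == "ok"]
        assert len(ok) == 2
        # identical layers + per-year seeding from the same stream layout
        df2 = run_pairs(es, pairs=("NPP_WY",), config=cfg, seed=9)
        assert df.equals(df2)

    def test_moved_peak_moves_threshold(self):
        es = {
            2000: layers_from_cloud(seed=1, x_star=4.0),
            2001: layers_from_cloud(seed=1, x_star=6.0),
        }
        df = run_pairs(es, pairs=("NPP_WY",), config=PairConfig(n_bins=30, min_points=5), seed=0)
        tx = df.set_index("year")["threshold_x"]
        assert tx[2001] > tx[2000]

    def test_insufficient_pair_recorded_missing(self):
        g = GridSpec(3, 3)
        tiny = {
            "NPP": ESLayer("NPP", 2000, np.random.default_rng(0).uniform(0, 1, g.shape), "t ha-1"),
            "WY": ESLayer("WY", 2000, np.random.default_rng(1).uniform(0, 1, g.shape), "mm"),
        }
        df = run_pairs({2000: tiny}, pairs=("NPP_WY",), seed=0)
        assert (df["status"] == "missing").all()

    def test_fp_pair_requires_landuse(self):
        layers = layers_from_cloud(seed=2)
        layers["FP"] = ESLayer("FP", 2000, layers["NPP"].values, "t ha-1")
        df = run_pairs({2000: layers}, pairs=("FP_WY",), seed=0)
        assert (df["status"] == "missing").all()

    def test_fp_pair_uses_cropland_mask(self):
        from conftest import make_landuse

        layers = layers_from_cloud(seed=3)
        layers["FP"] = ESLayer("FP", 2000, layers["NPP"].values, "t ha-1")
        g = GridSpec(80, 80)
        classes = np.ones(g.shape, dtype=np.int16)
        classes[40:, :] = 2  # half the grid is not cropland
        lu = make_landuse(g, classes)
        cloud = build_cloud(layers, "FP_WY", landuse=lu, sample_n=10**9)
        assert len(cloud) == 40 * 80
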