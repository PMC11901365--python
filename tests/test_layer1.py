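import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from abtriage.errors import (
    DegenerateEllipse,
    DegenerateKernel,
    DimensionMismatch,
    EmptyGroup,
    InsufficientReference,
)
from abtriage.layer1 import (
    KPCAConfig,
    capture_rates,
    ellipse_from_reference,
    fit_kpca,
    gate,
    layer1_select,
    make_ellipse,
    point_in_ellipse,
    project,
)
from abtriage.synthetic_fixtures import EmbeddingCloudSpec, generate_embedding_clouds


def dense_kpca_oracle(X, gamma, n_components=2):
    """Independent eigendecomposition of the double-centered rbf kernel."""
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    K = np.exp(-gamma * sq)
    n = len(X)
    H = np.eye(n) - np.ones((n, n)) / n
    Kc = H @ K @ H
    w, v = np.linalg.eigh(Kc)
    idx = np.argsort(w)[::-1][:n_components]
    return v[:, idx] * np.sqrt(np.maximum(w[idx], 0.0))


class TestFitKpca:
    def test_matches_dense_oracle(self, rng):
        for shape in [(10, 5), (30, 8), (50, 20)]:
            X = rng.normal(size=shape)
            gamma = 0.5 / shape[1]
            model = fit_kpca(X, KPCAConfig(gamma=gamma))
            oracle = dense_kpca_oracle(X, gamma)
            for j in range(2):
                col = model.training_projections[:, j]
                ref = oracle[:, j]
                assert (np.allclose(col, ref, atol=1e-8)
                        or np.allclose(col, -ref, atol=1e-8))

    def test_duplicate_points_identical_projections(self, rng):
        X = rng.normal(size=(6, 4))
        X = np.vstack([X, X[0]])
        model = fit_kpca(X, KPCAConfig(gamma=0.3))
        np.testing.assert_allclose(model.training_projections[0],
                                   model.training_projections[-1], atol=1e-8)

    def test_gamma_to_zero_degenerate(self, rng):
        X = rng.normal(size=(8, 3))
        with pytest.raises(DegenerateKernel):
            fit_kpca(X, KPCAConfig(gamma=1e-15))

    def test_eigenvalues_sorted_nonnegative(self, rng):
        model = fit_kpca(rng.normal(size=(15, 4)), KPCAConfig(gamma=0.2))
        eig = model.eigenvalues[:2]
        assert eig[0] >= eig[1] >= 0


class TestProject:
    def test_training_rows_self_projection(self, rng):
        X = rng.normal(size=(12, 5))
        model = fit_kpca(X, KPCAConfig(gamma=0.4))
        np.testing.assert_allclose(project(model, X),
                                   model.training_projections, atol=1e-8)

    def test_empty_input_empty_output(self, rng):
        model = fit_kpca(rng.normal(size=(5, 3)), KPCAConfig(gamma=0.5))
        assert project(model, np.empty((0, 3))).shape == (0, 2)

    def test_dimension_mismatch(self, rng):
        model = fit_kpca(rng.normal(size=(5, 3)), KPCAConfig(gamma=0.5))
        with pytest.raises(DimensionMismatch):
            project(model, rng.normal(size=(2, 4)))

    def test_midpoint_lands_between_neighbours_small_gamma(self, rng):
        X = rng.normal(size=(10, 3))
        model = fit_kpca(X, KPCAConfig(gamma=0.01))
        mid = (X[0] + X[1]) / 2
        p = project(model, mid[None, :])[0]
        lo = np.minimum(model.training_projections[0], model.training_projections[1])
        hi = np.maximum(model.training_projections[0], model.training_projections[1])
        pad = 0.1 * (hi - lo + 1e-9)
        assert np.all(p >= lo - pad) and np.all(p <= hi + pad)


class TestMakeEllipse:
    def test_axis_aligned(self):
        e = make_ellipse((-2, 0), (2, 0), 2)
        assert (e.a, e.b, e.theta, e.center) == (2.0, 1.0, 0.0, (0.0, 0.0))

    def test_vertical(self):
        e = make_ellipse((0, -3), (0, 3), 2)
        assert e.a == 3.0 and e.b == 1.0
        assert e.theta == pytest.approx(np.pi / 2)
        assert e.center == (0.0, 0.0)

    def test_diagonal(self):
        e = make_ellipse((1, 1), (3, 3), np.sqrt(2))
        assert e.a == pytest.approx(np.sqrt(2))
        assert e.b == pytest.approx(np.sqrt(2) / 2)
        assert e.theta == pytest.approx(np.pi / 4)
        assert e.center == (2.0, 2.0)

    def test_coincident_endpoints_rejected(self):
        with pytest.raises(DegenerateEllipse):
            make_ellipse((1, 1), (1, 1), 2)


class TestPointInEllipse:
    e = make_ellipse((-2, 0), (2, 0), 2)

    def test_center_inside(self):
        assert point_in_ellipse(self.e, (0, 0))

    def test_endpoint_on_boundary_inside(self):
        assert point_in_ellipse(self.e, (2, 0))

    def test_derived_outside_point(self):
        # (1.9/2)^2 + (0.5/1)^2 = 0.9025 + 0.25 > 1
        assert not point_in_ellipse(self.e, (1.9, 0.5))

    def test_agrees_with_polygon_oracle(self, rng):
        e = make_ellipse((-1.3, 0.4), (2.1, 2.9), 1.7)
        poly = Polygon(e.polygon(100))
        pts = rng.uniform(-4, 5, size=(20000, 2))
        agree = 0
        checked = 0
        for p in pts:
            x = p[0] - e.center[0]
            y = p[1] - e.center[1]
            u = np.cos(e.theta) * x + np.sin(e.theta) * y
            v = -np.sin(e.theta) * x + np.cos(e.theta) * y
            m = (u / e.a) ** 2 + (v / e.b) ** 2
            if abs(m - 1.0) < 1e-2:  # skip the boundary shell
                continue
            checked += 1
            if point_in_ellipse(e, p) == poly.contains(Point(p)):
                agree += 1
        assert checked > 15000
        assert agree / checked >= 0.999


class TestEllipseFromReference:
    def test_all_captures_every_reference_point(self, rng):
        pts = rng.normal(size=(100, 2))
        e = ellipse_from_reference(pts, "all")
        rates = capture_rates(e, {"ref": pts})
        assert rates["ref"] == 100.0

    def test_z_zero_degenerate(self, rng):
        pts = rng.normal(size=(20, 2))
        with pytest.raises(DegenerateEllipse):
            ellipse_from_reference(pts, 0.0)

    def test_two_points_insufficient(self):
        with pytest.raises(InsufficientReference):
            ellipse_from_reference(np.array([[0, 0], [1, 1]]), 2.0)

    def test_gaussian_two_sd_capture_close_to_ellipse_mass(self):
        # For an isotropic Gaussian the ideal 2-sd ellipse holds 1-exp(-2)
        # ~ 86.5%.  Endpoints are actual data points whose minor coordinates
        # tilt the ellipse slightly, so the tolerance is a few percent.
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(10000, 2))
        e = ellipse_from_reference(pts, 2.0)
        rate = capture_rates(e, {"ref": pts})["ref"]
        assert rate == pytest.approx(100 * (1 - np.exp(-2)), abs=5.0)

    def test_monotone_retained_sets_fixed_projection(self, rng):
        ref = rng.normal(size=(50, 2))
        query = rng.normal(scale=2.0, size=(200, 2))
        ids = list(range(200))
        prev: set = set()
        for z in (0.5, 1.0, 2.0, 3.0):
            e = ellipse_from_reference(ref, z)
            kept = set(layer1_select(ids, query, e))
            assert prev <= kept
            prev = kept

    def test_sign_flip_invariance(self, rng):
        ref = rng.normal(size=(40, 2))
        query = rng.normal(scale=2.0, size=(100, 2))
        ids = list(range(100))
        base = set(layer1_select(ids, query, ellipse_from_reference(ref, 1.5)))
        for flip in ([-1, 1], [1, -1], [-1, -1]):
            f = np.array(flip, dtype=float)
            kept = set(layer1_select(ids, query * f,
                                     ellipse_from_reference(ref * f, 1.5)))
            assert kept == base


class TestCaptureAndSelect:
    e = make_ellipse((-2, 0), (2, 0), 2)

    def test_fully_inside_group(self):
        pts = np.zeros((5, 2))
        assert capture_rates(self.e, {"g": pts})["g"] == 100.0

    def test_fully_outside_group(self):
        pts = np.full((5, 2), 10.0)
        assert capture_rates(self.e, {"g": pts})["g"] == 0.0

    def test_half_inside_by_construction(self):
        pts = np.array([[0, 0], [1, 0], [10, 0], [0, 10]])
        assert capture_rates(self.e, {"g": pts})["g"] == 50.0

    def test_empty_group_rejected(self):
        with pytest.raises(EmptyGroup):
            capture_rates(self.e, {"g": np.empty((0, 2))})

    def test_select_matches_brute_force(self, rng):
        pts = rng.uniform(-3, 3, size=(100, 2))
        ids = [f"q{i}" for i in range(100)]
        kept = layer1_select(ids, pts, self.e)
        brute = [i for i, p in zip(ids, pts) if point_in_ellipse(self.e, p)]
        assert kept == brute

    def test_empty_query(self):
        assert layer1_select([], np.empty((0, 2)), self.e) == []


class TestGateOnSyntheticClouds:
    def test_reference_cluster_fully_captured_background_spread_out(self):
        X, labels = generate_embedding_clouds(EmbeddingCloudSpec(
            n_reference=40, n_background=300, dimension=6,
            r_ref=0.5, r_bg=5.0, seed=3))
        model = fit_kpca(X, KPCAConfig(gamma=0.05))
        proj = model.training_projections
        ref = proj[labels == "reference"]
        bg = proj[labels == "background"]
        result = gate(ref, bg, "all")
        assert result.capture["reference"] == 100.0
        assert result.capture["query"] < 50.0
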