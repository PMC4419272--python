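"""Lattice construction, Bayesian map estimation and prediction."""

import warnings

import numpy as np
import pytest

from morphomap import (
    IdentifiabilityError,
    LatticeMap,
    OutOfDomainError,
    build_lattice,
    estimate_map,
    fit_affine,
    predict,
    register_embryos,
    residual_error,
)
from morphomap.geometry import Point2

from conftest import affine_pairs, make_pairs


def rot(deg):
    t = np.deg2rad(deg)
    return np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])


A_GENERIC = np.array([[1.3, 0.2], [0.1, 1.1]])
B_GENERIC = np.array([30.0, -20.0])


class TestBuildLattice:
    def test_envelops_data_with_margin(self):
        rng = np.random.default_rng(1)
        X = rng.uniform([0, 0], [1000, 500], (30, 2))
        pairs = make_pairs(X, X)
        lat = build_lattice(pairs, spacing=200.0, margin_cells=1)
        assert lat.origin[0] <= -200 and lat.origin[1] <= -200
        hi = np.asarray(lat.origin) + np.array(
            [lat.n_cols - 1, lat.n_rows - 1]
        ) * lat.spacing
        assert hi[0] >= 1200 and hi[1] >= 700
        assert np.all(lat.contains(X, strict=True))

    def test_degenerate_span_rejected(self):
        X = np.tile([100.0, 200.0], (8, 1))
        with pytest.raises(IdentifiabilityError):
            build_lattice(make_pairs(X, X))

    def test_paper_scale_grid(self, recovery):
        # ~2 x 1 mm organ at 200 µm spacing: grid of order 10 x 15 cells
        lat = recovery.fitted
        assert 5 <= lat.n_rows - 1 <= 12
        assert 10 <= lat.n_cols - 1 <= 18

    def test_too_few_landmarks(self):
        with pytest.raises(ValueError):
            build_lattice(make_pairs([[0, 0]], [[0, 0]]))


class TestEstimateMap:
    @pytest.mark.parametrize("alpha", [1e-6, 1e-2, 1.0, 1e2])
    def test_affine_data_reproduced_exactly_for_any_alpha(self, alpha):
        pairs = affine_pairs(A_GENERIC, B_GENERIC, n=20)
        lat = build_lattice(pairs, spacing=200.0)
        fit = estimate_map(pairs, lat, alpha=alpha, sigma2=400.0)
        expected = lat.ref_nodes @ A_GENERIC.T + B_GENERIC
        assert np.abs(fit.est_nodes - expected).max() < 1e-6

    def test_identity_data_gives_identity_map(self):
        pairs = affine_pairs(np.eye(2), np.zeros(2), n=15)
        lat = build_lattice(pairs)
        fit = estimate_map(pairs, lat)
        assert np.abs(fit.est_nodes - lat.ref_nodes).max() < 1e-6

    def test_alpha_infinity_limit_is_best_fit_affine(self):
        # noisy non-affine data: huge smoothing must collapse to the
        # least-squares affine map (the penalty null space)
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1000, (40, 2))
        x = X @ A_GENERIC.T + B_GENERIC + 30 * np.sin(X / 150.0)
        pairs = make_pairs(X, x)
        lat = build_lattice(pairs)
        fit = estimate_map(pairs, lat, alpha=1e9, sigma2=400.0)
        A_ls, b_ls = fit_affine(X, x)
        expected = lat.ref_nodes @ A_ls.T + b_ls
        assert np.abs(fit.est_nodes - expected).max() < 1e-3

    def test_translation_equivariance(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 1000, (30, 2))
        x = X @ A_GENERIC.T + 10 * np.cos(X / 200.0)
        t = np.array([123.0, -77.0])
        lat = build_lattice(make_pairs(X, x))
        f1 = estimate_map(make_pairs(X, x), lat, alpha=1e-2, sigma2=400.0)
        f2 = estimate_map(make_pairs(X, x + t), lat, alpha=1e-2, sigma2=400.0)
        assert np.abs(f2.est_nodes - (f1.est_nodes + t)).max() < 1e-6

    def test_rotation_equivariance_of_observations(self):
        # rotating the deformed positions rotates the solution: the prior
        # penalizes second differences, which are blind to the frame of x
        rng = np.random.default_rng(6)
        Q = rot(30.0)
        X = rng.uniform(0, 1000, (30, 2))
        x = X @ A_GENERIC.T + 10 * np.cos(X / 200.0)
        lat = build_lattice(make_pairs(X, x))
        f1 = estimate_map(make_pairs(X, x), lat, alpha=1e-2, sigma2=400.0)
        f2 = estimate_map(make_pairs(X, x @ Q.T), lat, alpha=1e-2, sigma2=400.0)
        assert np.abs(f2.est_nodes - f1.est_nodes @ Q.T).max() < 1e-5

    def test_collinear_landmarks_rejected(self):
        X = np.stack([np.linspace(0, 1000, 10), np.linspace(0, 500, 10)], axis=1)
        pairs = make_pairs(X, X)
        lat = LatticeMap(origin=(-200, -200), spacing=200, n_rows=6, n_cols=8)
        with pytest.raises(IdentifiabilityError):
            estimate_map(pairs, lat)

    def test_too_few_pairs_rejected(self):
        pairs = affine_pairs(np.eye(2), np.zeros(2), n=5)
        lat = LatticeMap(origin=(-200, -200), spacing=200, n_rows=9, n_cols=9)
        with pytest.raises(IdentifiabilityError):
            estimate_map(pairs, lat)

    def test_duplicate_reference_positions_averaged(self):
        pairs = affine_pairs(np.eye(2), np.zeros(2), n=12)
        p0 = pairs[0]
        dup = type(p0)(
            p0.embryo_id, p0.interval_id, p0.X,
            Point2(p0.x.pd + 10.0, p0.x.ap),
        )
        lat = build_lattice(pairs)
        with pytest.warns(UserWarning, match="duplicate"):
            estimate_map(pairs + [dup], lat, alpha=1.0, sigma2=400.0)

    def test_recovery_map_is_fold_free(self, recovery):
        assert recovery.fitted.folded_cells == ()

    def test_hyperparameters_recorded(self, recovery):
        hp = recovery.fitted.hyperparams
        assert hp["alpha"] > 0 and hp["sigma2"] > 0
        assert hp["lambda"] == pytest.approx(hp["alpha"] * hp["sigma2"])

    def test_noise_variance_estimate_plausible(self, recovery):
        # true observation noise is sigma = 20 µm in each coordinate
        assert 5.0**2 < recovery.fitted.hyperparams["sigma2"] < 40.0**2


@pytest.fixture(scope="module")
def affine_fit():
    pairs = affine_pairs(A_GENERIC, B_GENERIC, n=20)
    lat = build_lattice(pairs)
    return estimate_map(pairs, lat, alpha=1.0, sigma2=400.0)


class TestPredict:
    def test_at_reference_node(self, affine_fit):
        node = affine_fit.ref_nodes[affine_fit.n_cols + 1]
        assert np.allclose(
            predict(affine_fit, node), A_GENERIC @ node + B_GENERIC, atol=1e-6
        )

    def test_at_cell_center_reproduces_affine(self, affine_fit):
        c = affine_fit.cell_centers()[5]
        assert np.allclose(
            predict(affine_fit, c), A_GENERIC @ c + B_GENERIC, atol=1e-6
        )

    def test_no_extrapolation(self, affine_fit):
        lo = np.asarray(affine_fit.origin)
        with pytest.raises(OutOfDomainError):
            predict(affine_fit, lo - 1e-6)

    def test_point2_input(self, affine_fit):
        c = affine_fit.cell_centers()[3]
        out = predict(affine_fit, Point2(*c))
        assert out.shape == (2,)


class TestResidualError:
    def test_zero_for_perfect_affine_fit(self):
        pairs = affine_pairs(A_GENERIC, B_GENERIC, n=20)
        fit = estimate_map(pairs, build_lattice(pairs), alpha=1.0, sigma2=400.0)
        assert residual_error(fit, pairs) < 1e-8

    def test_uniform_translation_absorbed_by_free_fit(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(0, 1000, (20, 2))
        pairs = make_pairs(X, X + np.array([10.0, 0.0]))
        fit = estimate_map(pairs, build_lattice(pairs), alpha=1e-3, sigma2=400.0)
        assert residual_error(fit, pairs) < 1e-6

    def test_synthetic_recovery_residual_at_noise_floor(self, recovery):
        assert 10.0 <= recovery.residual_um <= 40.0

    def test_empty_list_rejected(self, recovery):
        with pytest.raises(ValueError):
            residual_error(recovery.fitted, [])


class TestSerialization:
    def test_json_roundtrip(self, recovery, tmp_path):
        path = tmp_path / "map.json"
        recovery.fitted.to_json(path, provenance={"source": "test"})
        back = LatticeMap.from_json(path)
        assert back.shape == recovery.fitted.shape
        assert np.allclose(back.est_nodes, recovery.fitted.est_nodes)
        assert back.hyperparams == recovery.fitted.hyperparams
        assert np.allclose(back.support_counts, recovery.fitted.support_counts)


class TestRegisterEmbryos:
    def test_moment_alignment_undoes_small_rigid_jitter(self):
        rng = np.random.default_rng(11)
        X = rng.uniform([0, 0], [2000, 1000], (60, 2))
        x = X * 1.2
        theta, t = np.deg2rad(4.0), np.array([40.0, -25.0])
        Q = rot(np.rad2deg(theta))
        pairs = make_pairs(X, x, embryo_id="a") + make_pairs(
            X @ Q.T + t, x @ Q.T + t, embryo_id="b"
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # coincident X across embryos is fine here
            reg = register_embryos(pairs)
        Xa = np.array([[p.X.pd, p.X.ap] for p in reg if p.embryo_id == "a"])
        Xb = np.array([[p.X.pd, p.X.ap] for p in reg if p.embryo_id == "b"])
        before = np.linalg.norm((X @ Q.T + t) - X, axis=1).mean()
        after = np.linalg.norm(Xb - Xa, axis=1).mean()
        assert after < 0.2 * before
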