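"""The four origin predictors: regression, scalar-distance, transfer-matrix."""

import numpy as np
import pytest

from pacemap.localizers import (
    InsufficientDataError,
    QimFit,
    fit_qim,
    fit_scalar_distance,
    multilaterate,
    predict_dcm,
    predict_ddm,
    predict_dem,
    predict_qim,
    predict_with_model,
)
from pacemap.morph import QrsIntTriple


def triple(v) -> QrsIntTriple:
    return QrsIntTriple(values=np.asarray(v, dtype=float))


# ---------------------------------------------------------------------------
# QIM
# ---------------------------------------------------------------------------

class TestQim:
    def test_exactly_affine_system_recovers_held_out_site(self, position_only_site, rng):
        m = rng.uniform(-1, 1, (3, 3)) + 3 * np.eye(3)
        c = rng.uniform(-5, 5, 3)
        positions = rng.uniform(-40, 40, (7, 3))
        integrals = [triple(m @ p + c) for p in positions]
        sites = [position_only_site(f"s{i}", p) for i, p in enumerate(positions)]
        fit = fit_qim(sites[:6], integrals[:6])
        pred = predict_qim(fit, integrals[6])
        np.testing.assert_allclose(pred.position, positions[6], atol=1e-6)

    def test_four_sites_rejected(self, position_only_site, rng):
        sites = [position_only_site(f"s{i}", rng.uniform(-10, 10, 3)) for i in range(4)]
        with pytest.raises(InsufficientDataError):
            fit_qim(sites, [triple(rng.uniform(-1, 1, 3)) for _ in range(4)])

    def test_duplicated_predictor_column_sets_rank_flag(self, position_only_site, rng):
        positions = rng.uniform(-20, 20, (6, 3))
        sites = [position_only_site(f"s{i}", p) for i, p in enumerate(positions)]
        raw = rng.uniform(-1, 1, (6, 2))
        integrals = [triple([r[0], r[0], r[1]]) for r in raw]  # I1 duplicated
        fit = fit_qim(sites, integrals)
        assert fit.rank_deficient
        pred = predict_qim(fit, integrals[0])
        assert np.all(np.isfinite(pred.position))

    def test_intercept_only_fit_predicts_intercept(self):
        coef = np.zeros((3, 4))
        coef[:, 0] = (1.0, -2.0, 3.0)
        pred = predict_qim(QimFit(coefficients=coef), triple([9.0, -4.0, 7.0]))
        np.testing.assert_allclose(pred.position, [1.0, -2.0, 3.0])

    def test_in_sample_exactness_under_exact_affine_map(self, position_only_site, rng):
        m = rng.uniform(-1, 1, (3, 3)) + 2 * np.eye(3)
        positions = rng.uniform(-30, 30, (6, 3))
        integrals = [triple(m @ p) for p in positions]
        sites = [position_only_site(f"s{i}", p) for i, p in enumerate(positions)]
        fit = fit_qim(sites, integrals)
        for p, q in zip(positions, integrals):
            np.testing.assert_allclose(predict_qim(fit, q).position, p, atol=1e-8)

    def test_matches_hand_rolled_normal_equations(self, position_only_site, rng):
        positions = rng.uniform(-25, 25, (9, 3))
        integrals = [triple(rng.uniform(-10, 10, 3)) for _ in range(9)]
        sites = [position_only_site(f"s{i}", p) for i, p in enumerate(positions)]
        fit = fit_qim(sites, integrals)
        x = np.column_stack([np.ones(9), np.stack([q.values for q in integrals])])
        beta = np.linalg.solve(x.T @ x, x.T @ positions)  # (4, 3)
        np.testing.assert_allclose(fit.coefficients, beta.T, atol=1e-8)


# ---------------------------------------------------------------------------
# scalar-distance fit and multilateration
# ---------------------------------------------------------------------------

class TestScalarDistanceFit:
    def test_exact_proportionality_recovers_slope(self):
        pairs = [(m, 2.0 * m) for m in (0.5, 1.0, 3.0, 7.0)]
        assert fit_scalar_distance(pairs).k == pytest.approx(2.0)

    def test_single_pair(self):
        assert fit_scalar_distance([(4.0, 10.0)]).k == pytest.approx(2.5)

    def test_matches_grid_search_oracle(self, rng):
        m = rng.uniform(0.1, 5.0, 30)
        d = 3.7 * m + rng.normal(0, 0.5, 30)
        k = fit_scalar_distance(list(zip(m, d))).k
        grid = np.linspace(0.1, 10.0, 20001)
        losses = [np.sum((d - kk * m) ** 2) for kk in grid]
        assert k == pytest.approx(grid[int(np.argmin(losses))], abs=1e-3)

    def test_all_zero_metrics_rejected(self):
        with pytest.raises(ValueError):
            fit_scalar_distance([(0.0, 5.0), (0.0, 3.0)])


class TestMultilateration:
    def test_exact_distances_recover_the_point(self, rng):
        anchors = np.array([[0, 0, 0], [40, 0, 0], [0, 40, 0], [0, 0, 40]], float)
        x = np.array([11.0, 7.0, 23.0])
        d = np.linalg.norm(anchors - x, axis=1)
        pred = multilaterate(anchors, d)
        np.testing.assert_allclose(pred.position, x, atol=1e-6)

    def test_coplanar_anchors_find_a_mirror_solution(self):
        anchors = np.array([[0, 0, 0], [30, 0, 0], [0, 30, 0]], float)
        x = np.array([10.0, 8.0, 17.0])
        d = np.linalg.norm(anchors - x, axis=1)
        pred = multilaterate(anchors, d)
        mirror = x * np.array([1, 1, -1])
        err = min(np.linalg.norm(pred.position - x), np.linalg.norm(pred.position - mirror))
        assert err < 1e-5
        assert pred.diagnostics["cost_J"] < 1e-10

    def test_zero_distances_minimize_sum_of_squared_distances(self, rng):
        anchors = rng.uniform(-20, 20, (5, 3))
        pred = multilaterate(anchors, np.zeros(5))
        # J(x) = sum ||x - a||^2 is minimized by the centroid; verify both
        # by closed form and by checking J at the prediction beats a grid
        centroid = anchors.mean(axis=0)
        np.testing.assert_allclose(pred.position, centroid, atol=1e-5)
        j = lambda x: np.sum(np.linalg.norm(anchors - x, axis=1) ** 2)  # noqa: E731
        for delta in rng.uniform(-1, 1, (20, 3)):
            assert j(pred.position) <= j(pred.position + delta) + 1e-9

    def test_two_anchors_rejected(self):
        with pytest.raises(InsufficientDataError):
            multilaterate(np.zeros((2, 3)), np.ones(2))


# ---------------------------------------------------------------------------
# DEM / DCM
# ---------------------------------------------------------------------------

NONCOPLANAR = [
    np.array([28.0, 6.0, 12.0]),
    np.array([-22.0, 18.0, 20.0]),
    np.array([4.0, -30.0, 25.0]),
    np.array([-5.0, 12.0, -44.0]),
    np.array([20.0, -15.0, -35.0]),
]


class TestDem:
    def test_recovers_target_on_proportional_forward_model(self, make_affine_site):
        modeling = [make_affine_site(f"m{i}", p) for i, p in enumerate(NONCOPLANAR)]
        target = make_affine_site("t", [6.0, 2.0, 18.0])
        pred = predict_dem(modeling, target.splice)
        assert np.linalg.norm(pred.position - target.position) < 1e-3

    def test_target_at_modeling_site_predicted_there(self, make_affine_site):
        modeling = [make_affine_site(f"m{i}", p) for i, p in enumerate(NONCOPLANAR[:4])]
        target = make_affine_site("t", NONCOPLANAR[1])
        pred = predict_dem(modeling, target.splice)
        assert np.linalg.norm(pred.position - NONCOPLANAR[1]) < 1e-3

    def test_slope_matches_fit_on_three_pairwise_pairs(self, make_affine_site):
        from itertools import combinations
        from pacemap.morph import e12

        modeling = [make_affine_site(f"m{i}", p) for i, p in enumerate(NONCOPLANAR[:3])]
        target = make_affine_site("t", [0.0, 0.0, 30.0])
        pred = predict_dem(modeling, target.splice)
        pairs = [
            (e12(a.splice, b.splice), float(np.linalg.norm(a.position - b.position)))
            for a, b in combinations(modeling, 2)
        ]
        assert pred.diagnostics["k"] == pytest.approx(fit_scalar_distance(pairs).k)


class TestDcm:
    def test_identical_waveform_gives_zero_estimated_distance(self, make_affine_site):
        modeling = [make_affine_site(f"m{i}", p) for i, p in enumerate(NONCOPLANAR[:4])]
        target = make_affine_site("t", NONCOPLANAR[2])
        pred = predict_dcm(modeling, target.splice)
        assert pred.diagnostics["estimated_distances"][2] == pytest.approx(0.0, abs=1e-9)

    def test_recovers_target_at_symmetric_anchor_cloud(self, make_affine_site):
        # 1 - Corr is locally quadratic in distance for a smooth forward
        # map; at a symmetric surround the distortion cancels and the
        # proportionality calibration is locally valid.
        rng = np.random.default_rng(5)
        target_pos = np.array([4.0, -6.0, 15.0])
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        verts = np.vstack([25.0 * q[:, i] * s for i in range(3) for s in (1, -1)])
        modeling = [make_affine_site(f"o{i}", target_pos + v) for i, v in enumerate(verts)]
        target = make_affine_site("t", target_pos)
        pred = predict_dcm(modeling, target.splice)
        assert np.linalg.norm(pred.position - target_pos) < 1.0

    def test_slope_positive_on_nondegenerate_training_set(self, make_affine_site):
        modeling = [make_affine_site(f"m{i}", p) for i, p in enumerate(NONCOPLANAR)]
        target = make_affine_site("t", [0.0, 10.0, 0.0])
        pred = predict_dcm(modeling, target.splice)
        assert pred.diagnostics["k"] > 0


# ---------------------------------------------------------------------------
# DDM
# ---------------------------------------------------------------------------

class TestDdm:
    def test_exact_recovery_of_in_plane_target(self, make_affine_site):
        p = [np.array([10.0, 0.0, 40.0]), np.array([-15.0, 20.0, 30.0]),
             np.array([0.0, -25.0, 35.0])]
        target_pos = p[0] + 0.3 * (p[1] - p[0]) + 0.5 * (p[2] - p[0])
        modeling = [make_affine_site(f"m{i}", q) for i, q in enumerate(p)]
        target = make_affine_site("t", target_pos)
        pred = predict_ddm(modeling, target.splice)
        assert np.linalg.norm(pred.position - target_pos) < 1e-9

    def test_target_sharing_a_sites_waveform_predicted_at_that_site(self, make_affine_site):
        modeling = [make_affine_site(f"m{i}", p) for i, p in enumerate(NONCOPLANAR[:3])]
        pred = predict_ddm(modeling, modeling[1].splice)
        assert np.linalg.norm(pred.position - modeling[1].position) < 1e-9

    def test_out_of_plane_target_projected_orthogonally(self, make_affine_site):
        p = [np.array([20.0, 0.0, 0.0]), np.array([0.0, 25.0, 0.0]),
             np.array([-20.0, -10.0, 0.0])]  # modeling plane z = 0
        target_pos = np.array([3.0, 5.0, 22.0])
        modeling = [make_affine_site(f"m{i}", q) for i, q in enumerate(p)]
        target = make_affine_site("t", target_pos)
        pred = predict_ddm(modeling, target.splice)
        np.testing.assert_allclose(pred.position, [3.0, 5.0, 0.0], atol=1e-9)

    def test_more_noiseless_sites_never_hurt(self, make_affine_site, affine_dataset):
        # start from a coplanar quadruple (nonzero projection error), then
        # add generic shell sites: the error must be non-increasing.
        coplanar = [
            make_affine_site("c0", [20.0, 0.0, 0.0]),
            make_affine_site("c1", [0.0, 25.0, 0.0]),
            make_affine_site("c2", [-20.0, -10.0, 0.0]),
            make_affine_site("c3", [10.0, 15.0, 0.0]),
        ]
        extra = list(affine_dataset.sites[:4])
        target = make_affine_site("t", [5.0, -4.0, 18.0])
        errors = []
        for m in range(4, 9):
            modeling = (coplanar + extra)[:m]
            pred = predict_ddm(modeling, target.splice)
            errors.append(float(np.linalg.norm(pred.position - target.position)))
        assert errors[0] > 1.0  # coplanar start genuinely off
        for a, b in zip(errors, errors[1:]):
            assert b <= a + 1e-9


# ---------------------------------------------------------------------------
# shared invariants
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("model", ["QIM", "DEM", "DCM", "DDM"])
def test_translation_equivariance(model, make_affine_site, affine_dataset):
    """Translating every site position translates the prediction identically."""
    from pacemap.ecg import PacingSite

    modeling = list(affine_dataset.sites[1:7])
    target = affine_dataset.sites[0]
    shift = np.array([13.0, -40.0, 8.0])

    def shifted(site: PacingSite) -> PacingSite:
        return PacingSite(site_id=site.site_id, position=site.position + shift,
                          beats=site.beats)

    base = predict_with_model(model, modeling, target)
    moved = predict_with_model(model, [shifted(s) for s in modeling], shifted(target))
    np.testing.assert_allclose(moved.position, base.position + shift, atol=1e-5)
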