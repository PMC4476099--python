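"""Sobol designs and the HDMR variance decomposition against analytic oracles."""

import numpy as np
import pytest
from scipy.stats import qmc

from gexsens import (
    HDMR,
    GridSpec,
    HDMRConfig,
    InitialConditionSpec,
    ObjectiveSpec,
    SobolDesign,
    TABLE1_SPACE,
    evaluate_objective_batch,
    extract_objective,
    hdmr_decompose,
    scale_to_space,
    simulate,
    sobol_unit_samples,
)
from gexsens.hdmr import shifted_legendre
from gexsens.model import build_initial_condition


class TestSobolDesign:
    def test_points_in_unit_interval(self):
        u = sobol_unit_samples(256, 6)
        assert u.shape == (256, 6)
        assert (u >= 0).all() and (u < 1).all()

    def test_deterministic_bit_for_bit(self):
        a = sobol_unit_samples(512, 6)
        b = sobol_unit_samples(512, 6)
        np.testing.assert_array_equal(a, b)

    def test_lower_discrepancy_than_random(self):
        sob = sobol_unit_samples(1024, 2)
        cd_sobol = qmc.discrepancy(sob, method="CD")
        rng = np.random.default_rng(42)
        cd_random = [
            qmc.discrepancy(rng.uniform(size=(1024, 2)), method="CD")
            for _ in range(100)
        ]
        assert cd_sobol < np.median(cd_random)

    def test_dimension_limit_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            sobol_unit_samples(8, 30000)

    @pytest.mark.parametrize(
        "u,expected",
        [(0.5, 1.006), (0.0, 0.012), (1.0, 2.0)],
    )
    def test_scaling_of_sigma_range(self, u, expected):
        pts = np.full((1, 6), u)
        scaled = scale_to_space(pts, TABLE1_SPACE)
        assert scaled[0, 0] == pytest.approx(expected)

    def test_degenerate_range_gives_constant_column(self):
        space = TABLE1_SPACE.with_range("d", 0.7, 0.7)
        scaled = scale_to_space(sobol_unit_samples(64, 6), space)
        np.testing.assert_array_equal(scaled[:, 1], np.full(64, 0.7))

    def test_out_of_unit_coordinates_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            scale_to_space(np.full((2, 6), 1.5), TABLE1_SPACE)

    def test_generate_carries_both_coordinate_systems(self):
        design = SobolDesign.generate(128, TABLE1_SPACE)
        assert design.scaled_points.shape == design.unit_points.shape
        for j, r in enumerate(TABLE1_SPACE.ranges):
            col = design.scaled_points[:, j]
            assert col.min() >= r.lower and col.max() <= r.upper
        assert design.names == ("sigma", "d", "lam", "tau", "delta", "gamma")


class TestBasis:
    def test_orthonormal_on_design(self):
        u = sobol_unit_samples(4096, 1)[:, 0]
        for p in range(4):
            for q in range(4):
                inner = float((shifted_legendre(p, u) * shifted_legendre(q, u)).mean())
                assert inner == pytest.approx(1.0 if p == q else 0.0, abs=0.02)


class TestHDMRAnalyticOracles:
    # Closed-form ANOVA decompositions of simple functions of independent
    # uniforms; Var(u1) = 1/12, Var(u1*u2) = 7/144 with first-order pieces
    # 1/48 each and interaction 1/144*4.

    def test_single_coordinate_function(self):
        u = sobol_unit_samples(8192, 3)
        res = HDMR(u[:, 0], u).fit()
        assert res.first_order["x1"] == pytest.approx(1.0, abs=0.02)
        assert res.first_order["x2"] <= 0.02
        assert res.first_order["x3"] <= 0.02
        assert float(res.second_order.sum()) <= 0.02

    def test_product_of_two_uniforms(self):
        u = sobol_unit_samples(8192, 3)
        res = HDMR(u[:, 0] * u[:, 1], u).fit()
        assert res.first_order["x1"] == pytest.approx(3 / 7, abs=0.03)
        assert res.first_order["x2"] == pytest.approx(3 / 7, abs=0.03)
        assert res.second_order_index("x1", "x2") == pytest.approx(1 / 7, abs=0.03)
        assert res.first_order["x3"] <= 0.02

    def test_additive_function_has_no_interactions(self):
        u = sobol_unit_samples(8192, 3)
        f = u[:, 0] ** 3 + 2.0 * u[:, 1] ** 2 + 0.5 * u[:, 2]
        res = HDMR(f, u).fit()
        assert float(res.first_order.sum()) >= 0.97
        assert (res.second_order <= 0.02).all()

    def test_zero_variance_convention(self):
        u = sobol_unit_samples(256, 4)
        res = HDMR(np.full(256, 3.25), u).fit()
        assert res.f0 == 3.25
        assert res.total_variance == 0.0
        assert (res.first_order == 0).all()
        assert (res.second_order == 0).all()

    def test_affine_output_invariance(self):
        u = sobol_unit_samples(4096, 3)
        f = u[:, 0] * u[:, 1] + u[:, 2] ** 2
        res_a = HDMR(f, u).fit()
        res_b = HDMR(-2.5 * f + 7.0, u).fit()
        np.testing.assert_allclose(
            res_a.first_order.to_numpy(), res_b.first_order.to_numpy(), atol=1e-10
        )
        np.testing.assert_allclose(
            res_a.second_order.to_numpy(), res_b.second_order.to_numpy(), atol=1e-10
        )

    def test_symmetric_pair_lookup(self):
        u = sobol_unit_samples(1024, 2)
        res = HDMR(u[:, 0] * u[:, 1], u).fit()
        assert res.second_order_index("x1", "x2") == res.second_order_index("x2", "x1")

    def test_matches_brute_force_anova_on_tensor_grid(self):
        # Independent oracle: full ANOVA of f on a 50^3 midpoint tensor grid.
        K = 50
        x = (np.arange(K) + 0.5) / K
        X1, X2, X3 = np.meshgrid(x, x, x, indexing="ij")
        F = X1**2 * X2 + 0.5 * X3
        f0 = F.mean()
        D = F.var()
        fi = [F.mean(axis=(1, 2)) - f0, F.mean(axis=(0, 2)) - f0, F.mean(axis=(0, 1)) - f0]
        S_true = [float((g**2).mean() / D) for g in fi]
        f12 = F.mean(axis=2) - f0 - fi[0][:, None] - fi[1][None, :]
        S12_true = float((f12**2).mean() / D)

        u = sobol_unit_samples(8192, 3)
        res = HDMR(u[:, 0] ** 2 * u[:, 1] + 0.5 * u[:, 2], u).fit()
        for i, name in enumerate(["x1", "x2", "x3"]):
            assert res.first_order[name] == pytest.approx(S_true[i], abs=0.03)
        assert res.second_order_index("x1", "x2") == pytest.approx(S12_true, abs=0.03)

    def test_screening_removes_pure_noise_interactions(self):
        u = sobol_unit_samples(4096, 3)
        f = u[:, 0]  # x2, x3 and every pair are inert
        res = HDMR(f, u).fit()
        assert res.pairwise_sum("x2") == 0.0
        res_raw = HDMR(f, u, coef_screen=0.0).fit()
        assert res_raw.pairwise_sum("x2") > 0.0  # squared-noise bias

    def test_errors(self):
        u = sobol_unit_samples(128, 2)
        with pytest.raises(ValueError, match="poly_order"):
            HDMR(np.zeros(128), u, poly_order=128)
        with pytest.raises(ValueError, match="finite"):
            HDMR(np.full(128, np.nan), u)
        with pytest.raises(ValueError, match="length"):
            HDMR(np.zeros(64), u)


class TestEvaluateObjectiveBatch:
    def test_batch_of_one_reproduces_direct_simulation(self):
        grid = GridSpec(5)
        design = SobolDesign.generate(1, TABLE1_SPACE)
        ic = InitialConditionSpec("anterior", 1.0)
        obj = ObjectiveSpec("middle_nucleus", 2.0)
        batch = evaluate_objective_batch(design, ic, obj, grid=grid, dt=0.02)

        from gexsens import ModelParameters

        params = ModelParameters.from_array(design.scaled_points[0])
        res = simulate(
            build_initial_condition(ic, grid), params, 2.0, dt=0.02, grid=grid
        )
        assert batch[0] == pytest.approx(extract_objective(res, obj), abs=1e-12)

    def test_ubiquitous_outputs_ignore_diffusion_columns(self):
        import dataclasses

        grid = GridSpec(5)
        design = SobolDesign.generate(64, TABLE1_SPACE)
        shuffled = design.scaled_points.copy()
        rng = np.random.default_rng(3)
        shuffled[:, 1] = rng.permutation(shuffled[:, 1])  # d
        shuffled[:, 4] = rng.permutation(shuffled[:, 4])  # delta
        design2 = dataclasses.replace(design, scaled_points=shuffled)
        ic = InitialConditionSpec("ubiquitous", 1.0)
        obj = ObjectiveSpec("middle_nucleus", 2.0)
        a = evaluate_objective_batch(design, ic, obj, grid=grid, dt=0.02)
        b = evaluate_objective_batch(design2, ic, obj, grid=grid, dt=0.02)
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_outputs_finite_and_nonnegative(self):
        design = SobolDesign.generate(64, TABLE1_SPACE)
        out = evaluate_objective_batch(
            design, InitialConditionSpec("ubiquitous", 0.5),
            ObjectiveSpec("spatial_mean", 2.0), grid=GridSpec(5), dt=0.02,
        )
        assert np.isfinite(out).all()
        assert (out >= -1e-9).all()

    def test_decompose_checks_output_length(self):
        design = SobolDesign.generate(128, TABLE1_SPACE)
        with pytest.raises(ValueError, match="design size"):
            hdmr_decompose(design, np.zeros(64), HDMRConfig(n_samples=128))
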