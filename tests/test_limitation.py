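"""Limitation partitioning: weights, contributions, and REW curves."""

from dataclasses import replace

import numpy as np
import pytest

from leaflim import limitation as lim
from leaflim.drought_response import LinearPlateauFit
from leaflim.kinetics import TOBACCO_CC, TOBACCO_CI
from leaflim.presets import POTATO_RESPONSE_FITS
from leaflim.synthetic import fick_fvcb_solve


@pytest.fixture(scope="module")
def continuous_fits():
    """Potato response parameters with continuity-restored intercepts."""
    return {
        k: replace(f, intercept_b=f.y_max - f.slope_a * f.rew_th)
        for k, f in POTATO_RESPONSE_FITS.items()
    }


class TestRelativeVariation:
    def test_plateau_extreme_and_midpoint(self):
        fit = POTATO_RESPONSE_FITS["a_sat"]
        assert lim.relative_variation(fit, 0.9) == 0.0
        assert lim.relative_variation(fit, 0.24) == pytest.approx(1.0)
        y_half = fit.predict(0.5)
        y_ext = fit.predict(0.24)
        expected = (18.74 - y_half) / (18.74 - y_ext)
        assert lim.relative_variation(fit, 0.5) == pytest.approx(expected, rel=1e-12)
        assert lim.relative_variation(fit, 0.5) == pytest.approx(0.462, abs=0.001)

    def test_rising_variable_magnitude_one_at_extreme(self):
        fit = POTATO_RESPONSE_FITS["g_1"]
        assert lim.relative_variation(fit, 0.24) == pytest.approx(1.0)

    def test_unresponsive_variable(self):
        flat = LinearPlateauFit("flat", 2.0, 0.0, 2.0, 0.5)
        assert lim.relative_variation(flat, 0.3) == 0.0


class TestAssimilationSlope:
    def test_hand_value_and_monotonicity(self):
        s = lim.assimilation_slope(14.85, 143.9, 710.3, 42.75)
        assert s == pytest.approx(14.85 * (710.3 + 42.75) / (143.9 + 710.3) ** 2, rel=1e-12)
        assert s == pytest.approx(0.0153, abs=2e-4)
        assert lim.assimilation_slope(14.85, 200.0, 710.3, 42.75) < s

    def test_matches_finite_difference(self, rng):
        for _ in range(50):
            v = rng.uniform(20, 250)
            cc = rng.uniform(60, 300)
            km, gamma = 617.36, 37.43
            a = lambda c: v * (c - gamma) / (c + km)
            h = 1e-4 * cc
            fd = (a(cc + h) - a(cc - h)) / (2 * h)
            assert lim.assimilation_slope(v, cc, km, gamma) == pytest.approx(fd, rel=1e-6)


class TestGrassiScheme:
    def test_symmetry_and_limits(self):
        l_gs, l_gm, l_vc = lim.grassi_fractions(0.1, 0.1, 0.02)
        assert l_gs == pytest.approx(l_gm)
        l_gs, l_gm, l_vc = lim.grassi_fractions(0.1, 0.2, 1e-12)
        assert l_vc == pytest.approx(1.0, abs=1e-9)

    def test_partition_identity_random_states(self, rng):
        for _ in range(1000):
            g_s = rng.lognormal(-2.5, 1.0)
            g_m = rng.lognormal(-2.0, 1.0)
            d = rng.lognormal(-4.0, 1.0)
            assert sum(lim.grassi_fractions(g_s, g_m, d)) == pytest.approx(1.0, abs=1e-10)

    def test_perturbation_oracle_with_independent_gs(self, rng):
        """0.1% decreases of gs, gm, Vcmax change A by the l-predicted amounts."""
        kin = TOBACCO_CC
        for _ in range(20):
            v, g_s, g_m = rng.uniform(30, 200), rng.uniform(0.02, 0.3), rng.uniform(0.03, 0.3)
            a0 = fick_fvcb_solve(v, g_s, g_m, 400.0, kin)
            g_t = 1 / (1 / g_s + 1 / g_m)
            c_c = 400.0 - a0 / g_t
            dA = lim.assimilation_slope(v, c_c, kin.km_25, kin.gamma_star_25)
            fracs = dict(
                zip(("g_s", "g_m", "v"), lim.grassi_fractions(g_s, g_m, dA))
            )
            eps = 1e-3
            for name, args in {
                "g_s": (v, g_s * (1 - eps), g_m),
                "g_m": (v, g_s, g_m * (1 - eps)),
                "v": (v * (1 - eps), g_s, g_m),
            }.items():
                a1 = fick_fvcb_solve(*args, 400.0, kin)
                observed = (a0 - a1) / a0 / eps
                assert observed == pytest.approx(fracs[name], rel=0.01)


class TestUsoScheme:
    def test_algebraic_relations(self, rng):
        for _ in range(200):
            l_gs, l_gm = rng.uniform(0.05, 0.45), rng.uniform(0.05, 0.45)
            l_vc = 1.0 - l_gs - l_gm
            cics = rng.uniform(0.3, 0.9)
            l_g1, l_gmu, l_vcu, l_vpd = lim.uso_fractions(l_gs, l_gm, l_vc, cics)
            assert l_vpd == pytest.approx(-0.5 * l_g1, rel=1e-12)
            assert l_gmu * (1 - l_gs) == pytest.approx(l_gm, rel=1e-12)
            assert l_vcu * (1 - l_gs) == pytest.approx(l_vc, rel=1e-12)

    def test_domain(self):
        with pytest.raises(ValueError):
            lim.uso_fractions(1.0, 0.0, 0.0, 0.5)

    def test_vpd_contribution_zero_without_vpd_change(self):
        rel = {"g_1": 0.5, "g_m_25": 0.5, "v_cmax_25": 0.5, "vpd": 0.0}
        out = lim.uso_contributions(rel, 0.3, 0.4, 0.2, -0.15)
        assert out[3] == 0.0


class TestStomatalClosureDecomposition:
    def test_algebraic_identity_with_consistent_variations(self, rng):
        """The closure identity is exact when dA/A is the Grassi-scheme sum.

        Construct signed log-variations where dln(gs) follows from the USO
        closure; then the decomposition of L_gs must balance to zero.
        """
        for _ in range(200):
            l_gs, l_gm = rng.uniform(0.05, 0.45), rng.uniform(0.05, 0.45)
            l_vc = 1.0 - l_gs - l_gm
            cics = rng.uniform(0.3, 0.9)
            dg1, dgm, dvc, dvpd = rng.normal(0, 0.3, size=4)
            # USO closure: dlnA(1-l_gs) = l_gs*cics*(dg1 - dvpd/2) + l_gm*dgm + l_vc*dvc
            dA = (l_gs * cics * (dg1 - 0.5 * dvpd) + l_gm * dgm + l_vc * dvc) / (1 - l_gs)
            dgs = dA + cics * (dg1 - 0.5 * dvpd)
            assert dA == pytest.approx(l_gs * dgs + l_gm * dgm + l_vc * dvc, abs=1e-12)
            L_gs = l_gs * dgs
            l_g1u, l_gmu, l_vcu, l_vpdu = lim.uso_fractions(l_gs, l_gm, l_vc, cics)
            recomposed = (
                (l_gmu * dgm - l_gm * dgm)
                + (l_vcu * dvc - l_vc * dvc)
                + (-l_vpdu) * (-dvpd)  # L_vpd with the explicit minus
                + l_g1u * dg1
            )
            assert recomposed == pytest.approx(L_gs, abs=1e-10)

    def test_plateau_state_all_zero(self, continuous_fits):
        curves = lim.evaluate_curves(continuous_fits, n_grid=60)
        state = curves.states[-1]  # REW = 1, above every threshold
        out = lim.stomatal_closure_decomposition(state)
        for key in ("nsol_gm", "nsol_vcmax", "vpd", "g1"):
            assert out[key] == pytest.approx(0.0, abs=1e-12)

    def test_residual_reported(self, continuous_fits):
        curves = lim.evaluate_curves(continuous_fits, n_grid=60)
        out = lim.stomatal_closure_decomposition(curves.states[0])
        total = out["nsol_gm"] + out["nsol_vcmax"] + out["vpd"] + out["g1"]
        assert out["residual"] == pytest.approx(total - curves.states[0].L_gs, abs=1e-12)


class TestVpdRelation:
    def test_slope_recovery(self, rng):
        rew = rng.uniform(0.2, 1.0, 40)
        vpd = -2.5 * rew + 4.0 + rng.normal(0, 0.2, 40)
        rel = lim.fit_vpd_rew(vpd, rew)
        assert abs(rel.slope - (-2.5)) <= 2 * rel.sd_slope

    def test_constant_vpd_gives_zero_variation(self):
        rel = lim.VpdRewRelation(slope=0.0, intercept=2.0)
        assert lim.vpd_relative_variation(rel, 0.5) == 0.0

    def test_convention_magnitude_one_at_extreme(self):
        rel = lim.DEFAULT_VPD_REW
        assert lim.vpd_relative_variation(rel, 0.24) == pytest.approx(1.0)
        assert lim.vpd_relative_variation(rel, 1.0) == pytest.approx(0.0)

    def test_convention_invariant_to_line_coefficients(self):
        a = lim.VpdRewRelation(slope=-1.0, intercept=2.0)
        b = lim.VpdRewRelation(slope=-5.0, intercept=7.0)
        grid = np.linspace(0.24, 1.0, 7)
        assert lim.vpd_relative_variation(a, grid) == pytest.approx(
            lim.vpd_relative_variation(b, grid)
        )


class TestCurves:
    def test_all_zero_above_thresholds(self, continuous_fits):
        curves = lim.evaluate_curves(continuous_fits)
        top = curves.table[curves.table.rew > 0.75]
        for col in ("L_gs", "L_gm", "L_vcmax", "L_g1_uso", "L_gm_uso", "L_vcmax_uso"):
            assert np.allclose(top[col], 0.0)

    def test_partition_identity_on_grid(self, continuous_fits):
        curves = lim.evaluate_curves(continuous_fits)
        s = curves.table[["l_gs", "l_gm", "l_vcmax"]].sum(axis=1)
        assert np.allclose(s, 1.0, atol=1e-10)

    def test_crossover_near_printed_value(self):
        curves = lim.evaluate_curves(POTATO_RESPONSE_FITS)
        assert curves.crossover_rew == pytest.approx(0.28, abs=0.03)

    def test_crossover_stable_across_kinetic_basis(self):
        cc = lim.evaluate_curves(POTATO_RESPONSE_FITS, kin=TOBACCO_CC).crossover_rew
        ci = lim.evaluate_curves(POTATO_RESPONSE_FITS, kin=TOBACCO_CI).crossover_rew
        assert abs(cc - ci) < 0.03

    def test_bisection_matches_dense_grid(self, continuous_fits):
        coarse = lim.evaluate_curves(continuous_fits, n_grid=50)
        dense = lim.evaluate_curves(continuous_fits, n_grid=2000)
        tab = dense.table[dense.table.dA_over_A > 0]
        i = int(np.argmin(np.abs(tab.L_gm - tab.L_gs)))
        assert coarse.crossover_rew == pytest.approx(tab.rew.iloc[i], abs=(1.0 - 0.24) / 50)

    def test_identical_gs_gm_fits_no_crossing(self, continuous_fits):
        fits = dict(continuous_fits)
        fits["g_m_25"] = replace(fits["g_s"], variable="g_m_25")
        curves = lim.evaluate_curves(fits)
        assert curves.crossover_rew is None

    def test_grid_below_min_rew_refused(self, continuous_fits):
        with pytest.raises(ValueError):
            lim.evaluate_curves(continuous_fits, rew_grid=np.linspace(0.1, 1.0, 10))

    def test_signs_on_continuous_inputs(self, continuous_fits):
        curves = lim.evaluate_curves(continuous_fits)
        assert (curves.table.L_vpd_uso <= 1e-12).all()
        assert (curves.table.L_g1_uso >= -1e-12).all()

    def test_normalized_contributions_near_monotone_under_full_limitation(
        self, continuous_fits
    ):
        # below every threshold the normalized magnitudes relax as soil rewets
        # (to within ~1% ripple from the varying weight factors)
        curves = lim.evaluate_curves(continuous_fits)
        below = curves.table[curves.table.rew < 0.36]
        for col in (
            "L_gs_norm", "L_gm_norm", "L_vcmax_norm",
            "L_g1_uso_norm", "L_gm_uso_norm", "L_vcmax_uso_norm", "L_vpd_uso_norm",
        ):
            d = np.diff(np.abs(below[col].to_numpy()))
            assert d.max() <= 0.011

    def test_fvcb_consistency_diagnostic_reported(self):
        curves = lim.evaluate_curves(POTATO_RESPONSE_FITS)
        assert "a_consistency" in curves.table.columns
        assert np.isfinite(curves.table.a_consistency).all()
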