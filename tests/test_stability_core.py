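import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from condstab.sequence_features import IonizableCounts, StickerCounts
from condstab.solution_model import SolutionCondition, salt_ions
from condstab.stability_core import (
    FloryHugginsState,
    InteractionParameters,
    R_KJ,
    charge_optimum,
    composition_objective,
    composition_optimum,
    dgsat_from_concentrations,
    dilute_from_ka,
    effective_sticker_counts,
    flory_huggins_ddg,
    flory_huggins_dg,
    interaction_ratio_estimates,
    ka_from_concentrations,
    optimal_pH,
    parabola_coefficients,
    predict_dgsat,
)

ZERO_SALT = InteractionParameters(
    dG0_FGRG=0.3, dG0_pp=-0.05, dG0_nn=-0.08, dG0_pn=0.046,
    r0_FGRG=0.0, r0_pp=0.0, r0_nn=0.0, r0_pn=0.0, eps_r=47.0,
)


def series_ctot(c1_M: float, ka: float, n_terms: int = 10**6) -> float:
    """Brute-force isodesmic series: ctot = sum_i i*(c1*Ka)^(i-1)*c1."""
    x = c1_M * ka
    i = np.arange(1, n_terms + 1, dtype=float)
    return float(np.sum(i * x ** (i - 1)) * c1_M)


class TestPolymerizationModel:
    def test_no_condensate_gives_zero_ka(self):
        with pytest.warns(UserWarning, match="no condensate"):
            assert ka_from_concentrations(100.0, 100.0) == 0.0

    def test_hand_value(self):
        ka = ka_from_concentrations(100.0, 200.0)
        assert ka == pytest.approx(1e4 - 1 / math.sqrt(2e-8), rel=1e-12)
        assert ka == pytest.approx(2928.9, abs=0.1)

    def test_large_excess_limit(self):
        ka = ka_from_concentrations(1.0, 1e6)
        assert ka == pytest.approx((1 - 1e-3) / 1e-6, rel=1e-12)

    def test_c1_above_ctot_rejected(self):
        with pytest.raises(ValueError):
            ka_from_concentrations(2.0, 1.0)

    def test_round_trip_hand_example(self):
        ka = ka_from_concentrations(100.0, 200.0)
        assert dilute_from_ka(ka, 200.0) == pytest.approx(100.0, rel=1e-10)

    def test_zero_ka_returns_ctot(self):
        assert dilute_from_ka(0.0, 170.0) == pytest.approx(170.0)

    @given(
        c1=st.floats(1e-3, 1e3),
        ratio=st.floats(1.0 + 1e-6, 1e6),
    )
    @settings(max_examples=60, deadline=None)
    def test_mutual_inverses(self, c1, ratio):
        ctot = c1 * ratio
        ka = ka_from_concentrations(c1, ctot)
        assert dilute_from_ka(ka, ctot) == pytest.approx(c1, rel=1e-10)

    def test_truncated_series_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            c1 = float(rng.uniform(1.0, 150.0))
            ctot = c1 * float(rng.uniform(1.5, 50.0))
            ka = ka_from_concentrations(c1, ctot)
            assert series_ctot(c1 * 1e-6, ka) * 1e6 == pytest.approx(
                ctot, rel=1e-8
            )

    def test_dgsat_hand_value(self):
        assert dgsat_from_concentrations(100.0, 200.0, T=295.15) == pytest.approx(
            R_KJ * 295.15 * math.log(2928.932188), abs=1e-6
        )
        assert dgsat_from_concentrations(100.0, 200.0) == pytest.approx(19.6, abs=0.05)

    def test_standard_state_reference(self):
        # Ka*c0 = 1: pick c1 so that 1/c1 - 1/sqrt(c1*ctot) = 1 M^-1
        ctot = 1e6  # uM
        from scipy.optimize import brentq

        c1 = brentq(lambda c: ka_from_concentrations(c, ctot) - 1.0, 1e5, 1e6 - 1)
        assert dgsat_from_concentrations(c1, ctot) == pytest.approx(0.0, abs=1e-6)


class TestFloryHuggins:
    def test_equal_states_have_zero_difference(self):
        s = FloryHugginsState(chi=1.2, phi1b=0.3, N1=200, V0=0.1)
        assert flory_huggins_ddg(s, s) == 0.0

    def test_general_difference_equals_two_evaluations(self):
        a = FloryHugginsState(chi=1.2, phi1b=0.3, N1=200, V0=0.1)
        b = FloryHugginsState(chi=1.1, phi1b=0.25, N1=200, V0=0.1)
        assert flory_huggins_ddg(a, b) == pytest.approx(
            flory_huggins_dg(a) - flory_huggins_dg(b), abs=1e-12
        )

    def test_equal_phi_closed_form(self):
        a = FloryHugginsState(chi=1.2, phi1b=0.3, N1=200, V0=0.1)
        b = FloryHugginsState(chi=1.1, phi1b=0.3, N1=200, V0=0.1)
        assert flory_huggins_ddg(a, b, T=300.0) == pytest.approx(
            2 * (1.2 - 1.1) * R_KJ * 300.0 * 0.3 * 200, rel=1e-12
        )

    def test_ideal_monomer_limit(self):
        s = FloryHugginsState(chi=0.0, phi1b=0.3, N1=1, V0=0.05)
        assert flory_huggins_dg(s, T=300.0) == pytest.approx(
            -R_KJ * 300.0 * math.log(0.3 / 0.05), rel=1e-12
        )

    def test_invalid_volume_fraction_rejected(self):
        with pytest.raises(ValueError):
            FloryHugginsState(chi=1.0, phi1b=1.5, N1=10, V0=0.1)


class TestPredictDgsat:
    def test_zero_energies_give_zero(self):
        params = InteractionParameters(
            dG0_FGRG=0.0, dG0_pp=0.0, dG0_nn=0.0, dG0_pn=0.0,
            r0_FGRG=0.0, r0_pp=0.0, r0_nn=0.0, r0_pn=0.0, eps_r=47.0,
        )
        s = StickerCounts(x_FG=10, x_RG=10, x_p=5.0, x_n=5.0)
        cond = SolutionCondition(pH=7.0)
        assert predict_dgsat(s, cond, params, screening=False) == 0.0

    def test_charge_free_chain_is_pure_cation_pi(self):
        s = StickerCounts(x_FG=10, x_RG=12, x_p=0.0, x_n=0.0)
        cond = SolutionCondition(pH=7.0, ions=tuple(salt_ions("Na", 1, 150.0)))
        got = predict_dgsat(s, cond, ZERO_SALT, screening=False)
        assert got == pytest.approx(10 * 12 * ZERO_SALT.dG0_FGRG, rel=1e-12)

    def test_restricted_model_is_exactly_the_parabola(self):
        x_fg, x_rg, x_p = 14, 14, 32.0
        alpha, beta, gamma = parabola_coefficients(x_fg, x_rg, x_p, ZERO_SALT)
        cond = SolutionCondition(pH=7.0)
        for x_n in np.linspace(0.0, 40.0, 41):
            q = x_p - x_n
            s = StickerCounts(x_FG=x_fg, x_RG=x_rg, x_p=x_p, x_n=float(x_n))
            direct = predict_dgsat(s, cond, ZERO_SALT, screening=False)
            assert direct == pytest.approx(
                alpha + beta * q + gamma * q**2, abs=1e-12
            )

    def test_monovalent_salt_destabilizes_cation_pi_dominated_chain(self):
        params = InteractionParameters(
            dG0_FGRG=1.0, dG0_pp=0.0, dG0_nn=0.0, dG0_pn=0.0,
            r0_FGRG=5e-10, r0_pp=0.0, r0_nn=0.0, r0_pn=0.0, eps_r=47.0,
        )
        s = StickerCounts(x_FG=14, x_RG=14, x_p=32.0, x_n=36.0)
        prev = math.inf
        for na in (0.0, 10.0, 30.0, 100.0, 300.0):
            cond = SolutionCondition(pH=8.0, ions=tuple(salt_ions("Na", 1, 150.0 + na)))
            val = predict_dgsat(s, cond, params, screening=True)
            assert val < prev
            prev = val

    def test_divalent_binding_stabilizes_overly_negative_chain(
        self, true_params, saline_condition, reference_counts
    ):
        base = StickerCounts(x_FG=14, x_RG=14, x_p=32.0, x_n=36.0)
        with_ca = replace(
            saline_condition,
            ions=tuple(saline_condition.ions) + tuple(salt_ions("Ca", 2, 10.0)),
        )
        dg_ctrl = predict_dgsat(
            effective_sticker_counts(base, reference_counts, saline_condition,
                                     true_params),
            saline_condition, true_params,
        )
        dg_ca = predict_dgsat(
            effective_sticker_counts(base, reference_counts, with_ca, true_params),
            with_ca, true_params,
        )
        assert dg_ca > dg_ctrl


class TestAnalyticOptima:
    def test_gamma_is_half_nn_energy(self):
        _, _, gamma = parabola_coefficients(14, 14, 32.0, ZERO_SALT)
        assert gamma == ZERO_SALT.dG0_nn / 2

    def test_no_repulsion_no_interior_optimum(self):
        params = replace(ZERO_SALT, dG0_nn=0.0)
        _, _, gamma = parabola_coefficients(14, 14, 32.0, params)
        assert gamma == 0.0

    def test_vertex_matches_numeric_argmax(self):
        alpha, beta, gamma = parabola_coefficients(14, 14, 32.0, ZERO_SALT)
        qs = np.linspace(-40, 40, 400001)
        numeric = qs[np.argmax(alpha + beta * qs + gamma * qs**2)]
        assert -beta / (2 * gamma) == pytest.approx(numeric, abs=1e-3)

    def test_published_charge_optimum(self):
        q_opt, _ = charge_optimum(32.0, -0.578125)
        assert q_opt == pytest.approx(13.0, abs=1e-12)

    def test_cancellation_limit(self):
        q_opt, _ = charge_optimum(32.0, -1.0)
        assert q_opt == -0.5

    def test_published_acid_count_optimum(self):
        _, xn_opt = charge_optimum(32.0, -35.0 / 64.0)
        assert xn_opt == pytest.approx(18.0, abs=1e-12)

    def test_ratio_from_charge_optimum(self):
        ratio = interaction_ratio_estimates("from_qopt", x_p=32, Q_opt=13)
        assert ratio == pytest.approx(-0.578125, abs=1e-12)
        assert ratio == pytest.approx(-0.57, abs=0.01)

    def test_ratio_from_ph_optimum_at_pka(self):
        ratio = interaction_ratio_estimates(
            "from_phopt", x_p=32, pKa=4.25, pH_opt=4.25, x_n0=36
        )
        assert ratio == pytest.approx((1 - 36) / 64, abs=1e-12)
        assert ratio == pytest.approx(-0.55, abs=0.005)

    def test_single_acid_gives_zero_ratio(self):
        ratio = interaction_ratio_estimates(
            "from_phopt", x_p=32, pKa=4.25, pH_opt=4.25, x_n0=1
        )
        assert ratio == 0.0

    def test_round_trip_ratio_to_optimum(self):
        ratio = interaction_ratio_estimates("from_qopt", x_p=32, Q_opt=13)
        q_opt, _ = charge_optimum(32.0, ratio)
        assert q_opt == pytest.approx(13.0, abs=1e-12)


class TestCompositionOptimum:
    def test_closed_form_matches_grid_refinement(self):
        A, B, C, x_fg = 20.0, 3.0, 3.0, 10.0
        xp_opt, xn_opt, q_opt, kind = composition_optimum(A, B, C, x_fg)
        assert kind == "max"
        # coarse grid then local quadratic refinement via dense local grid
        xs = np.linspace(xp_opt - 1, xp_opt + 1, 2001)
        ys = np.linspace(xn_opt - 1, xn_opt + 1, 2001)
        xx, yy = np.meshgrid(xs, ys)
        zz = composition_objective(xx, yy, A, B, C, x_fg)
        i, j = np.unravel_index(np.argmax(zz), zz.shape)
        assert xx[i, j] == pytest.approx(xp_opt, abs=1e-3)
        assert yy[i, j] == pytest.approx(xn_opt, abs=1e-3)
        assert q_opt == pytest.approx(xp_opt - xn_opt, abs=1e-12)

    def test_stationary_point_satisfies_gradient(self):
        A, B, C, x_fg = 5.0, 2.0, 4.0, 8.0
        xp_opt, xn_opt, _, _ = composition_optimum(A, B, C, x_fg)
        eps = 1e-6
        f = composition_objective
        gx = (f(xp_opt + eps, xn_opt, A, B, C, x_fg)
              - f(xp_opt - eps, xn_opt, A, B, C, x_fg)) / (2 * eps)
        gy = (f(xp_opt, xn_opt + eps, A, B, C, x_fg)
              - f(xp_opt, xn_opt - eps, A, B, C, x_fg)) / (2 * eps)
        assert gx == pytest.approx(0.0, abs=1e-6)
        assert gy == pytest.approx(0.0, abs=1e-6)

    def test_weak_repulsions_give_saddle(self):
        _, _, _, kind = composition_optimum(20.0, 0.5, 0.5, 10.0)
        assert kind == "saddle"

    def test_degenerate_ratios_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            composition_optimum(20.0, 2.0, 0.5, 10.0)


class TestOptimalPh:
    def _counts(self, n_asp: int) -> IonizableCounts:
        return IonizableCounts(counts={"Asp": n_asp, "Arg": 26, "Lys": 6})

    def test_matches_closed_form_for_single_acid_type(self):
        # all acids share pKa 4.0: interior optimum at
        # pH = pKa - log10(x_n0/x_n_opt - 1)
        counts = self._counts(36)
        base = StickerCounts(x_FG=14, x_RG=14, x_p=32.0, x_n=36.0)
        ratio = ZERO_SALT.dG0_pn / ZERO_SALT.dG0_nn
        xn_opt = 0.5 - 32.0 * ratio
        expected = 4.0 - math.log10(36.0 / xn_opt - 1.0)
        got = optimal_pH(base, counts, ZERO_SALT)
        assert got == pytest.approx(expected, abs=1e-3)
        # consistency: the pH-optimum ratio estimate recovers the ratio
        back = interaction_ratio_estimates(
            "from_phopt", x_p=32.0, pKa=4.0, pH_opt=got, x_n0=36.0
        )
        assert back == pytest.approx(ratio, abs=1e-3)

    def test_pure_attraction_pushes_to_high_ph_boundary(self):
        # no n/n repulsion: more acid charge always helps, so the optimum
        # sits at the top of the scanned range (Arg-only positives keep
        # x_p essentially constant below pH 8)
        params = replace(ZERO_SALT, dG0_nn=0.0, dG0_pn=0.1)
        counts = IonizableCounts(counts={"Asp": 36, "Arg": 32})
        base = StickerCounts(x_FG=14, x_RG=14, x_p=32.0, x_n=36.0)
        got = optimal_pH(base, counts, params, pH_grid=np.linspace(2, 8, 61))
        assert got == pytest.approx(8.0, abs=0.01)
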