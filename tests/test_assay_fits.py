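import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from condstab.assay_fits import (
    CspRecord,
    FrapFit,
    FrapTrace,
    PartitionMeasurement,
    TitrationCurve,
    csp,
    fit_binding_curve,
    fit_competition,
    fit_frap,
    ki_from_ic50,
    partition_energy,
    random_coil_deviation,
    select_significant,
)
from condstab.stability_core import R_KJ
from condstab.synthetic_data import NoiseSpec, generate_frap_trace, generate_titration


class TestCsp:
    def test_zero_shifts(self):
        assert csp(0.0, 0.0) == 0.0

    def test_hand_value(self):
        assert csp(0.02, 0.1) == pytest.approx(0.025)

    def test_nitrogen_only(self):
        assert csp(0.0, 0.3) == pytest.approx(0.045)

    @given(dh=st.floats(-1, 1), dn=st.floats(-5, 5))
    @settings(max_examples=40, deadline=None)
    def test_sign_invariance(self, dh, dn):
        assert csp(dh, dn) == pytest.approx(csp(-dh, -dn), abs=1e-15)
        assert csp(dh, dn) >= 0


class TestBindingCurve:
    def test_forward_model_value(self):
        # dS=0.1, Kd=150, A=0.02, B=150: bound fraction ~ 0.5
        curve = generate_titration(
            "binding", xs=[1.0, 150.0, 600.0], noise=NoiseSpec(sigma_obs=0.0),
            Kd=150.0, A_conc=0.02, amplitude=0.1, offset=0.0,
        )
        assert curve.y[1] == pytest.approx(0.050, abs=0.0005)

    def test_noiseless_recovery(self):
        xs = np.geomspace(1.0, 600.0, 12)
        curve = generate_titration("binding", xs=xs,
                                   noise=NoiseSpec(sigma_obs=0.0, seed=1),
                                   Kd=119.0, amplitude=0.08, offset=0.01)
        fit = fit_binding_curve(curve)
        assert fit.Kd == pytest.approx(119.0, rel=1e-6)
        assert fit.amplitude == pytest.approx(0.08, rel=1e-6)
        assert fit.offset == pytest.approx(0.01, rel=1e-4)

    def test_many_random_parameter_draws_recovered(self):
        rng = np.random.default_rng(8)
        xs = np.geomspace(0.5, 900.0, 14)
        for _ in range(50):
            kd = float(rng.uniform(20, 500))
            amp = float(rng.uniform(0.02, 0.3))
            off = float(rng.uniform(-0.05, 0.05))
            curve = generate_titration(
                "binding", xs=xs, noise=NoiseSpec(sigma_obs=0.0),
                Kd=kd, amplitude=amp, offset=off,
            )
            fit = fit_binding_curve(curve)
            assert fit.Kd == pytest.approx(kd, rel=1e-4)
            assert fit.amplitude == pytest.approx(amp, rel=1e-4)

    def test_noisy_recovery_within_bootstrap_interval(self):
        xs = np.geomspace(1.0, 600.0, 16)
        curve = generate_titration("binding", xs=xs,
                                   noise=NoiseSpec(sigma_obs=0.002, seed=5),
                                   Kd=120.0, amplitude=0.1, offset=0.0)
        fit = fit_binding_curve(curve, bootstrap_reps=200, seed=5)
        lo, hi = fit.err["Kd"]
        assert lo < 120.0 < hi


class TestRandomCoilDeviation:
    def test_no_movement(self):
        assert random_coil_deviation(8.3, 8.2, 8.2, 120.0, 118.0, 118.0) == 0.0

    def test_full_convergence_to_reference(self):
        got = random_coil_deviation(8.3, 8.2, 8.3, 120.0, 118.0, 120.0)
        assert got == pytest.approx(0.5 * (0.1 + 0.15 * 2.0))

    def test_mixed_case_hand_value(self):
        got = random_coil_deviation(8.30, 8.20, 8.26, 120.0, 118.5, 119.2)
        expected = 0.5 * ((0.10 - 0.04) + 0.15 * (1.5 - 0.8))
        assert got == pytest.approx(expected, abs=1e-12)


class TestSelectSignificant:
    def test_strict_threshold(self):
        records = [CspRecord(1, 0.01, 0, 0.01), CspRecord(2, 0.025, 0, 0.025),
                   CspRecord(3, 0.02, 0, 0.02)]
        kept = select_significant(records)
        assert [r.residue for r in kept] == [2]

    def test_empty_input(self):
        assert select_significant([]) == []

    def test_synthetic_profile_selects_acidic_clusters(self):
        records, curves = generate_titration(
            "csp", xs=[3.3, 10.0, 30.0, 100.0, 300.0],
            noise=NoiseSpec(sigma_obs=0.0, seed=3),
        )
        selected = {r.residue for r in select_significant(records)}
        in_cluster = {res for res, c in curves.items() if c.meta["in_cluster"]}
        assert selected  # some residues respond
        assert selected <= in_cluster  # responders sit in negative regions


class TestCompetition:
    def test_limits(self):
        xs = np.geomspace(0.001, 10.0, 12)
        curve = generate_titration("competition", xs=xs,
                                   noise=NoiseSpec(sigma_obs=0.0),
                                   IC50=0.2, hill_n=1.0, F0=1e5, dF=9e5)
        # C -> 0 approaches F0 + dF; C = IC50 gives F0 + dF/2 (n = 1)
        assert curve.y[0] == pytest.approx(1e6, rel=1e-2)
        mid = 1e5 + 9e5 * (1 + 0.2 / 0.2) ** -1
        assert mid == 1e5 + 4.5e5

    def test_noiseless_recovery_with_fractional_hill(self):
        xs = np.geomspace(0.001, 50.0, 16)
        curve = generate_titration("competition", xs=xs,
                                   noise=NoiseSpec(sigma_obs=0.0),
                                   IC50=0.35, hill_n=1.3, F0=2e5, dF=7e5)
        fit = fit_competition(curve)
        assert fit.IC50 == pytest.approx(0.35, rel=1e-6)
        assert fit.n == pytest.approx(1.3, rel=1e-6)


class TestKiFromIc50:
    def test_no_probe_ligand(self):
        assert ki_from_ic50(200.0, 0.0, 100.0) == 200.0

    def test_hand_value(self):
        assert ki_from_ic50(200.0, 100.0, 100.0) == pytest.approx(100.0)

    def test_published_mean_affinity(self):
        assert np.mean([93.0, 145.0]) == pytest.approx(119.0)


class TestFrap:
    TRUTH = FrapFit(Rtot=0.95, A1=0.3, A2=0.25, r1=0.5, r2=0.05)

    def test_time_zero_and_plateau(self):
        f = self.TRUTH
        assert f.Rtot - f.A1 - f.A2 == pytest.approx(0.40)

    def test_noiseless_recovery(self):
        times = np.arange(0.0, 180.0, 2.0)
        trace = generate_frap_trace(self.TRUTH, times,
                                    noise=NoiseSpec(sigma_obs=0.0, seed=2))
        fit = fit_frap(trace)
        assert fit.Rtot == pytest.approx(0.95, rel=1e-4)
        assert fit.r1 == pytest.approx(0.5, rel=1e-3)
        assert fit.r2 == pytest.approx(0.05, rel=1e-3)

    def test_noisy_recovery_of_slow_fraction(self):
        times = np.arange(0.0, 180.0, 2.0)
        trace = generate_frap_trace(self.TRUTH, times,
                                    noise=NoiseSpec(sigma_obs=0.01, seed=4))
        fit = fit_frap(trace)
        truth_slow = self.TRUTH.slow_fraction
        assert fit.slow_fraction == pytest.approx(truth_slow, rel=0.10)

    def test_amplitude_bookkeeping_at_fit(self):
        times = np.arange(0.0, 120.0, 2.0)
        trace = generate_frap_trace(self.TRUTH, times,
                                    noise=NoiseSpec(sigma_obs=0.0, seed=2))
        fit = fit_frap(trace)
        r0 = fit.Rtot - fit.A1 - fit.A2  # model value at t = 0
        assert fit.Rtot - r0 == pytest.approx(fit.A1 + fit.A2, abs=1e-12)

    def test_rate_ordering_enforced(self):
        times = np.arange(0.0, 120.0, 2.0)
        trace = generate_frap_trace(self.TRUTH, times,
                                    noise=NoiseSpec(sigma_obs=0.005, seed=6))
        fit = fit_frap(trace)
        assert fit.r1 >= fit.r2

    def test_too_few_points_rejected(self):
        trace = FrapTrace(t=(0.0, 1.0, 2.0, 3.0, 4.0), recovery=(0.4,) * 5)
        with pytest.raises(ValueError, match="post-bleach"):
            fit_frap(trace)


class TestPartition:
    def test_unit_ratio_is_zero_energy(self):
        m = PartitionMeasurement(I_in=100.0, I_out=100.0)
        assert partition_energy(m) == 0.0

    def test_tenfold_enrichment(self):
        m = PartitionMeasurement(I_in=1000.0, I_out=100.0, T=295.15)
        assert partition_energy(m) == pytest.approx(
            R_KJ * 295.15 * math.log(10.0), abs=1e-9
        )
        assert partition_energy(m) == pytest.approx(5.65, abs=0.01)

    def test_excluded_species_is_negative(self):
        m = PartitionMeasurement(I_in=50.0, I_out=100.0)
        assert partition_energy(m) < 0

    def test_background_subtraction(self):
        m = PartitionMeasurement(I_in=1100.0, I_out=200.0, bg_in=100.0,
                                 bg_out=100.0)
        assert m.Kp == pytest.approx(10.0)

    def test_background_exceeding_signal_rejected(self):
        with pytest.raises(ValueError):
            PartitionMeasurement(I_in=90.0, I_out=100.0, bg_in=100.0)

    def test_in_cell_temperature(self):
        m = PartitionMeasurement(I_in=1000.0, I_out=100.0, T=310.15)
        assert partition_energy(m) == pytest.approx(
            R_KJ * 310.15 * math.log(10.0), abs=1e-9
        )
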