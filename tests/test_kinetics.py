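"""Core propagator: bolus input, free evolution oracles, RF, fingerprints."""

import numpy as np
import pytest
from scipy.linalg import expm

from hpmrf.kinetics import (
    Fingerprint,
    MagnetizationState,
    apply_rf,
    bolus_input_rate,
    evolve_free,
    gamma_scale,
    isochromat_offsets,
    simulate_fingerprint,
    simulate_signal_batch,
)
from hpmrf.params import BolusParams, FieldConditions, KineticParams
from hpmrf.sequences import build_schedule


def system_matrix(kin, f_pyr, f_lac):
    """Independent 6x6 Bloch-McConnell generator (oracle construction)."""
    k = kin.kPL
    wp, wl = 2 * np.pi * f_pyr, 2 * np.pi * f_lac
    A = np.zeros((6, 6))
    A[0, 0] = A[1, 1] = -1 / kin.T2_pyr - k
    A[0, 1], A[1, 0] = wp, -wp
    A[2, 2] = -1 / kin.T1_pyr - k
    A[3, 3] = A[4, 4] = -1 / kin.T2_lac
    A[3, 4], A[4, 3] = wl, -wl
    A[5, 5] = -1 / kin.T1_lac
    A[3, 0] = A[4, 1] = A[5, 2] = k  # one-way exchange on all components
    return A


class TestBolusInput:
    def test_zero_before_arrival(self):
        b = BolusParams()
        assert bolus_input_rate(b.t_arrival - 1.0, b) == 0.0
        assert bolus_input_rate(b.t_arrival, b) == 0.0

    def test_rate_is_nonnegative_and_normalized(self):
        b = BolusParams()
        t = np.linspace(b.t_arrival, b.t_arrival + b.t_duration, 12001)
        u = bolus_input_rate(t, b)
        assert np.all(u >= 0)
        assert np.trapezoid(u, t) >= 0.99 - 1e-4  # 0.99 by construction, minus quadrature error

    def test_fraction_delivered_before_acquisition_start(self):
        # trapezoid quadrature at 1 ms of the gamma rate over [-4, 0):
        # shape 2, scale chosen so 99% falls within the 12 s duration
        b = BolusParams()
        t = np.arange(b.t_arrival, 0.0, 1e-3)
        frac = np.trapezoid(bolus_input_rate(t, b), t)
        assert frac == pytest.approx(0.6485, abs=2e-3)

    def test_gamma_scale_puts_99pct_inside_duration(self):
        for dur in (6.0, 12.0, 20.0):
            b = BolusParams(t_duration=dur)
            t = np.linspace(b.t_arrival, b.t_arrival + dur, 20001)
            assert np.trapezoid(bolus_input_rate(t, b), t) == pytest.approx(0.99, abs=1e-4)

    def test_invalid_bolus_rejected(self):
        with pytest.raises(ValueError):
            BolusParams(t_duration=-1.0)


class TestEvolveFree:
    def test_negative_dt_rejected(self, no_bolus, small_cond):
        with pytest.raises(ValueError):
            evolve_free(MagnetizationState.zeros(5), -0.1, KineticParams(), no_bolus, small_cond)

    def test_pure_t1_decay(self, no_bolus):
        kin = KineticParams(kPL=0.0)
        cond = FieldConditions(n_isochromats=1, linewidth_fwhm=0.0)
        state = MagnetizationState.zeros(1)
        state.M[0, 2] = 1.0
        out = evolve_free(state, kin.T1_pyr, kin, no_bolus, cond)
        assert out.M[0, 2] == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_one_way_exchange_closed_form_without_relaxation(self, no_bolus):
        kin = KineticParams(kPL=0.03, T1_pyr=np.inf, T1_lac=np.inf,
                            T2_pyr=np.inf, T2_lac=np.inf)
        cond = FieldConditions(n_isochromats=1, linewidth_fwhm=0.0)
        state = MagnetizationState.zeros(1)
        state.M[0, 2] = 1.0
        dt = 7.3
        out = evolve_free(state, dt, kin, no_bolus, cond)
        assert out.M[0, 2] == pytest.approx(np.exp(-kin.kPL * dt), rel=1e-12)
        assert out.M[0, 2] + out.M[0, 5] == pytest.approx(1.0, abs=1e-12)

    def test_longitudinal_conservation_with_bolus_inflow(self):
        # zero relaxation: Mz_pyr + Mz_lac must track the delivered input exactly
        kin = KineticParams(kPL=0.05, T1_pyr=np.inf, T1_lac=np.inf,
                            T2_pyr=np.inf, T2_lac=np.inf)
        bolus = BolusParams()
        cond = FieldConditions(n_isochromats=1, linewidth_fwhm=0.0)
        state = MagnetizationState.zeros(1)
        out, delivered = evolve_free(
            state, 20.0, kin, bolus, cond, t0=bolus.t_arrival, return_input=True
        )
        total_z = out.M[0, 2] + out.M[0, 5]
        assert abs(total_z - delivered) <= 1e-9

    def test_matches_scipy_matrix_exponential(self, no_bolus):
        # full-system oracle, including the 392 Hz lactate shift
        rng = np.random.default_rng(11)
        cond = FieldConditions(n_isochromats=1, linewidth_fwhm=0.0, b0_offset=3.0)
        for _ in range(5):
            kin = KineticParams(
                kPL=rng.uniform(0, 0.1),
                T1_pyr=rng.uniform(10, 40), T1_lac=rng.uniform(10, 40),
                T2_pyr=rng.uniform(0.2, 2), T2_lac=rng.uniform(0.2, 2),
            )
            state = MagnetizationState(rng.standard_normal((1, 6)))
            dt = rng.uniform(0.001, 0.5)
            A = system_matrix(kin, kin.omega_pyr + cond.b0_offset,
                              kin.omega_lac + cond.b0_offset)
            expected = expm(A * dt) @ state.M[0]
            out = evolve_free(state, dt, kin, no_bolus, cond)
            np.testing.assert_allclose(out.M[0], expected, rtol=0, atol=1e-10)

    def test_matches_fine_step_euler_with_bolus(self):
        # forward-Euler oracle at 10 us including the exact gamma inflow;
        # run on-resonance with gentle relaxation rates, where the oracle's
        # own O(h) truncation error stays below the comparison tolerance
        kin = KineticParams(kPL=0.04, omega_lac=0.0, T2_pyr=5.0, T2_lac=8.0)
        bolus = BolusParams()
        cond = FieldConditions(n_isochromats=1, linewidth_fwhm=0.0)
        state = MagnetizationState(np.array([[0.1, -0.05, 0.4, 0.02, 0.01, 0.05]]))
        t0, dt = -1.0, 0.1
        out = evolve_free(state, dt, kin, bolus, cond, t0=t0)
        A = system_matrix(kin, 0.0, 0.0)
        h = 1e-5
        M = state.M[0].copy()
        for i in range(int(round(dt / h))):
            t = t0 + i * h
            dM = A @ M
            dM[2] += bolus_input_rate(t + h / 2, bolus)
            M = M + h * dM
        np.testing.assert_allclose(out.M[0], M, rtol=1e-6, atol=1e-9)


class TestApplyRF:
    def test_zero_flip_is_identity(self, small_cond):
        state = MagnetizationState(np.random.default_rng(0).standard_normal((5, 6)))
        out = apply_rf(state, 0.0, 0.0, "pyruvate", small_cond)
        np.testing.assert_allclose(out.M, state.M)

    def test_90_degree_excitation(self):
        cond = FieldConditions(n_isochromats=1)
        state = MagnetizationState.zeros(1)
        state.M[0, 2] = 1.0
        out = apply_rf(state, 90.0, 0.0, "pyruvate", cond)
        assert np.hypot(out.M[0, 0], out.M[0, 1]) == pytest.approx(1.0, abs=1e-12)
        assert out.M[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_b1_scale_equivalence(self):
        state = MagnetizationState(np.random.default_rng(1).standard_normal((1, 6)))
        a = apply_rf(state, 30.0, 45.0, "lactate", FieldConditions(n_isochromats=1, b1_scale=1.2))
        b = apply_rf(state, 36.0, 45.0, "lactate", FieldConditions(n_isochromats=1, b1_scale=1.0))
        np.testing.assert_allclose(a.M, b.M, atol=1e-14)

    def test_untargeted_pool_untouched(self, small_cond):
        state = MagnetizationState(np.random.default_rng(2).standard_normal((5, 6)))
        out = apply_rf(state, 37.0, 10.0, "pyruvate", small_cond)
        np.testing.assert_allclose(out.M[:, 3:], state.M[:, 3:])

    def test_unknown_target_rejected(self, small_cond):
        with pytest.raises(ValueError):
            apply_rf(MagnetizationState.zeros(5), 30.0, 0.0, "urea", small_cond)


class TestSpoiledGREClosedForm:
    def test_longitudinal_loss_is_cos_theta_power_n(self, no_bolus):
        # n spoiled excitations at spacing TR: Mz -> Mz cos(theta)^n exp(-n TR/T1)
        kin = KineticParams(kPL=0.0)
        cond = FieldConditions(n_isochromats=1, linewidth_fwhm=0.0)
        theta, tr, n = 10.0, 1.0, 7
        state = MagnetizationState.zeros(1)
        state.M[0, 2] = 1.0
        for _ in range(n):
            state = apply_rf(state, theta, 0.0, "pyruvate", cond)
            state = evolve_free(state, tr, kin, no_bolus, cond)
            state.M[0, :2] = 0.0  # spoil
        expected = np.cos(np.deg2rad(theta)) ** n * np.exp(-n * tr / kin.T1_pyr)
        assert state.M[0, 2] == pytest.approx(expected, rel=1e-12)


class TestIsochromats:
    def test_center_isochromat_on_resonance(self):
        offs = isochromat_offsets(5.0, 101)
        assert offs[50] == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(offs, -offs[::-1], atol=1e-12)

    def test_zero_linewidth_collapses_to_delta(self):
        assert np.all(isochromat_offsets(0.0, 101) == 0.0)

    def test_offsets_bounded_by_truncation(self):
        offs = isochromat_offsets(5.0, 101)
        assert np.all(np.abs(offs) <= 3 * 5.0 + 1e-9)


class TestSimulateFingerprint:
    def test_no_conversion_means_zero_lactate(self, short_schedule):
        fp = simulate_fingerprint(
            short_schedule, KineticParams(kPL=0.0),
            cond=FieldConditions(n_isochromats=5),
        )
        assert np.all(fp.lac == 0)
        assert np.all(np.abs(fp.pyr) > 0)

    def test_linearity_in_total_input(self, short_schedule):
        sig, _, _ = simulate_signal_batch(
            short_schedule, KineticParams(kPL=0.02),
            cond=FieldConditions(n_isochromats=5),
            total_input=np.array([1.0, 2.0]),
        )
        np.testing.assert_allclose(sig[1], 2.0 * sig[0], rtol=1e-12)

    def test_zero_linewidth_limit_matches_single_isochromat(self, short_schedule):
        kin = KineticParams(kPL=0.02)
        a, _, _ = simulate_signal_batch(
            short_schedule, kin, cond=FieldConditions(n_isochromats=1, linewidth_fwhm=0.0)
        )
        b, _, _ = simulate_signal_batch(
            short_schedule, kin, cond=FieldConditions(n_isochromats=101, linewidth_fwhm=1e-9)
        )
        np.testing.assert_allclose(a, b, rtol=1e-6)

    @pytest.mark.parametrize("kpl", [0.01, 0.02])
    def test_sigmoid_design_delays_pyruvate_peak(self, kpl):
        kin = KineticParams(kPL=kpl)
        t_peak = {}
        for design in ("mrf_constant", "mrf_sigmoid"):
            fp = simulate_fingerprint(build_schedule(design), kin)
            t_peak[design] = fp.times[np.argmax(np.abs(fp.pyr))]
        assert t_peak["mrf_sigmoid"] > t_peak["mrf_constant"]

    def test_fingerprint_export_round_trip(self, short_schedule, tmp_path):
        fp = simulate_fingerprint(
            short_schedule, KineticParams(kPL=0.02), cond=FieldConditions(n_isochromats=3)
        )
        df = fp.to_dataframe()
        assert list(df.columns) == ["time_s", "metabolite", "real", "imag"]
        assert len(df) == len(fp.signal)
        fp.to_csv(tmp_path / "fp.csv")
        fp.to_hdf5(tmp_path / "fp.h5")
        import h5py

        with h5py.File(tmp_path / "fp.h5") as h:
            np.testing.assert_allclose(h["fingerprint/signal"][:], fp.signal)

    def test_catalyzation_ramp_damps_transient_oscillation(self, no_bolus):
        # on a kPL = 0 state, ramped preparation reduces the peak-to-peak
        # echo variation over the first imaging TRs relative to no ramp
        kin = KineticParams(kPL=0.0, omega_lac=0.0)
        cond = FieldConditions(n_isochromats=1, linewidth_fwhm=0.0)
        tr, flip = 0.0156, 60.0

        def echoes(n_cat):
            from hpmrf.sequences import catalyzation_ramp

            state = MagnetizationState.zeros(1)
            state.M[0, 2] = 1.0
            ramp = list(catalyzation_ramp(flip, n_cat)) if n_cat else []
            out = []
            for i, f in enumerate(ramp + [flip] * 5):
                phase = 180.0 * (i % 2)
                state = apply_rf(state, f, phase, "pyruvate", cond)
                state = evolve_free(state, tr / 2, kin, no_bolus, cond)
                if i >= len(ramp):
                    out.append(np.hypot(state.M[0, 0], state.M[0, 1]))
                state = evolve_free(state, tr / 2, kin, no_bolus, cond)
            return np.array(out)

        ptp_ramped = np.ptp(echoes(10))
        ptp_abrupt = np.ptp(echoes(0))
        assert ptp_ramped < ptp_abrupt
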