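"""Tracer kinetics: forward convolution against independent oracles,
signal/concentration conversion round trips, AIF extraction, voxel fits."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.interpolate import interp1d

from lungdce import AcquisitionProtocol
from lungdce.io import VolumeSeries
from lungdce.kinetics import (ConcentrationSeries, PlasmaCurve,
                              exp_convolution, extended_tofts_forward,
                              extract_aif, fit_extended_tofts,
                              signal_to_concentration)
from lungdce.phantom import population_aif
from lungdce.relaxometry import T1FitResult, spgr_signal


def brute_force_tofts(ktrans, ve, vp, times_sec, cp, refine=100):
    """Independent oracle: trapezoidal convolution on a 100x refined uniform
    grid (FFT-accelerated; endpoint-corrected rectangle rule = trapezoid)."""
    from scipy.signal import fftconvolve
    t = np.asarray(times_sec) / 60.0
    fine = np.linspace(t[0], t[-1], (t.size - 1) * refine + 1)
    dt = fine[1] - fine[0]
    cp_fine = interp1d(t, cp)(fine)
    kep = ktrans / ve
    kernel = np.exp(-kep * (fine - fine[0]))
    full = fftconvolve(cp_fine, kernel)[: fine.size]
    trap = dt * (full - 0.5 * cp_fine[0] * kernel - 0.5 * cp_fine * kernel[0])
    ct = vp * cp + ktrans * interp1d(fine, trap)(t)
    return ct


def ode_standard_tofts(ktrans, ve, times_sec, cp):
    """Independent standard Tofts (vp = 0) solution via the compartment ODE
    dCe/dt = (Ktrans/ve) (Cp - Ce), Ct = ve * Ce."""
    t = np.asarray(times_sec) / 60.0
    cp_f = interp1d(t, cp, fill_value=(cp[0], cp[-1]), bounds_error=False)
    kep = ktrans / ve

    def rhs(ti, y):
        return [kep * (cp_f(ti) - y[0])]

    sol = solve_ivp(rhs, (t[0], t[-1]), [0.0], t_eval=t, rtol=1e-10,
                    atol=1e-12, max_step=np.diff(t).min())
    return ve * sol.y[0]


@pytest.fixture(scope="module")
def aif(protocol):
    return population_aif(protocol)


class TestForwardModel:
    def test_vascular_only_limit(self, aif):
        ct = extended_tofts_forward(0.0, 0.3, 0.1, aif)
        assert np.allclose(ct, 0.1 * aif.cp_mM)

    def test_step_aif_closed_form(self):
        """Constant input: Ct = vp + ve (1 - exp(-Ktrans t / ve)),
        plateau vp + ve."""
        times = np.arange(0, 1200.0, 2.5)
        step = PlasmaCurve(times, np.ones_like(times))
        kt, ve, vp = 0.25, 0.35, 0.05
        ct = extended_tofts_forward(kt, ve, vp, step)
        expected = vp + ve * (1.0 - np.exp(-kt * (times / 60.0) / ve))
        assert np.allclose(ct, expected, atol=1e-10)
        assert ct[-1] == pytest.approx(0.40, abs=1e-4)  # plateau = vp + ve

    def test_matches_brute_force_quadrature(self, aif):
        rng = np.random.default_rng(2024)
        for _ in range(10):
            kt = rng.uniform(0.02, 1.5)
            ve = rng.uniform(0.1, 0.8)
            vp = rng.uniform(0.0, 0.5)
            ct = extended_tofts_forward(kt, ve, vp, aif)
            oracle = brute_force_tofts(kt, ve, vp, aif.times_sec, aif.cp_mM)
            assert np.max(np.abs(ct - oracle)) < 1e-4

    def test_vp_zero_reduces_to_standard_tofts_ode(self, aif):
        kt, ve = 0.3, 0.4
        ct = extended_tofts_forward(kt, ve, 0.0, aif)
        oracle = ode_standard_tofts(kt, ve, aif.times_sec, aif.cp_mM)
        assert np.max(np.abs(ct - oracle)) < 1e-5

    def test_linearity_in_input(self, aif):
        ct1 = extended_tofts_forward(0.2, 0.3, 0.1, aif)
        scaled = PlasmaCurve(aif.times_sec, 3.0 * aif.cp_mM)
        ct3 = extended_tofts_forward(0.2, 0.3, 0.1, scaled)
        assert np.allclose(ct3, 3.0 * ct1, rtol=1e-12)

    def test_ve_zero_with_transfer_rejected(self, aif):
        with pytest.raises(ValueError, match="ve"):
            extended_tofts_forward(0.2, 0.0, 0.1, aif)

    def test_zero_rate_limit_matches_pure_integral(self):
        times = np.arange(0, 100.0, 2.5)
        cp = np.linspace(0, 2.0, times.size)
        conv = exp_convolution(times / 60.0, cp, 0.0)
        expected = np.array([np.trapezoid(cp[: i + 1], times[: i + 1] / 60.0)
                             for i in range(times.size)])
        assert np.allclose(conv, expected, atol=1e-12)


class TestSignalToConcentration:
    def _make(self, protocol, conc_curve, t10=1200.0, s0=1000.0):
        r1 = protocol.relaxivity_per_mM_per_sec
        r1_t = 1000.0 / t10 + r1 * conc_curve
        t1_t = 1000.0 / r1_t
        sig = spgr_signal(s0, t1_t, protocol.tr_msec,
                          protocol.dynamic_flip_deg)
        data = np.zeros((1, 1, 1, protocol.n_dynamics))
        data[0, 0, 0, :] = sig
        dyn = VolumeSeries(data, np.eye(4),
                           times_sec=protocol.dynamic_times_sec)
        fit = T1FitResult(np.full((1, 1, 1), t10), np.full((1, 1, 1), s0),
                          np.ones((1, 1, 1), bool), np.zeros((1, 1, 1)))
        return dyn, fit

    def test_constant_baseline_gives_zero(self, protocol):
        conc_true = np.zeros(protocol.n_dynamics)
        dyn, fit = self._make(protocol, conc_true)
        cs = signal_to_concentration(dyn, fit, protocol)
        assert np.allclose(cs.ct_mM, 0.0, atol=1e-10)

    def test_round_trip_recovers_known_concentration(self, protocol):
        """1 mM at T10 = 1200 ms, r1 = 5: T1 drops to 1200/7 ~ 171.4 ms and
        the inversion recovers the concentration to 1e-6."""
        conc_true = np.zeros(protocol.n_dynamics)
        conc_true[protocol.n_baseline:] = 1.0
        r1_post = 1000.0 / 1200.0 + 5.0 * 1.0
        assert 1000.0 / r1_post == pytest.approx(1200.0 / 7.0, rel=1e-12)
        dyn, fit = self._make(protocol, conc_true)
        cs = signal_to_concentration(dyn, fit, protocol)
        assert np.allclose(cs.ct_mM[0, protocol.n_baseline:], 1.0, atol=1e-6)

    def test_relaxivity_inverse_proportionality(self, protocol):
        conc_true = np.zeros(protocol.n_dynamics)
        conc_true[protocol.n_baseline:] = 0.8
        dyn, fit = self._make(protocol, conc_true)
        doubled = AcquisitionProtocol(
            **{**protocol.to_dict(),
               "relaxivity_per_mM_per_sec":
               2 * protocol.relaxivity_per_mM_per_sec})
        cs1 = signal_to_concentration(dyn, fit, protocol)
        cs2 = signal_to_concentration(dyn, fit, doubled)
        post = slice(protocol.n_baseline, None)
        assert np.allclose(cs2.ct_mM[0, post], cs1.ct_mM[0, post] / 2.0,
                           rtol=1e-10)

    def test_signal_above_ceiling_flagged_not_raised(self, protocol):
        conc_true = np.zeros(protocol.n_dynamics)
        dyn, fit = self._make(protocol, conc_true)
        dyn.data[0, 0, 0, 50] = 1e9  # unphysical spike -> E1 outside (0,1)
        cs = signal_to_concentration(dyn, fit, protocol)
        assert not cs.valid[0, 50]
        assert cs.valid[0, 40]


class TestExtractAif:
    def test_hematocrit_correction_is_exact_division(self, noiseless_session):
        s = noiseless_session
        cp_042 = extract_aif(s["dyn"], s["regions"].vessel, s["protocol"],
                             hematocrit=0.42)
        cp_0 = extract_aif(s["dyn"], s["regions"].vessel, s["protocol"],
                           hematocrit=0.0)
        assert np.allclose(cp_042.cp_mM, cp_0.cp_mM / 0.58, rtol=1e-12)

    def test_round_trip_recovers_plasma_curve(self, noiseless_session):
        """Vessel holds whole blood Cp (1 - Hct); extraction re-divides."""
        s = noiseless_session
        cp_hat = extract_aif(s["dyn"], s["regions"].vessel, s["protocol"],
                             hematocrit=s["gt"].hematocrit)
        post = slice(s["protocol"].injection_dynamic + 1, None)
        rel = np.abs(cp_hat.cp_mM[post] - s["aif"].cp_mM[post]) / \
            s["aif"].cp_mM[post]
        assert np.max(rel) < 0.02

    def test_invalid_hematocrit_rejected(self, noiseless_session):
        s = noiseless_session
        with pytest.raises(ValueError, match="hematocrit"):
            extract_aif(s["dyn"], s["regions"].vessel, s["protocol"],
                        hematocrit=1.2)

    def test_empty_roi_rejected(self, noiseless_session):
        s = noiseless_session
        empty = np.zeros_like(s["regions"].vessel)
        with pytest.raises(ValueError, match="empty"):
            extract_aif(s["dyn"], empty, s["protocol"], hematocrit=0.4)


def _conc_series(protocol, ct_rows):
    n = ct_rows.shape[0]
    vox = np.stack([np.arange(n), np.zeros(n, int), np.zeros(n, int)], axis=1)
    return ConcentrationSeries(protocol.dynamic_times_sec, ct_rows,
                               protocol.n_baseline, voxel_index=vox,
                               valid=np.ones_like(ct_rows, bool))


class TestFitExtendedTofts:
    def test_noiseless_recovery(self, protocol, aif):
        truth = (0.22, 0.33, 0.05)
        ct = extended_tofts_forward(*truth, aif)[None, :]
        fit = fit_extended_tofts(_conc_series(protocol, ct), aif,
                                 grid_shape=(1, 1, 1))
        assert fit.ktrans_map[0, 0, 0] == pytest.approx(truth[0], abs=1e-3)
        assert fit.ve_map[0, 0, 0] == pytest.approx(truth[1], abs=1e-3)
        assert fit.vp_map[0, 0, 0] == pytest.approx(truth[2], abs=1e-3)
        assert fit.valid_mask[0, 0, 0]

    def test_null_curve_fits_to_zero(self, protocol, aif):
        ct = np.zeros((1, protocol.n_dynamics))
        fit = fit_extended_tofts(_conc_series(protocol, ct), aif,
                                 grid_shape=(1, 1, 1))
        assert fit.ktrans_map[0, 0, 0] == pytest.approx(0.0, abs=1e-5)
        assert fit.vp_map[0, 0, 0] == pytest.approx(0.0, abs=1e-5)

    def test_grid_mismatch_rejected(self, protocol, aif):
        ct = np.zeros((1, protocol.n_dynamics))
        other = PlasmaCurve(aif.times_sec + 0.5, aif.cp_mM)
        with pytest.raises(ValueError, match="grid"):
            fit_extended_tofts(_conc_series(protocol, ct), other,
                               grid_shape=(1, 1, 1))

    def test_too_few_samples_rejected(self):
        times = np.arange(10) * 2.5
        short_aif = PlasmaCurve(times, np.ones(10))
        cs = ConcentrationSeries(times, np.zeros((1, 10)), 3,
                                 voxel_index=np.array([[0, 0, 0]]),
                                 valid=np.ones((1, 10), bool))
        with pytest.raises(ValueError, match="20"):
            fit_extended_tofts(cs, short_aif, grid_shape=(1, 1, 1))

    def test_noisy_ktrans_error_within_calibrated_bound(self, protocol, aif):
        """0.02 mM Gaussian concentration noise, HV-like truths, 100 voxels:
        median |dKtrans| stays below the pre-calibrated 0.02 min^-1."""
        rng = np.random.default_rng(42)
        n = 100
        kt = np.exp(rng.normal(np.log(0.25), 0.15, n))
        ve = np.clip(rng.normal(0.33, 0.03, n), 0.05, 0.95)
        vp = np.clip(rng.normal(0.45, 0.05, n), 0.01, 0.9)
        ct = extended_tofts_forward(kt, ve, vp, aif)
        ct += rng.normal(0, 0.02, ct.shape)
        fit = fit_extended_tofts(_conc_series(protocol, ct), aif,
                                 grid_shape=(n, 1, 1))
        err = np.abs(fit.ktrans_map[:, 0, 0] - kt)
        assert np.median(err) < 0.02
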