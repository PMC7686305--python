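"""Nonlinear least-squares relaxometry fitters."""

import numpy as np
import pytest

from qrelax.parameter_fitting import fit_adc, fit_ir_t1, fit_mse_t2, fit_vfa_t1, fit_volume
from qrelax.sequence_models import dwi_signal, ir_signal_signed, mse_signal, spgr_signal
from qrelax.types import InvalidParameterError, TissueParams


def _ir_signals(t1, protocol, pd=1.0, signed=False):
    tis = TissueParams(t1=t1, t2=100.0, pd=pd)
    s = np.array([ir_signal_signed(tis, ti, protocol.tr_ms)
                  for ti in protocol.sample_points])
    return s if signed else np.abs(s)


def _vfa_signals(t1, protocol, pd=1.0):
    tis = TissueParams(t1=t1, t2=100.0, pd=pd)
    return np.array([spgr_signal(tis, a, protocol.tr_ms)
                     for a in protocol.sample_points])


def _mse_signals(t2, protocol, pd=1.0):
    tis = TissueParams(t1=3000.0, t2=t2, pd=pd)
    return np.array([mse_signal(tis, te) for te in protocol.sample_points])


def _dwi_signals(adc, protocol, pd=1.0):
    tis = TissueParams(t1=3000.0, t2=100.0, pd=pd, adc=adc)
    return np.array([dwi_signal(tis, b) for b in protocol.sample_points])


class TestInverseCrime:
    """Noiseless model-generated data must be recovered to < 0.1%."""

    @pytest.mark.parametrize("t1", [414.3, 1000.0, 1666.0, 2521.0])
    def test_ir(self, t1, presets):
        fit = fit_ir_t1(_ir_signals(t1, presets["phantom_ir"]), presets["phantom_ir"])
        assert fit.converged
        assert fit.estimate == pytest.approx(t1, rel=1e-3)

    @pytest.mark.parametrize("t1", [414.3, 800.0, 1990.0, 2521.0])
    def test_vfa(self, t1, presets):
        fit = fit_vfa_t1(_vfa_signals(t1, presets["invivo_vfa"]), presets["invivo_vfa"])
        assert fit.converged
        assert fit.estimate == pytest.approx(t1, rel=1e-3)

    @pytest.mark.parametrize("t2", [41.6, 100.0, 139.4])
    def test_mse(self, t2, presets):
        fit = fit_mse_t2(_mse_signals(t2, presets["invivo_mse"]), presets["invivo_mse"])
        assert fit.converged
        assert fit.estimate == pytest.approx(t2, rel=1e-3)

    @pytest.mark.parametrize("adc", [0.08, 0.94, 1.61])
    def test_adc(self, adc, presets):
        fit = fit_adc(_dwi_signals(adc, presets["invivo_dwi"]), presets["invivo_dwi"])
        assert fit.converged
        assert fit.estimate == pytest.approx(adc, rel=1e-3)


class TestIR:
    def test_zero_signals_flagged_not_raised(self, presets):
        fit = fit_ir_t1(np.zeros(7), presets["phantom_ir"])
        assert not fit.converged

    def test_polarity_restoration_under_noise(self, presets):
        """Magnitude data recover the same T1 as fitting the signed data."""
        protocol = presets["phantom_ir"]
        t1 = 1000.0
        signed = _ir_signals(t1, protocol, pd=100.0, signed=True)
        rng = np.random.default_rng(3)
        sigma = np.mean(np.abs(signed)) / 50.0
        noisy_signed = signed + sigma * rng.standard_normal(signed.size)
        fit_mag = fit_ir_t1(np.abs(noisy_signed), protocol)
        fit_signed = fit_ir_t1(noisy_signed, protocol)  # no-flip candidate
        assert fit_mag.converged and fit_mag.polarity_restored
        assert fit_mag.estimate == pytest.approx(fit_signed.estimate, rel=0.005)

    def test_monte_carlo_median_recovery(self, presets):
        protocol = presets["phantom_ir"]
        t1 = 1830.0
        clean = _ir_signals(t1, protocol, pd=100.0, signed=True)
        rng = np.random.default_rng(7)
        estimates = []
        for _ in range(100):
            noisy = np.abs(clean + 1.0 * rng.standard_normal(clean.size))  # 1% of PD
            fit = fit_ir_t1(noisy, protocol)
            if fit.converged:
                estimates.append(fit.estimate)
        assert np.median(estimates) == pytest.approx(t1, rel=0.02)


class TestVFA:
    def test_linearised_initialiser_matches_nlls_noiseless(self, presets):
        """DESPOT1 line alone equals the NLLS refinement on clean data."""
        protocol = presets["invivo_vfa"]
        t1 = 800.0
        s = _vfa_signals(t1, protocol)
        alpha = np.deg2rad(np.asarray(protocol.sample_points))
        slope = np.polyfit(s / np.tan(alpha), s / np.sin(alpha), 1)[0]
        t1_lin = -protocol.tr_ms / np.log(slope)
        fit = fit_vfa_t1(s, protocol)
        assert fit.estimate == pytest.approx(t1_lin, rel=1e-4)

    def test_noisier_than_ir_at_matched_noise(self, presets):
        """VFA T1 is more noise-sensitive than IR T1 at the same 2% noise."""
        t1 = 1990.0
        rng = np.random.default_rng(11)
        vfa_p, ir_p = presets["invivo_vfa"], presets["phantom_ir"]
        vfa_clean = _vfa_signals(t1, vfa_p, pd=100.0)
        ir_clean = _ir_signals(t1, ir_p, pd=100.0, signed=True)
        vfa_err, ir_err = [], []
        for _ in range(100):
            fv = fit_vfa_t1(np.abs(vfa_clean + 2.0 * rng.standard_normal(vfa_clean.size)), vfa_p)
            fi = fit_ir_t1(np.abs(ir_clean + 2.0 * rng.standard_normal(ir_clean.size)), ir_p)
            if fv.converged:
                vfa_err.append(fv.estimate - t1)
            if fi.converged:
                ir_err.append(fi.estimate - t1)
        rmse = lambda e: np.sqrt(np.mean(np.square(e)))  # noqa: E731
        assert rmse(vfa_err) > rmse(ir_err)

    def test_degenerate_slope_flagged(self, presets):
        # signals consistent with E1 > 1 are unphysical: slope outside (0, 1)
        protocol = presets["invivo_vfa"]
        a = np.deg2rad(np.asarray(protocol.sample_points))
        e1 = 1.05
        s = np.sin(a) * (1 - e1) / (1 - e1 * np.cos(a))
        fit = fit_vfa_t1(np.abs(s), protocol)
        assert not fit.converged and fit.flags


class TestMSEAndADC:
    def test_extrapolation_flag_for_long_t2(self, presets):
        protocol = presets["invivo_mse"]
        fit = fit_mse_t2(_mse_signals(443.6, protocol), presets["invivo_mse"])
        assert fit.converged
        assert any("extrapolated" in f for f in fit.flags)
        # longest TE 67.7 ms is four-fold shorter than this T2
        assert fit.estimate > 4 * max(protocol.sample_points)

    def test_log_linear_slope_identity(self, presets):
        protocol = presets["invivo_mse"]
        t2 = 100.0
        s = _mse_signals(t2, protocol)
        slope = np.polyfit(np.asarray(protocol.sample_points), np.log(s), 1)[0]
        assert slope == pytest.approx(-1.0 / t2, rel=1e-12)

    def test_adc_two_points_exact(self):
        from qrelax.types import ConventionalProtocol

        protocol = ConventionalProtocol(kind="DWI", sample_points=(0, 1000))
        fit = fit_adc(np.array([1.0, np.exp(-1.0)]), protocol)
        assert fit.estimate == pytest.approx(1.0, rel=1e-9)
        assert fit.residual_sse == pytest.approx(0.0, abs=1e-15)

    def test_adc_monte_carlo(self, presets):
        protocol = presets["invivo_dwi"]
        adc = 1.61
        clean = _dwi_signals(adc, protocol, pd=100.0)
        rng = np.random.default_rng(13)
        est = [fit_adc(np.abs(clean + 2.0 * rng.standard_normal(3)), protocol).estimate
               for _ in range(100)]
        assert np.median(est) == pytest.approx(adc, rel=0.03)

    def test_nonpositive_signals_dropped_with_warning(self, presets):
        protocol = presets["invivo_mse"]
        s = _mse_signals(80.0, protocol)
        s[-1] = -0.1
        with pytest.warns(UserWarning):
            fit = fit_mse_t2(s, protocol)
        assert fit.estimate == pytest.approx(80.0, rel=1e-3)


class TestScaleInvariance:
    def test_estimates_invariant_scale_absorbs(self, presets):
        t1 = 1200.0
        s = _vfa_signals(t1, presets["invivo_vfa"])
        f1 = fit_vfa_t1(s, presets["invivo_vfa"])
        f2 = fit_vfa_t1(123.0 * s, presets["invivo_vfa"])
        assert f2.estimate == pytest.approx(f1.estimate, rel=1e-6)
        assert f2.scale == pytest.approx(123.0 * f1.scale, rel=1e-6)


class TestFitVolume:
    def test_uniform_slab_and_mask(self, presets):
        protocol = presets["invivo_mse"]
        s = _mse_signals(90.0, protocol)
        stack = np.tile(s, (3, 3, 1))
        mask = np.ones((3, 3), bool)
        mask[0, 0] = False
        qmap, quality = fit_volume(stack, protocol, mask=mask)
        assert np.isnan(qmap.data[0, 0])
        fitted = qmap.data[mask]
        assert np.allclose(fitted, 90.0, rtol=1e-3)
        assert np.all(quality.data[mask] == 1.0)

    def test_shape_mismatch_rejected(self, presets):
        with pytest.raises(InvalidParameterError):
            fit_volume(np.zeros((2, 2, 4)), presets["invivo_mse"])
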