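"""Closed-form signal models, the EPG engine and its Bloch oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qrelax.sequence_models import (
    bloch_isochromat_fingerprint,
    default_flip_train,
    dwi_signal,
    epg_fingerprint,
    epg_fingerprints,
    get_preset,
    ir_signal,
    load_flip_angles,
    make_default_flip_train,
    mse_signal,
    spgr_signal,
)
from qrelax.types import InvalidParameterError, MRFSequenceParams, TissueParams


def tissue(t1=1000.0, t2=100.0, pd=1.0, **kw):
    return TissueParams(t1=t1, t2=t2, pd=pd, **kw)


class TestClosedFormModels:
    def test_ir_null_point(self):
        # with TR >> T1 the signal nulls at TI = T1 ln 2
        s = ir_signal(tissue(t1=1000), ti_ms=1000 * math.log(2), tr_ms=1e6)
        assert abs(s) < 1e-3

    def test_ir_full_inversion_and_recovery_limits(self):
        assert ir_signal(tissue(t1=1000), ti_ms=1e-9, tr_ms=1e6) == pytest.approx(1.0, abs=1e-6)
        assert ir_signal(tissue(t1=100), ti_ms=5e5, tr_ms=1e6) == pytest.approx(1.0, abs=1e-6)

    def test_ir_three_term_formula(self):
        # independent direct evaluation of the three-exponential-term model
        t1, ti, tr = 500.0, 400.0, 8000.0
        expected = abs(1 - 2 * math.exp(-ti / t1) + math.exp(-tr / t1))
        assert ir_signal(tissue(t1=t1), ti, tr) == pytest.approx(expected, rel=1e-12)

    def test_ir_rejects_bad_times(self):
        with pytest.raises(InvalidParameterError):
            ir_signal(tissue(), ti_ms=-5, tr_ms=1000)
        with pytest.raises(InvalidParameterError):
            ir_signal(tissue(), ti_ms=2000, tr_ms=1000)

    def test_spgr_reaches_pd_at_90_long_tr(self):
        s = spgr_signal(tissue(t1=800, pd=3.5), flip_deg=90, tr_ms=1e6)
        assert s == pytest.approx(3.5, rel=1e-6)

    def test_spgr_ernst_angle_maximum(self):
        t1, tr = 1000.0, 10.0
        ernst = math.degrees(math.acos(math.exp(-tr / t1)))
        s_ernst = spgr_signal(tissue(t1=t1), ernst, tr)
        for a in (2, 5, 12, 20, 32):
            assert s_ernst > spgr_signal(tissue(t1=t1), a, tr)

    def test_spgr_direct_formula(self):
        t1, pd_, tr, a = 800.0, 100.0, 15.0, 12.0
        e1 = math.exp(-tr / t1)
        ar = math.radians(a)
        expected = pd_ * math.sin(ar) * (1 - e1) / (1 - e1 * math.cos(ar))
        assert spgr_signal(tissue(t1=t1, pd=pd_), a, tr) == pytest.approx(expected, rel=1e-12)

    def test_spgr_zero_flip_and_bad_tr(self):
        assert spgr_signal(tissue(), 0.0, 10.0) == 0.0
        with pytest.raises(InvalidParameterError):
            spgr_signal(tissue(), 12.0, -1.0)

    def test_mse_examples(self):
        assert mse_signal(tissue(t2=100, pd=100), 100.0) == pytest.approx(100 / math.e, rel=1e-9)
        assert mse_signal(tissue(t2=100, pd=100), 1e-9) == pytest.approx(100.0, rel=1e-6)
        assert mse_signal(tissue(t1=500, t2=76.6), 65.3) == pytest.approx(
            math.exp(-65.3 / 76.6), rel=1e-12)

    def test_dwi_examples(self):
        t_adc = TissueParams(t1=1000, t2=100, adc=0.94)
        assert dwi_signal(t_adc, 0.0) == pytest.approx(1.0)
        assert dwi_signal(TissueParams(t1=1000, t2=100, adc=1.0), 1000) == pytest.approx(
            math.exp(-1.0), rel=1e-12)
        assert dwi_signal(t_adc, 1400) == pytest.approx(math.exp(-1.316), rel=1e-12)

    def test_dwi_requires_adc(self):
        with pytest.raises(InvalidParameterError):
            dwi_signal(tissue(), 500)

    @settings(max_examples=40, deadline=None)
    @given(pd_=st.floats(0.1, 100), t2=st.floats(20, 500),
           te=st.floats(1, 200), scale=st.floats(1.5, 4))
    def test_decay_monotone_and_pd_linear(self, pd_, t2, te, scale):
        tis = tissue(t1=3000, t2=t2, pd=pd_)
        assert mse_signal(tis, te * scale) < mse_signal(tis, te)
        doubled = tissue(t1=3000, t2=t2, pd=2 * pd_)
        assert mse_signal(doubled, te) == pytest.approx(2 * mse_signal(tis, te), rel=1e-12)
        tis_adc = TissueParams(t1=3000, t2=t2, pd=pd_, adc=1.2)
        assert dwi_signal(tis_adc, 1000.0) < dwi_signal(tis_adc, 100.0)


class TestEPG:
    def test_no_excitation_limit_is_inversion_recovery(self):
        """With vanishing flips the sampled signal tracks the analytic IR curve."""
        eps = 1e-6  # degrees
        seq = MRFSequenceParams(flip_angles_deg=(eps,) * 600, tr_ms=10, te_ms=2.5,
                                inversion=True, inversion_delay_ms=18.0)
        t1, t2 = 1000.0, 100.0
        s = epg_fingerprint(TissueParams(t1=t1, t2=t2), seq)
        t = 18.0 + np.arange(600) * 10.0
        envelope = np.abs(1 - 2 * np.exp(-t / t1))
        recovered = np.abs(s) / (np.sin(np.deg2rad(eps)) * np.exp(-2.5 / t2))
        rel = np.abs(recovered - envelope) / np.maximum(envelope, 1e-3)
        assert rel.max() < 1e-9

    def test_single_90_pulse_is_fid(self):
        seq = MRFSequenceParams(flip_angles_deg=(90.0,), tr_ms=10, te_ms=2.5,
                                inversion=False)
        s = epg_fingerprint(TissueParams(t1=800, t2=60, pd=2.0), seq)
        assert abs(s[0]) == pytest.approx(2.0 * math.exp(-2.5 / 60.0), rel=1e-12)

    def test_agrees_with_bloch_oracle(self, short_seq):
        tis = TissueParams(t1=1696.0, t2=69.3)
        e = epg_fingerprint(tis, short_seq)
        b = bloch_isochromat_fingerprint(tis, short_seq, n_isochromats=200)
        rel = np.sqrt(np.mean(np.abs(b - e) ** 2)) / np.sqrt(np.mean(np.abs(e) ** 2))
        assert rel < 0.01

    def test_truncation_error_small_in_tissue_regime(self, mrf_seq):
        # retained-order truncation: K=40 vs K=100 on the full train
        a40 = epg_fingerprints(np.array([1696.0]), np.array([69.3]), mrf_seq, n_states=40)
        a100 = epg_fingerprints(np.array([1696.0]), np.array([69.3]), mrf_seq, n_states=100)
        assert np.linalg.norm(a40 - a100) / np.linalg.norm(a100) < 1e-6

    def test_complex_path_matches_real_path(self, short_seq):
        """A constant RF phase only rotates the frame: same signal magnitude."""
        import dataclasses

        seq_c = dataclasses.replace(short_seq,
                                    rf_phase_deg=(90.0,) * short_seq.n_excitations)
        tis = TissueParams(t1=1200, t2=90)
        s_real = epg_fingerprint(tis, short_seq)
        s_complex = epg_fingerprint(tis, seq_c)
        assert np.iscomplexobj(s_complex) and not np.iscomplexobj(s_real)
        assert np.allclose(np.abs(s_complex), np.abs(s_real), rtol=1e-9, atol=1e-12)

    def test_empty_train_rejected(self):
        with pytest.raises(InvalidParameterError):
            MRFSequenceParams(flip_angles_deg=())


class TestBlochOracle:
    def test_zero_flips_match_ir_envelope(self):
        seq = MRFSequenceParams(flip_angles_deg=(0.0,) * 100, tr_ms=10, te_ms=2.5,
                                inversion=True)
        b = bloch_isochromat_fingerprint(TissueParams(t1=900, t2=80), seq, 64)
        assert np.allclose(np.abs(b), 0.0, atol=1e-12)  # no transverse signal

    def test_isochromat_convergence(self, short_seq):
        tis = TissueParams(t1=1000, t2=150)
        b200 = bloch_isochromat_fingerprint(tis, short_seq, 200)
        b400 = bloch_isochromat_fingerprint(tis, short_seq, 400)
        rel = np.sqrt(np.mean(np.abs(b400 - b200) ** 2)) / np.sqrt(np.mean(np.abs(b400) ** 2))
        assert rel < 0.002

    def test_requires_enough_isochromats(self, short_seq):
        with pytest.raises(InvalidParameterError):
            bloch_isochromat_fingerprint(tissue(), short_seq, n_isochromats=10)


class TestPresets:
    def test_phantom_ir_preset(self, presets):
        p = presets["phantom_ir"]
        assert p.sample_points == (50, 100, 200, 400, 800, 1600, 2400)
        assert p.tr_ms == 8000 and p.te_ms == 13

    def test_mrf_default_preset(self, mrf_seq):
        assert mrf_seq.n_excitations == 979
        assert mrf_seq.tr_ms == 10.0 and mrf_seq.te_ms == 2.5
        assert mrf_seq.inversion
        assert mrf_seq.dephasing_per_tr == pytest.approx(8 * np.pi)
        assert mrf_seq.train_duration_ms == pytest.approx(9790.0)

    def test_invivo_presets(self, presets):
        assert presets["invivo_dwi"].sample_points == (150, 750, 1400)
        assert presets["invivo_vfa"].sample_points == (2, 5, 12, 20, 32)
        assert presets["invivo_vfa"].total_acquisition_seconds == pytest.approx(260.0)
        assert presets["invivo_mse"].sample_points == (8.5, 16.9, 25.4, 42.3, 50.8, 59.2, 67.7)
        assert presets["phantom_vfa"].sample_points == (2, 5, 8, 12, 15, 18, 22, 26)
        assert presets["phantom_mse"].sample_points == (8.2, 16.3, 24.5, 32.6, 40.8, 49.0, 57.1, 65.3)

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            get_preset("no_such_protocol")


class TestFlipTrain:
    def test_packaged_train_matches_generator(self):
        packaged = default_flip_train()
        assert packaged.size == 979
        assert np.allclose(packaged, make_default_flip_train(), atol=5e-4)

    def test_load_ignores_comments(self, tmp_path):
        path = tmp_path / "train.txt"
        path.write_text("# comment\n10.0\n20.0 # inline\n\n30.0\n")
        assert np.allclose(load_flip_angles(path), [10, 20, 30])

    def test_load_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.txt"
        path.write_text("# nothing\n")
        with pytest.raises(InvalidParameterError):
            load_flip_angles(path)
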