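"""Phantom / virtual-pelvis generators, contrast model, acquisition noise."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from qrelax.synthetic_data import (
    ContrastModel,
    PhantomLayerSpec,
    apply_contrast,
    default_phantom_spec,
    default_tissue_specs,
    make_phantom,
    make_virtual_pelvis,
    sample_class_roi_means,
    simulate_acquisition,
)
from qrelax.sequence_models import protocol_presets
from qrelax.types import InvalidParameterError


@pytest.fixture(scope="module")
def cohort():
    return make_virtual_pelvis(seed=1)


@pytest.fixture(scope="module")
def truth(cohort):
    return pd.concat([p.roi_table for p in cohort], ignore_index=True)


class TestPhantom:
    def test_fourteen_disjoint_spheres(self):
        volume, masks = make_phantom(default_phantom_spec("T1"))
        assert len(masks) == 14
        total = np.zeros(volume.shape, int)
        for mask in masks.values():
            assert mask.sum() >= 20
            total += mask
        assert total.max() == 1  # mutually disjoint

    def test_sphere_means_equal_spec_exactly(self):
        spec = default_phantom_spec("T1")
        volume, masks = make_phantom(spec)
        for i, (t1v, t2v, _) in enumerate(spec.sphere_params):
            mask = masks[f"sphere_{i:02d}"]
            assert volume.t1[mask].mean() == pytest.approx(t1v, rel=1e-12)
            assert volume.t2[mask].mean() == pytest.approx(t2v, rel=1e-12)

    def test_t2_layer_spans_a_decade(self):
        spec = default_phantom_spec("T2")
        t2s = [p[1] for p in spec.sphere_params]
        assert max(t2s) / min(t2s) >= 10

    def test_overlapping_spheres_rejected(self):
        spec = dataclasses.replace(default_phantom_spec("T1"), spacing_vox=6.0)
        with pytest.raises(InvalidParameterError):
            make_phantom(spec)

    def test_too_small_grid_rejected(self):
        with pytest.raises(InvalidParameterError):
            make_phantom(default_phantom_spec("T1"), grid_shape=(32, 32))


class TestVirtualPelvis:
    def test_cohort_roi_counts(self, truth):
        counts = truth.groupby("tissue_class")["label"].count()
        assert counts["PZ_lesion"] == 10
        assert counts["TZ_lesion"] == 9
        for cls in ("normal_PZ", "normal_TZ", "muscle", "fat"):
            assert counts[cls] == 14
        assert truth.tissue_class.isin(["PZ_lesion", "TZ_lesion"]).sum() == 19

    def test_zero_sd_collapses_to_class_means(self):
        specs = {
            name: dataclasses.replace(s, t1_sd_ms=0.0, t2_sd_ms=0.0, adc_sd=0.0)
            for name, s in default_tissue_specs().items()
        }
        cohort = make_virtual_pelvis(specs=specs, n_patients=4, seed=0)
        truth = pd.concat([p.roi_table for p in cohort])
        for name, spec in specs.items():
            sub = truth[truth.tissue_class == name]
            if sub.empty:
                continue
            assert np.allclose(sub.t1_ms, spec.t1_mean_ms)
            assert np.allclose(sub.t2_ms, spec.t2_mean_ms)
            assert np.allclose(sub.adc, spec.adc_mean)

    def test_large_draw_matches_spec_moments(self):
        """Seeded 1000-ROI draws reproduce every class mean and SD within 5%.

        The ROI-level T2/ADC draws are heavy-tailed (log-normal moment
        matching), so the sample SD converges slowly; the check is a seeded
        law-of-large-numbers test, not a distribution-free bound.
        """
        rng = np.random.default_rng(15)
        for name, spec in default_tissue_specs().items():
            df = sample_class_roi_means(spec, 1000, rng)
            assert df.t1_ms.mean() == pytest.approx(spec.t1_mean_ms, rel=0.05)
            assert df.t1_ms.std() == pytest.approx(spec.t1_sd_ms, rel=0.05)
            assert df.t2_ms.mean() == pytest.approx(spec.t2_mean_ms, rel=0.05)
            assert df.t2_ms.std() == pytest.approx(spec.t2_sd_ms, rel=0.05)
            assert df.adc.mean() == pytest.approx(spec.adc_mean, rel=0.05)
            assert df.adc.std() == pytest.approx(spec.adc_sd, rel=0.05)

    def test_roi_voxel_means_near_generating_means(self, cohort):
        for patient in cohort[:3]:
            for _, roi in patient.roi_table.iterrows():
                mask = patient.label_map == roi["label"]
                # 5% within-ROI CV over >= ~15 voxels: mean within a few percent
                assert patient.t1[mask].mean() == pytest.approx(roi["t1_ms"], rel=0.06)

    def test_generation_is_pure_function_of_seed(self):
        a = make_virtual_pelvis(n_patients=2, seed=9)
        b = make_virtual_pelvis(n_patients=2, seed=9)
        assert np.array_equal(a[0].t1, b[0].t1)
        assert a[0].roi_table.equals(b[0].roi_table)


class TestContrast:
    def test_relaxivity_arithmetic(self):
        model = ContrastModel(r1=5.0, r2=6.0)
        # 1/(1/1.666 s + 0.5 /s) = 0.909 s
        post = model.shorten(np.array([1666.0]), model.r1, np.array([0.1]))
        assert post[0] == pytest.approx(909.0, abs=1.0)

    def test_zero_uptake_is_identity(self, cohort):
        specs = {
            name: dataclasses.replace(s, gbca_uptake_mean=0.0)
            for name, s in default_tissue_specs().items()
        }
        post = apply_contrast(cohort[0], specs=specs, seed=5)
        assert np.array_equal(post.t1, cohort[0].t1)
        assert np.array_equal(post.t2, cohort[0].t2)
        assert (post.roi_table["c_mmol"] == 0).all()

    def test_strict_shortening_where_uptake_positive(self, cohort):
        post = apply_contrast(cohort[0], seed=5)
        fg = cohort[0].foreground
        took_up = post.roi_table.set_index("label")["c_mmol"] > 0
        for label, positive in took_up.items():
            mask = cohort[0].label_map == label
            if positive:
                assert np.all(post.t1[mask] < cohort[0].t1[mask])
                assert np.all(post.t2[mask] < cohort[0].t2[mask])
        assert post.phase == "post"
        assert np.all(post.t1[fg] <= cohort[0].t1[fg])

    def test_deterministic_given_seed(self, cohort):
        a = apply_contrast(cohort[1], seed=8)
        b = apply_contrast(cohort[1], seed=8)
        assert np.array_equal(a.t1, b.t1)

    def test_invalid_relaxivities_rejected(self):
        with pytest.raises(InvalidParameterError):
            ContrastModel(r1=5.0, r2=4.0)
        with pytest.raises(InvalidParameterError):
            ContrastModel(r1=-1.0, r2=2.0)


class TestAcquisition:
    def test_noiseless_matches_closed_form(self, cohort):
        protocol = protocol_presets()["invivo_mse"]
        stack = simulate_acquisition(cohort[0], protocol, snr=None)
        mask = cohort[0].foreground
        te0 = protocol.sample_points[0]
        expected = cohort[0].pd[mask] * np.exp(-te0 / cohort[0].t2[mask])
        assert np.allclose(stack[mask][:, 0], expected, rtol=1e-12)

    def test_seeded_rerun_bit_identical(self, cohort):
        protocol = protocol_presets()["invivo_dwi"]
        a = simulate_acquisition(cohort[0], protocol, snr=30.0, seed=4)
        b = simulate_acquisition(cohort[0], protocol, snr=30.0, seed=4)
        assert np.array_equal(a, b)

    def test_rician_floor_in_background(self, cohort):
        """Zero-signal voxels acquire the Rayleigh mean sigma*sqrt(pi/2)."""
        protocol = protocol_presets()["invivo_mse"]
        vol = cohort[0]
        mask = np.ones(vol.shape, bool)  # include background (pd = 0)
        snr = 10.0
        stack = simulate_acquisition(vol, protocol, snr=snr, seed=2, mask=mask)
        clean = simulate_acquisition(vol, protocol, snr=None, mask=mask)
        sigma = np.abs(clean[mask]).mean() / snr
        background = stack[~vol.foreground]
        assert background.mean() == pytest.approx(sigma * np.sqrt(np.pi / 2), rel=0.02)

    def test_invalid_snr_rejected(self, cohort):
        with pytest.raises(InvalidParameterError):
            simulate_acquisition(cohort[0], protocol_presets()["invivo_dwi"], snr=0.0)


class TestSpecValidation:
    def test_phantom_spec_requires_decade_span(self):
        with pytest.raises(InvalidParameterError):
            PhantomLayerSpec(layer="T1",
                             sphere_params=((500.0, 50.0, 1.0), (900.0, 80.0, 1.0)))

    def test_tissue_spec_rejects_negative_sd(self):
        from qrelax.synthetic_data import TissueClassSpec

        with pytest.raises(InvalidParameterError):
            TissueClassSpec(name="fat", t1_mean_ms=400, t1_sd_ms=-1,
                            t2_mean_ms=200, t2_sd_ms=10, adc_mean=0.1, adc_sd=0.01)
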