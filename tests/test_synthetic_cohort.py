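"""Generator: texture spectra, phantom calibration, rendering, marginals."""

import numpy as np
import pandas as pd
import pytest

from maskscope.errors import ConvergenceError, ParameterError, PlacementError
from maskscope.synthetic_cohort import (
    default_cohort_config,
    generate_texture,
    insert_lesion,
    make_phantom,
    render_mammogram,
    sample_cohort,
    SCREENING_AGE_RANGE,
)


class TestGenerateTexture:
    def test_white_noise_rescaling(self):
        tex = generate_texture((64, 64), beta=0.0, sigma_tex=1.0, seed=7)
        assert 0.98 <= tex.pixels.std() <= 1.02
        assert abs(tex.pixels.mean()) < 1e-12

    def test_deterministic_given_seed(self):
        a = generate_texture((64, 64), 0.0, 1.0, seed=7)
        b = generate_texture((64, 64), 0.0, 1.0, seed=7)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_power_law_slope(self):
        """Radially averaged log-periodogram slope recovers -beta."""
        tex = generate_texture((256, 256), beta=3.0, sigma_tex=1.0, seed=3)
        p = np.abs(np.fft.fft2(tex.pixels)) ** 2
        fy = np.fft.fftfreq(256)[:, None]
        fx = np.fft.fftfreq(256)[None, :]
        f = np.hypot(fy, fx).ravel()
        p = p.ravel()
        keep = (f > 0.01) & (f < 0.4)
        # independent oracle: least-squares slope on log-binned radial means
        bins = np.logspace(np.log10(0.01), np.log10(0.4), 25)
        idx = np.digitize(f[keep], bins)
        fs, ps = [], []
        for i in range(1, len(bins)):
            sel = idx == i
            if sel.sum() > 4:
                fs.append(np.log(f[keep][sel].mean()))
                ps.append(np.log(p[keep][sel].mean()))
        slope = np.polyfit(fs, ps, 1)[0]
        assert -3.4 <= slope <= -2.6

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_sigma_rejected(self, bad):
        with pytest.raises(ParameterError):
            generate_texture((64, 64), 1.0, bad, seed=0)


class TestMakePhantom:
    @pytest.mark.parametrize(
        "target,lo,hi",
        [(0.5, 0.4, 0.6), (8.3, 8.2, 8.4), (25.0, 24.9, 25.1)],
    )
    def test_vbd_calibration(self, small_acq, target, lo, hi):
        tex = generate_texture(small_acq.image_shape, 3.0, 1.0, seed=2)
        ph = make_phantom(small_acq, target, tex)
        assert lo <= ph.true_vbd <= hi

    def test_zero_texture_gives_uniform_map(self, small_acq):
        tex = generate_texture(small_acq.image_shape, 0.0, 1.0, seed=2)
        tex = type(tex)(np.zeros(small_acq.image_shape), 0.0, 1.0, 2)
        ph = make_phantom(small_acq, 12.0, tex)
        inside = ph.dense_thickness_map[ph.breast_mask]
        assert np.allclose(inside, inside[0])
        assert ph.true_vbd == pytest.approx(12.0, abs=1e-6)

    def test_dense_within_thickness(self, phantom_83):
        m = phantom_83.breast_mask
        td = phantom_83.dense_thickness_map
        assert (td[m] >= 0).all() and (td[m] <= phantom_83.thickness_map[m]).all()
        assert (td[~m] == 0).all()

    def test_out_of_range_target_rejected(self, small_acq):
        tex = generate_texture(small_acq.image_shape, 3.0, 1.0, seed=2)
        with pytest.raises(ParameterError):
            make_phantom(small_acq, 0.0, tex)


class TestInsertLesion:
    def test_zero_amplitude_is_identity(self, phantom_83):
        ph = insert_lesion(phantom_83, (64, 40), 2.0, 0.0)
        np.testing.assert_array_equal(
            ph.dense_thickness_map, phantom_83.dense_thickness_map
        )
        assert len(ph.lesions) == 1

    def test_added_volume_matches_gaussian_integral(self, small_acq):
        """Discrete added dense volume ~ amplitude * 2 pi sigma^2 (pre-clamp)."""
        tex = generate_texture(small_acq.image_shape, 0.0, 1.0, seed=2)
        tex = type(tex)(np.zeros(small_acq.image_shape), 0.0, 1.0, 2)
        ph = make_phantom(small_acq, 5.0, tex)  # uniform, far from clamp
        amp, sig = 3.0, 2.0
        ph2 = insert_lesion(ph, (64, 40), sig, amp)
        added = (
            ph2.dense_thickness_map - ph.dense_thickness_map
        ).sum() * small_acq.pixel_pitch**2
        assert added == pytest.approx(amp * 2 * np.pi * sig**2, rel=0.01)

    def test_two_lesions_recorded(self, phantom_83):
        ph = insert_lesion(phantom_83, (64, 40), 2.0, 1.0)
        ph = insert_lesion(ph, (50, 30), 2.0, 1.0)
        assert len(ph.lesions) == 2

    def test_center_outside_mask_rejected(self, phantom_83):
        with pytest.raises(PlacementError):
            insert_lesion(phantom_83, (0, 127), 2.0, 1.0)


class TestRenderMammogram:
    def test_all_fat_closed_form(self, small_acq):
        tex = generate_texture(small_acq.image_shape, 0.0, 1.0, seed=2)
        tex = type(tex)(np.zeros(small_acq.image_shape), 0.0, 1.0, 2)
        ph = make_phantom(small_acq, 1e-9 + 0.001, tex)
        ph.dense_thickness_map[:] = 0.0
        raw = render_mammogram(ph, small_acq, rng=None)
        expected = small_acq.open_beam * np.exp(
            -small_acq.mu_fat * small_acq.thickness_mm
        )
        assert np.allclose(raw.pixels[ph.breast_mask], expected)

    def test_background_equals_open_beam(self, phantom_83, small_acq):
        raw = render_mammogram(phantom_83, small_acq, rng=None)
        assert np.allclose(raw.pixels[~phantom_83.breast_mask], small_acq.open_beam)

    def test_noisy_background_mean(self, phantom_83, small_acq, rng):
        raw = render_mammogram(phantom_83, small_acq, rng=rng)
        bg = raw.pixels[~phantom_83.breast_mask]
        assert bg.size > 1e4 * 0.3  # enough background pixels to average
        assert abs(bg.mean() - small_acq.open_beam) < 0.01 * small_acq.open_beam

    def test_saturation_clipping(self, phantom_83, small_acq):
        from dataclasses import replace

        acq = replace(small_acq, saturation_level=small_acq.open_beam * 0.5)
        raw = render_mammogram(phantom_83, acq, rng=None)
        assert raw.pixels.max() <= acq.saturation_level


class TestSampleCohort:
    def test_deterministic_tables(self):
        cfg = default_cohort_config(50, 50, seed=9, image_size="small")
        a = sample_cohort(cfg)
        b = sample_cohort(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_ages_within_screening_window(self):
        cfg = default_cohort_config(2000, 2000, seed=9, image_size="small")
        rec = sample_cohort(cfg)
        lo, hi = SCREENING_AGE_RANGE
        assert rec["age"].between(lo, hi).all()

    def test_group_marginals_recovered(self):
        """Medians and the visible-mass rate track the configured values."""
        cfg = default_cohort_config(5000, 5000, seed=9, image_size="small")
        rec = sample_cohort(cfg)
        sd = rec[rec.group == "screen_detected"]
        ic = rec[rec.group == "interval"]
        assert sd["age"].median() == pytest.approx(64.0, abs=1.0)
        assert ic["age"].median() == pytest.approx(58.0, abs=1.0)
        assert sd["vbd"].median() == pytest.approx(5.9, abs=0.5)
        assert ic["vbd"].median() == pytest.approx(8.3, abs=0.5)
        assert sd["mass_visible"].mean() == pytest.approx(0.82, abs=0.03)
        assert ic["mass_visible"].mean() == pytest.approx(0.55, abs=0.03)

    def test_interval_diagnosis_timing(self):
        cfg = default_cohort_config(10, 3000, seed=9, image_size="small")
        rec = sample_cohort(cfg)
        m = rec.loc[rec.group == "interval", "months_to_diagnosis"]
        assert m.between(0, 24).all()
        assert m.median() == pytest.approx(13, abs=1)
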