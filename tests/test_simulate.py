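"""Synthetic acquisition: samplers, scatterer fields, RF synthesis, PSF."""

import numpy as np
import pytest

import qusmap as q
from qusmap.config import ParameterError
from qusmap.simulate import ScattererField, _fwhm_of_profile, rasterize_truth_mask

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


class TestNakagamiSampler:
    def test_rayleigh_case_mean_square_is_omega(self):
        a = q.sample_nakagami_envelope(m=1.0, omega=1.0, n=10**6, seed=0)
        assert np.all(a >= 0)
        assert np.mean(a**2) == pytest.approx(1.0, abs=3.0 / np.sqrt(10**6))

    @pytest.mark.parametrize("m,omega", [(0.5, 2.0), (2.0, 1.0)])
    def test_moment_estimator_round_trip(self, m, omega):
        a = q.sample_nakagami_envelope(m, omega, n=10**6, seed=42)
        est = q.nakagami_moment_estimate(a)
        assert est.m == pytest.approx(m, abs=0.02)
        assert est.omega == pytest.approx(omega, rel=0.02)

    @pytest.mark.parametrize(
        "kwargs", [dict(m=0, omega=1, n=10), dict(m=1, omega=-1, n=10),
                   dict(m=1, omega=1, n=0)],
    )
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ParameterError):
            q.sample_nakagami_envelope(**kwargs, seed=0)


class TestHKSampler:
    def test_rayleigh_limit_has_nakagami_m_one(self):
        a = q.sample_hk_envelope(epsilon=0.0, sigma=2**-0.5, alpha=500.0,
                                 n=10**6, seed=3)
        assert q.nakagami_moment_estimate(a).m == pytest.approx(1.0, abs=0.02)

    def test_mean_intensity_closed_form(self):
        # mu = eps^2 + 2 alpha sigma^2 = 1 + 2*4*0.25 = 3.0
        a = q.sample_hk_envelope(epsilon=1.0, sigma=0.5, alpha=4.0, n=10**6, seed=7)
        assert np.mean(a**2) == pytest.approx(3.0, rel=0.01)

    def test_coherent_limit_is_nearly_constant(self):
        a = q.sample_hk_envelope(epsilon=2.0, sigma=1e-9, alpha=1.0, n=1000, seed=0)
        assert np.allclose(a, 2.0, atol=1e-6)

    @pytest.mark.parametrize("eps,sigma,alpha,n", [
        (-1, 1, 1, 10), (1, 0, 1, 10), (1, 1, 0, 10), (1, 1, 1, 0),
    ])
    def test_invalid_parameters(self, eps, sigma, alpha, n):
        with pytest.raises(ParameterError):
            q.sample_hk_envelope(eps, sigma, alpha, n, seed=0)

    @pytest.mark.parametrize("eps,sigma,alpha", [(0.0, 1.0, 2.0), (1.5, 0.7, 5.0)])
    def test_mean_intensity_invariant(self, eps, sigma, alpha):
        a = q.sample_hk_envelope(eps, sigma, alpha, n=400_000, seed=11)
        mu = eps**2 + 2 * alpha * sigma**2
        assert np.mean(a**2) == pytest.approx(mu, rel=0.02)


class TestScattererField:
    def test_expected_background_count(self):
        # 2 S/RC over 40x40 mm with a 0.7175 x 0.7194 mm cell => ~6199
        spec = q.PhantomSpec(background_density=2.0, inclusion_density=16.0)
        counts = [
            q.generate_scatterer_field(spec, seed=s).n_background for s in range(8)
        ]
        expected = 2.0 * 40 * 40 / (0.7175 * 0.7194)
        assert np.mean(counts) == pytest.approx(expected, rel=0.02)

    def test_inclusion_density_ratio(self):
        spec = q.PhantomSpec(background_density=2.0, inclusion_density=16.0)
        per_area_in, per_area_out = [], []
        for s in range(6):
            f = q.generate_scatterer_field(spec, seed=s)
            inside = f.in_inclusion(f.positions[:, 0], f.positions[:, 1])
            area_in = np.pi * 5.0**2
            area_out = 40 * 40 - area_in
            per_area_in.append(inside.sum() / area_in)
            per_area_out.append((~inside).sum() / area_out)
        ratio = np.mean(per_area_in) / np.mean(per_area_out)
        assert ratio == pytest.approx(8.0, rel=0.1)

    def test_seed_determinism(self):
        spec = q.PhantomSpec()
        f1 = q.generate_scatterer_field(spec, seed=5)
        f2 = q.generate_scatterer_field(spec, seed=5)
        assert np.array_equal(f1.positions, f2.positions)
        assert np.array_equal(f1.amplitudes, f2.amplitudes)

    def test_inclusion_sparser_than_background_rejected(self):
        with pytest.raises(ParameterError):
            q.PhantomSpec(background_density=10.0, inclusion_density=2.0)


class TestRFSynthesis:
    def test_default_output_shape(self):
        spec = q.PhantomSpec.homogeneous(2.0)
        rf = q.simulate_phantom_frame(spec, seed=0)
        assert rf.shape == (1558, 256)
        assert np.all(np.isfinite(rf.data))

    def test_linearity_in_amplitudes(self, small_config):
        spec = q.PhantomSpec.homogeneous(
            2.0, field_width_mm=small_config.lateral_extent_mm,
            field_depth_mm=small_config.depth_mm,
        )
        base = q.generate_scatterer_field(spec, seed=9)
        f2 = ScattererField(base.positions, 2.5 * base.amplitudes, spec)
        rf1 = q.synthesize_rf_frame(base, small_config)
        rf2 = q.synthesize_rf_frame(f2, small_config)
        np.testing.assert_allclose(rf2.data, 2.5 * rf1.data, rtol=1e-12, atol=1e-12)

    def test_point_target_fwhm_matches_calibration(self):
        cell = q.measure_psf_resolution_cell()
        assert cell.axial_fwhm_mm == pytest.approx(0.7175, rel=0.05)
        assert cell.lateral_fwhm_mm == pytest.approx(0.7194, rel=0.05)

    def test_rayleigh_envelope_snr_at_high_density(self, small_config):
        # unit amplitudes at 10 S/RC approach fully developed speckle:
        # envelope SNR = sqrt(pi / (4 - pi)) = 1.913
        spec = q.PhantomSpec.homogeneous(
            10.0, field_width_mm=small_config.lateral_extent_mm,
            field_depth_mm=small_config.depth_mm,
            amplitude_distribution="unit",
        )
        rf = q.simulate_phantom_frame(spec, small_config, seed=21)
        env = q.compute_envelope(rf).data[100:-100, 15:-15]
        assert env.mean() / env.std() == pytest.approx(1.9130, rel=0.05)

    def test_empty_field_yields_flagged_zero_frame(self, small_config):
        spec = q.PhantomSpec.homogeneous(2.0)
        field = ScattererField(np.empty((0, 2)), np.empty(0), spec)
        rf = q.synthesize_rf_frame(field, small_config)
        assert rf.all_zero
        assert not rf.data.any()

    def test_nakagami_m_monotone_in_density_unit_amplitudes(self, small_config):
        # fully developed speckle regime is approached from below
        ms = []
        for d in (2.0, 4.0, 10.0):
            spec = q.PhantomSpec.homogeneous(
                d, field_width_mm=small_config.lateral_extent_mm,
                field_depth_mm=small_config.depth_mm,
                amplitude_distribution="unit",
            )
            rf = q.simulate_phantom_frame(spec, small_config, seed=77)
            env = q.compute_envelope(rf).data[60:-60, 10:-10]
            ms.append(q.nakagami_moment_estimate(env.ravel()).m)
        assert ms[0] <= ms[1] <= ms[2]
        assert ms[2] == pytest.approx(1.0, abs=0.12)


class TestResolutionCell:
    def test_volume_of_calibrated_psf(self):
        cell = q.measure_psf_resolution_cell()
        assert cell.volume_mm3 == pytest.approx(0.3713, rel=0.01)

    def test_doubling_fwhms_scales_volume_by_eight(self):
        base = q.ResolutionCell(0.7175, 0.7194, 0.7194)
        doubled = q.ResolutionCell(2 * 0.7175, 2 * 0.7194, 2 * 0.7194)
        assert doubled.volume_mm3 == pytest.approx(8 * base.volume_mm3, rel=1e-12)

    def test_fwhm_measurement_on_known_gaussian(self):
        sigma = 0.31
        x = np.arange(-3.0, 3.0, 0.15625)  # coarse, lateral-pitch-like sampling
        profile = np.exp(-0.5 * (x / sigma) ** 2)
        fwhm = _fwhm_of_profile(x, profile)
        assert abs(fwhm - FWHM_PER_SIGMA * sigma) < 0.15625  # one sample spacing
        assert fwhm == pytest.approx(FWHM_PER_SIGMA * sigma, rel=1e-6)


class TestTruthMask:
    def test_rasterized_disk_geometry(self, small_config):
        spec = q.PhantomSpec(
            field_width_mm=small_config.lateral_extent_mm,
            field_depth_mm=small_config.depth_mm,
            background_density=2.0, inclusion_density=16.0,
            inclusion_center_mm=(10.0, 6.5), inclusion_diameter_mm=6.0,
        )
        mask = rasterize_truth_mask(spec, small_config)
        assert mask.shape == (small_config.n_samples, small_config.n_lines)
        # center pixel inside
        r = int(6.5 / small_config.axial_spacing_mm)
        c = int(10.0 / small_config.lateral_pitch_mm)
        assert mask[r, c] == 1
        assert mask[0, 0] == 0
        # area close to pi r^2
        area_mm2 = mask.sum() * small_config.axial_spacing_mm * small_config.lateral_pitch_mm
        assert area_mm2 == pytest.approx(np.pi * 3.0**2, rel=0.02)


class TestBinIO:
    @pytest.mark.parametrize("dtype,rtol", [("float32", 1e-6), ("int16", 1e-3)])
    def test_round_trip(self, tmp_path, small_config, dtype, rtol):
        spec = q.PhantomSpec.homogeneous(
            2.0, field_width_mm=small_config.lateral_extent_mm,
            field_depth_mm=small_config.depth_mm,
        )
        rf = q.simulate_phantom_frame(spec, small_config, seed=4)
        path = tmp_path / "frame.bin"
        q.write_rf_bin(rf, path, dtype=dtype)
        back = q.read_rf_bin(path)
        assert back.config == small_config
        np.testing.assert_allclose(
            back.data, rf.data, rtol=rtol, atol=rtol * np.abs(rf.data).max()
        )
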