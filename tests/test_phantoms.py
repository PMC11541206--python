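"""Phantom generators: determinism, conservation, geometry oracles."""

import numpy as np
import pytest

import exmqc as q


def two_gaussian_profile(x, d, sigma):
    """Analytic transverse profile of two parallel line sources."""
    return np.exp(-((x - d / 2) ** 2) / (2 * sigma**2)) + np.exp(
        -((x + d / 2) ** 2) / (2 * sigma**2)
    )


def n_local_maxima(y):
    return int(np.sum((y[1:-1] > y[:-2]) & (y[1:-1] > y[2:])))


class TestDeterminism:
    @pytest.mark.parametrize("noise", ["none", "gaussian", "poisson"])
    def test_fixed_spec_and_seed_bit_identical(self, noise):
        def render():
            spec = q.PhantomSpec(
                4.0, (96, 96), 12.0, noise=q.NoiseModel(noise, snr=8), seed=77
            )
            return q.render_npc_field(spec, 4)

        (s1, tr1), (s2, tr2) = render(), render()
        assert np.array_equal(s1.voxels, s2.voxels)
        assert tr1.to_json() == tr2.to_json()

    def test_different_seeds_differ(self):
        spec_a = q.PhantomSpec(4.0, (96, 96), 12.0, seed=1)
        spec_b = q.PhantomSpec(4.0, (96, 96), 12.0, seed=2)
        a, _ = q.render_npc_field(spec_a, 4)
        b, _ = q.render_npc_field(spec_b, 4)
        assert not np.array_equal(a.voxels, b.voxels)


class TestMicrotubulePhantom:
    def test_analytic_two_peaks_at_separation(self):
        # separation 62.1, sigma 15: two maxima exactly 62.1 apart at this
        # separation/sigma ratio (verified on the closed-form profile)
        x = np.linspace(-120, 120, 4801)
        y = two_gaussian_profile(x, 62.1, 15.0)
        assert n_local_maxima(y) == 2
        peaks = x[np.flatnonzero((y[1:-1] > y[:-2]) & (y[1:-1] > y[2:])) + 1]
        assert peaks[1] - peaks[0] == pytest.approx(62.1, abs=0.1)

    def test_analytic_peaks_merge_at_large_sigma(self):
        x = np.linspace(-200, 200, 4801)
        assert n_local_maxima(two_gaussian_profile(x, 62.1, 60.0)) == 1

    def test_rendered_profile_matches_analytic(self):
        spec = q.PhantomSpec(2.0, (192, 192), 15.0, seed=5)
        stack, truth = q.render_microtubules(
            spec, 1, 62.1, orientation_policy="horizontal"
        )
        seg = truth.parameters["segments"][0]
        cy = int(round(seg["center_nm"][0] / 2.0))
        cx = int(round(seg["center_nm"][1] / 2.0))
        col = stack.voxels[cy - 60 : cy + 61, cx]
        x = (np.arange(-60, 61)) * 2.0
        ref = two_gaussian_profile(x, 62.1, 15.0)
        assert np.allclose(col / col.max(), ref / ref.max(), atol=5e-3)

    def test_zero_segments_gives_empty_image_and_truth(self):
        spec = q.PhantomSpec(4.0, (64, 64), 12.0, seed=0)
        stack, truth = q.render_microtubules(spec, 0, 60.0)
        assert not stack.voxels.any()
        assert truth.parameters["segments"] == []

    def test_subnyquist_separation_rejected(self):
        spec = q.PhantomSpec(40.0, (64, 64), 60.0, seed=0)
        with pytest.raises(ValueError, match="Nyquist"):
            q.render_microtubules(spec, 1, 70.0)


class TestNpcPhantom:
    def test_truth_chord_distance_matches_formula(self):
        spec = q.PhantomSpec(2.0, (128, 128), 15.0, seed=9)
        _, truth = q.render_npc_field(spec, 1, radius_nm=53.5)
        npc = truth.parameters["npcs"][0]
        pts = np.array(npc["corner_positions_nm"])
        chords = np.linalg.norm(pts - np.roll(pts, -1, axis=0), axis=1)
        assert np.allclose(chords, 2 * 53.5 * np.sin(np.pi / 8), atol=1e-9)
        assert truth.parameters["corner_spacing_nm"] == pytest.approx(40.947, abs=1e-3)

    def test_full_labeling_gives_point_mass_at_eight(self):
        spec = q.PhantomSpec(4.0, (640, 640), 12.0, seed=2)
        _, truth = q.render_npc_field(spec, 100, corner_prob=1.0)
        counts = [sum(n["corners_present"]) for n in truth.parameters["npcs"]]
        assert counts == [8] * 100

    def test_half_labeling_mean_is_binomial(self):
        spec = q.PhantomSpec(4.0, (1280, 1280), 12.0, seed=3)
        _, truth = q.render_npc_field(spec, 400, corner_prob=0.5)
        counts = np.array([sum(n["corners_present"]) for n in truth.parameters["npcs"]])
        # mean 4 within ~4 binomial standard errors of the mean
        sem = np.sqrt(8 * 0.25 / counts.size)
        assert abs(counts.mean() - 4.0) < 4 * sem

    def test_intensity_conservation_under_psf(self):
        # total rendered intensity = emitter count x 2 pi sigma^2 / px^2
        spec = q.PhantomSpec(2.0, (256, 256), 15.0, seed=4)
        _, truth = q.render_npc_field(spec, 4)
        total = truth.parameters["clean_total_intensity"] * spec.pixel_size_nm**2
        expected = truth.parameters["n_emitters"] * 2 * np.pi * 15.0**2
        assert total == pytest.approx(expected, rel=1e-6)


class TestWarpAndFrcPairs:
    def test_zero_amplitude_identity(self):
        spec = q.PhantomSpec(4.0, (96, 96), 15.0, seed=6)
        pre, post, truth = q.make_warp_pair(spec, 0.0, 200.0)
        assert np.array_equal(pre.voxels, post.voxels)
        assert not np.asarray(truth.parameters["displacement_nm"]).any()

    def test_field_rms_matches_requested_amplitude(self):
        spec = q.PhantomSpec(4.0, (128, 128), 15.0, seed=6)
        _, _, truth = q.make_warp_pair(spec, 10.0, 100.0)
        u = np.asarray(truth.parameters["displacement_nm"])
        rms = np.sqrt(np.mean(np.sum(u**2, axis=0)))
        assert rms == pytest.approx(10.0, rel=1e-9)

    def test_frc_pair_noise_free_identical_and_seeded(self):
        spec = q.PhantomSpec(4.0, (64, 64), 12.0, seed=1)
        clean, _ = q.render_npc_field(spec, 1)
        a, b = q.make_frc_pair(clean, q.NoiseModel("none"), seed=0)
        assert np.array_equal(a.voxels, b.voxels)
        n1a, n1b = q.make_frc_pair(clean, q.NoiseModel("gaussian", snr=5), seed=3)
        n2a, n2b = q.make_frc_pair(clean, q.NoiseModel("gaussian", snr=5), seed=3)
        assert np.array_equal(n1a.voxels, n2a.voxels)
        assert np.array_equal(n1b.voxels, n2b.voxels)
        assert not np.array_equal(n1a.voxels, n1b.voxels)

    def test_noise_mean_converges_to_clean_as_snr_grows(self):
        spec = q.PhantomSpec(4.0, (64, 64), 12.0, seed=1)
        clean, _ = q.render_npc_field(spec, 1)
        a, b = q.make_frc_pair(clean, q.NoiseModel("gaussian", snr=1e6), seed=2)
        mean = 0.5 * (a.voxels + b.voxels)
        assert np.allclose(mean, clean.voxels, atol=1e-4 * clean.voxels.max())


class TestUnitConsistency:
    def test_physical_rescale_with_matching_factor_is_invariant(self):
        # doubling physical pixel size and expansion factor together leaves
        # every biological-unit estimate unchanged
        spec = q.PhantomSpec(5.0, (256, 256), 15.0, seed=8, expansion_factor=20.0)
        stack, truth = q.render_microtubules(spec, 1, 62.1)
        rescaled = q.ImageStack(
            stack.voxels, tuple(2 * p for p in stack.pixel_size_nm), 40.0
        )
        box = q.boxes_from_truth(truth.parameters)[0]
        f1 = q.fit_double_gaussian(q.extract_profile(stack, box))
        f2 = q.fit_double_gaussian(q.extract_profile(rescaled, box))
        assert f1.peak_to_peak_nm == pytest.approx(f2.peak_to_peak_nm, abs=1e-9)
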