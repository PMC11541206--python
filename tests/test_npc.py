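"""NPC ring quantification: radius, corner counting, adjacent distances."""

import numpy as np
import pytest
from scipy import ndimage, stats

import exmqc as q
from exmqc.npc import NoRingError, analyze_ring, npc_population_report

CHORD = 2 * np.sin(np.pi / 8)  # adjacent-corner chord per unit radius


def render_single_npc(radius_nm=53.5, psf_nm=15.0, px_nm=2.0, seed=0,
                      corner_prob=1.0, noise=None, shape=128):
    spec = q.PhantomSpec(
        px_nm, (shape, shape), psf_nm,
        noise=noise or q.NoiseModel("none"), seed=seed,
    )
    stack, truth = q.render_npc_field(spec, 1, radius_nm, corner_prob)
    return stack, truth.parameters["npcs"][0]


class TestRadialProfileRadius:
    def test_noiseless_radius_recovery_within_one_nm(self):
        stack, _ = render_single_npc(53.5, psf_nm=15.0, px_nm=2.0, seed=1)
        radius, curve, _ = q.radial_profile_radius(stack.voxels, pixel_size_nm=2.0)
        assert radius == pytest.approx(53.5, abs=1.0)
        assert curve.values[np.isfinite(curve.values)].max() > 0

    def test_point_source_raises_no_ring(self):
        img = np.zeros((64, 64))
        img[32, 32] = 1.0
        img = ndimage.gaussian_filter(img, 5.0)
        with pytest.raises(NoRingError):
            q.radial_profile_radius(img, pixel_size_nm=2.0)

    def test_intensity_scale_invariance(self):
        stack, _ = render_single_npc(seed=2)
        r1, _, _ = q.radial_profile_radius(stack.voxels, pixel_size_nm=2.0)
        r2, _, _ = q.radial_profile_radius(stack.voxels * 37.0, pixel_size_nm=2.0)
        assert r1 == pytest.approx(r2, abs=1e-9)

    def test_peak_method_reads_raw_profile_maximum(self):
        # the raw profile peak sits slightly inside the true radius
        # (curvature bias ~ sigma^2 / 2R); the model fit removes it
        stack, _ = render_single_npc(53.5, psf_nm=15.0, seed=3)
        r_model, _, _ = q.radial_profile_radius(stack.voxels, pixel_size_nm=2.0)
        r_peak, _, _ = q.radial_profile_radius(
            stack.voxels, pixel_size_nm=2.0, method="peak"
        )
        assert r_peak < r_model
        assert r_model - r_peak == pytest.approx(15.0**2 / (2 * 53.5), abs=1.0)


class TestCountCorners:
    def test_all_corners_counted_noiseless(self):
        stack, _ = render_single_npc(seed=4)
        r, _, center = q.radial_profile_radius(stack.voxels, pixel_size_nm=2.0)
        n, flags, _ = q.count_corners(stack.voxels, center, r, pixel_size_nm=2.0)
        assert n == 8 and all(flags)

    def test_partial_labeling_flags_match_truth(self):
        # knock out specific corners with a deterministic pattern
        stack, npc = render_single_npc(seed=6, corner_prob=[1, 1, 0, 1, 1, 1, 0, 1])
        present_truth = npc["corners_present"]
        if sum(present_truth) < 4:
            pytest.skip("degenerate draw")
        r, _, center = q.radial_profile_radius(stack.voxels, pixel_size_nm=2.0)
        n, flags, angles = q.count_corners(stack.voxels, center, r,
                                           pixel_size_nm=2.0)
        assert n == sum(present_truth)
        # the detected corner angles coincide with true present corners
        truth_angles = [
            np.rad2deg(np.arctan2(
                c[0] - npc["center_nm"][0], c[1] - npc["center_nm"][1]
            ))
            for c, p in zip(npc["corner_positions_nm"], present_truth) if p
        ]
        for a in angles:
            diffs = np.abs((np.array(truth_angles) - a + 180) % 360 - 180)
            assert diffs.min() < 5.0

    def test_rotation_invariance_of_count(self):
        stack, _ = render_single_npc(seed=7, corner_prob=[1, 1, 0, 1, 1, 1, 1, 1])
        img = np.asarray(stack.voxels)
        counts = set()
        for ang in np.arange(0, 360, 22.5):
            rot = ndimage.rotate(img, ang, reshape=False, order=3)
            r, _, center = q.radial_profile_radius(rot, pixel_size_nm=2.0)
            n, _, _ = q.count_corners(rot, center, r, pixel_size_nm=2.0)
            counts.add(n)
        assert counts == {7}

    def test_count_never_exceeds_eight_and_monotone_in_threshold(self):
        stack, _ = render_single_npc(
            seed=8, noise=q.NoiseModel("gaussian", snr=8)
        )
        r, _, center = q.radial_profile_radius(stack.voxels, pixel_size_nm=2.0)
        prev = 9
        for thr in (0.2, 0.4, 0.6, 0.8, 0.95):
            n, _, _ = q.count_corners(
                stack.voxels, center, r, threshold=thr, pixel_size_nm=2.0
            )
            assert 0 <= n <= 8
            assert n <= prev
            prev = n


class TestCornerDistances:
    def test_full_ring_matches_chord_formula(self):
        stack, _ = render_single_npc(53.5, psf_nm=12.0, seed=9)
        r, _, center = q.radial_profile_radius(stack.voxels, pixel_size_nm=2.0)
        n, flags, angles = q.count_corners(stack.voxels, center, r,
                                           pixel_size_nm=2.0)
        d = q.corner_distances(stack.voxels, center, r, flags, angles,
                               pixel_size_nm=2.0, psf_sigma_nm=12.0)
        assert len(d) == 8
        assert np.mean(d) == pytest.approx(53.5 * CHORD, abs=2.0)

    def test_opposite_corners_only_gives_empty_list(self):
        stack, npc = render_single_npc(seed=10, psf_nm=12.0,
                                       corner_prob=[1, 0, 0, 0, 1, 0, 0, 0])
        if sum(npc["corners_present"]) != 2:
            pytest.skip("degenerate draw")
        r = npc["radius_nm"]
        center = np.asarray(npc["center_nm"]) / 2.0
        flags = [True, False, False, False, True, False, False, False]
        angles = [
            np.rad2deg(np.arctan2(
                c[0] - npc["center_nm"][0], c[1] - npc["center_nm"][1]
            ))
            for c, p in zip(npc["corner_positions_nm"], npc["corners_present"])
            if p
        ]
        d = q.corner_distances(stack.voxels, center, r, flags, angles,
                               pixel_size_nm=2.0, psf_sigma_nm=12.0)
        assert d == []


class TestPopulationReport:
    def _rings(self, radii, corner_counts, distances=()):
        rings = []
        for r, n in zip(radii, corner_counts):
            ring = q.NpcRing((0.0, 0.0), r, q.RadialCurve(np.arange(5.0), np.ones(5)))
            ring.n_corners = n
            ring.adjacent_distances_nm = list(distances)
            rings.append(ring)
        return rings

    def test_mean_and_median(self):
        rep = npc_population_report(self._rings([50, 55, 60], [8, 8, 8]))
        assert rep["radius_mean_nm"] == pytest.approx(55.0)
        assert rep["radius_median_nm"] == pytest.approx(55.0)

    def test_low_corner_rings_excluded_from_radius_but_histogrammed(self):
        rep = npc_population_report(self._rings([50, 90], [8, 2]))
        assert rep["radius_mean_nm"] == pytest.approx(50.0)
        assert rep["n_radius_rings"] == 1
        assert rep["corner_histogram"][2] == 1 and rep["corner_histogram"][8] == 1

    def test_corner_histogram_matches_binomial(self):
        spec = q.PhantomSpec(4.0, (1280, 1280), 12.0, seed=11)
        _, truth = q.render_npc_field(spec, 400, corner_prob=0.8)
        counts = np.array(
            [sum(n["corners_present"]) for n in truth.parameters["npcs"]]
        )
        observed = np.bincount(counts, minlength=9)[:9]
        expected = stats.binom.pmf(np.arange(9), 8, 0.8) * counts.size
        # pool low-probability bins for a valid chi-square
        keep = expected > 1.0
        chi2 = np.sum((observed[keep] - expected[keep]) ** 2 / expected[keep])
        crit = stats.chi2.ppf(0.99, keep.sum() - 1)
        assert chi2 < crit


class TestEndToEndRing:
    def test_analyze_ring_pipeline(self):
        stack, _ = render_single_npc(
            53.5, psf_nm=12.0, seed=12, noise=q.NoiseModel("poisson",
                                                           peak_counts=500),
        )
        ring = analyze_ring(stack.voxels, pixel_size_nm=2.0, psf_sigma_nm=12.0)
        assert ring.radius_nm == pytest.approx(53.5, abs=2.5)
        assert ring.n_corners >= 7
        assert len(ring.adjacent_distances_nm) >= 6
        assert np.mean(ring.adjacent_distances_nm) == pytest.approx(
            53.5 * CHORD, abs=3.0
        )
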