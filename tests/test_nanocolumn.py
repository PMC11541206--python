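"""Synapse segmentation, autocorrelation g_a(r), enrichment and SNR."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import exmqc as q
from exmqc.nanocolumn import (
    autocorrelation_ga,
    autocorrelation_ga_bruteforce,
    cross_enrichment,
    nanodomain_size,
    segment_synapses,
    pair_clusters,
    snr,
)

from conftest import make_roi


def gaussian_hotspot_roi(fwhm_nm=60.0, box=24, voxel_nm=5.0, base=1.0, amp=4.0):
    """Uniform ball cluster with one central Gaussian hotspot."""
    zz, yy, xx = np.indices((box, box, box))
    c = (box - 1) / 2
    r_nm = np.sqrt((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) * voxel_nm
    mask = r_nm <= (box // 2 - 1) * voxel_nm
    sigma = fwhm_nm / 2.3548
    inten = base + amp * np.exp(-(r_nm**2) / (2 * sigma**2))
    return make_roi(mask, inten, (voxel_nm,) * 3)


class TestSegmentation:
    def test_phantom_synapse_count_recovered(self):
        spec = q.PhantomSpec(
            10.0, (96, 96, 96), 15.0, seed=3,
            noise=q.NoiseModel("gaussian", snr=15),
        )
        stack, _ = q.render_synapse_pair(spec, 8, cluster_radius_nm=120.0)
        for ch in ("reference", "measured"):
            rois = segment_synapses(stack, channel=ch, n_keep=8)
            assert len(rois) == 8

    def test_background_image_gives_empty_list(self, rng):
        vol = rng.normal(0, 1, (24, 24, 24))
        st_ = q.ImageStack(vol, (10.0,) * 3)
        assert segment_synapses(st_, k_sigma=7) == []

    def test_threshold_monotonicity(self):
        spec = q.PhantomSpec(
            10.0, (64, 64, 64), 15.0, seed=4,
            noise=q.NoiseModel("gaussian", snr=10),
        )
        stack, _ = q.render_synapse_pair(spec, 4, cluster_radius_nm=120.0)
        counts = [
            len(segment_synapses(stack, channel=0, k_sigma=k))
            for k in (3.0, 5.0, 7.0, 9.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_mutual_nearest_pairing(self):
        spec = q.PhantomSpec(10.0, (96, 96, 96), 15.0, seed=5,
                             noise=q.NoiseModel("gaussian", snr=15))
        stack, _ = q.render_synapse_pair(spec, 8, cleft_nm=80.0,
                                         cluster_radius_nm=120.0)
        a = segment_synapses(stack, channel="reference", n_keep=8)
        b = segment_synapses(stack, channel="measured", n_keep=8)
        pairs = pair_clusters(a, b, max_distance_nm=500.0)
        assert len(pairs) == 8
        for ra, rb in pairs:
            d = np.linalg.norm(ra.centroid_nm - rb.centroid_nm)
            assert d < 200.0


class TestAutocorrelation:
    def test_uniform_cluster_is_unity_everywhere(self, rng):
        mask = rng.random((10, 10, 10)) < 0.5
        mask[4, 4, 4] = True
        roi = make_roi(mask, np.ones(mask.shape), (10.0,) * 3)
        curve = autocorrelation_ga(roi, shell_nm=5.0)
        finite = np.isfinite(curve.values)
        assert np.allclose(curve.values[finite], 1.0, atol=1e-9)

    def test_fft_matches_bruteforce_oracle(self, blob_roi):
        a = autocorrelation_ga(blob_roi, shell_nm=7.0)
        b = autocorrelation_ga_bruteforce(blob_roi, shell_nm=7.0)
        both = np.isfinite(a.values) & np.isfinite(b.values)
        assert np.array_equal(np.asarray(a.n), np.asarray(b.n))
        assert np.max(np.abs(a.values[both] - b.values[both])) < 1e-6

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_fft_oracle_equivalence_property(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(5, 12, 3))
        mask = rng.random(shape) < 0.5
        mask[tuple(s // 2 for s in shape)] = True
        inten = rng.random(shape) + 0.05
        vsz = tuple(rng.uniform(5, 30, 3).round(1))
        roi = make_roi(mask, inten, vsz)
        a = autocorrelation_ga(roi, shell_nm=6.0)
        b = autocorrelation_ga_bruteforce(roi, shell_nm=6.0)
        both = np.isfinite(a.values) & np.isfinite(b.values)
        assert np.max(np.abs(a.values[both] - b.values[both])) < 1e-6

    def test_intensity_scale_invariance(self, blob_roi):
        doubled = make_roi(
            blob_roi.mask, blob_roi.intensities * 2.0, blob_roi.voxel_size_nm
        )
        c1 = autocorrelation_ga(blob_roi, shell_nm=7.0)
        c2 = autocorrelation_ga(doubled, shell_nm=7.0)
        assert np.allclose(c1.values, c2.values, atol=1e-9, equal_nan=True)

    def test_hotspot_elevates_short_radii(self):
        roi = gaussian_hotspot_roi(fwhm_nm=60.0)
        curve = autocorrelation_ga(roi, shell_nm=10.0, max_radius_nm=120.0)
        assert curve.values[0] > 1.1
        # decays toward baseline by the hotspot scale
        long_r = curve.values[np.isfinite(curve.values)][-1]
        assert curve.values[0] > long_r

    def test_anisotropic_voxels_honoured(self):
        # the same isotropic object sampled at 1:1:1 and 2:1:1 aspect gives
        # the same nm-binned curve
        iso = gaussian_hotspot_roi(fwhm_nm=60.0, box=24, voxel_nm=6.0)
        zz, yy, xx = np.indices((12, 24, 24))
        c_z, c = 5.5, 11.5
        r_nm = np.sqrt(
            ((zz - c_z) * 12.0) ** 2 + ((yy - c) * 6.0) ** 2 + ((xx - c) * 6.0) ** 2
        )
        mask = r_nm <= 66.0
        sigma = 60.0 / 2.3548
        inten = 1.0 + 4.0 * np.exp(-(r_nm**2) / (2 * sigma**2))
        aniso = make_roi(mask, inten, (12.0, 6.0, 6.0))
        c1 = autocorrelation_ga(iso, shell_nm=12.0, max_radius_nm=120.0)
        c2 = autocorrelation_ga(aniso, shell_nm=12.0, max_radius_nm=120.0)
        both = np.isfinite(c1.values) & np.isfinite(c2.values)
        assert np.allclose(c1.values[both], c2.values[both], rtol=0.1)


class TestNanodomainSize:
    def test_flat_curve_has_no_domain(self):
        curve = q.RadialCurve(np.arange(0, 100, 5.0), np.ones(20))
        size, defined = nanodomain_size(curve)
        assert size == 0.0 and not defined

    @staticmethod
    def _phantom_curve(fwhm_nm, seed=5):
        spec = q.PhantomSpec(8.0, (72, 72, 72), 10.0, seed=seed,
                             noise=q.NoiseModel("gaussian", snr=10))
        stack, _ = q.render_synapse_pair(
            spec, 1, nanodomain_size_nm=fwhm_nm, n_nanodomains=2,
            trans_offset_nm=0.0,
        )
        roi = segment_synapses(stack, channel="reference", n_keep=1)[0]
        return autocorrelation_ga(roi, shell_nm=8.0, max_radius_nm=300.0)

    def test_phantom_hotspot_recovery_near_rendered_fwhm(self):
        curve = self._phantom_curve(60.0)
        size, defined = nanodomain_size(curve)
        assert defined
        assert size == pytest.approx(60.0, abs=20.0)

    def test_size_grows_with_rendered_hotspot(self):
        sizes = []
        for fwhm in (40.0, 60.0, 80.0):
            size, defined = nanodomain_size(self._phantom_curve(fwhm))
            assert defined
            sizes.append(size)
        assert sizes[0] < sizes[1] < sizes[2]

    def test_invariant_to_appended_flat_tail(self):
        curve = self._phantom_curve(60.0)
        size1, _ = nanodomain_size(curve)
        ext = q.RadialCurve(
            np.concatenate([curve.radii, curve.radii[-1] + np.arange(1, 6) * 8.0]),
            np.concatenate([curve.values, np.full(5, curve.values[-1])]),
        )
        size2, _ = nanodomain_size(ext)
        assert size1 == pytest.approx(size2, abs=1e-9)


class TestEnrichment:
    def test_uniform_measured_cluster_is_unity(self, rng):
        mask = rng.random((12, 12, 12)) < 0.6
        mask[6, 6, 6] = True
        meas = make_roi(mask, np.ones(mask.shape), (10.0,) * 3)
        ref = make_roi(mask, rng.random((12, 12, 12)) + 0.1, (10.0,) * 3)
        curve = cross_enrichment(meas, ref, shell_nm=10.0, max_radius_nm=100.0)
        finite = np.isfinite(curve.values)
        assert np.allclose(curve.values[finite], 1.0, atol=1e-9)

    def test_aligned_nanocolumn_peaks_at_origin(self):
        # SNR 30: post-expansion staining regime where the cluster envelope
        # clears the 7-sigma segmentation threshold
        spec = q.PhantomSpec(8.0, (72, 72, 72), 15.0, seed=5,
                             noise=q.NoiseModel("gaussian", snr=30))
        stack, _ = q.render_synapse_pair(
            spec, 1, nanodomain_size_nm=60.0, n_nanodomains=2,
            trans_offset_nm=0.0, cleft_nm=80.0,
        )
        meas = segment_synapses(stack, channel="measured", n_keep=1)[0]
        ref = segment_synapses(stack, channel="reference", n_keep=1)[0]
        curve = cross_enrichment(meas, ref, shell_nm=8.0, max_radius_nm=150.0)
        v = curve.values
        finite = np.isfinite(v)
        assert v[finite][0] > 1.5  # enriched at the projected peak
        assert v[finite][0] == np.nanmax(v)  # decays outward
        assert v[finite][-1] < v[finite][0]

    def test_displaced_hotspots_anti_enrich_origin(self):
        spec = q.PhantomSpec(8.0, (72, 72, 72), 15.0, seed=7,
                             noise=q.NoiseModel("gaussian", snr=30))
        stack, _ = q.render_synapse_pair(
            spec, 1, nanodomain_size_nm=50.0, n_nanodomains=1,
            trans_offset_nm=120.0,
        )
        meas = segment_synapses(stack, channel="measured", n_keep=1)[0]
        ref = segment_synapses(stack, channel="reference", n_keep=1)[0]
        curve = cross_enrichment(meas, ref, shell_nm=8.0, max_radius_nm=150.0)
        first = curve.values[np.isfinite(curve.values)][0]
        assert first <= 1.0

    def test_intensity_scale_invariance(self, blob_roi, rng):
        ref = make_roi(blob_roi.mask, rng.random(blob_roi.mask.shape) + 0.1,
                       blob_roi.voxel_size_nm)
        c1 = cross_enrichment(blob_roi, ref, shell_nm=10.0, max_radius_nm=150.0)
        scaled = make_roi(blob_roi.mask, blob_roi.intensities * 9.0,
                          blob_roi.voxel_size_nm)
        c2 = cross_enrichment(scaled, ref, shell_nm=10.0, max_radius_nm=150.0)
        assert np.allclose(c1.values, c2.values, atol=1e-9, equal_nan=True)


class TestSnr:
    def test_known_ratio(self, rng):
        vol = rng.normal(0, 10.0, (20, 20, 20))
        vol[8:12, 8:12, 8:12] = 70.0
        st_ = q.ImageStack(vol, (10.0,) * 3)
        rois = segment_synapses(st_, k_sigma=5, n_keep=1)
        bg = np.ones(vol.shape, bool)
        sl = tuple(slice(o, o + s) for o, s in zip(rois[0].origin,
                                                   rois[0].mask.shape))
        bg[sl] = False
        value = snr(st_, rois, bg)[0]
        assert value == pytest.approx(7.0, rel=0.15)

    def test_scaling_image_leaves_snr_unchanged(self, rng):
        vol = rng.normal(0, 10.0, (20, 20, 20))
        vol[8:12, 8:12, 8:12] = 70.0
        bg = np.ones(vol.shape, bool)
        bg[6:14, 6:14, 6:14] = False
        st1 = q.ImageStack(vol, (10.0,) * 3)
        st2 = q.ImageStack(vol * 3.7, (10.0,) * 3)
        r1 = segment_synapses(st1, k_sigma=5, n_keep=1)
        r2 = segment_synapses(st2, k_sigma=5, n_keep=1)
        assert snr(st1, r1, bg)[0] == pytest.approx(snr(st2, r2, bg)[0], rel=1e-9)

    def test_overlapping_background_rejected(self, rng):
        vol = rng.normal(0, 1.0, (16, 16, 16))
        vol[8, 8, 8] = 100.0
        st_ = q.ImageStack(vol, (10.0,) * 3)
        rois = segment_synapses(st_, k_sigma=5, n_keep=1)
        with pytest.raises(ValueError):
            snr(st_, rois, np.ones(vol.shape, bool))
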