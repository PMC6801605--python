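"""Profiling geometry, aggregation, AUC, decay fitting, accumulation."""

import numpy as np
import pytest

import mabpen as mp
from mabpen.exceptions import FitError, ProfilingError, UsageError
from mabpen.microdistribution import MeanProfile
from conftest import truth_geometry


def _segment(sec):
    tumor, contour = mp.segment_tumor(sec)
    return tumor, contour


class TestEdgeProfiles:
    def test_uniform_field_gives_constant_profiles(self, uniform_section):
        _, sec, truth = uniform_section
        tumor, contour, _ = truth_geometry(truth)
        for p in mp.edge_profiles(sec, tumor, contour):
            np.testing.assert_allclose(p.intensities, 0.3, rtol=1e-6)

    def test_mean_profile_matches_analytic_single_source(self, circular_edge_only):
        params, sec, truth = circular_edge_only
        tumor, contour, _ = truth_geometry(truth)
        prof = mp.edge_profiles(sec, tumor, contour)
        mean = mp.aggregate_profiles(prof)
        expected = mp.analytic_profile(params, "edge", mean.bin_centers)
        rel = np.abs(mean.mean - expected) / expected
        assert rel.max() < 0.03

    def test_inward_normal_geometry(self, circular_edge_only):
        # on a circle the inward normal must pass within 2 px of the centroid
        _, sec, truth = circular_edge_only
        tumor, contour, _ = truth_geometry(truth)
        from mabpen.microdistribution import ProfileParams, _inward_normals
        params = ProfileParams()
        arclen = contour.arclength()
        targets = np.linspace(0, arclen[-1], 36, endpoint=False)
        idx = np.unique(np.searchsorted(arclen, targets))
        idx = idx[idx < len(contour.coords) - 1]
        anchors, normals = _inward_normals(contour, tumor.pixels, idx,
                                           params.tangent_halfspan,
                                           params.contour_smoothing_window)
        centroid = np.argwhere(tumor.pixels).mean(axis=0)
        for a, n in zip(anchors, normals):
            # perpendicular distance from centroid to the ray a + t n
            v = centroid - a
            dist = abs(v[0] * n[1] - v[1] * n[0])
            assert dist < 2.0

    def test_truncation_at_mask_exit(self, circular_edge_only):
        params, sec, _ = circular_edge_only
        tumor, contour = _segment(sec)
        deep = mp.ProfileParams(max_depth_edge=5000.0)
        prof = mp.edge_profiles(sec, tumor, contour, deep)
        diameter = 2 * params.tumor_radius
        for p in prof:
            assert p.distances[-1] <= diameter + 5 * sec.pixel_size

    def test_thin_tumor_rejected(self):
        z = np.zeros((64, 64))
        nuclei = z.copy()
        nuclei[32, 10:50] = 1.0  # 1-pixel-thin strip
        sec = mp.SectionImage(nuclei=nuclei, antibody=z, vessel=z, pixel_size=10.0)
        params = mp.SegmentationParams(smoothing_sigma=0.0, min_object_area=0.0)
        tumor, contour = mp.segment_tumor(sec, params)
        with pytest.raises(ProfilingError):
            mp.edge_profiles(sec, tumor, contour, mp.ProfileParams(bin_width=30.0))


class TestVesselProfiles:
    def test_uniform_field_gives_constant_profiles(self, uniform_section):
        _, sec, truth = uniform_section
        tumor, _, vessels = truth_geometry(truth)
        for p in mp.vessel_profiles(sec, tumor, vessels):
            np.testing.assert_allclose(p.intensities, 0.3, rtol=1e-6)

    def test_profile_matches_analytic_single_vessel(self, circular_vessel_only):
        params, sec, truth = circular_vessel_only
        tumor, _, vessels = truth_geometry(truth)
        profs = mp.vessel_profiles(sec, tumor, vessels)
        assert len(profs) == 1
        p = profs[0]
        expected = mp.analytic_profile(params, "vessel", p.distances)
        rel = np.abs(p.intensities - expected) / expected
        assert rel.max() < 0.03

    def test_far_vessel_sees_only_background(self):
        # field decays from vessel 1 only; vessel 2 sits far away, so its
        # near-wall bins read ~background
        shape = (300, 300)
        rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
        tumor = (rr - 149.5) ** 2 + (cc - 149.5) ** 2 <= 130 ** 2
        v1 = (rr - 149.5) ** 2 + (cc - 80) ** 2 <= 5 ** 2
        v2 = (rr - 149.5) ** 2 + (cc - 220) ** 2 <= 5 ** 2
        from scipy import ndimage as ndi
        d1 = np.maximum(ndi.distance_transform_edt(~v1) - 0.5, 0)  # px = µm here
        background = 0.05
        field = np.where(tumor, background + np.exp(-d1 / 15.0), 0.0)
        sec = mp.SectionImage(nuclei=tumor.astype(float), antibody=field,
                              vessel=(v1 | v2).astype(float), pixel_size=1.0)
        profs = mp.vessel_profiles(sec, mp.Mask(tumor), mp.Mask(v1 | v2, "vessel"),
                                   mp.ProfileParams(max_depth_vessel=30.0))
        by_col = {round(p.anchor[1] / 10) * 10: p for p in profs}
        near_wall = by_col[220].intensities[:5]
        assert np.all(near_wall < background + np.exp(-(140 - 60) / 15.0) + 0.01)
        assert by_col[80].intensities[0] > 0.9

    def test_empty_vessel_mask_rejected(self, uniform_section):
        _, sec, _ = uniform_section
        tumor, _ = _segment(sec)
        empty = mp.Mask(np.zeros(sec.shape, dtype=bool), "vessel")
        with pytest.raises(ProfilingError):
            mp.vessel_profiles(sec, tumor, empty)

    def test_peripheral_central_labels(self, default_section):
        _, sec, _ = default_section
        tumor, _ = _segment(sec)
        vessels = mp.segment_vessels(sec, tumor)
        profs = mp.vessel_profiles(sec, tumor, vessels)
        assert all(p.region in ("peripheral", "central") for p in profs)


class TestAggregation:
    def _const(self, value, n_bins=5, bw=1.0):
        d = np.arange(n_bins) * bw
        return mp.LineProfile(distances=d, intensities=np.full(n_bins, float(value)),
                              source="edge")

    def test_identical_profiles_zero_sd(self):
        mean = mp.aggregate_profiles([self._const(2.0)] * 30)
        np.testing.assert_allclose(mean.mean, 2.0)
        np.testing.assert_allclose(mean.sd, 0.0)
        assert np.all(mean.n == 30)

    def test_two_constant_profiles_sample_sd(self):
        mean = mp.aggregate_profiles([self._const(0.0), self._const(2.0)])
        np.testing.assert_allclose(mean.mean, 1.0)
        np.testing.assert_allclose(mean.sd, np.sqrt(2.0))  # sample sd of {0, 2}

    def test_single_profile_sd_zero_n_one(self):
        mean = mp.aggregate_profiles([self._const(1.5)])
        np.testing.assert_allclose(mean.sd, 0.0)
        assert np.all(mean.n == 1)

    def test_mixed_sources_rejected(self):
        a = self._const(1.0)
        b = mp.LineProfile(distances=a.distances, intensities=a.intensities,
                           source="vessel")
        with pytest.raises(UsageError):
            mp.aggregate_profiles([a, b])

    def test_ragged_profiles_counted_per_bin(self):
        long = self._const(1.0, n_bins=6)
        short = self._const(3.0, n_bins=3)
        mean = mp.aggregate_profiles([long, short])
        np.testing.assert_allclose(mean.n, [2, 2, 2, 1, 1, 1])
        np.testing.assert_allclose(mean.mean, [2, 2, 2, 1, 1, 1])


class TestAUC:
    def test_constant_profile_rectangle(self):
        d = np.arange(0.0, 81.0, 1.0)
        prof = MeanProfile(bin_centers=d, mean=np.ones_like(d), sd=np.zeros_like(d),
                           n=np.ones_like(d), source="edge")
        res = mp.profile_auc(prof)
        assert res.auc_raw == pytest.approx(80.0)

    def test_exponential_matches_closed_form(self):
        d = np.arange(0.0, 81.0, 1.0)
        y = np.exp(-d / 20.0)
        prof = MeanProfile(bin_centers=d, mean=y, sd=np.zeros_like(d),
                           n=np.ones_like(d), source="edge")
        res = mp.profile_auc(prof)
        exact = 20.0 * (1 - np.exp(-4.0))
        assert res.auc_raw == pytest.approx(exact, rel=1e-3)

    def test_linearity_in_intensity(self):
        rng = np.random.default_rng(0)
        d = np.arange(0.0, 40.0, 1.0)
        y = rng.random(len(d)) + 0.1
        mk = lambda yy: MeanProfile(bin_centers=d, mean=yy, sd=0 * d, n=0 * d + 1,
                                    source="edge")
        a1 = mp.profile_auc(mk(y)).auc_raw
        a3 = mp.profile_auc(mk(3.0 * y)).auc_raw
        assert a3 == pytest.approx(3.0 * a1, rel=1e-12)

    def test_trapezoid_error_quadratic_in_bin_width(self):
        # halving the bin width should shrink the error ~4x
        exact = 20.0 * (1 - np.exp(-4.0))
        errs = []
        for bw in (4.0, 2.0, 1.0):
            d = np.arange(0.0, 80.0 + bw / 2, bw)
            y = np.exp(-d / 20.0)
            prof = MeanProfile(bin_centers=d, mean=y, sd=0 * d, n=0 * d + 1,
                               source="edge")
            errs.append(abs(mp.profile_auc(prof).auc_raw - exact))
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.15)
        assert errs[1] / errs[2] == pytest.approx(4.0, rel=0.15)

    def test_too_few_bins_rejected(self):
        prof = MeanProfile(bin_centers=np.array([0.0]), mean=np.array([1.0]),
                           sd=np.array([0.0]), n=np.array([1]), source="edge")
        with pytest.raises(UsageError):
            mp.profile_auc(prof)


class TestFitDecay:
    def _profile(self, a, lam, b, d=None, noise=0.0, seed=0):
        d = np.arange(0.0, 81.0, 1.0) if d is None else d
        y = a * np.exp(-d / lam) + b
        if noise:
            y = y + np.random.default_rng(seed).normal(0, noise, len(d))
        return MeanProfile(bin_centers=d, mean=y, sd=0 * d, n=0 * d + 1, source="edge")

    def test_exact_exponential_recovered(self):
        fit = mp.fit_decay(self._profile(1.0, 20.0, 0.0))
        assert fit.decay_length == pytest.approx(20.0, rel=0.01)
        assert fit.amplitude == pytest.approx(1.0, rel=0.01)

    def test_constant_profile_unidentifiable(self):
        with pytest.raises(FitError):
            mp.fit_decay(self._profile(0.0, 20.0, 0.7))

    def test_end_to_end_noiseless_within_10pct(self, circular_edge_only):
        params, sec, _ = circular_edge_only
        tumor, contour = _segment(sec)
        mean = mp.aggregate_profiles(mp.edge_profiles(sec, tumor, contour))
        fit = mp.fit_decay(mean)
        assert abs(fit.decay_length - params.edge_decay) / params.edge_decay < 0.10


class TestAccumulation:
    def test_uniform_field(self, uniform_section):
        params, sec, truth = uniform_section
        res = mp.total_accumulation(sec, mp.Mask(truth.tumor_mask))
        assert res.accumulation == pytest.approx(0.3 / params.pixel_size ** 2)
        assert res.accumulation * res.tumor_area == pytest.approx(res.total_intensity)

    def test_doubling_intensities_doubles_accumulation(self, default_section):
        _, sec, truth = default_section
        mask = mp.Mask(truth.tumor_mask)
        r1 = mp.total_accumulation(sec, mask)
        doubled = mp.SectionImage(nuclei=sec.nuclei, antibody=2 * sec.antibody,
                                  vessel=sec.vessel, pixel_size=sec.pixel_size)
        r2 = mp.total_accumulation(doubled, mask)
        assert r2.accumulation == pytest.approx(2 * r1.accumulation, rel=1e-12)

    def test_matches_bruteforce_loop(self, default_section):
        _, sec, truth = default_section
        mask = mp.Mask(truth.tumor_mask)
        res = mp.total_accumulation(sec, mask)
        total = 0.0
        count = 0
        for r in range(sec.shape[0]):
            for c in range(sec.shape[1]):
                if truth.tumor_mask[r, c]:
                    total += sec.antibody[r, c]
                    count += 1
        assert res.total_intensity == pytest.approx(total, rel=1e-12)
        assert res.accumulation == pytest.approx(total / (count * sec.pixel_size ** 2),
                                                 rel=1e-12)

    def test_invariant_under_pixel_permutation(self, uniform_section):
        _, sec, truth = uniform_section
        rng = np.random.default_rng(1)
        perm = rng.permutation(sec.antibody.size)
        shuffled = mp.SectionImage(
            nuclei=sec.nuclei,
            antibody=sec.antibody.ravel()[perm].reshape(sec.shape),
            vessel=sec.vessel, pixel_size=sec.pixel_size)
        mask_perm = mp.Mask(truth.tumor_mask.ravel()[perm].reshape(sec.shape))
        a = mp.total_accumulation(sec, mp.Mask(truth.tumor_mask))
        b = mp.total_accumulation(shuffled, mask_perm)
        assert b.accumulation == pytest.approx(a.accumulation, rel=1e-12)

    def test_empty_mask_rejected(self, uniform_section):
        _, sec, _ = uniform_section
        with pytest.raises(UsageError):
            mp.total_accumulation(sec, mp.Mask(np.zeros(sec.shape, dtype=bool)))


def test_distance_map_mode_agrees_with_dense_lines(circular_edge_only):
    """Two independent computations of the edge profile agree within 5%/bin."""
    _, sec, _ = circular_edge_only
    tumor, contour = mp.segment_tumor(sec)
    dense = mp.ProfileParams(n_lines_per_section=360)
    line_mean = mp.aggregate_profiles(mp.edge_profiles(sec, tumor, contour, dense), dense)
    map_mean = mp.edge_profile_distance_map(sec, tumor)
    interp = np.interp(map_mean.bin_centers, line_mean.bin_centers, line_mean.mean)
    rel = np.abs(map_mean.mean - interp) / interp
    assert rel.max() < 0.05
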