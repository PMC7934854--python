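"""Cone detection: Otsu, bright/dim passes, fragmentation, full counting."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import retmosaic as rm
from retmosaic.detection import detect_bright, detect_dim, log_response
from retmosaic.errors import (
    DegenerateHistogramError,
    InsufficientDataError,
    ValidationError,
)
from retmosaic.synthetic import render_image

from oracles import brute_force_otsu


class TestOtsu:
    def test_perfectly_bimodal_split(self):
        img = np.full((40, 25), 10.0)
        img.ravel()[:100] = 200.0
        thr = rm.otsu_threshold(img)
        assert (img > thr).sum() == 100
        assert ((img > thr) == (img == 200.0)).all()

    def test_matches_exhaustive_search_on_random_histograms(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(50, 2000))
            # bimodal-ish 8-bit data
            vals = np.concatenate(
                [
                    rng.normal(rng.uniform(20, 100), rng.uniform(5, 30), n),
                    rng.normal(rng.uniform(120, 240), rng.uniform(5, 30), n // 2 + 1),
                ]
            )
            vals = np.clip(np.round(vals), 0, 255)
            if vals.max() == vals.min():
                continue
            img = vals.reshape(1, -1).repeat(2, axis=0)
            assert rm.otsu_threshold(img) == brute_force_otsu(img.ravel())

    def test_constant_image_raises(self):
        with pytest.raises(DegenerateHistogramError):
            rm.otsu_threshold(np.full((8, 8), 3.0))

    def test_masked_histogram_only(self):
        img = np.full((10, 10), 5.0)
        img[:, 5:] = 100.0
        mask = np.zeros((10, 10), bool)
        mask[:, :5] = True
        with pytest.raises(DegenerateHistogramError):
            rm.otsu_threshold(img, mask)


class TestBrightPass:
    def test_blank_image_no_components(self):
        img = np.full((64, 64), 9.0)
        img[0, 0] = 9.5  # lone bright pixel, below the minimum component area
        assert detect_bright(img, None) == []

    def test_separated_nuclei_recovered_with_subpixel_centroids(self):
        spec = rm.FlatMountSpec(
            seed=4,
            image_height_px=256,
            image_width_px=256,
            retina_radius_px=110,
            n_cones=10,
            dim_fraction=0.0,
            cluster_fraction=0.0,
            min_separation_px=25.0,
            noise_sd=0.0,
            shot_noise=False,
        )
        t = rm.generate_flatmount(spec)
        comps = detect_bright(t.image, t.retina_mask)
        assert len(comps) == 10
        cents = np.array([c.centroid for c in comps])
        d, _ = __import__("scipy.spatial", fromlist=["cKDTree"]).cKDTree(cents).query(t.centroids)
        assert np.all(d <= 1.0)

    def test_touching_pair_merges_into_double_area_component(self):
        # singletons and one touching pair share the image, hence the threshold
        spec = rm.FlatMountSpec(
            seed=0, image_height_px=256, image_width_px=256, retina_radius_px=120,
            noise_sd=0.0, shot_noise=False, n_cones=0,
        )
        singles = np.array([[60.0 + 40 * i, 60.0] for i in range(4)] + [[60.0 + 40 * i, 180.0] for i in range(4)])
        pair = np.array([[190.0, 120.0], [190.0, 122.0]])
        pts = np.vstack([singles, pair])
        img = render_image(spec, pts, np.full(len(pts), 2000.0))
        comps = detect_bright(img, None)
        assert len(comps) == len(singles) + 1
        areas = sorted(c.area_px for c in comps)
        a1 = float(np.median(areas[: len(singles)]))
        merged = areas[-1]
        # overlapping tails add intensity, so the union is not exactly 2x
        assert merged == pytest.approx(2 * a1, rel=0.35)
        assert merged > 1.4 * a1


class TestDimPass:
    def _bright_and_dim_scene(self):
        spec = rm.FlatMountSpec(
            seed=6, image_height_px=512, image_width_px=512, retina_radius_px=240,
            n_cones=0, noise_sd=2.0,
        )
        rng = np.random.default_rng(11)
        nb, nd = 120, 20
        pts = []
        while len(pts) < nb + nd:
            cand = rng.uniform(100, 412, size=2)
            if not pts or np.min(np.hypot(*(np.array(pts) - cand).T)) > 18:
                pts.append(cand)
        pts = np.array(pts)
        amps = np.r_[np.full(nb, 3000.0), np.full(nd, 600.0)]
        img = render_image(spec, pts, amps, np.random.default_rng(3))
        mask = np.ones(img.shape, bool)
        return img, mask, pts[:nb], pts[nb:]

    def test_dim_nuclei_found_near_truth(self):
        img, mask, bright_pts, dim_pts = self._bright_and_dim_scene()
        comps = detect_bright(img, mask)
        # the global threshold must have left the dim nuclei for the 2nd pass
        thr = rm.otsu_threshold(img, mask)
        assert thr > 600 + 100
        calls = detect_dim(img, mask, comps)
        from scipy.spatial import cKDTree

        got = np.array([c.centroid for c in calls])
        d, _ = cKDTree(got).query(dim_pts)
        assert (d <= 1.5).sum() >= 19

    def test_no_dim_calls_when_all_bright_captured(self):
        spec = rm.FlatMountSpec(
            seed=8, image_height_px=256, image_width_px=256, retina_radius_px=110,
            n_cones=15, dim_fraction=0.0, min_separation_px=20.0,
        )
        t = rm.generate_flatmount(spec)
        comps = detect_bright(t.image, t.retina_mask)
        calls = detect_dim(t.image, t.retina_mask, comps)
        assert len(calls) <= 1  # at most stray noise

    def test_log_response_peaks_at_spot_center(self):
        spec = rm.FlatMountSpec(
            seed=0, image_height_px=64, image_width_px=64, retina_radius_px=30,
            n_cones=0, noise_sd=0.0, shot_noise=False,
        )
        img = render_image(spec, np.array([[31.0, 33.0]]), np.array([500.0]))
        resp = log_response(img, spec.nucleus_sigma_px)
        peak = np.unravel_index(np.argmax(resp), resp.shape)
        assert np.hypot(peak[0] - 31.0, peak[1] - 33.0) <= 1.0


class TestFragmentation:
    def test_round_half_even_rule(self):
        assert rm.fragment_count(10.0, 10.0) == 1
        assert rm.fragment_count(34.0, 10.0) == 3  # 3.4 rounds down
        assert rm.fragment_count(25.0, 10.0) == 2  # 2.5 rounds half-to-even
        assert rm.fragment_count(35.0, 10.0) == 4  # 3.5 rounds half-to-even
        assert rm.fragment_count(1.0, 10.0) == 1  # floor at one cone

    def test_rejects_nonpositive(self):
        with pytest.raises(ValidationError):
            rm.fragment_count(0, 10)
        with pytest.raises(ValidationError):
            rm.fragment_count(10, -1)

    @given(
        st.floats(min_value=1.0, max_value=1e4),
        st.floats(min_value=1.0, max_value=1e4),
        st.floats(min_value=1.0, max_value=500.0),
    )
    def test_monotone_in_area(self, a1, a2, est):
        lo, hi = sorted([a1, a2])
        assert rm.fragment_count(lo, est) <= rm.fragment_count(hi, est)

    def test_estimate_identical_areas(self):
        assert rm.estimate_cone_area([30.0] * 8) == 30.0

    def test_estimate_robust_to_doublets(self):
        areas = [30.0] * 90 + [60.0] * 10
        assert rm.estimate_cone_area(areas) == 30.0

    def test_estimate_needs_five_components(self):
        with pytest.raises(InsufficientDataError):
            rm.estimate_cone_area([30.0] * 4)


class TestCountCones:
    def test_blank_image_counts_zero(self):
        assert rm.count_cones(np.full((64, 64), 7.0)).n_cones == 0

    def test_gain_invariance(self, small_mosaic):
        truth, cone_set = small_mosaic
        scaled = rm.count_cones(truth.image * 3.0, truth.retina_mask)
        assert abs(scaled.n_cones - cone_set.n_cones) <= max(1, 0.005 * cone_set.n_cones)

    def test_deterministic(self, small_mosaic):
        truth, cone_set = small_mosaic
        again = rm.count_cones(truth.image, truth.retina_mask)
        assert again.n_cones == cone_set.n_cones
        assert np.array_equal(again.centroids(), cone_set.centroids())

    def test_noiseless_nonoverlapping_count_is_exact(self):
        spec = rm.FlatMountSpec(
            seed=5, image_height_px=512, image_width_px=512, retina_radius_px=240,
            n_cones=400, noise_sd=0.0, shot_noise=False, cluster_fraction=0.0,
            min_separation_px=10.0,
        )
        t = rm.generate_flatmount(spec)
        assert rm.count_cones(t.image, t.retina_mask).n_cones == t.n_true

    def test_small_mosaic_recovery(self, small_mosaic):
        truth, cone_set = small_mosaic
        m = rm.match_points(truth.centroids, cone_set.centroids(), 3.0)
        assert m.recall >= 0.93 and m.precision >= 0.93
        assert abs(cone_set.n_cones - truth.n_true) / truth.n_true <= 0.07

    def test_summary_records_provenance(self, small_mosaic):
        _, cone_set = small_mosaic
        s = cone_set.summary()
        assert s["n_cones"] == cone_set.n_cones
        assert s["otsu_threshold"] > 0
        assert s["log_sigma_px"] > 0
        assert s["cone_area_estimate_px"] > 0


class TestMatching:
    def test_exact_match(self):
        pts = np.array([[1.0, 1.0], [5.0, 5.0]])
        m = rm.match_points(pts, pts, radius=1.0)
        assert m.recall == 1.0 and m.precision == 1.0

    def test_one_to_one_greedy(self):
        truth = np.array([[0.0, 0.0], [0.0, 2.0]])
        pred = np.array([[0.0, 0.9]])  # near both, may serve only one
        m = rm.match_points(truth, pred, radius=1.5)
        assert m.n_matched == 1
        assert m.recall == 0.5 and m.precision == 1.0

    def test_empty_cases(self):
        m = rm.match_points(np.empty((0, 2)), np.array([[1.0, 1.0]]), 2.0)
        assert m.recall == 1.0 and m.precision == 0.0
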