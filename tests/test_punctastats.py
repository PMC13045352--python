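import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exmkit.fixtures import FWHM_PER_SIGMA, PSFModel, render_volume
from exmkit.punctastats import (
    PunctaSet,
    Punctum,
    SegmentConfig,
    chord_table,
    ellipse_width,
    manders_percent,
    moments_threshold,
    nearest_neighbor_distances,
    percent_change,
    ratio_stats,
    segment_puncta,
)
from exmkit.volume import ImageVolume


def make_set(centroids, widths=30.0, volumes=1000.0, channel=""):
    centroids = np.atleast_2d(centroids)
    widths = np.broadcast_to(np.asarray(widths, float), (len(centroids),))
    volumes = np.broadcast_to(np.asarray(volumes, float), (len(centroids),))
    return PunctaSet(
        [Punctum(tuple(c), w, v, 1.0, channel) for c, w, v in zip(centroids, widths, volumes)],
        channel,
    )


@pytest.fixture(scope="module")
def rendered_scene():
    rng = np.random.default_rng(1)
    grid = np.stack(np.meshgrid([400, 800, 1200, 1600],
                                [400, 800, 1200, 1600, 2000], indexing="ij"), -1).reshape(-1, 2)[:20]
    pts = np.array([
        [rng.uniform(500, 1100), gy + rng.uniform(-80, 80), gx + rng.uniform(-80, 80)]
        for gy, gx in grid
    ])
    vol = render_volume(pts, np.full(20, 2000.0), PSFModel(60.0, 120.0),
                        (32, 128, 128), (50.0, 25.0, 25.0), poisson_gain=10.0, seed=3)
    return vol, pts


class TestSegmentation:
    def test_recovers_all_separated_puncta_with_accurate_centroids(self, rendered_scene):
        vol, pts = rendered_scene
        ps = segment_puncta(vol, SegmentConfig(seed_fwhm_nm=140.0, min_volume_nm3=1e4))
        assert len(ps) == 20  # recall and precision both 1
        from scipy.spatial import cKDTree

        d, _ = cKDTree(ps.centroids).query(pts)
        assert d.max() < 12.5  # half of the 25 nm lateral voxel

    def test_widths_within_fifteen_percent_of_rendered_fwhm(self, rendered_scene):
        vol, _ = rendered_scene
        ps = segment_puncta(vol, SegmentConfig(seed_fwhm_nm=140.0, min_volume_nm3=1e4))
        true_fwhm = 60.0 * FWHM_PER_SIGMA
        assert np.all(np.abs(ps.widths / true_fwhm - 1) < 0.15)

    def test_empty_volume_gives_empty_set(self):
        vol = ImageVolume(np.zeros((8, 32, 32), np.float32), (50.0, 25.0, 25.0))
        assert len(segment_puncta(vol)) == 0

    def test_merged_puncta_flagged_by_solidity(self):
        # three puncta in an L, all closer than the seed separation, fuse into
        # one concave region that the solidity check flags as a merge
        pts = np.array([
            [400.0, 450.0, 350.0],
            [400.0, 450.0, 750.0],
            [400.0, 750.0, 750.0],
        ])
        vol = render_volume(pts, np.full(3, 2000.0), PSFModel(60.0, 120.0),
                            (16, 48, 48), (50.0, 25.0, 25.0))
        ps = segment_puncta(vol, SegmentConfig(seed_fwhm_nm=140.0, min_separation_nm=450.0,
                                               min_volume_nm3=1e4, min_solidity=0.9))
        assert len(ps) == 1
        assert ps.puncta[0].flags == "low_solidity"


class TestNearestNeighbor:
    def test_coincident_pair_distance_zero(self):
        a = make_set([[0, 0, 0]])
        b = make_set([[0, 0, 0]])
        assert nearest_neighbor_distances(a, b)[0] == 0.0

    def test_pythagorean_example(self):
        src = make_set([[0.0, 0.0, 0.0]])
        tgt = make_set([[0.0, 30.0, 40.0], [0.0, 100.0, 0.0]])
        assert nearest_neighbor_distances(src, tgt)[0] == pytest.approx(50.0)

    def test_matches_exhaustive_pairwise_minimum(self):
        rng = np.random.default_rng(5)
        src = rng.uniform(0, 1000, (100, 3))
        tgt = rng.uniform(0, 1000, (100, 3))
        d = nearest_neighbor_distances(make_set(src), make_set(tgt))
        brute = np.min(np.linalg.norm(src[:, None, :] - tgt[None, :, :], axis=-1), axis=1)
        np.testing.assert_array_equal(d, brute)

    def test_empty_target_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            nearest_neighbor_distances(make_set([[0, 0, 0]]), PunctaSet([]))


class TestRatios:
    def test_identical_sets_give_unity(self):
        a = make_set(np.zeros((3, 3)), volumes=[100, 200, 300])
        r = ratio_stats(a, a)
        assert r == {"volume_ratio": 1.0, "count_ratio": 1.0}

    def test_worked_example(self):
        a = make_set(np.zeros((3, 3)), volumes=100.0)
        b = make_set(np.zeros((2, 3)), volumes=300.0)
        r = ratio_stats(a, b)
        assert r["volume_ratio"] == pytest.approx(0.5)
        assert r["count_ratio"] == pytest.approx(1.5)

    def test_empty_a_gives_zero_and_empty_b_errors(self):
        b = make_set(np.zeros((2, 3)), volumes=300.0)
        r = ratio_stats(PunctaSet([]), b)
        assert r["volume_ratio"] == 0.0 and r["count_ratio"] == 0.0
        with pytest.raises(ValueError):
            ratio_stats(b, PunctaSet([]))


def brute_force_moments_threshold(image):
    """Independent oracle: exhaustive 256-level search for the cut whose
    cumulative histogram fraction best matches the moment-preserving p0."""
    img = np.asarray(image, float)
    lo, hi = img.min(), img.max()
    q = np.clip(np.round((img - lo) / (hi - lo) * 255), 0, 255).astype(int)
    p = np.bincount(q.ravel(), minlength=256) / q.size
    lv = np.arange(256.0)
    m1, m2, m3 = (p * lv).sum(), (p * lv**2).sum(), (p * lv**3).sum()
    cd = m2 - m1 * m1
    c0 = (m1 * m3 - m2 * m2) / cd
    c1 = (m1 * m2 - m3) / cd
    disc = max(c1 * c1 - 4 * c0, 0.0)
    z0, z1 = 0.5 * (-c1 - np.sqrt(disc)), 0.5 * (-c1 + np.sqrt(disc))
    p0 = (z1 - m1) / (z1 - z0)
    best, best_err = 0, np.inf
    csum = 0.0
    for t in range(256):
        csum += p[t]
        if abs(csum - p0) < best_err:
            best, best_err = t, abs(csum - p0)
    return best  # quantized level; mask = q > best


class TestMomentsThreshold:
    def test_two_level_image_reproduces_the_split(self):
        img = np.concatenate([np.full(600, 10.0), np.full(400, 200.0)]).reshape(25, 40)
        t = moments_threshold(img)
        assert 10.0 < t < 200.0
        assert (img > t).mean() == pytest.approx(0.4)

    def test_equals_brute_force_search_on_random_images(self):
        rng = np.random.default_rng(0)
        for _ in range(15):
            img = rng.gamma(2.0, 30.0, (40, 40))
            img += (rng.uniform(size=(40, 40)) < 0.2) * rng.uniform(100, 255, (40, 40))
            t = moments_threshold(img)
            t8 = brute_force_moments_threshold(img)
            q = np.clip(np.round((img - img.min()) / (img.max() - img.min()) * 255), 0, 255)
            np.testing.assert_array_equal(img > t, q > t8)

    def test_constant_offset_preserves_the_mask(self):
        rng = np.random.default_rng(1)
        img = rng.gamma(2.0, 30.0, (32, 32)) + (rng.uniform(size=(32, 32)) < 0.3) * 150
        m1 = img > moments_threshold(img)
        shifted = img + 37.0
        m2 = shifted > moments_threshold(shifted)
        np.testing.assert_array_equal(m1, m2)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            moments_threshold(np.full((8, 8), 3.0))


class TestManders:
    def test_identical_channels_100_percent(self):
        rng = np.random.default_rng(2)
        img = rng.gamma(2.0, 30.0, (10, 10, 10)) + (rng.uniform(size=(10, 10, 10)) < 0.2) * 200
        r = manders_percent(img, img)
        assert r.percent_a_in_b == 100.0 and r.percent_b_in_a == 100.0

    def test_disjoint_masks_0_percent(self):
        a = np.zeros((6, 10, 10))
        b = np.zeros((6, 10, 10))
        a[:3] = 100.0
        b[3:] = 100.0
        a += np.linspace(0, 1, a.size).reshape(a.shape)  # avoid constant halves
        b += np.linspace(0, 1, b.size).reshape(b.shape)
        r = manders_percent(a, b)
        assert r.percent_a_in_b == 0.0 and r.percent_b_in_a == 0.0

    def test_counted_overlap_percentages_and_recomputability(self):
        a = np.zeros(1000)
        b = np.zeros(1000)
        a[:200] = 100.0
        b[50:450] = 100.0
        r = manders_percent(a.reshape(10, 10, 10), b.reshape(10, 10, 10))
        assert r.percent_a_in_b == pytest.approx(75.0)
        assert r.percent_b_in_a == pytest.approx(37.5)
        # directionality + exact recomputability from stored counts
        assert r.percent_a_in_b == 100.0 * r.n_overlap / r.n_a
        assert r.percent_b_in_a == 100.0 * r.n_overlap / r.n_b

    def test_empty_mask_direction_is_undefined_not_zero(self):
        a = np.zeros((5, 5, 5))
        a[0, 0, 0] = -1.0  # all mass below threshold, mask empty after cut at min
        b = np.zeros((5, 5, 5))
        b[2] = 50.0
        b += np.linspace(0, 1, b.size).reshape(b.shape)
        amin = np.zeros((5, 5, 5))
        amin[0, 0, 0] = 1e-12  # nearly-constant: mask may be empty
        r = manders_percent(amin, b, threshold_fn=lambda img: float(img.max()))
        assert r.percent_a_in_b is None


class TestChordTable:
    def test_equal_occupancy_gives_equal_arcs(self):
        ct = chord_table({"a": 20.0, "b": 20.0}, {("a", "b"): 50.0, ("b", "a"): 40.0})
        assert ct.arc_fractions == {"a": 0.5, "b": 0.5}

    def test_occupancy_normalization(self):
        ct = chord_table({"a": 10.0, "b": 30.0}, {("a", "b"): 1.0, ("b", "a"): 2.0})
        assert ct.arc_fractions["a"] == pytest.approx(0.25)
        assert ct.arc_fractions["b"] == pytest.approx(0.75)

    def test_single_marker_full_arc_no_pairs(self):
        ct = chord_table({"only": 12.0}, {})
        assert ct.arc_fractions == {"only": 1.0}
        assert ct.pair_percent == {}

    def test_missing_pair_listed_in_error(self):
        with pytest.raises(ValueError, match="b.*a|a.*b"):
            chord_table({"a": 1.0, "b": 1.0}, {("a", "b"): 5.0})


class TestScalarHelpers:
    @pytest.mark.parametrize("before,after,expected", [
        (32.0, 44.0, 37.5),   # EGF punctum widening, 15 -> 30 min
        (42.0, 67.0, 59.5),   # EGF-to-EGFR1 NND increase, approx 60%
        (7.0, 7.0, 0.0),
    ])
    def test_percent_change_worked_examples(self, before, after, expected):
        assert percent_change(before, after) == pytest.approx(expected, abs=0.05)

    def test_percent_change_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)

    @given(major=st.floats(1.0, 1e4), minor=st.floats(1.0, 1e4))
    @settings(max_examples=50, deadline=None)
    def test_ellipse_width_is_axis_mean_regardless_of_order(self, major, minor):
        assert ellipse_width(major, minor) == pytest.approx((major + minor) / 2)

    def test_ellipse_width_examples(self):
        assert ellipse_width(300.0, 260.0) == 280.0
        assert ellipse_width(200.0, 200.0) == 200.0
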