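import heapq

import numpy as np
import pytest
from scipy import ndimage
from skimage.morphology import disk as disk_se

from amsmw.errors import DomainError
from amsmw.image_model import RROI, mask_to_contour
from amsmw.marked_watershed import (
    CandidateContour,
    MarkedArea,
    amsmw_segment,
    ard,
    binarize_at,
    label_markers,
    marked_area,
    marker_function,
    select_final_contour,
    watershed_flood,
)
from amsmw.metrics import area_metrics


def erosion_oracle(mask, footprint):
    """Brute-force erosion: shift-AND over every offset of the SE."""
    r0 = footprint.shape[0] // 2
    c0 = footprint.shape[1] // 2
    out = np.ones_like(mask)
    padded = np.pad(mask, (r0, c0) if r0 == c0 else ((r0, r0), (c0, c0)),
                    mode="constant", constant_values=False)
    for dr in range(footprint.shape[0]):
        for dc in range(footprint.shape[1]):
            if footprint[dr, dc]:
                out &= padded[dr : dr + mask.shape[0], dc : dc + mask.shape[1]]
    return out


def flood_oracle(surface, markers):
    """Exhaustive priority-flood simulation, 4-connectivity, FIFO plateaus."""
    h, w = surface.shape
    lab = markers.astype(np.int64).copy()
    heap = []
    age = 0
    for i in range(h):
        for j in range(w):
            if lab[i, j] > 0:
                heapq.heappush(heap, (float(surface[i, j]), age, i, j))
                age += 1
    while heap:
        _, _, i, j = heapq.heappop(heap)
        for ni, nj in ((i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)):
            if 0 <= ni < h and 0 <= nj < w and lab[ni, nj] == 0:
                lab[ni, nj] = lab[i, j]
                heapq.heappush(heap, (float(surface[ni, nj]), age, ni, nj))
                age += 1
    return lab


def make_disk(shape, centre, radius):
    yy = np.arange(shape[0])[:, None]
    xx = np.arange(shape[1])[None, :]
    return (yy - centre[0]) ** 2 + (xx - centre[1]) ** 2 <= radius**2


class TestBinarize:
    def test_zero_image_empty(self):
        assert binarize_at(np.zeros((4, 4)), 1).sum() == 0

    def test_full_image_at_255(self):
        assert binarize_at(np.full((4, 4), 255.0), 255).all()

    def test_ramp_threshold_96(self):
        ramp = np.tile(np.arange(256, dtype=float), (4, 1))
        mask = binarize_at(ramp, 96)
        assert np.array_equal(np.nonzero(mask[0])[0], np.arange(96, 256))

    @pytest.mark.parametrize("th", [0, 256])
    def test_out_of_range_threshold_rejected(self, th):
        with pytest.raises(DomainError):
            binarize_at(np.zeros((4, 4)), th)


class TestMarkerFunction:
    def test_internal_marker_matches_erosion_oracle(self):
        f_p = make_disk((128, 128), (64, 64), 40)
        marker = marker_function(f_p)
        assert np.array_equal(marker.internal, erosion_oracle(f_p, disk_se(15)))

    def test_external_marker_matches_morphology_oracle(self):
        f_p = make_disk((96, 96), (48, 48), 20)
        marker = marker_function(f_p)
        grown = ndimage.binary_dilation(f_p, structure=disk_se(15))
        sq = np.ones((15, 15), bool)
        expected = ndimage.binary_dilation(grown, structure=sq) & ~ndimage.binary_erosion(
            grown, structure=sq, border_value=0
        )
        assert np.array_equal(marker.external, expected)

    def test_empty_input_gives_empty_markers(self):
        marker = marker_function(np.zeros((40, 40), bool))
        assert not marker.internal.any() and not marker.external.any()

    @pytest.mark.parametrize("seed", range(5))
    def test_internal_subset_of_input(self, seed):
        from conftest import random_blob

        f_p = random_blob((64, 64), seed)
        marker = marker_function(f_p)
        assert not (marker.internal & ~f_p).any()


class TestMarkedArea:
    def test_full_ams_returns_closed_marker_union(self):
        f_p = make_disk((128, 128), (64, 64), 30)
        marker = marker_function(f_p)
        full = np.ones((128, 128), bool)
        area = marked_area(full, marker, 96)
        from amsmw.marked_watershed import _closing_disk

        assert np.array_equal(area.mask, _closing_disk(marker.union, 25))

    def test_disjoint_gives_empty(self):
        f_p = make_disk((128, 128), (20, 20), 5)
        marker = marker_function(f_p)
        ams = make_disk((128, 128), (100, 100), 5)
        area = marked_area(ams, marker, 50)
        assert area.empty

    def test_concentric_disks_intersection(self):
        marker_disk = make_disk((128, 128), (64, 64), 30)
        ams = make_disk((128, 128), (64, 64), 25)
        inter = ams & marker_disk
        # independent oracle: structuring-element closing of the intersection
        se = disk_se(25)
        pad = 26
        padded = np.pad(inter, pad)
        closed = ndimage.binary_erosion(
            ndimage.binary_dilation(padded, structure=se), structure=se, border_value=0
        )[pad:-pad, pad:-pad]
        # marker stub with the pure-disk geometry of the example
        area = marked_area(ams, MarkerStub(marker_disk), 96)
        assert np.array_equal(area.mask, closed)
        assert (area.mask | ams).sum() == area.mask.sum()  # closing is extensive


class MarkerStub:
    """Marker whose union is a given mask (for geometry-only tests)."""

    def __init__(self, union):
        self.internal = union
        self.external = np.zeros_like(union)
        self.union = union


class TestLabelMarkers:
    RROI_ = RROI(w1=40, w2=90, h1=40, h2=90)

    def test_single_blob_labels(self):
        blob = make_disk((128, 128), (64, 64), 10)
        labels = label_markers(MarkedArea(blob, 96), self.RROI_, (128, 128))
        assert ((labels == 1) == blob).all()
        border = labels == 2
        assert border[0, :].any() and border[-1, :].any()
        assert not (border & blob).any()

    def test_central_blob_wins(self):
        blob_a = make_disk((128, 128), (64, 64), 8)   # at RROI centre
        blob_b = make_disk((128, 128), (15, 110), 8)
        labels = label_markers(MarkedArea(blob_a | blob_b, 96), self.RROI_, (128, 128))
        assert ((labels == 1) == blob_a).all()

    def test_border_band_excludes_lesion_dilation(self):
        blob = make_disk((60, 60), (3, 30), 6)  # touches the top border
        labels = label_markers(MarkedArea(blob, 96), RROI(w1=20, w2=40, h1=0, h2=20), (60, 60))
        grown = ndimage.binary_dilation(blob, structure=disk_se(5))
        assert not ((labels == 2) & grown).any()

    def test_empty_area_rejected(self):
        with pytest.raises(DomainError, match="no lesion marker"):
            label_markers(MarkedArea(np.zeros((32, 32), bool), 96), self.RROI_, (32, 32))


class TestWatershedFlood:
    @pytest.mark.parametrize("trial", range(8))
    def test_two_basin_surface_matches_flood_oracle(self, trial):
        ridge, v1, v2 = 30, 10, 50
        cols = np.arange(60, dtype=float)
        profile = np.minimum(np.abs(cols - v1), np.abs(cols - v2)) * (1 + 0.1 * trial)
        profile[ridge] += 5 + trial
        surface = np.tile(profile, (20, 1))
        markers = np.zeros((20, 60), np.int32)
        markers[10, v1] = 1
        markers[10, v2] = 2
        lesion = watershed_flood(surface, markers)
        oracle = flood_oracle(surface, markers) == 1
        assert np.array_equal(lesion, oracle)
        cols_on = np.nonzero(lesion.any(axis=0))[0]
        assert cols_on.max() <= ridge  # boundary falls on the ridge column

    def test_constant_surface_assigns_nearest_marker(self):
        surface = np.zeros((20, 60))
        markers = np.zeros((20, 60), np.int32)
        markers[0, 0] = 1
        markers[19, 59] = 2
        lesion = watershed_flood(surface, markers)
        ii, jj = np.mgrid[0:20, 0:60]
        d1 = np.abs(ii) + np.abs(jj)
        d2 = np.abs(ii - 19) + np.abs(jj - 59)
        assert lesion[d1 < d2].all()
        assert not lesion[d2 < d1].any()
        assert lesion[d1 == d2].all()  # ties go to label 1

    def test_seed_region_contained_in_output(self):
        rng = np.random.default_rng(3)
        surface = rng.random((30, 30))
        markers = np.zeros((30, 30), np.int32)
        seed_blob = make_disk((30, 30), (15, 15), 3)
        markers[seed_blob] = 1
        markers[0, :] = 2
        lesion = watershed_flood(surface, markers)
        assert lesion[seed_blob].all()

    def test_single_label_rejected(self):
        markers = np.zeros((10, 10), np.int32)
        markers[5, 5] = 1
        with pytest.raises(DomainError):
            watershed_flood(np.zeros((10, 10)), markers)


class TestArd:
    def _circle_contour(self, centre, radius, shape):
        return mask_to_contour(make_disk(shape, centre, radius))

    def test_constant_image_zero(self):
        contour = self._circle_contour((32, 32), 10, (64, 64))
        assert ard(np.full((64, 64), 99.0), contour, (32, 32)) == 0.0

    def test_radial_ramp_gives_unit_derivative(self):
        yy, xx = np.mgrid[0:64, 0:64]
        ramp = np.sqrt((yy - 32.0) ** 2 + (xx - 32.0) ** 2)
        ramp = np.clip(ramp, 0, 255)
        contour = self._circle_contour((32, 32), 15, (64, 64))
        assert ard(ramp, contour, (32, 32)) == pytest.approx(1.0, abs=0.05)

    def test_sign_flips_under_negation(self):
        yy, xx = np.mgrid[0:64, 0:64]
        ramp = np.clip(np.sqrt((yy - 32.0) ** 2 + (xx - 32.0) ** 2), 0, 255)
        contour = self._circle_contour((32, 32), 15, (64, 64))
        neg = 255.0 - ramp
        assert ard(neg, contour, (32, 32)) == pytest.approx(-1.0, abs=0.05)

    def test_centre_point_skipped(self):
        contour = np.array([[32, 32], [32, 33], [33, 33]])
        val = ard(np.full((64, 64), 5.0), contour, (32, 32))
        assert np.isfinite(val)


class TestSelectFinalContour:
    def _cand(self, th, score):
        return CandidateContour(contour=np.array([[0, 0]]), threshold=th, ard_score=score)

    def test_fast_mode_picks_96(self):
        cands = [self._cand(95, 1.0), self._cand(96, 0.5), self._cand(97, 2.0)]
        assert select_final_contour(cands, mode="fast").threshold == 96

    def test_full_mode_picks_argmax(self):
        cands = [self._cand(10, 1.0), self._cand(20, 3.0), self._cand(30, 2.0)]
        assert select_final_contour(cands, mode="full").ard_score == 3.0

    def test_fast_fallback_nearest_tie_to_lower(self):
        cands = [self._cand(90, 1.0), self._cand(99, 1.0)]
        assert select_final_contour(cands, mode="fast").threshold == 99
        cands = [self._cand(93, 1.0), self._cand(99, 1.0)]
        assert select_final_contour(cands, mode="fast").threshold == 93

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            select_final_contour([], mode="fast")


class TestPipeline:
    def test_fast_mode_recovers_phantom(self, segmented_phantom):
        sample, result = segmented_phantom
        m = area_metrics(sample.gt, result.mask)
        assert m.DSC >= 0.85
        assert not result.fallback

    def test_deterministic(self, default_phantom, segmented_phantom):
        _, first = segmented_phantom
        again = amsmw_segment(
            default_phantom.image, default_phantom.rroi, mode="fast", keep_candidates=True
        )
        assert np.array_equal(first.mask, again.mask)
        assert np.array_equal(first.contour, again.contour)
        assert first.threshold == again.threshold

    def test_final_mask_contains_its_marker(self, segmented_phantom):
        sample, result = segmented_phantom
        labels = label_markers(result.marked, sample.rroi, sample.image.shape)
        assert result.mask[labels == 1].all()

    def test_full_mode_ard_at_least_fast(self, default_phantom, segmented_phantom):
        _, fast = segmented_phantom
        full = amsmw_segment(
            default_phantom.image, default_phantom.rroi, mode="full", keep_candidates=True
        )
        fast_score = next(
            c.ard_score for c in fast.candidates if c.threshold == fast.threshold
        )
        best_score = max(c.ard_score for c in full.candidates)
        assert best_score >= fast_score

    def test_fast_mode_floods_once(self, default_phantom, monkeypatch):
        import amsmw.marked_watershed as mw

        calls = {"n": 0}
        orig = mw.watershed_flood

        def counting(surface, markers):
            calls["n"] += 1
            return orig(surface, markers)

        monkeypatch.setattr(mw, "watershed_flood", counting)
        mw.amsmw_segment(default_phantom.image, default_phantom.rroi, mode="fast")
        assert calls["n"] == 1

    def test_tiny_rroi_rejected(self, default_phantom):
        with pytest.raises(DomainError):
            amsmw_segment(default_phantom.image, RROI(w1=0, w2=3, h1=0, h2=3))
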