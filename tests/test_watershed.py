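from collections import deque

import numpy as np
import pytest

from cytoseg.imgio import InstanceLabelMap
from cytoseg.watershed import extract_contours, threshold_probmap, watershed_cytoplasm


def geodesic_flood_reference(fg: np.ndarray, markers: np.ndarray) -> np.ndarray:
    """Brute-force oracle: per-marker-label BFS distance over the foreground,
    each pixel assigned the nearest label, ties to the lower label."""
    h, w = fg.shape
    labels = sorted(int(v) for v in np.unique(markers) if v > 0 and (markers == v)[fg].any())
    dists = {}
    for lab in labels:
        d = np.full((h, w), np.inf)
        q = deque()
        for r, c in np.argwhere((markers == lab) & fg):
            d[r, c] = 0
            q.append((r, c))
        while q:
            r, c = q.popleft()
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                nr, nc = r + dr, c + dc
                if 0 <= nr < h and 0 <= nc < w and fg[nr, nc] and d[nr, nc] == np.inf:
                    d[nr, nc] = d[r, c] + 1
                    q.append((nr, nc))
        dists[lab] = d
    out = np.zeros((h, w), dtype=np.int64)
    for r in range(h):
        for c in range(w):
            if not fg[r, c]:
                continue
            best, best_d = 0, np.inf
            for lab in labels:  # ascending labels -> ties go to the lower one
                if dists[lab][r, c] < best_d:
                    best, best_d = lab, dists[lab][r, c]
            out[r, c] = best
    return out


class TestThreshold:
    def test_zero_threshold_all_foreground(self):
        probs = np.random.default_rng(0).dirichlet(np.ones(2), size=(4, 4))
        assert threshold_probmap(probs, 1, 0.0).all()

    def test_boundary_thresholds(self):
        probs = np.zeros((2, 2, 2))
        probs[:, :, 1] = [[1.0, 0.4], [0.5, 0.0]]
        probs[:, :, 0] = 1 - probs[:, :, 1]
        assert threshold_probmap(probs, 1, 1.0).sum() == 1
        with pytest.raises(ValueError):
            threshold_probmap(probs, 1, 1.0001)
        with pytest.raises(ValueError):
            threshold_probmap(probs, 5, 0.5)

    def test_counts_match_per_pixel_scan(self):
        grid = np.array([[0.9, 0.4, 0.5, 0.1],
                         [0.6, 0.5, 0.2, 0.8],
                         [0.3, 0.7, 0.5, 0.4],
                         [0.0, 1.0, 0.6, 0.5]])
        probs = np.stack([1 - grid, grid], axis=-1)
        mask = threshold_probmap(probs, 1, 0.5)
        assert mask.sum() == sum(v >= 0.5 for v in grid.ravel())


class TestWatershed:
    def test_single_marker_floods_whole_blob(self):
        fg = np.zeros((10, 10), bool)
        fg[2:8, 2:8] = True
        markers = np.zeros((10, 10), dtype=np.int64)
        markers[4, 4] = 3
        out = watershed_cytoplasm(fg, InstanceLabelMap(markers))
        assert np.array_equal(out.labels == 3, fg)

    def test_dumbbell_splits_at_neck(self):
        fg = np.zeros((9, 17), bool)
        fg[2:7, 1:7] = True      # left lobe
        fg[2:7, 10:16] = True    # right lobe
        fg[4, 7:10] = True       # neck
        markers = np.zeros_like(fg, dtype=np.int64)
        markers[4, 3], markers[4, 13] = 1, 2
        out = watershed_cytoplasm(fg, InstanceLabelMap(markers)).labels
        assert np.all(out[2:7, 1:7] == 1)
        assert np.all(out[2:7, 10:16] == 2)
        assert np.array_equal(out, geodesic_flood_reference(fg, markers))

    def test_empty_foreground_all_zero(self):
        markers = np.zeros((5, 5), dtype=np.int64)
        markers[2, 2] = 1
        out = watershed_cytoplasm(np.zeros((5, 5), bool), InstanceLabelMap(markers))
        assert out.labels.sum() == 0

    def test_marker_outside_foreground_clipped(self, caplog):
        fg = np.zeros((6, 6), bool)
        fg[0:3, 0:3] = True
        markers = np.zeros((6, 6), dtype=np.int64)
        markers[1, 1], markers[5, 5] = 1, 2
        with caplog.at_level("WARNING"):
            out = watershed_cytoplasm(fg, InstanceLabelMap(markers))
        assert "clipped" in caplog.text
        assert set(np.unique(out.labels)) == {0, 1}

    def test_marker_pixels_retain_their_label(self, rng):
        fg = rng.random((16, 16)) > 0.35
        markers = np.zeros((16, 16), dtype=np.int64)
        pos = np.argwhere(fg)
        a, b = pos[3], pos[-3]
        markers[tuple(a)], markers[tuple(b)] = 1, 2
        out = watershed_cytoplasm(fg, InstanceLabelMap(markers)).labels
        assert out[tuple(a)] == 1 and out[tuple(b)] == 2

    def test_labels_subset_of_markers_and_foreground(self, rng):
        fg = rng.random((20, 20)) > 0.4
        markers = np.zeros((20, 20), dtype=np.int64)
        pos = np.argwhere(fg)
        markers[tuple(pos[0])], markers[tuple(pos[-1])] = 4, 9
        out = watershed_cytoplasm(fg, InstanceLabelMap(markers)).labels
        assert set(np.unique(out)) <= {0, 4, 9}
        assert not out[~fg].any()

    def test_matches_geodesic_reference_on_random_grids(self):
        # pixel-exact oracle equivalence under the lower-label tie rule
        for seed in range(20):
            rng = np.random.default_rng(seed)
            fg = rng.random((16, 16)) > 0.35
            pos = np.argwhere(fg)
            if len(pos) < 2:
                continue
            i, j = rng.choice(len(pos), size=2, replace=False)
            markers = np.zeros((16, 16), dtype=np.int64)
            markers[tuple(pos[i])], markers[tuple(pos[j])] = 1, 2
            got = watershed_cytoplasm(fg, InstanceLabelMap(markers)).labels
            want = geodesic_flood_reference(fg, markers)
            assert np.array_equal(got, want), f"seed {seed}"

    def test_small_regions_removed(self):
        fg = np.zeros((8, 8), bool)
        fg[0:2, 0:2] = True   # 4-pixel region
        fg[4:8, 4:8] = True   # 16-pixel region
        markers = np.zeros((8, 8), dtype=np.int64)
        markers[0, 0], markers[5, 5] = 1, 2
        out = watershed_cytoplasm(fg, InstanceLabelMap(markers), min_region_pixels=10)
        assert set(np.unique(out.labels)) == {0, 2}

    def test_no_markers_warns_and_returns_zero(self, caplog):
        fg = np.ones((4, 4), bool)
        with caplog.at_level("WARNING"):
            out = watershed_cytoplasm(fg, InstanceLabelMap(np.zeros((4, 4), np.int64)))
        assert out.labels.sum() == 0
        assert "no markers" in caplog.text


class TestContours:
    def test_square_contour_bounding_box(self):
        lab = np.zeros((20, 20), dtype=np.int64)
        lab[5:15, 3:13] = 1
        cs = extract_contours(InstanceLabelMap(lab))
        verts = cs.contours[1]
        assert verts[:, 0].min() >= 4.0 and verts[:, 0].max() <= 14.5
        assert verts[:, 1].min() >= 2.0 and verts[:, 1].max() <= 12.5
        assert verts[:, 0].max() - verts[:, 0].min() >= 9.0

    def test_disk_contour_close_to_ideal_circle(self):
        lab = np.zeros((40, 40), dtype=np.int64)
        rr, cc = np.meshgrid(np.arange(40), np.arange(40), indexing="ij")
        lab[(rr - 20) ** 2 + (cc - 20) ** 2 <= 10 ** 2] = 1
        verts = extract_contours(InstanceLabelMap(lab)).contours[1]
        radii = np.hypot(verts[:, 0] - 20, verts[:, 1] - 20)
        assert np.max(np.abs(radii - 10)) < 1.5

    def test_shoelace_area_close_to_pixel_count(self):
        lab = np.zeros((30, 30), dtype=np.int64)
        lab[10:20, 10:20] = 1
        verts = extract_contours(InstanceLabelMap(lab)).contours[1]
        r, c = verts[:, 0], verts[:, 1]
        area = 0.5 * abs(np.sum(c * np.roll(r, -1) - np.roll(c, -1) * r))
        assert abs(area - 100) / 100 < 0.1

    def test_counterclockwise_and_open(self):
        lab = np.zeros((12, 12), dtype=np.int64)
        lab[3:9, 3:9] = 2
        verts = extract_contours(InstanceLabelMap(lab)).contours[2]
        assert not np.allclose(verts[0], verts[-1])
        r, c = verts[:, 0], verts[:, 1]
        assert 0.5 * np.sum(c * np.roll(r, -1) - np.roll(c, -1) * r) > 0
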