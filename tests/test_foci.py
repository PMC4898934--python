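"""Focus segmentation and resolvable-focus counting."""

from collections import deque

import numpy as np
import pytest

from sirs_quant.foci import (FociSet, count_resolvable_foci,
                             robust_background_threshold, segment_foci)
from sirs_quant.synthetic import render_frame


def flood_fill_components(mask):
    """Independent 8-connected component counter (BFS oracle)."""
    seen = np.zeros_like(mask, dtype=bool)
    n = 0
    h, w = mask.shape
    for sy in range(h):
        for sx in range(w):
            if mask[sy, sx] and not seen[sy, sx]:
                n += 1
                queue = deque([(sy, sx)])
                seen[sy, sx] = True
                while queue:
                    y, x = queue.popleft()
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if (0 <= yy < h and 0 <= xx < w and mask[yy, xx]
                                    and not seen[yy, xx]):
                                seen[yy, xx] = True
                                queue.append((yy, xx))
    return n


class TestSegmentFoci:
    def test_five_separated_spots_give_five_regions(self):
        sigma = 1.5
        xs = [(12, 12), (12, 36), (36, 12), (36, 36), (24, 24)]
        spots = [(x, y, 100.0) for x, y in xs]  # pairwise >= 6*sigma apart
        img = render_frame(spots, (48, 48), sigma)
        assert segment_foci(img).count == 5

    def test_all_zero_image_gives_zero_regions(self):
        fs = segment_foci(np.zeros((32, 32)))
        assert fs.count == 0
        assert fs.total_area == 0

    def test_two_close_spots_merge_into_one_region(self):
        sigma = 1.5
        img = render_frame([(20.0, 20.0, 100.0), (21.5, 20.0, 100.0)], (40, 40), sigma)
        fs = segment_foci(img)
        # cross-check with an independent flood fill on the same threshold
        oracle = flood_fill_components(img >= fs.threshold)
        assert fs.count == 1
        assert oracle == 1

    def test_negative_pixels_rejected(self):
        img = np.zeros((20, 20))
        img[3, 3] = -5
        with pytest.raises(ValueError, match="negative"):
            segment_foci(img)

    def test_spot_order_in_generator_does_not_change_count(self):
        spots = [(10.0, 10.0, 80.0), (30.0, 12.0, 120.0), (20.0, 30.0, 60.0)]
        img_fwd = render_frame(spots, (40, 40), 1.5)
        img_rev = render_frame(spots[::-1], (40, 40), 1.5)
        assert segment_foci(img_fwd).count == segment_foci(img_rev).count == 3

    def test_planted_count_recovered_exactly_on_separated_noise_free_spots(self):
        rng = np.random.default_rng(42)
        sigma = 1.5
        exact = 0
        n_draws = 50
        for _ in range(n_draws):
            n = int(rng.integers(2, 8))
            pts = []
            while len(pts) < n:  # rejection placement at >= 6 sigma spacing
                cand = rng.uniform(12, 68, size=2)
                if all(np.hypot(*(cand - p)) >= 6 * sigma for p in pts):
                    pts.append(cand)
            img = render_frame([(x, y, 100.0) for x, y in pts], (80, 80), sigma)
            exact += segment_foci(img).count == n
        assert exact == n_draws

    def test_regions_sorted_row_major(self):
        img = render_frame([(30.0, 30.0, 90.0), (8.0, 8.0, 90.0)], (40, 40), 1.5)
        fs = segment_foci(img)
        assert fs.centroids[0][1] < fs.centroids[1][1]  # y ascending


class TestCounting:
    def test_empty_foci_set_counts_zero(self):
        assert count_resolvable_foci(FociSet()) == 0

    def test_count_equals_number_of_regions(self):
        img = render_frame([(10.0, 10.0, 90.0), (30.0, 30.0, 90.0)], (40, 40), 1.5)
        fs = segment_foci(img)
        assert count_resolvable_foci(fs) == len(fs.areas) == 2


def test_robust_background_threshold_sits_above_noise_floor():
    rng = np.random.default_rng(0)
    img = rng.normal(10.0, 2.0, size=(64, 64)).clip(0)
    thr = robust_background_threshold(img)
    assert thr > img.mean() + 3 * img.std()
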