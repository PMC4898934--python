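"""Kinetochore clusteredness score over time.

As centromeres disperse, the total thresholded area they cover grows while
the intensity of each individual punctum falls, so the ratio

    S_t = (mean intensity over all focus pixels) / (total focus area)

drops sharply at the onset of sister separation.  Per cell the raw series
is min-max normalized to K_t in [0, 1] (1 = most clustered state observed,
0 = most dispersed), which also removes any global intensity scale.

"Mean intensity" is taken over the union of all focus pixels, not as an
average of per-region means: only the union statistic makes the normalized
score invariant to multiplying the image by a constant.
"""

from __future__ import annotations

import warnings

import numpy as np

from .errors import DegenerateSeriesWarning, UndefinedScoreError
from .foci import FociSet


def raw_clusteredness(image, foci: FociSet) -> float:
    """S = mean intensity of focus pixels divided by their total area."""
    image = np.asarray(image, dtype=float)
    if foci.total_area == 0:
        raise UndefinedScoreError("no above-threshold kinetochore pixels in frame")
    pixels = image[foci.label_image > 0]
    return float(pixels.mean() / foci.total_area)


def normalize_unit_interval(series) -> np.ndarray:
    """Min-max normalize to [0, 1]; a constant series maps to zeros + warning."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("series length must be >= 2")
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi == lo:
        warnings.warn("constant series; normalization degenerate, returning zeros",
                      DegenerateSeriesWarning)
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def clusteredness_series(movie, foci_sets) -> tuple[np.ndarray, np.ndarray]:
    """Raw S_t and normalized K_t across all frames of a movie.

    Frames with an undefined score (no focus pixels) carry NaN in S_t and
    are ignored by the normalization.
    """
    stack = movie.channel("kinetochore")
    s = np.full(len(foci_sets), np.nan)
    for k, fs in enumerate(foci_sets):
        if fs.total_area > 0:
            s[k] = raw_clusteredness(stack[k], fs)
    k_t = normalize_unit_interval(s)
    return s, k_t
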