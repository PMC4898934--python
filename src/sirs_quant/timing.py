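"""Mitotic event timing from fluorescence traces and centroid dynamics.

NEBD is defined operationally as the half-maximal point of the normalized
nuclear geminin-reporter trace (sub-frame resolution by linear
interpolation); anaphase as the first frame with poleward movement of the
kinetochores, detected as a robust jump in the separation of the two
1-D k-means groups of centroid projections along the division axis; the
metaphase plate as the collapse of the centroid spread along that axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clusteredness import normalize_unit_interval
from .errors import NoAnaphaseError, NoMetaphaseError, NoNEBDError

#: Frames the trace must stay below half-max for a crossing to count.
NEBD_PERSISTENCE = 2
#: Floor (px) on the robust spread term of the anaphase threshold; guards
#: against MAD collapsing to segmentation jitter on very stable traces.
MAD_FLOOR_PX = 1.0
#: Factor over the pre-anaphase minimum spread defining plate formation.
PLATE_SD_FACTOR = 1.5


@dataclass
class AnaphaseCall:
    """Anaphase onset plus the division-axis geometry it was found on."""

    time: float                 # minutes (frame-resolved)
    frame: int
    axis: np.ndarray            # unit 2-vector of the division axis
    separation: np.ndarray      # d(t) series used for detection


@dataclass
class EventTimes:
    """Per-cell mitotic event times (minutes from frame 0)."""

    t_nebd: float | None = None
    t_anaphase: float | None = None
    t_plate: float | None = None

    @property
    def duration_nebd_ana(self) -> float | None:
        if self.t_nebd is None or self.t_anaphase is None:
            return None
        return nebd_to_anaphase(self)

    @property
    def metaphase_length_min(self) -> float | None:
        if self.t_plate is None or self.t_anaphase is None:
            return None
        return self.t_anaphase - self.t_plate


@dataclass
class CellTrace:
    """Per-cell time series: geminin brightness plus kinetochore summaries."""

    times: np.ndarray
    geminin: np.ndarray                  # B_t, normalized to [0, 1]
    clusteredness: np.ndarray | None = None   # K_t
    foci_counts: np.ndarray | None = None     # F_t
    centroid_sets: list | None = None


def geminin_trace(movie, crop=None) -> np.ndarray:
    """Normalized geminin brightness B_t: per-frame mean over the cell crop.

    ``crop`` is an optional (slice_y, slice_x); by default the whole frame
    (the movie is assumed closely cropped around the cell of interest).
    """
    stack = movie.channel("geminin")
    if crop is not None:
        stack = stack[(slice(None),) + tuple(crop)]
    raw = stack.reshape(stack.shape[0], -1).mean(axis=1)
    return normalize_unit_interval(raw)


def detect_nebd(b_t, times) -> float:
    """First persistent downward half-max crossing, linearly interpolated.

    The crossing must stay below 0.5 for at least NEBD_PERSISTENCE
    subsequent frames to reject noise spikes.
    """
    b = np.asarray(b_t, dtype=float)
    times = np.asarray(times, dtype=float)
    for i in range(len(b) - 1):
        if b[i] >= 0.5 > b[i + 1]:
            tail = b[i + 1:i + 1 + NEBD_PERSISTENCE]
            if len(tail) >= NEBD_PERSISTENCE and np.all(tail < 0.5):
                frac = (b[i] - 0.5) / (b[i] - b[i + 1])
                return float(times[i] + frac * (times[i + 1] - times[i]))
    raise NoNEBDError("geminin trace never crosses half-maximum persistently")


def _two_means_1d(x) -> float:
    """Distance between the two group centers of an exact 1-D 2-means split."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    if n < 2:
        return np.nan
    csum = np.cumsum(x)
    total = csum[-1]
    best_cost, best_gap = np.inf, 0.0
    for m in range(1, n):  # left group = x[:m]
        lmean = csum[m - 1] / m
        rmean = (total - csum[m - 1]) / (n - m)
        lcost = np.sum((x[:m] - lmean) ** 2)
        rcost = np.sum((x[m:] - rmean) ** 2)
        if lcost + rcost < best_cost:
            best_cost = lcost + rcost
            best_gap = rmean - lmean
    return float(best_gap)


def separation_series(centroid_sets) -> tuple[np.ndarray, np.ndarray]:
    """d(t) = two-group separation of centroid projections, plus the axis.

    The projection axis is the principal axis of the final-frame centroid
    set, where the poleward displacement dominates.
    """
    final = np.asarray(centroid_sets[-1], dtype=float)
    if len(final) < 2:
        raise NoAnaphaseError("final frame has fewer than 2 centroids")
    centered = final - final.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0] / np.linalg.norm(vt[0])
    d = np.full(len(centroid_sets), np.nan)
    for k, pts in enumerate(centroid_sets):
        pts = np.asarray(pts, dtype=float)
        if len(pts) >= 2:
            d[k] = _two_means_1d((pts - pts.mean(axis=0)) @ axis)
    return d, axis


def detect_anaphase(centroid_sets, times) -> AnaphaseCall:
    """First frame whose group separation jumps above a robust baseline.

    Frame k qualifies when d(k) exceeds median(d[:k]) + max(2*MAD, 1 px)
    and d keeps increasing for the next two frames.
    """
    if len(centroid_sets) < 5:
        raise NoAnaphaseError("need at least 5 frames")
    times = np.asarray(times, dtype=float)
    d, axis = separation_series(centroid_sets)
    for k in range(5, len(d) - 2):
        history = d[:k][~np.isnan(d[:k])]
        if len(history) < 5 or np.isnan(d[k]):
            continue
        med = np.median(history)
        mad = np.median(np.abs(history - med))
        thr = med + max(2.0 * mad, MAD_FLOOR_PX)
        if d[k] > thr and d[k + 1] > d[k] and d[k + 2] > d[k + 1]:
            return AnaphaseCall(time=float(times[k]), frame=k, axis=axis,
                                separation=d)
    raise NoAnaphaseError("no frame with sustained poleward movement")


def nebd_to_anaphase(events: EventTimes) -> float:
    """NEBD-to-anaphase duration in minutes."""
    if events.t_nebd is None or events.t_anaphase is None:
        raise ValueError("both events must be detected")
    if events.t_anaphase < events.t_nebd:
        raise ValueError(
            f"inconsistent events: anaphase {events.t_anaphase} before "
            f"NEBD {events.t_nebd}")
    return float(events.t_anaphase - events.t_nebd)


def _axial_spread(entry, axis) -> float:
    """Spread of kinetochore signal along the axis for one frame.

    A FociSet contributes the spread of its above-threshold pixels (robust
    to neighbouring foci merging into one component); a bare centroid
    array contributes the spread of the centroids.
    """
    label_image = getattr(entry, "label_image", None)
    if label_image is not None:
        ys, xs = np.nonzero(label_image)
        if len(xs) < 4:
            return np.nan
        pts = np.column_stack([xs, ys]).astype(float)
    else:
        pts = np.asarray(entry, dtype=float)
        if len(pts) < 2:
            return np.nan
    proj = (pts - pts.mean(axis=0)) @ axis
    return float(proj.std())


def metaphase_length(frames, times, anaphase: AnaphaseCall) -> tuple[float, float]:
    """(metaphase length, t_plate): plate formation to anaphase onset.

    ``frames`` is a per-frame list of FociSet objects (preferred) or
    centroid arrays.  The plate level is the median axial spread over the
    last pre-anaphase frames; t_plate is the frame after the spread last
    exceeded PLATE_SD_FACTOR times that level (the first frame of the
    sustained collapse).  A spread that never contracts by that factor
    means the plate never formed.
    """
    times = np.asarray(times, dtype=float)
    k_ana = anaphase.frame
    sds = np.full(k_ana, np.nan)
    for k in range(k_ana):
        sds[k] = _axial_spread(frames[k], anaphase.axis)
    # If onset detection ran one frame late, the last "pre-anaphase" frame
    # already shows poleward separation; drop it when its spread doubles.
    if (k_ana >= 2 and np.isfinite(sds[-1]) and np.isfinite(sds[-2])
            and sds[-1] > 2.0 * sds[-2]):
        sds = sds[:-1]
    valid_idx = np.where(~np.isnan(sds))[0]
    if len(valid_idx) < 3:
        raise NoMetaphaseError("too few pre-anaphase frames")
    # plate level: median spread over the final (plate) frames
    plate_sd = float(np.median(sds[valid_idx[-3:]]))
    if plate_sd <= 0 or np.nanmax(sds) / plate_sd < PLATE_SD_FACTOR:
        raise NoMetaphaseError("centroid spread never collapses onto a plate")
    above = valid_idx[sds[valid_idx] > PLATE_SD_FACTOR * plate_sd]
    if len(above) == 0:
        t_plate = float(times[valid_idx[0]])
    else:
        later = valid_idx[valid_idx > above[-1]]
        if len(later) == 0:
            raise NoMetaphaseError("spread still collapsing at anaphase onset")
        t_plate = float(times[later[0]])
    return float(anaphase.time - t_plate), t_plate
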