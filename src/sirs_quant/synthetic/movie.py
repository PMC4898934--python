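"""Two-channel time-lapse simulator with planted ground truth.

The kinetochore channel renders punctate Cenp-C-like foci: initial clusters
(one per polytene/diplochromosome group) split into sister-pair foci between
NEBD and metaphase-plate formation (SIRS), congress to a plate, and at
anaphase each pair separates into two kinetochores moving poleward along a
randomly oriented division axis.  The geminin/chromatin channel renders a
nuclear geminin-like blob whose brightness collapses at NEBD (half-maximal
exactly at the planted t_NEBD) plus condensed-DNA masses that segregate at
anaphase, with optional planted DNA bridges and lagging chromatids.

All event times are continuous; the rendered state of frame k is the state
at time ``k * frame_interval``, with anaphase onset snapped to the nearest
frame so that the onset frame already shows poleward displacement (the
operational reading of "first frame with poleward movement").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import ConfigurationError
from ..io_core import Movie
from .presets import Preset, get_preset
from .render import (NoiseParams, add_noise, render_gaussian_blob, render_spots,
                     render_strand)

# Chromatin/geminin-channel rendering constants (arbitrary camera counts).
GEMININ_AMP = 150.0
GEMININ_SIGMA = 12.0
MASS_AMP = 200.0
MASS_SIGMA = 5.0
BRIDGE_AMP = 120.0
BRIDGE_SIGMA = 2.0
LAGGING_AMP = 70.0
LAGGING_SIGMA = 2.5
CONGRESSION_MIN = 2.0   # congression window length, minutes
PLATE_AXIAL_SD = 1.2    # px, spread of plate positions along the division axis
PLATE_LATERAL_HALF = 14.0  # px, half-width of the plate
NUCLEUS_RADIUS = 8.0    # px, spread of the pre-NEBD kinetochore clusters
CLUSTER_MIN_SEP = 6.0   # px, pre-NEBD clusters stay individually resolvable
UNSPLIT_AXIAL_OFFSET = (4.0, 8.0)  # px, off-plate displacement of unsplit clumps
SIRS_TIMESCALE_MIN = 0.5           # min, mean split delay after NEBD
PRE_CONGRESSION_DRIFT = 0.3        # fraction of the way to the plate at splitting


@dataclass
class GroundTruth:
    """Planted truth for one simulated movie (simulation bookkeeping)."""

    preset: str
    true_cluster_count: int
    n_pairs_total: int
    t_nebd_true: float | None
    t_anaphase_true: float | None   # snapped to the rendered onset frame
    t_plate_true: float | None
    planted_error: str = "none"     # none | lagging | bridge
    dispersal_complete: bool = True
    division_axis_deg: float | None = None
    cluster_positions: np.ndarray | None = None
    spots_per_frame: list = field(default_factory=list)

    @property
    def duration_true(self) -> float | None:
        if self.t_nebd_true is None or self.t_anaphase_true is None:
            return None
        return self.t_anaphase_true - self.t_nebd_true

    def spot_table(self) -> pd.DataFrame:
        rows = []
        for k, spots in enumerate(self.spots_per_frame):
            for x, y, amp in spots:
                rows.append({"frame": k, "x": x, "y": y, "amplitude": amp})
        return pd.DataFrame(rows, columns=["frame", "x", "y", "amplitude"])

    def event_table(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "preset": self.preset,
            "true_cluster_count": self.true_cluster_count,
            "n_pairs_total": self.n_pairs_total,
            "t_nebd_true": self.t_nebd_true,
            "t_anaphase_true": self.t_anaphase_true,
            "t_plate_true": self.t_plate_true,
            "planted_error": self.planted_error,
            "dispersal_complete": self.dispersal_complete,
            "division_axis_deg": self.division_axis_deg,
        }])


def _place_points(rng, n, center, radius, min_sep, max_tries=4000):
    """Dart-throwing placement of n points in a disc with minimum spacing."""
    pts = []
    for _ in range(max_tries):
        r = radius * np.sqrt(rng.uniform())
        phi = rng.uniform(0, 2 * np.pi)
        cand = np.array([center[0] + r * np.cos(phi), center[1] + r * np.sin(phi)])
        if all(np.hypot(*(cand - p)) >= min_sep for p in pts):
            pts.append(cand)
            if len(pts) == n:
                return np.array(pts)
    raise ConfigurationError(
        f"could not place {n} points with spacing {min_sep} in radius {radius}")


def _events(preset: Preset, rng):
    """Draw continuous event times honouring t_NEBD < t_plate < t_anaphase."""
    t_nebd = preset.nebd_time_dist.sample(rng)
    duration = preset.duration_dist.sample(rng)
    t_ana_cont = t_nebd + duration
    k_ana = int(round(t_ana_cont / preset.frame_interval))
    t_ana = k_ana * preset.frame_interval
    if preset.metaphase_len_dist is not None and preset.segregate:
        m = preset.metaphase_len_dist.sample(rng)
        m = float(np.clip(m, 2.0, duration - (CONGRESSION_MIN + 1.0)))
        t_plate = t_ana_cont - m
    else:
        t_plate = None
    return t_nebd, t_ana_cont, t_ana, k_ana, t_plate


def generate_movie(preset: Preset | str, seed: int) -> tuple[Movie, GroundTruth]:
    """Simulate one two-channel movie; bit-identical for identical inputs."""
    if isinstance(preset, str):
        preset = get_preset(preset)
    rng = np.random.default_rng(seed)
    h, w = preset.image_shape
    center = np.array([w / 2.0, h / 2.0])
    dt = preset.frame_interval
    times = np.arange(preset.n_frames) * dt

    n_clusters = int(preset.cluster_count_dist.sample(rng))
    pairs = preset.pairs_per_cluster
    pair_amp = 2.0 * preset.kinetochore_amp

    # Cluster layout: fixed cells use a wide nucleus with resolvable spacing;
    # live movies start from a compact cluster arrangement.
    if preset.static:
        radius = min(h, w) / 2.0 - 6.0 * preset.psf_sigma - 4.0
        parent_pos = _place_points(rng, n_clusters, center, radius,
                                   6.0 * preset.psf_sigma)
    else:
        # nucleus grows with cluster count so spacing stays feasible
        radius = max(NUCLEUS_RADIUS, CLUSTER_MIN_SEP * np.sqrt(n_clusters) / 1.5)
        parent_pos = _place_points(rng, n_clusters, center, radius, CLUSTER_MIN_SEP)

    truth = GroundTruth(
        preset=preset.name, true_cluster_count=n_clusters,
        n_pairs_total=n_clusters * pairs, t_nebd_true=None,
        t_anaphase_true=None, t_plate_true=None,
        cluster_positions=parent_pos,
    )

    if preset.static:
        _render_static(preset, rng, parent_pos, pairs, pair_amp, truth)
        movie = Movie(pixels=truth._pixels, pixel_size=0.2, frame_interval=dt)
        del truth._pixels
        return movie, truth

    # ---- event times -------------------------------------------------------
    t_nebd, t_ana_cont, t_ana, k_ana, t_plate = _events(preset, rng)
    if preset.segregate:
        needed = k_ana + 3  # detection needs two rising frames past onset
        if needed >= preset.n_frames:
            raise ConfigurationError(
                f"n_frames={preset.n_frames} too short for anaphase at frame {k_ana}")
        truth.t_anaphase_true = t_ana
        truth.t_plate_true = t_plate
    else:
        t_ana = None
        t_plate = None
    truth.t_nebd_true = t_nebd

    theta = rng.uniform(0.0, 2 * np.pi)
    axis = np.array([np.cos(theta), np.sin(theta)])
    lateral = np.array([-np.sin(theta), np.cos(theta)])
    truth.division_axis_deg = float(np.degrees(theta) % 360.0)

    # ---- dispersal plan ----------------------------------------------------
    incomplete = rng.uniform() < preset.dispersal.incomplete_prob
    n_unsplit = 0
    if incomplete:
        n_unsplit = max(1, int(round(preset.dispersal.unsplit_fraction * n_clusters)))
    unsplit = set(rng.choice(n_clusters, size=n_unsplit, replace=False)) if n_unsplit else set()
    truth.dispersal_complete = not incomplete

    # Sister separation bursts right at NEBD (the clusteredness drop is
    # synchronous with the geminin drop): per-cluster split delays are
    # exponential with a ~1-minute timescale, capped before congression.
    split_hi = (t_plate - CONGRESSION_MIN) if t_plate is not None \
        else t_nebd + 0.6 * (preset.duration_dist.mean if preset.duration_dist else 15.0)
    split_hi = max(split_hi, t_nebd + 1.0)
    split_times = {
        c: (np.inf if c in unsplit
            else min(t_nebd + 0.1 + rng.exponential(SIRS_TIMESCALE_MIN), split_hi))
        for c in range(n_clusters)
    }

    # per-pair child scatter position and plate position
    # On splitting, the sister-pair foci scatter around their parent cluster,
    # drifting slightly toward their eventual plate site; full congression
    # happens only in the window before t_plate, so the centroid spread
    # along the division axis collapses at plate formation.
    child_pos, plate_pos, cluster_of = [], [], []
    for c in range(n_clusters):
        for _ in range(pairs):
            off = preset.dispersal.child_scatter_px
            scatter = parent_pos[c] + rng.uniform(-off, off, size=2)
            ax = rng.normal(0.0, PLATE_AXIAL_SD)
            lat = rng.uniform(-PLATE_LATERAL_HALF, PLATE_LATERAL_HALF)
            plate = center + ax * axis + lat * lateral
            child_pos.append((1.0 - PRE_CONGRESSION_DRIFT) * scatter
                             + PRE_CONGRESSION_DRIFT * plate)
            plate_pos.append(plate)
            cluster_of.append(c)
    child_pos = np.array(child_pos)
    plate_pos = np.array(plate_pos)
    # Clusters that never split congress poorly: the clump ends up displaced
    # from the plate plane along the division axis, distorting the plate.
    cluster_plate = {
        c: center
        + rng.choice([-1.0, 1.0]) * rng.uniform(*UNSPLIT_AXIAL_OFFSET) * axis
        + rng.uniform(-PLATE_LATERAL_HALF, PLATE_LATERAL_HALF) * lateral
        for c in unsplit
    }

    # ---- planted error -----------------------------------------------------
    error = "none"
    if incomplete:
        error = "bridge"  # incomplete dispersal leaves chromatin conjoined
    elif preset.error_rates.error_prob > 0 and rng.uniform() < preset.error_rates.error_prob:
        error = "bridge" if rng.uniform() < preset.error_rates.bridge_given_error else "lagging"
    truth.planted_error = error
    lag_pair = int(rng.integers(len(child_pos))) if error == "lagging" else -1
    lag_axis_offset = rng.uniform(-2.0, 2.0)
    lag_side = 1.0 if rng.uniform() < 0.5 else -1.0

    # ---- render ------------------------------------------------------------
    n_pairs = len(child_pos)
    pixels = np.zeros((preset.n_frames, 2, h, w), dtype=np.float64)
    for k, t in enumerate(times):
        in_ana = preset.segregate and k >= k_ana
        disp = 0.0
        if in_ana:
            disp = min(preset.pole_speed * (k - k_ana + 1) * dt, preset.pole_cap_px)
        spots = []
        # unsplit clusters rendered as single (or post-anaphase: two) spots
        for c in unsplit:
            pos = _cluster_position(parent_pos[c], cluster_plate[c], t, t_plate)
            amp = pairs * pair_amp
            if in_ana:
                spots.append((*(pos + disp * axis), amp / 2))
                spots.append((*(pos - disp * axis), amp / 2))
            else:
                spots.append((*pos, amp))
        # split clusters: cluster spot before the split, pair foci after
        rendered_cluster = set()
        for i in range(n_pairs):
            c = cluster_of[i]
            if c in unsplit:
                continue
            if t < split_times[c]:
                if c not in rendered_cluster:
                    spots.append((*parent_pos[c], pairs * pair_amp))
                    rendered_cluster.add(c)
                continue
            pos = _pair_position(child_pos[i], plate_pos[i], t, t_plate)
            if not in_ana:
                spots.append((*pos, pair_amp))
            elif i == lag_pair:
                # one kinetochore segregates, its sister lags near the midzone
                spots.append((*(pos + lag_side * disp * axis), pair_amp / 2))
                lag_pos = center + lag_axis_offset * axis \
                    + (pos - center).dot(lateral) * lateral
                spots.append((*lag_pos, pair_amp / 2))
            else:
                spots.append((*(pos + disp * axis), pair_amp / 2))
                spots.append((*(pos - disp * axis), pair_amp / 2))
        truth.spots_per_frame.append(spots)
        pixels[k, 0] = render_spots(spots, (h, w), preset.psf_sigma)
        pixels[k, 1] = _chromatin_frame(
            preset, t, t_nebd, center, axis, lateral, disp, in_ana, error,
            lag_axis_offset, (h, w))

    if preset.noise.enabled:
        for k in range(preset.n_frames):
            for c in range(2):
                pixels[k, c] = add_noise(pixels[k, c], preset.noise, rng)

    movie = Movie(pixels=pixels, pixel_size=0.2, frame_interval=dt)
    return movie, truth


def _cluster_position(start, plate, t, t_plate):
    if t_plate is None:
        return start
    return _congress(start, plate, t, t_plate)


def _pair_position(child, plate, t, t_plate):
    if t_plate is None:
        return child
    return _congress(child, plate, t, t_plate)


def _congress(pos0, pos1, t, t_plate):
    """Linear congression onto the plate during the window before t_plate."""
    t0 = t_plate - CONGRESSION_MIN
    if t <= t0:
        return pos0
    if t >= t_plate:
        return pos1
    f = (t - t0) / CONGRESSION_MIN
    return pos0 + f * (pos1 - pos0)


def _geminin_brightness(t, t_nebd, dt):
    """High and flat before NEBD, half-maximal at t_NEBD, zero one frame later."""
    return float(np.clip((t_nebd + dt - t) / (2.0 * dt), 0.0, 1.0))


def _chromatin_frame(preset, t, t_nebd, center, axis, lateral, disp, in_ana,
                     error, lag_axis_offset, shape):
    img = np.zeros(shape, dtype=np.float64)
    b = _geminin_brightness(t, t_nebd, preset.frame_interval) if t_nebd is not None else 1.0
    if b > 0:
        render_gaussian_blob(img, center[0], center[1], GEMININ_SIGMA, GEMININ_AMP * b)
    m0 = center + disp * axis if in_ana else center
    m1 = center - disp * axis if in_ana else center
    render_gaussian_blob(img, m0[0], m0[1], MASS_SIGMA, MASS_AMP)
    render_gaussian_blob(img, m1[0], m1[1], MASS_SIGMA, MASS_AMP)
    if in_ana and disp > 0:
        if error == "bridge":
            render_strand(img, m0, m1, BRIDGE_SIGMA, BRIDGE_AMP)
        elif error == "lagging":
            lag = center + lag_axis_offset * axis
            render_gaussian_blob(img, lag[0], lag[1], LAGGING_SIGMA, LAGGING_AMP)
    return img


def _render_static(preset, rng, parent_pos, pairs, pair_amp, truth):
    """Fixed-cell rendering: identical signal every frame, fresh noise."""
    h, w = preset.image_shape
    center = (w / 2.0, h / 2.0)
    spots = [(x, y, pairs * pair_amp) for x, y in parent_pos]
    signal_k = render_spots(spots, (h, w), preset.psf_sigma)
    signal_g = np.zeros((h, w))
    render_gaussian_blob(signal_g, center[0], center[1], GEMININ_SIGMA, GEMININ_AMP)
    pixels = np.zeros((preset.n_frames, 2, h, w), dtype=np.float64)
    for k in range(preset.n_frames):
        truth.spots_per_frame.append(list(spots))
        pixels[k, 0] = signal_k
        pixels[k, 1] = signal_g
        if preset.noise.enabled:
            pixels[k, 0] = add_noise(pixels[k, 0], preset.noise, rng)
            pixels[k, 1] = add_noise(pixels[k, 1], preset.noise, rng)
    truth._pixels = pixels


def generate_cell_image(preset: Preset | str, seed: int):
    """Single fixed-cell kinetochore image + truth (foci-counting scenarios)."""
    movie, truth = generate_movie(preset, seed)
    return movie.frame("kinetochore", 0), truth
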