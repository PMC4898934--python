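"""Metaphase-plate line profiles, aggregates, and anaphase-error detection.

The plate profile is taken from the kinetochore channel at the frame
immediately before anaphase onset: the image is rotated so the division
axis is horizontal, the above-threshold plate region is cropped with 2 px
padding, intensity is summed column-wise, resampled to a fixed number of
bins and normalized to unit sum so profiles are comparable across cell
sizes.  Profiles are canonically oriented (center of mass in the left
half) so that the arbitrary sign of the estimated axis cannot flip them.

Anaphase errors are assessed a fixed offset after onset (default 4 min):
a DNA bridge is an above-threshold chromatin component connecting the two
segregating masses (spanning both outer-25% pole regions of the
pole-to-pole axis); a lagging chromosome is any kinetochore focus lying in
the middle third of that axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu

from .errors import InsufficientFootageError
from .foci import segment_foci
from .timing import AnaphaseCall

POLE_REGION_FRACTION = 0.25
DEFAULT_OFFSET_MIN = 4.0
DEFAULT_BINS = 100


@dataclass
class PlateProfile:
    """Unit-sum intensity profile of one metaphase plate.

    ``sd`` is the intensity-weighted spatial spread (px) of the signal
    along the division axis — the per-cell variability statistic: a tight
    plate concentrates signal in one plane (small sd) while off-plate
    clumps of unseparated centromeres widen the distribution.
    """

    profile: np.ndarray           # length n_bins, sums to 1
    sd: float                     # spatial spread of signal along the axis, px
    mirror_corr: float            # correlation with the reversed profile
    cell_id: str = ""
    degenerate: bool = False      # flat profile: mirror_corr = 1 by convention


@dataclass
class ErrorCall:
    """Anaphase-error assessment for one division."""

    lagging: bool
    bridge: bool
    assessed_at: float            # minutes after anaphase onset

    @property
    def any_error(self) -> bool:
        return self.lagging or self.bridge


def orient_and_profile(movie, anaphase: AnaphaseCall, n_bins: int = DEFAULT_BINS,
                       pad: int = 2, cell_id: str = "") -> PlateProfile:
    """Line profile of the plate at the frame immediately before anaphase."""
    k = max(anaphase.frame - 1, 0)
    img = movie.frame("kinetochore", k).astype(float)
    angle = np.degrees(np.arctan2(anaphase.axis[1], anaphase.axis[0]))
    rot = ndimage.rotate(img, angle, reshape=True, order=1, mode="constant", cval=0.0)
    rot = np.clip(rot, 0.0, None)
    thr = threshold_otsu(rot) if rot.max() > rot.min() else np.inf
    mask = rot >= thr
    if not mask.any():
        raise ValueError("empty plate region")
    rows = np.where(mask.any(axis=1))[0]
    cols = np.where(mask.any(axis=0))[0]
    r0, r1 = max(rows[0] - pad, 0), min(rows[-1] + pad + 1, rot.shape[0])
    c0, c1 = max(cols[0] - pad, 0), min(cols[-1] + pad + 1, rot.shape[1])
    colsum = rot[r0:r1, c0:c1].sum(axis=0)
    total = colsum.sum()
    if total <= 0:
        raise ValueError("empty plate region")
    # spatial spread in pixel units, before length-normalizing resampling
    px = np.arange(len(colsum), dtype=float)
    w = colsum / total
    mu = float(np.dot(px, w))
    sd = float(np.sqrt(np.dot((px - mu) ** 2, w)))
    x_src = np.linspace(0.0, 1.0, len(colsum))
    x_dst = np.linspace(0.0, 1.0, n_bins)
    prof = np.interp(x_dst, x_src, colsum)
    prof = prof / prof.sum()
    # canonical orientation: center of mass in the left half
    com = float(np.dot(np.arange(n_bins), prof))
    if com > (n_bins - 1) / 2.0:
        prof = prof[::-1].copy()
    if prof.std() == 0.0:
        return PlateProfile(profile=prof, sd=sd, mirror_corr=1.0,
                            cell_id=cell_id, degenerate=True)
    m = float(np.corrcoef(prof, prof[::-1])[0, 1])
    return PlateProfile(profile=prof, sd=sd, mirror_corr=m, cell_id=cell_id)


def aggregate_profiles(profiles, n_boot: int = 1000, seed: int = 0,
                       ci: float = 95.0):
    """Per-bin mean profile with a seeded bootstrap percentile CI."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to aggregate")
    mat = np.array([p.profile if isinstance(p, PlateProfile) else np.asarray(p)
                    for p in profiles])
    mean = mat.mean(axis=0)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(mat), size=(n_boot, len(mat)))
    boot_means = mat[idx].mean(axis=1)          # (n_boot, n_bins)
    alpha = (100.0 - ci) / 2.0
    lo = np.percentile(boot_means, alpha, axis=0)
    hi = np.percentile(boot_means, 100.0 - alpha, axis=0)
    return mean, lo, hi


def _offset_frame(movie, anaphase: AnaphaseCall, offset_min: float) -> int:
    k = anaphase.frame + int(round(offset_min / movie.frame_interval))
    if k >= movie.n_frames:
        raise InsufficientFootageError(
            f"movie ends before anaphase + {offset_min} min")
    return k


def detect_bridge(movie, anaphase: AnaphaseCall,
                  offset_min: float = DEFAULT_OFFSET_MIN) -> bool:
    """True iff a chromatin component spans both pole regions at +offset."""
    k = _offset_frame(movie, anaphase, offset_min)
    img = movie.frame("geminin", k).astype(float)
    if img.max() == img.min():
        return False
    mask = img >= threshold_otsu(img)
    labels = measure.label(mask, connectivity=2)
    ys, xs = np.nonzero(mask)
    proj = xs * anaphase.axis[0] + ys * anaphase.axis[1]
    pmin, pmax = proj.min(), proj.max()
    span = pmax - pmin
    if span <= 0:
        return False
    lo_cut = pmin + POLE_REGION_FRACTION * span
    hi_cut = pmax - POLE_REGION_FRACTION * span
    lab_vals = labels[ys, xs]
    for lab in np.unique(lab_vals):
        p = proj[lab_vals == lab]
        if p.min() <= lo_cut and p.max() >= hi_cut:
            return True
    return False


def detect_lagging(movie, anaphase: AnaphaseCall,
                   offset_min: float = DEFAULT_OFFSET_MIN,
                   method: str = "robust_background", min_area: int = 1) -> bool:
    """True iff any kinetochore focus sits in the middle third at +offset.

    A single lagging kinetochore carries half the flux of a sister-pair
    focus and survives thresholding as a region of only a pixel or two, so
    the scan uses the robust background threshold (stable against bright
    merged pole clumps) with no minimum region area; the threshold sits far
    above the noise floor, making single-pixel false detections negligible.
    """
    k = _offset_frame(movie, anaphase, offset_min)
    foci = segment_foci(movie.frame("kinetochore", k), method=method,
                        min_area=min_area, frame=k)
    if foci.count < 2:
        return False
    proj = (foci.centroids - foci.centroids.mean(axis=0)) @ anaphase.axis
    span = proj.max() - proj.min()
    if span <= 0:
        return False
    mid = (proj.max() + proj.min()) / 2.0
    return bool(np.any(np.abs(proj - mid) < span / 6.0))


def score_errors(movie, anaphase: AnaphaseCall,
                 offset_min: float = DEFAULT_OFFSET_MIN) -> ErrorCall:
    """Joint lagging + bridge assessment at the configured offset."""
    return ErrorCall(
        lagging=detect_lagging(movie, anaphase, offset_min),
        bridge=detect_bridge(movie, anaphase, offset_min),
        assessed_at=offset_min,
    )


def plot_aggregate(groups: dict, path, n_boot: int = 1000, seed: int = 0):
    """Aggregate-profile figure: per-group mean line plot with 95% CI band.

    ``groups`` maps a label to a list of PlateProfile objects.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    x = None
    for label, profiles in groups.items():
        mean, lo, hi = aggregate_profiles(profiles, n_boot=n_boot, seed=seed)
        x = np.arange(len(mean))
        line, = ax.plot(x, mean, label=f"{label} (n={len(profiles)})")
        ax.fill_between(x, lo, hi, alpha=0.25, color=line.get_color())
    ax.set_xlabel("position along division axis (bin)")
    ax.set_ylabel("normalized intensity")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
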