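"""Karyotype-spread segmentation and configuration/ploidy classification.

Chromatin bodies are segmented by thresholding + connected components;
centromere marks are local intensity maxima of the centromere channel and
are assigned to the body containing them.  Classification operationalizes
visual karyotyping:

* diplochromosome body — exactly 4 centromere marks, all mutually within
  the conjoined radius (four sister chromatids attached at centromeres);
* ploidy from the sister-pair inventory — 2N pair bodies = diploid,
  4N = tetraploid, 4N ± 1–2 = aneuploid tetraploid (haploid N = 4 female /
  5 male);
* polytene — the haploid number of giant bodies;
* clumped vs separated — median nearest-neighbour body distance below one
  body diameter means the recent sisters are still clumped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu

from .synthetic.presets import HAPLOID_N

log = logging.getLogger(__name__)

PLOIDY_CLASSES = ("euploid_diploid", "euploid_tetraploid",
                  "euploid_diplo_tetraploid", "aneuploid_tetraploid",
                  "unclassified")
CONFIG_CLASSES = ("polytene", "clumped", "separated", "unclassified")

#: Marks within this radius (px) of each other count as conjoined.
CONJOINED_RADIUS_PX = 7.0
#: Bodies at least this many px^2 count as giant (polytene candidates).
GIANT_AREA_PX = 150.0
MIN_BODY_AREA = 30
MIN_MARK_DISTANCE = 1
#: Light pre-smoothing of the centromere channel before peak detection;
#: suppresses shot-noise double peaks without merging marks ~3 px apart.
MARK_SMOOTH_SIGMA = 0.5


@dataclass
class SpreadSegmentation:
    """Bodies plus per-body centromere inventories for one spread."""

    n_bodies: int
    body_areas: np.ndarray
    body_centroids: np.ndarray                 # (n, 2) as (x, y)
    body_equiv_diameters: np.ndarray
    marks_per_body: list = field(default_factory=list)  # list of (m_i, 2) arrays
    n_unassigned_marks: int = 0

    @property
    def centromeres_per_body(self) -> list:
        return [len(m) for m in self.marks_per_body]


@dataclass
class SpreadCall:
    """Classification of one spread into ploidy and configuration classes."""

    n_bodies: int
    centromeres_per_body: list
    ploidy_class: str = "unclassified"
    config_class: str = "unclassified"


def segment_spread(image) -> SpreadSegmentation:
    """Segment chromatin bodies and assign centromere marks to them.

    ``image`` is a SpreadImage or a (2, Y, X) array with chromatin first.
    Marks falling outside every body are counted and logged, not assigned.
    """
    pixels = image.pixels if hasattr(image, "pixels") else np.asarray(image)
    chromatin = pixels[0].astype(float)
    centromere = pixels[1].astype(float)
    if chromatin.max() == chromatin.min():
        raise ValueError("empty spread image")
    mask = chromatin >= threshold_otsu(chromatin)
    labels = measure.label(mask, connectivity=2)
    props = [p for p in measure.regionprops(labels) if p.area >= MIN_BODY_AREA]
    props.sort(key=lambda p: (p.centroid[0], p.centroid[1]))
    relabel = np.zeros_like(labels)
    for new, p in enumerate(props, start=1):
        relabel[labels == p.label] = new

    smoothed = ndimage.gaussian_filter(centromere, MARK_SMOOTH_SIGMA)
    thr = threshold_otsu(smoothed) if smoothed.max() > smoothed.min() else np.inf
    peaks = peak_local_max(smoothed, min_distance=MIN_MARK_DISTANCE,
                           threshold_abs=float(thr))
    marks_per_body = [[] for _ in props]
    unassigned = 0
    for y, x in peaks:
        lab = relabel[y, x]
        if lab > 0:
            marks_per_body[lab - 1].append((x, y))
        else:
            unassigned += 1
    if unassigned:
        log.warning("%d centromere marks outside any body left unassigned", unassigned)
    return SpreadSegmentation(
        n_bodies=len(props),
        body_areas=np.array([p.area for p in props], dtype=float),
        body_centroids=np.array([(p.centroid[1], p.centroid[0]) for p in props])
        if props else np.empty((0, 2)),
        body_equiv_diameters=np.array([p.equivalent_diameter_area for p in props]),
        marks_per_body=[np.array(m, dtype=float).reshape(-1, 2) for m in marks_per_body],
        n_unassigned_marks=unassigned,
    )


def _is_conjoined_quad(marks: np.ndarray) -> bool:
    """A conjoined centromere group: 3-4 mutually close marks.

    Four sister centromeres sit in a tight cluster; occasionally two of
    them merge into one detected peak, so three close marks still count.
    """
    if not 3 <= len(marks) <= 4:
        return False
    d = np.linalg.norm(marks[:, None, :] - marks[None, :, :], axis=-1)
    return bool(d.max() < CONJOINED_RADIUS_PX)


def _median_nn_distance(centroids: np.ndarray) -> float:
    d = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return float(np.median(d.min(axis=1)))


def classify_spread(seg: SpreadSegmentation, sex: str = "female") -> SpreadCall:
    """Apply the configuration/ploidy rules; unclassified is the catch-all."""
    h = HAPLOID_N[sex]
    n = seg.n_bodies
    call = SpreadCall(n_bodies=n, centromeres_per_body=seg.centromeres_per_body)
    if n == 0:
        return call

    giant = seg.body_areas >= GIANT_AREA_PX
    if n == h and np.all(giant):
        call.config_class = "polytene"
        total_cm = int(sum(seg.centromeres_per_body))
        if total_cm == 8 * h:       # all 4N chromatid copies present
            call.ploidy_class = "euploid_tetraploid"
        return call

    quads = [_is_conjoined_quad(m) for m in seg.marks_per_body]
    if n == 2 * h and sum(quads) >= n / 2:
        call.ploidy_class = "euploid_diplo_tetraploid"
        call.config_class = "separated"
        return call

    # sister-pair bodies: 1-2 detected marks (sisters can merge into one peak)
    pair_like = sum(len(m) <= 2 for m in seg.marks_per_body)
    if pair_like >= 0.8 * n:
        if n == 2 * h:
            call.ploidy_class = "euploid_diploid"
        elif n == 4 * h:
            call.ploidy_class = "euploid_tetraploid"
        elif abs(n - 4 * h) <= 2:
            call.ploidy_class = "aneuploid_tetraploid"
        if call.ploidy_class != "unclassified" and n >= 2:
            nn = _median_nn_distance(seg.body_centroids)
            diameter = float(np.median(seg.body_equiv_diameters))
            call.config_class = "clumped" if nn < diameter else "separated"
    return call


def classify_image(image, sex: str = "female") -> SpreadCall:
    """Segment + classify in one step."""
    return classify_spread(segment_spread(image), sex=sex)
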