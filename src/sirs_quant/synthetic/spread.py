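"""Karyotype-spread renderer with planted configuration classes.

A spread is a two-channel single frame: condensed chromosome bodies
(elongated capsules, chromatin channel) and centromere marks (punctate
channel).  Classes follow the observable configurations of tetraploid
papillar/wing cells after ectopic genome reduplication:

* ``euploid_diploid``        — 2N bodies, 2 sister centromeres each.
* ``euploid_tetraploid``     — 4N bodies, 2 centromeres each (fully separated).
* ``separated``              — alias layout of ``euploid_tetraploid``.
* ``euploid_diplo_tetraploid`` — 2N diplochromosome bodies, 4 conjoined
  centromeres each (four sister chromatids attached at their centromeres).
* ``aneuploid_tetraploid``   — 4N ± 1–2 sister-pair bodies.
* ``polytene``               — the haploid number of giant bodies (all
  chromatid copies associated), 8 clustered centromeres each.
* ``clumped``                — 4N sister-pair bodies, but the four recent
  sisters of each former polytene remain tightly grouped.

The haploid number is 4 in females and 5 in males (X/Y un-pairing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ..errors import ConfigurationError
from .presets import HAPLOID_N, Preset, get_preset
from .render import NoiseParams, add_noise, render_spots

CENTROMERE_AMP = 200.0
BODY_AMP = 120.0
PAIR_BODY = (14.0, 4.5)     # length, width in px of a sister-pair body
DIPLO_BODY = (16.0, 7.0)
POLYTENE_BODY = (24.0, 10.0)
MARK_SPACING = 4.0          # px between individual centromere marks
CLUMP_SPACING = 8.0         # px between bodies inside a clumped group

DEFAULT_SPREAD_NOISE = NoiseParams(background=10.0, read_sd=4.0, poisson=True)


@dataclass
class SpreadImage:
    """Two-channel spread: chromatin (0) + centromere marks (1)."""

    pixels: np.ndarray        # (2, Y, X)
    pixel_size: float = 0.2
    psf_sigma: float = 1.0
    channel_roles: dict = field(default_factory=lambda: {"chromatin": 0, "centromere": 1})

    def channel(self, role: str) -> np.ndarray:
        return self.pixels[self.channel_roles[role]]


@dataclass
class SpreadTruth:
    """Planted inventory for one rendered spread."""

    class_label: str
    sex: str
    n_bodies: int
    centromeres_per_body: list
    body_centers: np.ndarray
    body_sizes: list          # (length, width) per body
    delta_pairs: int = 0      # aneuploid offset (sister-pair bodies vs 4N)


def _capsule(img, center, length, width, angle, amp):
    """Add a solid capsule (segment dilated by width/2) to the image."""
    h, w = img.shape
    u = np.array([np.cos(angle), np.sin(angle)])
    half = (length - width) / 2.0  # segment half-length so total extent = length
    p0 = np.asarray(center) - half * u
    p1 = np.asarray(center) + half * u
    r = width / 2.0
    pad = int(np.ceil(length / 2 + r + 2))
    x0, x1 = int(center[0]) - pad, int(center[0]) + pad + 1
    y0, y1 = int(center[1]) - pad, int(center[1]) + pad + 1
    x0, x1 = max(0, x0), min(w, x1)
    y0, y1 = max(0, y0), min(h, y1)
    xx, yy = np.meshgrid(np.arange(x0, x1, dtype=float), np.arange(y0, y1, dtype=float))
    d = _dist_to_segment(xx, yy, p0, p1)
    img[y0:y1, x0:x1][d <= r] += amp


def _dist_to_segment(xx, yy, p0, p1):
    v = p1 - p0
    vv = float(v @ v)
    wx, wy = xx - p0[0], yy - p0[1]
    t = np.clip((wx * v[0] + wy * v[1]) / vv, 0.0, 1.0) if vv > 0 else 0.0
    return np.hypot(wx - t * v[0], wy - t * v[1])


def _mark_layout(kind: str, angle: float) -> np.ndarray:
    """Centromere-mark offsets (px) from the body center, in body frame."""
    s = MARK_SPACING
    if kind == "pair":
        local = [(-s / 2, 0), (s / 2, 0)]       # sisters along the body axis
    elif kind == "diplo":
        local = [(-s / 2, -s / 2), (-s / 2, s / 2), (s / 2, -s / 2), (s / 2, s / 2)]
    elif kind == "polytene":
        local = [(dx, dy) for dx in (-1.5 * s, -0.5 * s, 0.5 * s, 1.5 * s)
                 for dy in (-s / 2, s / 2)]
    else:
        raise ValueError(kind)
    u = np.array([np.cos(angle), np.sin(angle)])
    v = np.array([-np.sin(angle), np.cos(angle)])
    return np.array([a * u + b * v for a, b in local])


def _body_plan(class_label: str, sex: str, rng) -> tuple[list, int]:
    """List of (kind, grouped) bodies for a class; returns (kinds, delta)."""
    if sex not in HAPLOID_N:
        raise ConfigurationError(f"unknown sex {sex!r}")
    h = HAPLOID_N[sex]
    delta = 0
    if class_label == "euploid_diploid":
        kinds = ["pair"] * (2 * h)
    elif class_label in ("euploid_tetraploid", "separated"):
        kinds = ["pair"] * (4 * h)
    elif class_label == "euploid_diplo_tetraploid":
        kinds = ["diplo"] * (2 * h)
    elif class_label == "aneuploid_tetraploid":
        delta = int(rng.choice([-2, -1, 1, 2]))
        kinds = ["pair"] * (4 * h + delta)
    elif class_label == "polytene":
        kinds = ["polytene"] * h
    elif class_label == "clumped":
        kinds = ["pair"] * (4 * h)
    else:
        raise ConfigurationError(f"unknown spread class {class_label!r}")
    return kinds, delta


def _place_bodies(class_label, kinds, rng, shape):
    """Centers and angles; clumped spreads place groups of four together."""
    h_img, w_img = shape
    margin = 22.0
    lo = np.array([margin, margin])
    hi = np.array([w_img - margin, h_img - margin])

    def throw(n, min_sep, within=None, tries=6000):
        pts = []
        for _ in range(tries):
            cand = rng.uniform(lo, hi) if within is None else within(rng)
            if all(np.hypot(*(cand - p)) >= min_sep for p in pts):
                pts.append(cand)
                if len(pts) == n:
                    return np.array(pts)
        raise ConfigurationError("could not place spread bodies")

    if class_label == "clumped":
        n_groups = len(kinds) // 4
        group_centers = throw(n_groups, 46.0)
        centers, angles = [], []
        for g in range(n_groups):
            ang = rng.uniform(0, np.pi)
            perp = np.array([-np.sin(ang), np.cos(ang)])
            for j in range(4):
                offset = (j - 1.5) * CLUMP_SPACING
                centers.append(group_centers[g] + offset * perp)
                angles.append(ang)
        return np.array(centers), np.array(angles)

    sep = 26.0 if kinds[0] == "polytene" else (24.0 if kinds[0] == "diplo" else 20.0)
    centers = throw(len(kinds), sep)
    angles = rng.uniform(0, np.pi, size=len(kinds))
    return centers, angles


def generate_spread(class_label: str, sex: str = "female", seed: int = 0,
                    noise: NoiseParams | None = DEFAULT_SPREAD_NOISE,
                    shape=(200, 200), psf_sigma: float = 1.0
                    ) -> tuple[SpreadImage, SpreadTruth]:
    """Render one karyotype spread with planted truth."""
    rng = np.random.default_rng(seed)
    kinds, delta = _body_plan(class_label, sex, rng)
    centers, angles = _place_bodies(class_label, kinds, rng, shape)

    size_of = {"pair": PAIR_BODY, "diplo": DIPLO_BODY, "polytene": POLYTENE_BODY}
    amp_of = {"pair": BODY_AMP, "diplo": BODY_AMP, "polytene": BODY_AMP * 1.2}
    chromatin = np.zeros(shape, dtype=np.float64)
    marks = []
    cm_per_body = []
    sizes = []
    for kind, c, a in zip(kinds, centers, angles):
        length, width = size_of[kind]
        _capsule(chromatin, c, length, width, a, amp_of[kind])
        offs = _mark_layout(kind, a)
        for o in offs:
            marks.append((c[0] + o[0], c[1] + o[1], CENTROMERE_AMP))
        cm_per_body.append(len(offs))
        sizes.append((length, width))
    chromatin = ndimage.gaussian_filter(chromatin, psf_sigma)
    centromere = render_spots(marks, shape, psf_sigma)

    if noise is not None and noise.enabled:
        chromatin = add_noise(chromatin, noise, rng)
        centromere = add_noise(centromere, noise, rng)

    image = SpreadImage(pixels=np.stack([chromatin, centromere]), psf_sigma=psf_sigma)
    truth = SpreadTruth(class_label=class_label, sex=sex, n_bodies=len(kinds),
                        centromeres_per_body=cm_per_body, body_centers=centers,
                        body_sizes=sizes, delta_pairs=delta)
    return image, truth


def generate_spread_from_preset(preset: Preset | str, sex: str = "female",
                                seed: int = 0) -> tuple[SpreadImage, SpreadTruth]:
    """Draw a class from the preset's mix and render it."""
    if isinstance(preset, str):
        preset = get_preset(preset)
    if preset.spread_class_mix is None:
        raise ConfigurationError(f"preset {preset.name!r} has no spread class mix")
    rng = np.random.default_rng(seed)
    label = preset.spread_class_mix.sample(rng)
    sub = int(rng.integers(0, 2**31 - 1))
    return generate_spread(label, sex=sex, seed=sub, noise=preset.noise,
                           shape=preset.image_shape, psf_sigma=preset.psf_sigma)
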