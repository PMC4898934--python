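"""Forward model for punctate and diffuse fluorescence.

Spots are isotropic Gaussians of width ``psf_sigma`` added into the frame by
local stamping; noise is the standard fluorescence model — constant
background, Poisson shot noise on the expected photon count, and Gaussian
read noise — applied as the last step so that noise-free renders are exactly
additive in their spots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import OutOfBoundsError


@dataclass
class NoiseParams:
    """Camera noise model: expected counts -> Poisson + read noise + offset."""

    background: float = 0.0   # constant offset added to the expectation
    read_sd: float = 0.0      # Gaussian read noise sd (counts)
    poisson: bool = True      # shot noise on (signal + background)

    @property
    def enabled(self) -> bool:
        return self.background > 0 or self.read_sd > 0 or self.poisson


def render_spots(spots, shape, psf_sigma, out=None) -> np.ndarray:
    """Render Gaussian spots into a float image of the given shape.

    ``spots`` is an iterable of (x, y, amplitude); amplitude is the peak
    height. Spot centroids outside the image are rejected.
    """
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be positive")
    h, w = shape
    if h < 16 or w < 16:
        raise ValueError("image shape must be at least 16 x 16")
    img = out if out is not None else np.zeros(shape, dtype=np.float64)
    r = int(np.ceil(6 * psf_sigma))  # wide stamp keeps total flux conserved
    for x, y, amp in spots:
        if amp < 0:
            raise ValueError("spot amplitude must be non-negative")
        if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
            raise OutOfBoundsError(f"spot centroid ({x:.1f}, {y:.1f}) outside {w}x{h} image")
        y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
        x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
        yy = np.arange(y0, y1)[:, None] - y
        xx = np.arange(x0, x1)[None, :] - x
        img[y0:y1, x0:x1] += amp * np.exp(-(yy * yy + xx * xx) / (2.0 * psf_sigma**2))
    return img


def render_gaussian_blob(img, x, y, sigma, amp) -> None:
    """Add one broad Gaussian blob (nucleus / DNA mass) in place."""
    h, w = img.shape
    r = int(np.ceil(4 * sigma))
    y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
    x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy = np.arange(y0, y1)[:, None] - y
    xx = np.arange(x0, x1)[None, :] - x
    img[y0:y1, x0:x1] += amp * np.exp(-(yy * yy + xx * xx) / (2.0 * sigma**2))


def render_strand(img, p0, p1, sigma, amp, spacing=1.5) -> None:
    """Add a chromatin strand: overlapping Gaussians along the segment p0-p1."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    length = float(np.hypot(*(p1 - p0)))
    n = max(2, int(np.ceil(length / spacing)) + 1)
    for t in np.linspace(0.0, 1.0, n):
        x, y = p0 + t * (p1 - p0)
        render_gaussian_blob(img, x, y, sigma, amp)


def add_noise(img, noise: NoiseParams, rng: np.random.Generator) -> np.ndarray:
    """Apply the Poisson-Gaussian camera model; clips negatives to zero."""
    expected = img + noise.background
    if noise.poisson:
        out = rng.poisson(np.clip(expected, 0, None)).astype(np.float64)
    else:
        out = expected.astype(np.float64)
    if noise.read_sd > 0:
        out = out + rng.normal(0.0, noise.read_sd, size=out.shape)
    return np.clip(out, 0.0, None)


def render_frame(spots, shape, psf_sigma, noise: NoiseParams | None = None,
                 seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Render one frame of punctate signal, optionally with camera noise."""
    img = render_spots(spots, shape, psf_sigma)
    if noise is not None and noise.enabled:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        img = add_noise(img, noise, rng)
    return img
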