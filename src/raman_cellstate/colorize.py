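"""Pixel-wise state visualization.

Two pseudo-color renderings of a hyperspectral Raman image:

``colorize_state``
    projects every pixel spectrum (including substrate pixels) into a
    frozen state space and maps the two QDA class log-probabilities onto
    an 8-bit RGB image — the first-listed ("naive") class drives the blue
    and green channels (synchronized), the second ("activated") class the
    red channel, so cells closer to the naive/activated state appear
    blue/red.

``band_composite``
    integrates intensity over three named band windows (defaults
    753 cm^-1 cytochrome c → blue, 2956 cm^-1 proteins → green,
    2852 cm^-1 lipids → red) with per-channel min-max scaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import imageio.v3 as iio
import numpy as np

from .core import AxisRangeError, HyperStack, ValidationError
from .dapc import qda_log_prob
from .nipals import project
from .state_space import StateSpaceBundle

__all__ = ["RGBImage", "colorize_state", "band_composite"]

# RGB channel indices
_R, _G, _B = 0, 1, 2


@dataclass
class RGBImage:
    """8-bit RGB image; ``pixels`` has shape (rows, cols, 3), dtype uint8."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3 or p.dtype != np.uint8:
            raise ValidationError("RGBImage needs a (rows, cols, 3) uint8 array")
        self.pixels = p

    def save(self, path) -> None:
        """Write as PNG/TIFF (by extension)."""
        iio.imwrite(path, self.pixels)


def _to_u8(frac: np.ndarray) -> np.ndarray:
    return np.round(255.0 * np.clip(frac, 0.0, 1.0)).astype(np.uint8)


def colorize_state(
    bundle: StateSpaceBundle,
    stack: HyperStack,
    clip: Optional[np.ndarray] = None,
) -> RGBImage:
    """QDA log-probability pseudo-color map of a background-subtracted stack.

    Every pixel spectrum is cropped to the bundle's wavenumber range,
    SNV-standardized, projected to the frozen PC space, and scored by the
    two class log-probabilities.  Each class's log-probability is mapped
    linearly from its clip range [lo, hi] to [0, 255] (clipped outside):
    first-listed class → blue and green (synchronized), second → red.
    ``clip`` is a (2, 2) array of per-class (lo, hi); by default the
    bundle's training-percentile ranges are used.  Pixels with
    zero-variance (flat) spectra render black.
    """
    cfg = bundle.preprocess_config
    work = stack
    if "crop_cm1" in cfg:
        work = work.crop(*cfg["crop_cm1"])
    if work.axis != bundle.axis:
        raise ValidationError(
            "stack axis does not match the state space "
            f"(bundle covers {bundle.axis.values[0]:g}-{bundle.axis.values[-1]:g} cm^-1, "
            f"{len(bundle.axis)} bands; crop the stack or rebuild the bundle)"
        )
    if clip is None:
        clip = bundle.log_prob_clip
    clip = np.asarray(clip, dtype=np.float64)
    if clip.shape != (2, 2) or not np.all(clip[:, 1] > clip[:, 0]):
        raise ValidationError("clip must be (2, 2) with hi > lo per class")

    rows, cols, B = work.cube.shape
    X = work.cube.reshape(-1, B).astype(np.float64)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    flat = sd.ravel() <= 1e-12
    sd_safe = np.where(sd > 1e-12, sd, 1.0)
    Z = (X - mu) / sd_safe

    scores = project(bundle.pca, Z)
    lp = qda_log_prob(bundle.disc, scores)  # (npix, 2) in class order

    frac = (lp - clip[:, 0]) / (clip[:, 1] - clip[:, 0])
    naive_u8 = _to_u8(frac[:, 0])
    act_u8 = _to_u8(frac[:, 1])
    naive_u8[flat] = 0
    act_u8[flat] = 0

    img = np.zeros((rows * cols, 3), dtype=np.uint8)
    img[:, _B] = naive_u8
    img[:, _G] = naive_u8  # blue and green synchronized
    img[:, _R] = act_u8
    return RGBImage(pixels=img.reshape(rows, cols, 3))


def band_composite(
    stack: HyperStack,
    bands: Sequence[float] = (753.0, 2956.0, 2852.0),
    half_width: float = 8.0,
) -> RGBImage:
    """Three-band intensity composite (band1→blue, band2→green, band3→red).

    Per pixel, intensity is summed over each window ``center ± half_width``;
    each channel is min-max rescaled over the image to [0, 255].  A
    constant channel (degenerate min-max) renders as zeros.  Raises
    :class:`AxisRangeError` when a window misses the axis entirely.
    """
    if len(bands) != 3:
        raise ValidationError("band_composite needs exactly 3 band centers")
    if half_width <= 0:
        raise ValueError("half_width must be > 0")
    nu = stack.axis.values
    channels = []
    for center in bands:
        sel = np.abs(nu - center) <= half_width
        if not sel.any():
            raise AxisRangeError(
                f"window {center} ± {half_width} cm^-1 intersects no axis band"
            )
        channels.append(stack.cube[:, :, sel].sum(axis=2))

    img = np.zeros(stack.cube.shape[:2] + (3,), dtype=np.uint8)
    for ch, dest in zip(channels, (_B, _G, _R)):
        lo, hi = float(ch.min()), float(ch.max())
        if hi > lo:
            img[:, :, dest] = _to_u8((ch - lo) / (hi - lo))
        # constant channel stays 0
    return RGBImage(pixels=img)
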