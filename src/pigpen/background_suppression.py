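"""Background-suppressed image generation for static cameras.

A fixed camera watching a pen sees a constant background; animals are the
only thing that changes between a frame and the per-environment background
plate.  The pipeline here turns a frame into a *background-suppressed image*:

1. absolute difference between frame and background plate,
2. Otsu threshold on the difference image,
3. binary foreground mask (difference strictly above the threshold),
4. keep the original pixel where the mask is set, zero elsewhere.

The output preserves the animals' original texture while removing all
background content, which is what makes it transferable to pens the
detector never saw during training.

All images are 8-bit: frames are ``(H, W, 3)`` uint8 RGB, grayscale images
``(H, W)`` uint8, and binary masks ``(H, W)`` uint8 with values in {0, 255}.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "difference_image",
    "otsu_threshold",
    "foreground_mask",
    "suppress_background",
    "big_generate",
]


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def difference_image(frame: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Per-pixel absolute difference between a frame and the background plate.

    The subtraction runs in widened integer arithmetic so that 8-bit values
    never wrap around; for RGB inputs the three per-channel absolute
    differences are reduced to a single channel by taking their maximum,
    which retains the strongest change in any channel.

    Parameters
    ----------
    frame, background : ndarray
        uint8 images of identical shape, either ``(H, W, 3)`` or ``(H, W)``.

    Returns
    -------
    ndarray
        uint8 ``(H, W)`` difference image.
    """
    _check_same_shape(frame, background)
    diff = np.abs(frame.astype(np.int16) - background.astype(np.int16))
    if diff.ndim == 3:
        diff = diff.max(axis=2)
    return diff.astype(np.uint8)


def otsu_threshold(gray: np.ndarray) -> int:
    """Otsu's threshold over the 256-bin histogram of an 8-bit image.

    Returns the threshold ``t`` maximizing the between-class variance
    ``w0*w1*(mu0-mu1)**2`` where class 0 holds pixels ``<= t`` and class 1
    pixels ``> t``.  Ties are broken toward the smallest maximizing ``t``.
    A constant image returns its single value, so the induced foreground
    (``> t``) is empty.
    """
    gray = np.asarray(gray)
    if gray.size == 0:
        raise ValueError("otsu_threshold: empty image")
    hist = np.bincount(gray.astype(np.uint8).ravel(), minlength=256).astype(np.float64)
    lo = int(gray.min())
    if lo == int(gray.max()):
        return lo
    n = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    # cumulative class-0 weight and mean for every candidate threshold t
    w0 = np.cumsum(hist)
    m0 = np.cumsum(hist * levels)
    total_mean = m0[-1]
    w1 = n - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = (total_mean - m0) / w1
        var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between = np.nan_to_num(var_between, nan=0.0)
    return int(np.argmax(var_between))  # argmax takes the first (smallest) maximizer


def foreground_mask(gray: np.ndarray, t: int) -> np.ndarray:
    """Binary mask marking pixels strictly above the threshold as 255."""
    if not 0 <= t <= 255:
        raise ValueError(f"threshold {t} outside [0, 255]")
    return np.where(np.asarray(gray) > t, 255, 0).astype(np.uint8)


def suppress_background(frame: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero out background pixels, keeping foreground texture untouched.

    Pixels where ``mask >= 128`` are copied from ``frame``; all others are
    set to 0 on every channel.
    """
    frame = np.asarray(frame)
    mask = np.asarray(mask)
    if mask.shape != frame.shape[:2]:
        raise ValueError(f"mask shape {mask.shape} incompatible with frame {frame.shape}")
    keep = mask >= 128
    if frame.ndim == 3:
        keep = keep[:, :, None]
    return np.where(keep, frame, 0).astype(np.uint8)


def big_generate(frame: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Full background-suppressed image generation for one frame.

    Composes :func:`difference_image`, :func:`otsu_threshold`,
    :func:`foreground_mask` and :func:`suppress_background`.  The background
    plate is computed once per static environment; this function runs per
    frame and recomputes the Otsu threshold on each frame's difference image.
    """
    diff = difference_image(frame, background)
    t = otsu_threshold(diff)
    mask = foreground_mask(diff, t)
    return suppress_background(frame, mask)
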