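"""Junction mask construction from the reference channel.

All intensity quantification downstream is restricted to mask-true
("relevant") junctional pixels. The source data behind this pipeline
are thin z-stacks masked in 3D; here images are single apical
projections, so the mask is 2D — the correspondence is one projection
plane instead of a stack.
"""
from __future__ import annotations

import logging
from typing import Optional

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

from .datatypes import DiscImage, JunctionMask

logger = logging.getLogger(__name__)

__all__ = ["build_mask", "apply_mask"]

#: connected components below this size are treated as noise speckle
DEFAULT_MIN_OBJECT_PX = 5


def build_mask(
    image: DiscImage,
    method: str = "otsu",
    param: Optional[float] = None,
    min_object_px: int = DEFAULT_MIN_OBJECT_PX,
) -> JunctionMask:
    """Threshold the reference channel into a junction mask.

    Parameters
    ----------
    method
        ``"otsu"`` (parameter-free, default), ``"percentile"`` (keep
        pixels above the ``param``-th intensity percentile) or
        ``"fixed"`` (keep pixels ``>= param``).
    min_object_px
        Connected components smaller than this are removed; pass 0 to
        disable.

    Raises
    ------
    ValueError
        If the reference channel has zero variance (mask undefined) or
        the mask is empty after thresholding/filtering.
    """
    ref = image.reference
    if np.ptp(ref) == 0:
        raise ValueError("mask undefined: reference channel is uniform")

    if method == "otsu":
        if param is not None:
            raise ValueError("otsu takes no parameter")
        threshold = float(threshold_otsu(ref))
        mask = ref > threshold
    elif method == "percentile":
        if param is None or not 0 < param < 100:
            raise ValueError("percentile method needs param in (0, 100)")
        threshold = float(np.percentile(ref, param))
        mask = ref > threshold
    elif method == "fixed":
        if param is None or param < 0:
            raise ValueError("fixed method needs param >= 0")
        threshold = float(param)
        mask = ref >= threshold
    else:
        raise ValueError(f"unknown mask method {method!r}")

    if min_object_px > 0:
        try:
            # skimage >= 0.26: max_size removes components <= its value
            mask = remove_small_objects(mask, max_size=min_object_px - 1)
        except TypeError:  # pragma: no cover - older scikit-image
            mask = remove_small_objects(mask, min_size=min_object_px)
    if not mask.any():
        raise ValueError(
            f"empty junction mask (method={method}, threshold={threshold:g})"
        )
    return JunctionMask(mask=mask, method=method, threshold_value=threshold)


def apply_mask(image: DiscImage, mask: JunctionMask, channel: str) -> np.ndarray:
    """Values of one channel at mask-true pixels (1D array)."""
    if channel not in image.channels:
        raise ValueError(f"unknown channel {channel!r}; have {sorted(image.channels)}")
    if mask.mask.shape != image.shape:
        raise ValueError("mask shape does not match image")
    values = image.channels[channel][mask.mask]
    if values.size == 0:
        logger.warning("apply_mask: mask selects 0 pixels on channel %r", channel)
    return values
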