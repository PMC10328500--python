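"""Pearson colocalization between two channels over the junction mask."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .datatypes import DiscImage, JunctionMask

__all__ = ["ColocResult", "pearson_coloc"]


@dataclass
class ColocResult:
    pearson_r: float
    n_pixels: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.pearson_r <= 1.0:
            raise ValueError("pearson_r must lie in [-1, 1]")
        if self.n_pixels < 2:
            raise ValueError("need at least 2 pixels")


def pearson_coloc(
    image: DiscImage,
    mask: JunctionMask,
    channel_a: str,
    channel_b: str,
    full_frame: bool = False,
) -> ColocResult:
    """Pearson correlation of two channels over mask-true pixels.

    ``full_frame=True`` correlates over every pixel instead of the
    junction mask. Raises when fewer than 2 pixels are selected or a
    channel has zero variance over the selection (correlation
    undefined).
    """
    for ch in (channel_a, channel_b):
        if ch not in image.channels:
            raise ValueError(f"unknown channel {ch!r}")
    sel = np.ones(image.shape, dtype=bool) if full_frame else mask.mask
    a = image.channels[channel_a][sel].ravel()
    b = image.channels[channel_b][sel].ravel()
    if a.size < 2:
        raise ValueError("need at least 2 masked pixels")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined: zero variance over the mask")
    if np.array_equal(a, b):
        r = 1.0  # exact by contract, immune to rounding
    else:
        r = float(sps.pearsonr(a, b).statistic)
    return ColocResult(pearson_r=float(np.clip(r, -1.0, 1.0)), n_pixels=int(a.size))
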