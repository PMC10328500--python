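"""Center-anchored block intensity maps and the posterior/anterior ratio.

The image is split into square blocks of a fixed physical size
(default 3x3 um^2) on a grid anchored at the manually picked disc
center, so the block lattice has a corner at the center pixel and the
four center-adjacent blocks sit symmetrically about it. Per block, the
mean masked-pixel intensity is taken; blocks with no masked pixels are
missing (NaN), never zero, because zeros would bias compartment means.
Maps from several discs are aligned on their center block and averaged
under a minimum-count rule; each disc's posterior/anterior ratio is the
mean over posterior blocks divided by the mean over anterior blocks.

Grid coordinates: block edges sit at ``floor(center + k * block_px)``
for integer k; only blocks fully inside the image are kept (partial
edge blocks are dropped, not rescaled). ``center_index`` names the
block immediately up-and-left of the anchor.
"""
from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np

from .datatypes import (
    ANTERIOR,
    EXCLUDED,
    POSTERIOR,
    CompartmentSplit,
    DiscAnnotation,
    DiscImage,
    HeatMap,
    JunctionMask,
    PARatio,
)

logger = logging.getLogger(__name__)

__all__ = [
    "block_quantify",
    "normalize",
    "average_discs",
    "split_compartments",
    "pa_ratio",
    "DEFAULT_BLOCK_UM",
    "DEFAULT_MIN_COUNT",
]

DEFAULT_BLOCK_UM = 3.0
DEFAULT_MIN_COUNT = 3


def _axis_edges(center: int, size: int, block_px: float) -> tuple[np.ndarray, int]:
    """Block edges along one axis; returns (edges, index of the k=-1 edge).

    Edges are ``floor(center + k * block_px)`` clipped to [0, size];
    only full blocks between consecutive in-bounds edges survive.
    """
    k_lo = -int(np.floor(center / block_px)) - 1
    k_hi = int(np.floor((size - center) / block_px)) + 1
    ks = np.arange(k_lo, k_hi + 1)
    edges = np.floor(center + ks * block_px).astype(int)
    keep = (edges >= 0) & (edges <= size)
    edges, ks = edges[keep], ks[keep]
    if len(edges) < 2:
        raise ValueError("no complete block fits between center and image border")
    anchor_pos = np.nonzero(ks == -1)[0]
    if len(anchor_pos) == 0:
        raise ValueError("center too close to the image border for a center block")
    return edges, int(anchor_pos[0])


def block_quantify(
    image: DiscImage,
    mask: JunctionMask,
    annotation: DiscAnnotation,
    channel: str,
) -> HeatMap:
    """Mean masked intensity of one channel per grid block.

    Raises if the block size is under one pixel, the center lies outside
    the image, or the mask is empty.
    """
    if channel not in image.channels:
        raise ValueError(f"unknown channel {channel!r}")
    h, w = image.shape
    r0, c0 = annotation.center_px
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise ValueError("center_px outside image bounds")
    block_px = annotation.block_size_um / image.pixel_size_um
    if block_px < 1:
        raise ValueError("block size is smaller than one pixel")
    if not mask.mask.any():
        raise ValueError("junction mask is empty")
    if mask.mask.shape != image.shape:
        raise ValueError("mask shape does not match image")

    row_edges, ci_r = _axis_edges(r0, h, block_px)
    col_edges, ci_c = _axis_edges(c0, w, block_px)
    nr, nc = len(row_edges) - 1, len(col_edges) - 1

    ch = image.channels[channel]
    values = np.full((nr, nc), np.nan)
    counts = np.zeros((nr, nc), dtype=int)
    m = mask.mask
    for i in range(nr):
        rs, re = row_edges[i], row_edges[i + 1]
        for j in range(nc):
            cs, ce = col_edges[j], col_edges[j + 1]
            sub = ch[rs:re, cs:ce][m[rs:re, cs:ce]]
            counts[i, j] = sub.size
            if sub.size:
                values[i, j] = sub.mean()

    return HeatMap(
        values=values,
        counts=counts,
        center_index=(ci_r, ci_c),
        block_size_um=annotation.block_size_um,
        normalization="none",
        row_edges=row_edges,
        col_edges=col_edges,
    )


def _check_congruent(a: HeatMap, b: HeatMap) -> None:
    if a.shape != b.shape or a.center_index != b.center_index:
        raise ValueError("heat maps are not on the same grid")
    if a.block_size_um != b.block_size_um:
        raise ValueError("heat maps differ in block size")


def normalize(hm_signal: HeatMap, hm_reference: HeatMap, mode: str = "ratio_to_reference") -> HeatMap:
    """Normalize a signal map by its own mean and (optionally) a reference.

    ``ratio_to_reference``: signal and reference maps are each divided
    by their own mean over non-missing blocks, then the elementwise
    signal/reference ratio is taken. ``self_mean``: the signal map is
    divided by its own mean only, so non-missing output blocks average
    to 1. Missing blocks propagate; blocks where the reference is zero
    become missing (counted in the log).
    """
    if mode not in ("ratio_to_reference", "self_mean"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    _check_congruent(hm_signal, hm_reference)

    sig = hm_signal.values / np.nanmean(hm_signal.values)
    if mode == "self_mean":
        out = sig
        counts = hm_signal.counts.copy()
    else:
        ref = hm_reference.values / np.nanmean(hm_reference.values)
        zero_ref = hm_reference.values == 0
        n_zero = int(np.count_nonzero(zero_ref & ~np.isnan(hm_signal.values)))
        if n_zero:
            logger.warning("normalize: %d blocks dropped (reference block is 0)", n_zero)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = sig / ref
        out = np.where(zero_ref, np.nan, out)
        counts = np.where(np.isnan(out), 0, hm_signal.counts)

    counts = np.where(np.isnan(out), 0, counts)
    return HeatMap(
        values=out,
        counts=counts,
        center_index=hm_signal.center_index,
        block_size_um=hm_signal.block_size_um,
        normalization=mode,
        row_edges=hm_signal.row_edges,
        col_edges=hm_signal.col_edges,
    )


def average_discs(maps: Sequence[HeatMap], min_count: int = DEFAULT_MIN_COUNT) -> HeatMap:
    """Average heat maps from several discs, aligned on the center block.

    Smaller maps are padded with missing values to the largest extent on
    each side of the center. A block keeps a value only when at least
    ``min_count`` discs contribute a non-missing value there; output
    ``counts`` record contributing discs per block.
    """
    if not maps:
        raise ValueError("no heat maps to average")
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    block = maps[0].block_size_um
    norm = maps[0].normalization
    for hm in maps[1:]:
        if hm.block_size_um != block:
            raise ValueError("heat maps differ in block size")
        if hm.normalization != norm:
            raise ValueError("heat maps differ in normalization mode")

    up = max(hm.center_index[0] for hm in maps)
    left = max(hm.center_index[1] for hm in maps)
    down = max(hm.shape[0] - hm.center_index[0] for hm in maps)
    right = max(hm.shape[1] - hm.center_index[1] for hm in maps)
    nr, nc = up + down, left + right

    stack = np.full((len(maps), nr, nc), np.nan)
    for k, hm in enumerate(maps):
        r_off = up - hm.center_index[0]
        c_off = left - hm.center_index[1]
        stack[k, r_off:r_off + hm.shape[0], c_off:c_off + hm.shape[1]] = hm.values

    counts = np.sum(~np.isnan(stack), axis=0).astype(int)
    sums = np.nansum(stack, axis=0)
    values = np.where(counts >= min_count, sums / np.maximum(counts, 1), np.nan)
    counts = np.where(counts >= min_count, counts, 0)
    return HeatMap(
        values=values,
        counts=counts,
        center_index=(up, left),
        block_size_um=block,
        normalization=norm,
    )


def split_compartments(
    hm: HeatMap,
    annotation: DiscAnnotation,
    compartment_map: Optional[np.ndarray] = None,
    mask: Optional[JunctionMask] = None,
) -> CompartmentSplit:
    """Label each block anterior, posterior or excluded.

    Geometric rule (default): blocks strictly on the posterior side of
    the center line are posterior, strictly on the other side anterior;
    the block row/column holding the center line is excluded. With a
    per-pixel ``compartment_map`` (True/nonzero = posterior) blocks are
    labeled by the majority of their masked pixels instead — the center
    row/column stays excluded so both routes agree on boundary blocks.
    """
    nr, nc = hm.shape
    ci_r, ci_c = hm.center_index
    side = annotation.posterior_side
    labels = np.full((nr, nc), EXCLUDED, dtype=np.int8)

    if compartment_map is None:
        rows = np.arange(nr)[:, None]
        cols = np.arange(nc)[None, :]
        if side == "right":
            labels[np.broadcast_to(cols > ci_c, (nr, nc))] = POSTERIOR
            labels[np.broadcast_to(cols < ci_c, (nr, nc))] = ANTERIOR
        elif side == "left":
            labels[np.broadcast_to(cols < ci_c, (nr, nc))] = POSTERIOR
            labels[np.broadcast_to(cols > ci_c, (nr, nc))] = ANTERIOR
        elif side == "down":
            labels[np.broadcast_to(rows > ci_r, (nr, nc))] = POSTERIOR
            labels[np.broadcast_to(rows < ci_r, (nr, nc))] = ANTERIOR
        else:  # up
            labels[np.broadcast_to(rows < ci_r, (nr, nc))] = POSTERIOR
            labels[np.broadcast_to(rows > ci_r, (nr, nc))] = ANTERIOR
        return CompartmentSplit(labels=labels)

    if hm.row_edges is None or hm.col_edges is None:
        raise ValueError("marker-based split requires a single-disc map with grid edges")
    cmap = np.asarray(compartment_map) != 0
    pix_sel = mask.mask if mask is not None else np.ones(cmap.shape, dtype=bool)
    re_, ce_ = hm.row_edges, hm.col_edges
    for i in range(nr):
        for j in range(nc):
            blk_sel = pix_sel[re_[i]:re_[i + 1], ce_[j]:ce_[j + 1]]
            blk_all = cmap[re_[i]:re_[i + 1], ce_[j]:ce_[j + 1]]
            blk_cmap = blk_all[blk_sel]
            if blk_cmap.size == 0:
                # no masked pixels (block is missing anyway): all-pixel majority
                blk_cmap = blk_all.ravel()
            labels[i, j] = POSTERIOR if blk_cmap.mean() > 0.5 else ANTERIOR
    # keep the center line's row/column excluded, matching the geometric rule
    if side in ("left", "right"):
        labels[:, ci_c] = EXCLUDED
    else:
        labels[ci_r, :] = EXCLUDED
    return CompartmentSplit(labels=labels)


def pa_ratio(hm: HeatMap, split: CompartmentSplit) -> PARatio:
    """Posterior over anterior mean of non-missing blocks."""
    if split.labels.shape != hm.shape:
        raise ValueError("split shape does not match heat map")
    post = hm.values[split.posterior]
    ant = hm.values[split.anterior]
    post = post[~np.isnan(post)]
    ant = ant[~np.isnan(ant)]
    if post.size == 0 or ant.size == 0:
        raise ValueError("a compartment has no non-missing blocks")
    return PARatio(
        value=float(post.mean() / ant.mean()),
        n_posterior_blocks=int(post.size),
        n_anterior_blocks=int(ant.size),
    )
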