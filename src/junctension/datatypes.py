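"""Shared domain types for the junctension pipeline.

All image coordinates are 0-based, row-major, origin at the top-left
pixel. Physical sizes are micrometres; intensities are arbitrary units.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "DiscImage",
    "JunctionMask",
    "HeatMap",
    "CompartmentSplit",
    "PARatio",
    "RecoilTrace",
    "RecoilVelocity",
    "GelLaneProfile",
    "BindingSeries",
    "BindingFit",
    "ANTERIOR",
    "POSTERIOR",
    "EXCLUDED",
]

#: Block labels used by :class:`CompartmentSplit`.
EXCLUDED = 0
ANTERIOR = 1
POSTERIOR = 2

_SIDES = ("left", "right", "up", "down")


@dataclass
class DiscImage:
    """Registered multi-channel apical-projection image.

    Parameters
    ----------
    channels
        Mapping of channel name to 2D nonnegative float array. All
        channels must share one shape.
    pixel_size_um
        Physical pixel size (µm per pixel), isotropic.
    roles
        Mapping of channel name to role, one of ``"reference"``,
        ``"signal"``, ``"marker"``. Exactly one reference channel is
        required; the reference is the junctional channel (E-cadherin
        equivalent) used to build the quantification mask.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    roles: dict[str, str]

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("DiscImage requires at least one channel")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels differ in shape: {shapes}")
        shape = shapes.pop()
        if len(shape) != 2:
            raise ValueError("channels must be 2D arrays")
        for name, arr in self.channels.items():
            if np.any(np.asarray(arr) < 0):
                raise ValueError(f"channel {name!r} has negative intensities")
        refs = [n for n, r in self.roles.items() if r == "reference"]
        if len(refs) != 1:
            raise ValueError("exactly one channel must have role 'reference'")
        for name in self.roles:
            if name not in self.channels:
                raise ValueError(f"role given for unknown channel {name!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def reference_name(self) -> str:
        return next(n for n, r in self.roles.items() if r == "reference")

    @property
    def reference(self) -> np.ndarray:
        return self.channels[self.reference_name]

    @property
    def signal_names(self) -> list[str]:
        return [n for n, r in self.roles.items() if r == "signal"]

    @property
    def marker_name(self) -> Optional[str]:
        for n, r in self.roles.items():
            if r == "marker":
                return n
        return None


@dataclass
class JunctionMask:
    """Binary mask selecting the junctional pixels of a disc image."""

    mask: np.ndarray
    method: str
    threshold_value: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")
        if self.method not in ("otsu", "percentile", "fixed"):
            raise ValueError(f"unknown mask method {self.method!r}")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class DiscAnnotation:
    """Per-image manual annotation.

    ``center_px`` is the (row, col) of the anatomical disc center — the
    intersection of the compartment boundaries — and anchors the block
    grid. ``posterior_side`` names the side of the center holding the
    posterior compartment.
    """

    center_px: tuple[int, int]
    posterior_side: str = "right"
    block_size_um: float = 3.0

    def __post_init__(self) -> None:
        if self.posterior_side not in _SIDES:
            raise ValueError(f"posterior_side must be one of {_SIDES}")
        if self.block_size_um <= 0:
            raise ValueError("block_size_um must be positive")
        r, c = self.center_px
        if r < 0 or c < 0:
            raise ValueError("center_px must be nonnegative")


@dataclass
class HeatMap:
    """Center-anchored matrix of per-block values.

    ``values`` holds block means with NaN marking missing blocks;
    ``counts`` records contributing pixels (single disc) or discs
    (cohort average) per block. ``center_index`` is the (row, col) of
    the block immediately up-and-left of the anchoring center pixel.
    ``row_edges``/``col_edges`` keep the pixel lattice of the block grid
    for single-disc maps; they are dropped (None) by cohort averaging.
    """

    values: np.ndarray
    counts: np.ndarray
    center_index: tuple[int, int]
    block_size_um: float
    normalization: str = "none"
    row_edges: Optional[np.ndarray] = field(default=None, repr=False)
    col_edges: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.values.shape != self.counts.shape:
            raise ValueError("values and counts must be congruent")
        if self.values.ndim != 2:
            raise ValueError("heat map must be 2D")
        if self.normalization not in ("none", "ratio_to_reference", "self_mean"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        r, c = self.center_index
        nr, nc = self.values.shape
        if not (0 <= r < nr and 0 <= c < nc):
            raise ValueError("center_index outside matrix bounds")
        if np.any(~np.isnan(self.values[self.counts == 0])):
            raise ValueError("blocks with count 0 must be missing-valued")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def missing(self) -> np.ndarray:
        return np.isnan(self.values)


@dataclass
class CompartmentSplit:
    """Per-block assignment to anterior/posterior (or excluded)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        valid = {EXCLUDED, ANTERIOR, POSTERIOR}
        if not set(np.unique(self.labels)).issubset(valid):
            raise ValueError("labels must be EXCLUDED/ANTERIOR/POSTERIOR")

    @property
    def anterior(self) -> np.ndarray:
        return self.labels == ANTERIOR

    @property
    def posterior(self) -> np.ndarray:
        return self.labels == POSTERIOR


@dataclass
class PARatio:
    """Posterior over anterior mean block-intensity ratio for one map."""

    value: float
    n_posterior_blocks: int
    n_anterior_blocks: int

    def __post_init__(self) -> None:
        if self.n_posterior_blocks <= 0 or self.n_anterior_blocks <= 0:
            raise ValueError("both compartments must contribute blocks")


@dataclass
class RecoilTrace:
    """Vertex separation versus time after a junction cut at t = 0."""

    t_s: np.ndarray
    separation_um: np.ndarray
    side: str = "anterior"
    disc_id: str = ""

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.separation_um = np.asarray(self.separation_um, dtype=float)
        if self.t_s.shape != self.separation_um.shape or self.t_s.ndim != 1:
            raise ValueError("t_s and separation_um must be equal-length 1D")
        if len(self.t_s) and self.t_s[0] != 0:
            raise ValueError("traces must start at t = 0 (the cut)")
        if np.any(np.diff(self.t_s) <= 0):
            raise ValueError("t_s must be strictly increasing")
        if np.any(self.separation_um < 0):
            raise ValueError("separations must be nonnegative")
        if self.side not in ("anterior", "posterior"):
            raise ValueError("side must be 'anterior' or 'posterior'")

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0])


@dataclass
class RecoilVelocity:
    v_um_per_s: float
    window_s: float = 1.0
    method: str = "endpoint"
    side: str = "anterior"
    disc_id: str = ""

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if self.method not in ("endpoint", "linear_fit"):
            raise ValueError("method must be 'endpoint' or 'linear_fit'")


@dataclass
class GelLaneProfile:
    """1D densitometry profile of one gel lane.

    ``band_windows`` maps ``"supernatant"``/``"pellet"`` to half-open
    position intervals; when absent the two dominant peaks are detected
    at quantification time.
    """

    position_px: np.ndarray
    intensity: np.ndarray
    band_windows: Optional[dict[str, tuple[float, float]]] = None
    titrant_uM: Optional[float] = None

    def __post_init__(self) -> None:
        self.position_px = np.asarray(self.position_px, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.position_px.shape != self.intensity.shape:
            raise ValueError("position and intensity must be equal length")
        if np.any(np.diff(self.position_px) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be nonnegative")


@dataclass
class BindingSeries:
    """Titrant concentration versus fraction of a protein in the pellet."""

    titrant_uM: np.ndarray
    fraction_bound: np.ndarray
    protein: str = "ligand"

    def __post_init__(self) -> None:
        self.titrant_uM = np.asarray(self.titrant_uM, dtype=float)
        self.fraction_bound = np.asarray(self.fraction_bound, dtype=float)
        if self.titrant_uM.shape != self.fraction_bound.shape:
            raise ValueError("titrant and fraction arrays must match")
        if np.any(self.titrant_uM < 0):
            raise ValueError("concentrations must be nonnegative")
        if np.any((self.fraction_bound < -1e-12) | (self.fraction_bound > 1 + 1e-12)):
            raise ValueError("fractions must lie in [0, 1]")


@dataclass
class BindingFit:
    """Result of fitting the ligand-depletion binding model."""

    kd_uM: float
    sites_uM: float
    rss: float
    kd_at_bound: bool = False

    def __post_init__(self) -> None:
        if self.kd_uM <= 0 or self.sites_uM <= 0:
            raise ValueError("kd_uM and sites_uM must be positive")
        if self.rss < 0:
            raise ValueError("rss must be nonnegative")
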