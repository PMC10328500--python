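"""Ground-truthed synthetic inputs for the quantification pipeline.

Three generators, all deterministic given their seed:

* :func:`generate_disc` — two-compartment epithelial junction images
  (Voronoi tessellation, junctional reference + signal channels, known
  posterior fold-change).
* :func:`generate_recoil_trace` — post-cut vertex separation with
  saturating-exponential kinetics.
* :func:`generate_gel` — supernatant/pellet lane profiles whose band
  areas follow a mass-action equilibrium binding model.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from skimage.morphology import binary_dilation, disk
from skimage.segmentation import find_boundaries

from .binding import solve_competition, solve_equilibrium
from .datatypes import BindingSeries, DiscImage, GelLaneProfile, RecoilTrace

logger = logging.getLogger(__name__)

__all__ = [
    "SynthDiscParams",
    "SynthDisc",
    "SynthRecoilParams",
    "SynthGelParams",
    "generate_disc",
    "generate_recoil_trace",
    "generate_gel",
]


@dataclass(frozen=True)
class SynthDiscParams:
    """Parameters of the two-compartment disc image generator.

    ``posterior_multiplier`` is the true fold-change of the signal
    channel on posterior junctions relative to anterior junctions — the
    quantity the downstream P/A ratio estimates. Gaussian noise has a
    per-pixel SD of ``noise_sd_frac`` times the noiseless pixel value,
    truncated at zero (cameras report nonnegative counts).
    """

    image_size_px: tuple[int, int] = (200, 200)
    pixel_size_um: float = 0.5
    n_cells: int = 60
    junction_width_px: int = 2
    ref_level: float = 100.0
    signal_level: float = 80.0
    posterior_multiplier: float = 1.0
    noise_sd_frac: float = 0.0
    background_level: float = 0.0
    posterior_side: str = "right"
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size_px
        if h < 8 or w < 8:
            raise ValueError("image must be at least 8x8 px")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_cells < 4:
            raise ValueError("n_cells must be >= 4 so both compartments hold junctions")
        if self.junction_width_px < 1:
            raise ValueError("junction_width_px must be >= 1")
        if self.ref_level <= 0 or self.signal_level <= 0:
            raise ValueError("channel levels must be positive")
        if self.posterior_multiplier <= 0:
            raise ValueError("posterior_multiplier must be positive")
        if not 0 <= self.noise_sd_frac < 1:
            raise ValueError("noise_sd_frac must be in [0, 1)")
        if self.background_level < 0:
            raise ValueError("background_level must be nonnegative")
        if self.posterior_side not in ("left", "right", "up", "down"):
            raise ValueError("invalid posterior_side")


@dataclass
class SynthDisc:
    """A synthetic disc image plus its generation ground truth."""

    image: DiscImage
    center_px: tuple[int, int]
    posterior_axis: str
    compartment_map: np.ndarray  # bool, True = posterior
    truth_pa_ratio: float
    junction_px: np.ndarray = field(repr=False, default=None)  # bool skeleton dilation

    def __post_init__(self) -> None:
        self.compartment_map = np.asarray(self.compartment_map, dtype=bool)
        if self.compartment_map.shape != self.image.shape:
            raise ValueError("compartment_map shape must match image")
        if self.truth_pa_ratio <= 0:
            raise ValueError("truth_pa_ratio must be positive")


def _voronoi_labels(shape: tuple[int, int], points: np.ndarray) -> np.ndarray:
    """Nearest-seed label image (an implicit Voronoi tessellation)."""
    h, w = shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    grid = np.column_stack([rr.ravel(), cc.ravel()])
    _, lab = cKDTree(points).query(grid)
    return lab.reshape(shape)


def _lloyd_step(labels: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Move each seed to the centroid of its Voronoi region (one step)."""
    new = points.copy()
    for i in range(len(points)):
        sel = labels == i
        if sel.any():
            rr, cc = np.nonzero(sel)
            new[i] = (rr.mean(), cc.mean())
    return new


def generate_disc(params: SynthDiscParams) -> SynthDisc:
    """Generate a two-compartment junctional disc image.

    Seed points are drawn uniformly, relaxed by one Lloyd iteration
    (avoids sliver cells), and turned into a junction skeleton at the
    boundaries between Voronoi regions, dilated to roughly
    ``junction_width_px``. The reference channel carries ``ref_level``
    on junctions; the signal channel carries ``signal_level`` on
    anterior junctions and ``signal_level * posterior_multiplier`` on
    posterior junctions. Off-junction pixels sit at
    ``background_level``. The straight compartment boundary passes
    through the image center.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size_px
    shape = (h, w)

    junctions = None
    for attempt in range(5):
        pts = rng.uniform((0, 0), (h - 1, w - 1), size=(params.n_cells, 2))
        labels = _voronoi_labels(shape, pts)
        pts = _lloyd_step(labels, pts)
        labels = _voronoi_labels(shape, pts)
        cand = find_boundaries(labels, mode="thick")
        if cand.any():
            junctions = cand
            break
        logger.warning("degenerate tessellation on attempt %d; regenerating with perturbed seeds", attempt + 1)
    if junctions is None:  # pragma: no cover - requires pathological params
        raise RuntimeError("could not generate a non-degenerate tessellation")

    # 'thick' boundaries are ~2 px wide; widen further if requested
    extra = (params.junction_width_px - 2 + 1) // 2
    if extra > 0:
        junctions = binary_dilation(junctions, disk(extra))

    center = (h // 2, w // 2)
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    side = params.posterior_side
    if side == "right":
        posterior = cc >= center[1]
    elif side == "left":
        posterior = cc < center[1]
    elif side == "down":
        posterior = rr >= center[0]
    else:
        posterior = rr < center[0]

    ref = np.where(junctions, params.ref_level, params.background_level).astype(float)
    sig_level = np.where(posterior, params.signal_level * params.posterior_multiplier, params.signal_level)
    sig = np.where(junctions, sig_level, params.background_level).astype(float)

    if params.noise_sd_frac > 0:
        ref = ref + rng.standard_normal(shape) * (params.noise_sd_frac * ref)
        sig = sig + rng.standard_normal(shape) * (params.noise_sd_frac * sig)
    ref = np.clip(ref, 0, None)
    sig = np.clip(sig, 0, None)

    image = DiscImage(
        channels={"ecad": ref, "signal": sig},
        pixel_size_um=params.pixel_size_um,
        roles={"ecad": "reference", "signal": "signal"},
    )
    return SynthDisc(
        image=image,
        center_px=center,
        posterior_axis=side,
        compartment_map=posterior,
        truth_pa_ratio=params.posterior_multiplier,
        junction_px=junctions,
    )


@dataclass(frozen=True)
class SynthRecoilParams:
    """Saturating-exponential recoil trace parameters.

    separation(t) = baseline + amplitude * (1 - exp(-t / tau)) + noise.
    """

    amplitude_um: float = 2.0
    tau_s: float = 0.5
    noise_sd_um: float = 0.0
    frame_interval_s: float = 0.2
    duration_s: float = 4.0
    baseline_um: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_um < 0:
            raise ValueError("amplitude_um must be nonnegative")
        if self.tau_s <= 0:
            raise ValueError("tau_s must be positive")
        if self.noise_sd_um < 0:
            raise ValueError("noise_sd_um must be nonnegative")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.frame_interval_s > self.duration_s:
            raise ValueError("frame_interval_s must not exceed duration_s")
        if self.baseline_um <= 0:
            raise ValueError("baseline_um must be positive")


def generate_recoil_trace(
    params: SynthRecoilParams, side: str = "anterior", disc_id: str = ""
) -> RecoilTrace:
    """Sample a noisy saturating-exponential recoil trace from t = 0."""
    rng = np.random.default_rng(params.seed)
    n = int(np.floor(params.duration_s / params.frame_interval_s + 1e-9)) + 1
    t = np.arange(n) * params.frame_interval_s
    sep = params.baseline_um + params.amplitude_um * (1.0 - np.exp(-t / params.tau_s))
    if params.noise_sd_um > 0:
        sep = sep + rng.normal(0.0, params.noise_sd_um, size=n)
    sep = np.clip(sep, 0, None)
    return RecoilTrace(t_s=t, separation_um=sep, side=side, disc_id=disc_id)


@dataclass(frozen=True)
class SynthGelParams:
    """Co-sedimentation lane generator parameters.

    ``ligand_concs_uM`` is the titration of the protein whose bands are
    drawn; ``site_conc_uM`` the F-actin binding-site concentration.
    Noise is multiplicative log-normal (densitometry-like) with
    log-scale SD ``noise_sd_frac``.
    """

    site_conc_uM: float = 2.0
    kd_uM: float = 5.0
    ligand_concs_uM: tuple[float, ...] = (0.375, 0.75, 1.5, 3.0, 6.0, 9.0, 12.0)
    band_sd_px: float = 6.0
    lane_length_px: int = 200
    noise_sd_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.site_conc_uM <= 0 or self.kd_uM <= 0:
            raise ValueError("site_conc_uM and kd_uM must be positive")
        concs = np.asarray(self.ligand_concs_uM, dtype=float)
        if np.any(concs < 0) or np.any(np.diff(concs) < 0):
            raise ValueError("ligand_concs_uM must be nonnegative and nondecreasing")
        if self.band_sd_px <= 0:
            raise ValueError("band_sd_px must be positive")
        if self.lane_length_px < 20:
            raise ValueError("lane_length_px must be >= 20")
        if self.noise_sd_frac < 0:
            raise ValueError("noise_sd_frac must be nonnegative")


def _band(positions: np.ndarray, center: float, sd: float) -> np.ndarray:
    """Discrete Gaussian band normalized to unit pixel sum."""
    g = np.exp(-0.5 * ((positions - center) / sd) ** 2)
    return g / g.sum()


def generate_gel(
    params: SynthGelParams,
    competitor_concs_uM: Optional[Sequence[float]] = None,
    competitor_kd_uM: Optional[float] = None,
) -> tuple[list[GelLaneProfile], BindingSeries]:
    """Generate supernatant/pellet lane profiles plus the truth series.

    For each titration point the bound fraction of the ligand of
    interest comes from the single-site depletion model
    (:func:`~junctension.binding.solve_equilibrium`) or, when a
    competitor titration is supplied, from the shared-site competition
    model (:func:`~junctension.binding.solve_competition`). Each lane
    holds two Gaussian bands: supernatant area proportional to free
    ligand, pellet area to bound ligand. A lane with zero total ligand
    is all-zero and its truth fraction is recorded as 0.

    The truth :class:`BindingSeries` uses the competitor concentration
    as titrant when a competitor is present, the ligand concentration
    otherwise.
    """
    if (competitor_concs_uM is None) != (competitor_kd_uM is None):
        raise ValueError("competitor_concs_uM and competitor_kd_uM must be given together")
    concs = np.asarray(params.ligand_concs_uM, dtype=float)
    if competitor_concs_uM is not None:
        comp = np.asarray(competitor_concs_uM, dtype=float)
        if comp.shape != concs.shape:
            raise ValueError("competitor_concs_uM length must match ligand_concs_uM")
    else:
        comp = None

    rng = np.random.default_rng(params.seed)
    n_px = params.lane_length_px
    pos = np.arange(n_px, dtype=float)
    sup_center, pel_center = 0.25 * n_px, 0.75 * n_px
    g_sup = _band(pos, sup_center, params.band_sd_px)
    g_pel = _band(pos, pel_center, params.band_sd_px)
    mid = n_px / 2.0
    windows = {"supernatant": (0.0, mid), "pellet": (mid, float(n_px - 1))}

    lanes: list[GelLaneProfile] = []
    fractions = np.zeros_like(concs)
    for i, ligand_total in enumerate(concs):
        if comp is not None:
            bound, _ = solve_competition(
                ligand_total, params.kd_uM, comp[i], competitor_kd_uM, params.site_conc_uM
            )
        else:
            bound = solve_equilibrium(ligand_total, params.site_conc_uM, params.kd_uM)
        free = ligand_total - bound
        fractions[i] = bound / ligand_total if ligand_total > 0 else 0.0
        profile = free * g_sup + bound * g_pel
        if params.noise_sd_frac > 0:
            profile = profile * np.exp(rng.normal(0.0, params.noise_sd_frac, size=n_px))
        titrant = comp[i] if comp is not None else ligand_total
        lanes.append(
            GelLaneProfile(
                position_px=pos.copy(),
                intensity=profile,
                band_windows=dict(windows),
                titrant_uM=float(titrant),
            )
        )

    titrants = comp if comp is not None else concs
    truth = BindingSeries(titrant_uM=titrants, fraction_bound=fractions, protein="ligand")
    return lanes, truth
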