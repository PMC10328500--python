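"""File formats: multi-page TIFF images, JSON sidecars, CSV tables.

Disc images are written as one TIFF page per channel with channel
order, roles, pixel size and (for synthetic discs) the ground truth in
a JSON sidecar next to the image. Heat maps round-trip through a CSV
value matrix plus a JSON metadata record. Traces, lane profiles and
binding series are plain CSV.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .datatypes import (
    BindingSeries,
    DiscAnnotation,
    DiscImage,
    GelLaneProfile,
    HeatMap,
    JunctionMask,
    RecoilTrace,
)
from .synthetic import SynthDisc

__all__ = [
    "save_disc",
    "load_disc",
    "save_mask",
    "load_mask",
    "save_heatmap",
    "load_heatmap",
    "save_traces",
    "load_traces",
    "save_lanes",
    "load_lanes",
    "save_binding_series",
    "load_binding_series",
]


def save_disc(disc: SynthDisc, out_dir: str | Path, stem: str = "disc") -> tuple[Path, Path]:
    """Write a synthetic disc as TIFF + JSON truth sidecar.

    Pages: one per channel (order in the sidecar), then the compartment
    map and junction skeleton as uint8 pages. Downstream tests read
    truth from the sidecar, never from the images.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    img = disc.image
    names = list(img.channels)
    pages = [np.asarray(img.channels[n], dtype=np.float32) for n in names]
    pages.append(disc.compartment_map.astype(np.uint8))
    pages.append(disc.junction_px.astype(np.uint8))
    tif_path = out_dir / f"{stem}.tif"
    tifffile.imwrite(
        tif_path,
        np.stack([p.astype(np.float32) for p in pages]),
        photometric="minisblack",
    )
    sidecar = {
        "channels": names,
        "roles": img.roles,
        "pixel_size_um": img.pixel_size_um,
        "center_px": list(disc.center_px),
        "posterior_axis": disc.posterior_axis,
        "truth_pa_ratio": disc.truth_pa_ratio,
        "compartment_map_page": len(names),
        "junction_px_page": len(names) + 1,
    }
    json_path = out_dir / f"{stem}.json"
    json_path.write_text(json.dumps(sidecar, indent=2))
    return tif_path, json_path


def load_disc(tif_path: str | Path, sidecar_path: Optional[str | Path] = None) -> SynthDisc:
    """Read a disc TIFF and its JSON sidecar back into a SynthDisc."""
    tif_path = Path(tif_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else tif_path.with_suffix(".json")
    meta = json.loads(Path(sidecar_path).read_text())
    stack = tifffile.imread(tif_path)
    channels = {
        name: stack[i].astype(float) for i, name in enumerate(meta["channels"])
    }
    image = DiscImage(
        channels=channels,
        pixel_size_um=float(meta["pixel_size_um"]),
        roles=dict(meta["roles"]),
    )
    return SynthDisc(
        image=image,
        center_px=tuple(meta["center_px"]),
        posterior_axis=meta["posterior_axis"],
        compartment_map=stack[meta["compartment_map_page"]].astype(bool),
        truth_pa_ratio=float(meta["truth_pa_ratio"]),
        junction_px=stack[meta["junction_px_page"]].astype(bool),
    )


def annotation_from_sidecar(sidecar_path: str | Path, block_size_um: float = 3.0) -> DiscAnnotation:
    meta = json.loads(Path(sidecar_path).read_text())
    return DiscAnnotation(
        center_px=tuple(meta["center_px"]),
        posterior_side=meta["posterior_axis"],
        block_size_um=block_size_um,
    )


def save_mask(mask: JunctionMask, out_dir: str | Path, stem: str = "mask") -> tuple[Path, Path]:
    """Binary single-page TIFF plus a JSON record of method + threshold."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tif_path = out_dir / f"{stem}.tif"
    tifffile.imwrite(tif_path, mask.mask.astype(np.uint8))
    meta = {"method": mask.method, "threshold_value": mask.threshold_value}
    json_path = out_dir / f"{stem}.json"
    json_path.write_text(json.dumps(meta, indent=2))
    return tif_path, json_path


def load_mask(tif_path: str | Path, json_path: Optional[str | Path] = None) -> JunctionMask:
    tif_path = Path(tif_path)
    json_path = Path(json_path) if json_path else tif_path.with_suffix(".json")
    meta = json.loads(Path(json_path).read_text())
    return JunctionMask(
        mask=tifffile.imread(tif_path).astype(bool),
        method=meta["method"],
        threshold_value=float(meta["threshold_value"]),
    )


def save_heatmap(hm: HeatMap, out_dir: str | Path, stem: str = "heatmap") -> tuple[Path, Path]:
    """Heat map as a CSV value matrix plus a JSON metadata record."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{stem}.csv"
    np.savetxt(csv_path, hm.values, delimiter=",", fmt="%.17g")
    meta = {
        "center_index": list(hm.center_index),
        "block_size_um": hm.block_size_um,
        "normalization": hm.normalization,
        "counts": hm.counts.tolist(),
    }
    json_path = out_dir / f"{stem}.json"
    json_path.write_text(json.dumps(meta, indent=2))
    return csv_path, json_path


def load_heatmap(csv_path: str | Path, json_path: Optional[str | Path] = None) -> HeatMap:
    csv_path = Path(csv_path)
    json_path = Path(json_path) if json_path else csv_path.with_suffix(".json")
    meta = json.loads(Path(json_path).read_text())
    values = np.atleast_2d(np.loadtxt(csv_path, delimiter=","))
    return HeatMap(
        values=values,
        counts=np.asarray(meta["counts"], dtype=int),
        center_index=tuple(meta["center_index"]),
        block_size_um=float(meta["block_size_um"]),
        normalization=meta["normalization"],
    )


def save_traces(traces: list[RecoilTrace], path: str | Path) -> Path:
    path = Path(path)
    frames = [
        pd.DataFrame(
            {"t_s": tr.t_s, "separation_um": tr.separation_um,
             "side": tr.side, "disc_id": tr.disc_id or f"trace{i}"}
        )
        for i, tr in enumerate(traces)
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def load_traces(path: str | Path) -> list[RecoilTrace]:
    """Read traces from CSV with columns t_s, separation_um [,side, disc_id].

    Vertex-coordinate CSVs (t_s, x1, y1, x2, y2) are converted to
    separations on the fly.
    """
    df = pd.read_csv(path)
    if "separation_um" not in df.columns:
        from .recoil import separation_from_vertices

        df = df.copy()
        df["separation_um"] = separation_from_vertices(df)
    if "disc_id" not in df.columns:
        df["disc_id"] = "trace0"
    if "side" not in df.columns:
        df["side"] = "anterior"
    traces = []
    for disc_id, grp in df.groupby("disc_id", sort=False):
        traces.append(
            RecoilTrace(
                t_s=grp["t_s"].to_numpy(),
                separation_um=grp["separation_um"].to_numpy(),
                side=str(grp["side"].iloc[0]),
                disc_id=str(disc_id),
            )
        )
    return traces


def save_lanes(lanes: list[GelLaneProfile], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for i, lane in enumerate(lanes):
        wins = lane.band_windows or {}
        sup = wins.get("supernatant", (np.nan, np.nan))
        pel = wins.get("pellet", (np.nan, np.nan))
        rows.append(
            pd.DataFrame(
                {
                    "lane": i,
                    "titrant_uM": lane.titrant_uM,
                    "position_px": lane.position_px,
                    "intensity": lane.intensity,
                    "sup_lo": sup[0],
                    "sup_hi": sup[1],
                    "pel_lo": pel[0],
                    "pel_hi": pel[1],
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    return path


def load_lanes(path: str | Path) -> list[GelLaneProfile]:
    df = pd.read_csv(path)
    lanes = []
    for _, grp in df.groupby("lane", sort=True):
        first = grp.iloc[0]
        windows = None
        if np.isfinite(first.get("sup_lo", np.nan)):
            windows = {
                "supernatant": (float(first["sup_lo"]), float(first["sup_hi"])),
                "pellet": (float(first["pel_lo"]), float(first["pel_hi"])),
            }
        titrant = float(first["titrant_uM"]) if "titrant_uM" in grp.columns else None
        lanes.append(
            GelLaneProfile(
                position_px=grp["position_px"].to_numpy(),
                intensity=grp["intensity"].to_numpy(),
                band_windows=windows,
                titrant_uM=titrant,
            )
        )
    return lanes


def save_binding_series(series: BindingSeries, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"titrant_uM": series.titrant_uM, "fraction_bound": series.fraction_bound,
         "protein": series.protein}
    ).to_csv(path, index=False)
    return path


def load_binding_series(path: str | Path) -> BindingSeries:
    df = pd.read_csv(path)
    protein = str(df["protein"].iloc[0]) if "protein" in df.columns else "ligand"
    return BindingSeries(
        titrant_uM=df["titrant_uM"].to_numpy(),
        fraction_bound=df["fraction_bound"].to_numpy(),
        protein=protein,
    )
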