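"""Heat-map rendering: red (high) to blue (low), missing blocks neutral."""
from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .datatypes import HeatMap

__all__ = ["render_heatmap"]


def render_heatmap(
    hm: HeatMap,
    scale: tuple[float, float],
    out_path: str | Path,
    title: Optional[str] = None,
) -> Path:
    """Render a heat map to a PNG with an annotated color scale.

    Values at/below ``scale[0]`` map to the blue end, at/above
    ``scale[1]`` to the red end; missing blocks render light gray.
    Rendering never mutates the heat-map data.
    """
    low, high = scale
    if not (np.isfinite(low) and np.isfinite(high)) or not low < high:
        raise ValueError("scale must be finite with low < high")
    if np.all(np.isnan(hm.values)):
        raise ValueError("cannot render an empty heat map")

    cmap = plt.get_cmap("RdBu_r").copy()
    cmap.set_bad("0.85")
    data = np.ma.masked_invalid(hm.values)

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(data, cmap=cmap, vmin=low, vmax=high, interpolation="nearest")
    fig.colorbar(im, ax=ax, label=f"block intensity ({hm.normalization})")
    ax.plot(hm.center_index[1], hm.center_index[0], "k+", markersize=10)
    ax.set_xlabel(f"blocks ({hm.block_size_um:g} µm)")
    ax.set_ylabel(f"blocks ({hm.block_size_um:g} µm)")
    if title:
        ax.set_title(title)
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return out_path
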