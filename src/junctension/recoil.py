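"""Recoil velocity after junction ablation and anterior/posterior comparison.

The displacement of the cut junction's vertices over the first second
after ablation is the tension proxy: velocity = displacement within the
analysis window divided by elapsed time. Vertex tracking itself is out
of scope; input is the vertex-separation time series (a helper converts
paired vertex coordinates to Euclidean separation).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import RecoilTrace, RecoilVelocity

__all__ = ["recoil_velocity", "compare_sides", "separation_from_vertices", "SideComparison"]

#: analysis window (s) — the first second after the cut
DEFAULT_WINDOW_S = 1.0

_T_TOL = 1e-9


def recoil_velocity(
    trace: RecoilTrace, window_s: float = DEFAULT_WINDOW_S, method: str = "endpoint"
) -> RecoilVelocity:
    """Initial recoil velocity over the analysis window.

    ``endpoint`` (default): separation change between t = 0 and the
    last sample with t <= window, divided by that elapsed time (no
    interpolation). ``linear_fit``: least-squares slope over all
    samples in the window, a robustness check for noisy traces.
    """
    if trace.duration_s + _T_TOL < window_s:
        raise ValueError("trace shorter than the analysis window")
    in_win = trace.t_s <= window_s + _T_TOL
    t = trace.t_s[in_win]
    s = trace.separation_um[in_win]
    if t.size < 2:
        raise ValueError("fewer than 2 samples inside the window")
    if method == "endpoint":
        v = (s[-1] - s[0]) / (t[-1] - t[0])
    elif method == "linear_fit":
        v = float(np.polyfit(t, s, 1)[0])
    else:
        raise ValueError(f"unknown method {method!r}")
    return RecoilVelocity(
        v_um_per_s=float(v),
        window_s=window_s,
        method=method,
        side=trace.side,
        disc_id=trace.disc_id,
    )


def separation_from_vertices(frame: pd.DataFrame) -> np.ndarray:
    """Euclidean vertex separation from columns x1, y1, x2, y2 (µm)."""
    dx = frame["x2"].to_numpy() - frame["x1"].to_numpy()
    dy = frame["y2"].to_numpy() - frame["y1"].to_numpy()
    return np.hypot(dx, dy)


@dataclass
class SideComparison:
    """Anterior-versus-posterior recoil velocity comparison."""

    mean_anterior: float
    mean_posterior: float
    ci95_anterior: tuple[float, float]
    ci95_posterior: tuple[float, float]
    t_statistic: float
    p_value: float
    effect: float  # posterior mean / anterior mean
    n_anterior: int
    n_posterior: int


def _mean_ci(x: np.ndarray) -> tuple[float, tuple[float, float]]:
    m = float(x.mean())
    if x.size < 2:
        return m, (m, m)
    sem = x.std(ddof=1) / np.sqrt(x.size)
    half = float(sps.t.ppf(0.975, x.size - 1) * sem)
    return m, (m - half, m + half)


def compare_sides(velocities: Sequence[RecoilVelocity]) -> SideComparison:
    """Two-sided Student's t comparison of per-side velocities.

    Requires at least 2 velocities on each side. The effect size is the
    posterior/anterior ratio of mean velocities.
    """
    ant = np.array([v.v_um_per_s for v in velocities if v.side == "anterior"])
    post = np.array([v.v_um_per_s for v in velocities if v.side == "posterior"])
    if ant.size < 2 or post.size < 2:
        raise ValueError("need >= 2 velocities on each side")
    mean_a, ci_a = _mean_ci(ant)
    mean_p, ci_p = _mean_ci(post)
    if np.ptp(np.concatenate([ant, post])) == 0:
        t_stat, p = 0.0, 1.0  # identical data: no evidence of a difference
    else:
        res = sps.ttest_ind(post, ant, equal_var=True)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return SideComparison(
        mean_anterior=mean_a,
        mean_posterior=mean_p,
        ci95_anterior=ci_a,
        ci95_posterior=ci_p,
        t_statistic=t_stat,
        p_value=p,
        effect=mean_p / mean_a,
        n_anterior=int(ant.size),
        n_posterior=int(post.size),
    )
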