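"""Co-sedimentation quantification and equilibrium binding models.

Single-site mass action with ligand depletion (ligand and site
concentrations comparable, so free ligand cannot be approximated by
total ligand), plus a two-ligand shared-site competition solver, lane
densitometry quantification and binding-curve fitting.
"""
from __future__ import annotations

import numpy as np
from scipy.integrate import trapezoid
from scipy.optimize import brentq, least_squares, minimize_scalar
from scipy.signal import find_peaks

from .datatypes import BindingFit, BindingSeries, GelLaneProfile

__all__ = [
    "solve_equilibrium",
    "solve_competition",
    "quantify_lane",
    "fit_binding",
    "displacement_percent",
    "fraction_bound_model",
]

_KD_GRID_LO, _KD_GRID_HI = 1e-4, 1e4


def solve_equilibrium(ligand_total_uM, sites_total_uM, kd_uM):
    """Bound ligand at single-site equilibrium with ligand depletion.

    Solves ``bound^2 - (L + S + K) * bound + L * S = 0`` for the
    physical root ``0 <= bound <= min(L, S)``. Accepts scalars or
    arrays (broadcast).

    Uses the cancellation-free form
    ``bound = 2 L S / (p + sqrt(p^2 - 4 L S))`` with ``p = L + S + K``.
    """
    L = np.asarray(ligand_total_uM, dtype=float)
    S = np.asarray(sites_total_uM, dtype=float)
    K = np.asarray(kd_uM, dtype=float)
    if np.any(L < 0) or np.any(S < 0):
        raise ValueError("concentrations must be nonnegative")
    if np.any(K <= 0):
        raise ValueError("kd_uM must be positive")
    p = L + S + K
    disc = np.sqrt(np.maximum(p * p - 4.0 * L * S, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        bound = np.where(p + disc > 0, 2.0 * L * S / (p + disc), 0.0)
    bound = np.minimum(bound, np.minimum(L, S))
    if bound.ndim == 0:
        return float(bound)
    return bound


def solve_competition(
    ligA_total_uM: float,
    kdA_uM: float,
    ligB_total_uM: float,
    kdB_uM: float,
    sites_total_uM: float,
) -> tuple[float, float]:
    """Simultaneous equilibrium of two ligands sharing one site class.

    With free sites F, bound_X = X_total * F / (F + kd_X); F is the root
    of the monotone site-conservation equation
    ``F + boundA(F) + boundB(F) = S_total`` on [0, S_total], found by
    bracketed root finding. Returns (boundA_uM, boundB_uM).
    """
    A, B, S = float(ligA_total_uM), float(ligB_total_uM), float(sites_total_uM)
    kA, kB = float(kdA_uM), float(kdB_uM)
    if min(A, B, S) < 0:
        raise ValueError("concentrations must be nonnegative")
    if kA <= 0 or kB <= 0:
        raise ValueError("dissociation constants must be positive")
    if S == 0:
        return 0.0, 0.0

    def g(F: float) -> float:
        return F + A * F / (F + kA) + B * F / (F + kB) - S

    free = brentq(g, 0.0, S, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    residual = abs(g(free))
    if residual > 1e-9:  # pragma: no cover - brentq converges for this monotone g
        raise RuntimeError(f"competition solver did not converge (residual {residual:.3e})")
    boundA = A * free / (free + kA)
    boundB = B * free / (free + kB)
    return boundA, boundB


def _window_area(profile: GelLaneProfile, lo: float, hi: float) -> float:
    sel = (profile.position_px >= lo) & (profile.position_px <= hi)
    if sel.sum() < 2:
        raise ValueError("band window covers fewer than 2 samples")
    y = profile.intensity[sel]
    x = profile.position_px[sel]
    baseline = y.min()
    return float(trapezoid(y - baseline, x))


def _detect_windows(profile: GelLaneProfile) -> dict[str, tuple[float, float]]:
    """Fallback band windows from the two dominant peaks."""
    y = profile.intensity
    peaks, props = find_peaks(y, height=0)
    if len(peaks) < 2:
        raise ValueError("could not detect two bands; supply band_windows")
    order = np.argsort(props["peak_heights"])[::-1]
    p1, p2 = sorted(peaks[order[:2]])
    cut_idx = p1 + int(np.argmin(y[p1:p2 + 1]))
    x = profile.position_px
    return {
        "supernatant": (float(x[0]), float(x[cut_idx])),
        "pellet": (float(x[cut_idx]), float(x[-1])),
    }


def quantify_lane(profile: GelLaneProfile) -> float:
    """Fraction of lane signal in the pellet band, P / (S + P).

    Each band window gets its own minimum-intensity baseline
    subtracted; band areas are trapezoid integrals over the window.
    """
    windows = profile.band_windows or _detect_windows(profile)
    for name in ("supernatant", "pellet"):
        if name not in windows:
            raise ValueError(f"band window {name!r} missing")
    s_lo, s_hi = windows["supernatant"]
    p_lo, p_hi = windows["pellet"]
    if max(s_lo, p_lo) < min(s_hi, p_hi) and not (s_hi <= p_lo or p_hi <= s_lo):
        raise ValueError("supernatant and pellet windows overlap")
    area_s = _window_area(profile, s_lo, s_hi)
    area_p = _window_area(profile, p_lo, p_hi)
    total = area_s + area_p
    if total <= 0:
        raise ValueError("no band signal above baseline (S + P <= 0)")
    return area_p / total


def fraction_bound_model(titrant_uM, kd_uM: float, sites_uM: float):
    """Fraction of titrated ligand bound under the depletion model.

    At titrant -> 0 the fraction tends to the finite limit
    ``sites / (sites + kd)``, used for zero-concentration points.
    """
    L = np.asarray(titrant_uM, dtype=float)
    frac = np.empty_like(L)
    zero = L == 0
    if np.any(~zero):
        frac[~zero] = solve_equilibrium(L[~zero], sites_uM, kd_uM) / L[~zero]
    frac[zero] = sites_uM / (sites_uM + kd_uM)
    return frac if frac.ndim else float(frac)


def fit_binding(
    series: BindingSeries, sites_total_uM: float, fix_sites: bool = True
) -> BindingFit:
    """Least-squares fit of the depletion model to a titration series.

    Multi-starts over a log-spaced kd grid, then polishes the best
    start with bounded scalar minimization (in log kd). With
    ``fix_sites=False`` the site concentration is refined as well by
    alternating scalar minimizations. A kd landing on the grid edge is
    flagged ``kd_at_bound`` (identifiability limit, e.g. the
    stoichiometric-binding regime).
    """
    L = series.titrant_uM
    y = series.fraction_bound
    if len(L) < 4:
        raise ValueError("need at least 4 titration points")
    if np.ptp(L) == 0:
        raise ValueError("no spread in titrant concentrations")
    if np.ptp(y) < 1e-12:
        raise ValueError("degenerate series: all fractions equal")
    if sites_total_uM <= 0:
        raise ValueError("sites_total_uM must be positive")

    def rss(log_kd: float, sites: float) -> float:
        pred = fraction_bound_model(L, np.exp(log_kd), sites)
        return float(np.sum((pred - y) ** 2))

    lo, hi = np.log(_KD_GRID_LO), np.log(_KD_GRID_HI)
    grid = np.linspace(lo, hi, 60)
    sites = float(sites_total_uM)
    grid_rss = [rss(g, sites) for g in grid]
    best = int(np.argmin(grid_rss))
    a = grid[max(best - 1, 0)]
    b = grid[min(best + 1, len(grid) - 1)]
    res = minimize_scalar(rss, args=(sites,), bounds=(a, b), method="bounded",
                          options={"xatol": 1e-10})
    log_kd = float(res.x)

    if not fix_sites:
        def residuals(theta):
            return fraction_bound_model(L, np.exp(theta[0]), np.exp(theta[1])) - y

        s_hi = 10 * max(sites_total_uM, float(L.max()))
        ls = least_squares(
            residuals,
            x0=[log_kd, np.log(sites)],
            bounds=([lo, np.log(1e-6)], [hi, np.log(s_hi)]),
        )
        log_kd = float(ls.x[0])
        sites = float(np.exp(ls.x[1]))

    # within 0.1 log-units (~10%) of the search-grid edge => unidentifiable
    at_bound = log_kd <= lo + 0.1 or log_kd >= hi - 0.1
    kd = float(np.exp(min(max(log_kd, lo), hi)))
    return BindingFit(kd_uM=kd, sites_uM=sites, rss=rss(np.log(kd), sites),
                      kd_at_bound=at_bound)


def displacement_percent(baseline_fraction: float, competed_fraction: float) -> float:
    """Percent displacement of a bound ligand by a competitor."""
    if baseline_fraction <= 0:
        raise ValueError("baseline_fraction must be positive")
    return 100.0 * (1.0 - competed_fraction / baseline_fraction)
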