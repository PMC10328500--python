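"""Group summaries and multiple-comparison statistics.

Matches the reporting style of the source analyses: per-group mean with
t-based 95% CI, Student's t-test for two groups, one-way ANOVA with
Dunnett adjustment for comparisons against a control and Tukey HSD for
all pairwise comparisons. Welch correction is off by default and
available behind a flag.

Dunnett-adjusted p-values use the multivariate-t distribution (SciPy)
when available, with a seeded Monte-Carlo max-|t| fallback.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "ComparisonRow",
    "ComparisonTable",
    "summarize_groups",
    "compare_groups",
    "dunnett_pvalues_mc",
]

_MC_DRAWS = 100_000


@dataclass
class GroupSummary:
    group: str
    n: int
    mean: float
    ci95_low: float
    ci95_high: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summaries need n >= 2")
        if not self.ci95_low <= self.mean <= self.ci95_high:
            raise ValueError("CI must bracket the mean")


@dataclass
class ComparisonRow:
    group_a: str
    group_b: str
    statistic: float
    p_raw: float
    p_adjusted: float
    method: str


@dataclass
class ComparisonTable:
    rows: list[ComparisonRow]
    anova_f: Optional[float] = None
    anova_p: Optional[float] = None

    def __post_init__(self) -> None:
        for row in self.rows:
            if not 0 <= row.p_raw <= 1 or not 0 <= row.p_adjusted <= 1:
                raise ValueError("p-values must lie in [0, 1]")
            if row.p_adjusted < row.p_raw - 1e-12:
                raise ValueError("adjusted p below raw p")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])


def summarize_groups(values: Mapping[str, Sequence[float]]) -> list[GroupSummary]:
    """Per-group mean and t-based 95% confidence interval."""
    out = []
    for name, vals in values.items():
        x = np.asarray(vals, dtype=float)
        if x.size < 2:
            raise ValueError(f"group {name!r} has n < 2")
        m = float(x.mean())
        sem = float(x.std(ddof=1) / np.sqrt(x.size))
        half = float(sps.t.ppf(0.975, x.size - 1)) * sem
        out.append(GroupSummary(group=name, n=int(x.size), mean=m,
                                ci95_low=m - half, ci95_high=m + half))
    return out


def _pooled_sd(groups: Sequence[np.ndarray]) -> tuple[float, int]:
    """Pooled SD across groups and its error degrees of freedom."""
    n_total = sum(g.size for g in groups)
    df = n_total - len(groups)
    ss = sum(((g - g.mean()) ** 2).sum() for g in groups)
    return float(np.sqrt(ss / df)), df


def _pooled_t(a: np.ndarray, b: np.ndarray, sd: float, df: int) -> tuple[float, float]:
    """t statistic and two-sided p using the shared pooled error term."""
    se = sd * np.sqrt(1.0 / a.size + 1.0 / b.size)
    t = float((a.mean() - b.mean()) / se) if se > 0 else 0.0
    p = float(2.0 * sps.t.sf(abs(t), df)) if se > 0 else 1.0
    return t, p


def dunnett_pvalues_mc(
    t_obs: np.ndarray,
    group_sizes: Sequence[int],
    control_size: int,
    df: int,
    n_draws: int = _MC_DRAWS,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo Dunnett adjustment: null distribution of max |t|.

    Simulates ``n_draws`` balanced null datasets with the given group
    sizes, computes each treatment-vs-control t with the pooled error
    term, and returns P(max_i |t_i| >= |t_obs|) per contrast.
    """
    rng = np.random.default_rng(seed)
    sizes = [control_size, *group_sizes]
    max_abs_t = np.zeros(n_draws)
    # vectorized over draws: one normal matrix per group
    samples = [rng.standard_normal((n_draws, n)) for n in sizes]
    means = [s.mean(axis=1) for s in samples]
    ss = sum(((s - m[:, None]) ** 2).sum(axis=1) for s, m in zip(samples, means))
    sd = np.sqrt(ss / df)
    for gi, n in enumerate(sizes[1:], start=1):
        se = sd * np.sqrt(1.0 / n + 1.0 / sizes[0])
        t = (means[gi] - means[0]) / se
        max_abs_t = np.maximum(max_abs_t, np.abs(t))
    return np.array([(max_abs_t >= abs(t)).mean() for t in np.atleast_1d(t_obs)])


def compare_groups(
    values: Mapping[str, Sequence[float]],
    design: str = "two_sample",
    control: Optional[str] = None,
    welch: bool = False,
    seed: int = 0,
) -> ComparisonTable:
    """Group comparisons in one of three designs.

    ``two_sample``
        Exactly two groups; two-sided Student's t (Welch behind the
        flag); adjusted p equals raw p.
    ``vs_control``
        One-way ANOVA plus Dunnett-adjusted p for each non-control
        group against ``control``.
    ``all_pairs``
        One-way ANOVA plus Tukey HSD over all pairs.

    Adjusted p-values are guaranteed monotone (>= raw) for every row.
    """
    names = list(values.keys())
    arrays = {k: np.asarray(v, dtype=float) for k, v in values.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has n < 2")

    if design == "two_sample":
        if len(names) != 2:
            raise ValueError("two_sample design needs exactly 2 groups")
        a, b = arrays[names[0]], arrays[names[1]]
        if np.ptp(np.concatenate([a, b])) == 0:
            t, p = 0.0, 1.0
        else:
            res = sps.ttest_ind(a, b, equal_var=not welch)
            t, p = float(res.statistic), float(res.pvalue)
        row = ComparisonRow(names[0], names[1], t, p, p, "ttest")
        return ComparisonTable(rows=[row])

    if len(names) < 3:
        raise ValueError("ANOVA designs need >= 3 groups")
    groups = [arrays[n] for n in names]
    if np.ptp(np.concatenate(groups)) == 0:
        f_stat, f_p = 0.0, 1.0
    else:
        f_res = sps.f_oneway(*groups)
        f_stat, f_p = float(f_res.statistic), float(f_res.pvalue)
    sd, df = _pooled_sd(groups)

    if design == "vs_control":
        if control is None or control not in names:
            raise ValueError("vs_control design needs a control group name")
        treat_names = [n for n in names if n != control]
        ctrl = arrays[control]
        raws, stats = [], []
        for n in treat_names:
            t, p = _pooled_t(arrays[n], ctrl, sd, df)
            stats.append(t)
            raws.append(p)
        if sd == 0:
            adj = np.ones(len(treat_names))
        else:
            try:
                res = sps.dunnett(*[arrays[n] for n in treat_names], control=ctrl)
                adj = np.asarray(res.pvalue, dtype=float)
            except Exception:  # pragma: no cover - SciPy without dunnett
                adj = dunnett_pvalues_mc(
                    np.asarray(stats),
                    [arrays[n].size for n in treat_names],
                    ctrl.size,
                    df,
                    seed=seed,
                )
        rows = [
            ComparisonRow(n, control, stats[i], raws[i],
                          float(np.clip(max(adj[i], raws[i]), 0, 1)), "anova_dunnett")
            for i, n in enumerate(treat_names)
        ]
        return ComparisonTable(rows=rows, anova_f=f_stat, anova_p=f_p)

    if design == "all_pairs":
        if sd == 0:
            res = None
        else:
            res = sps.tukey_hsd(*groups)
        rows = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                t, p = _pooled_t(arrays[names[i]], arrays[names[j]], sd, df)
                adj = 1.0 if res is None else float(res.pvalue[i, j])
                rows.append(ComparisonRow(names[i], names[j], t, p,
                                          float(np.clip(max(adj, p), 0, 1)),
                                          "anova_tukey"))
        return ComparisonTable(rows=rows, anova_f=f_stat, anova_p=f_p)

    raise ValueError(f"unknown design {design!r}")
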