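"""Shared statistical primitives: Welch's one-way test and quantile binning.

Both the density and the conservation analyses summarise methylation
variability (MV) across ordered groups; they share one Welch heteroscedastic
one-way test and one quantile-binning implementation so that quartile and
decile boundaries are computed by identical code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "OneWayResult",
    "BinSummary",
    "welch_oneway",
    "quantile_bin",
    "quartile_bin",
    "decile_bin",
    "format_p",
]


@dataclass(frozen=True)
class OneWayResult:
    """Welch's heteroscedastic one-way test over k groups."""

    statistic: float
    df_num: float
    df_den: float
    p_value: float
    group_sizes: tuple[int, ...]
    group_means: tuple[float, ...]
    group_medians: tuple[float, ...]

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df_num": self.df_num,
            "df_den": self.df_den,
            "p_value": self.p_value,
            "p_display": format_p(self.p_value),
            "group_sizes": list(self.group_sizes),
            "group_means": list(self.group_means),
            "group_medians": list(self.group_medians),
        }


@dataclass(frozen=True)
class BinSummary:
    label: str
    n: int
    median: float
    mean: float


def welch_oneway(groups) -> OneWayResult:
    """Welch's one-way test allowing unequal group variances.

    This is the statistic R's ``oneway.test`` computes with its default
    ``var.equal = FALSE``. For two groups the F statistic equals the square
    of the Welch two-sample t statistic.

    Parameters
    ----------
    groups
        Sequence of 1-D array-likes, one per group; each group needs at
        least two values and nonzero variance.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("welch_oneway needs at least two groups")
    for i, a in enumerate(arrs):
        if a.size < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
        if np.var(a) == 0:
            raise ValueError(f"group {i} has zero within-group variance")

    k = len(arrs)
    n = np.array([a.size for a in arrs], dtype=float)
    means = np.array([a.mean() for a in arrs])
    v = np.array([a.var(ddof=1) for a in arrs])

    w = n / v
    w_sum = w.sum()
    grand = (w * means).sum() / w_sum
    a_num = ((w * (means - grand) ** 2).sum()) / (k - 1)
    lam = ((1.0 - w / w_sum) ** 2 / (n - 1.0)).sum()
    b_den = 1.0 + 2.0 * (k - 2.0) / (k**2 - 1.0) * lam
    f = a_num / b_den
    df1 = k - 1.0
    df2 = (k**2 - 1.0) / (3.0 * lam)
    p = float(sps.f.sf(f, df1, df2))
    return OneWayResult(
        statistic=float(f),
        df_num=df1,
        df_den=float(df2),
        p_value=p,
        group_sizes=tuple(int(x) for x in n),
        group_means=tuple(float(m) for m in means),
        group_medians=tuple(float(np.median(a)) for a in arrs),
    )


def quantile_bin(values, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Bin values into ``n_bins`` equal-probability bins.

    Boundaries are the linear-interpolation percentiles at
    ``100*i/n_bins`` for i in 1..n_bins-1. Bins are left-closed,
    right-open; the last bin is right-closed (it simply absorbs everything
    at or above the final boundary).

    Returns
    -------
    labels : int array in [0, n_bins)
    boundaries : the n_bins-1 internal boundaries
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < n_bins:
        raise ValueError(f"need at least {n_bins} values to form {n_bins} bins")
    qs = [100.0 * i / n_bins for i in range(1, n_bins)]
    bounds = np.percentile(x, qs, method="linear")
    if np.unique(bounds).size != len(bounds):
        raise ValueError("degenerate bin boundaries: two percentiles coincide")
    labels = np.searchsorted(bounds, x, side="right")
    return labels.astype(int), bounds


def quartile_bin(values) -> tuple[np.ndarray, np.ndarray]:
    """Quartile labels Q1..Q4 (returned as 0..3) plus the three boundaries."""
    if np.unique(np.asarray(values, dtype=float)).size < 4:
        raise ValueError("quartile binning needs at least 4 distinct values")
    return quantile_bin(values, 4)


def decile_bin(values) -> tuple[np.ndarray, np.ndarray]:
    """Decile labels (0..9) plus the nine boundaries."""
    if np.unique(np.asarray(values, dtype=float)).size < 10:
        raise ValueError("decile binning needs at least 10 distinct values")
    return quantile_bin(values, 10)


def summarize_bins(labels: np.ndarray, stat_values, prefix: str) -> list[BinSummary]:
    """Per-bin n/median/mean of ``stat_values`` for integer bin labels."""
    stat = np.asarray(stat_values, dtype=float)
    out = []
    for b in range(int(labels.max()) + 1):
        sel = stat[labels == b]
        out.append(
            BinSummary(
                label=f"{prefix}{b + 1}",
                n=int(sel.size),
                median=float(np.median(sel)) if sel.size else float("nan"),
                mean=float(sel.mean()) if sel.size else float("nan"),
            )
        )
    return out


def format_p(p: float, floor: float = 2.2e-16) -> str:
    """Display string for a p-value, using the R-style '< 2.2e-16' floor."""
    if p < floor:
        return "< 2.2e-16"
    return f"{p:.3g}"
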