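"""Ancient-selection overlay: GERP-RS lookup, non-negative filter, quartiles.

Each probe inherits the rejected-substitutions (GERP-RS) score of the
base-resolution track interval containing it. Probes with negative scores
are removed (negative rejected-substitution scores are hard to interpret),
the remainder are split into score quartiles, and methylation variability
(MV) is summarised per quartile with a Welch one-way test and a
monotonicity flag for the expected conserved-sites-are-stable trend.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import OneWayResult, quartile_bin, welch_oneway

__all__ = [
    "GERP_MIN",
    "GERP_MAX",
    "gerp_lookup",
    "nonneg_filter",
    "annotate_quartiles",
    "mv_by_quartile",
    "QuartileTrend",
]

GERP_MIN = -12.36
GERP_MAX = 6.18

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")


def gerp_lookup(track: pd.DataFrame, manifest: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Score each probe from a bedGraph-style conservation track.

    ``track`` has columns chrom, start (0-based), end, score with
    non-overlapping intervals per chromosome; ``manifest`` has probe,
    chrom, pos (1-based). Probes covered by no interval are dropped.

    Returns (DataFrame[probe, score], number of probes dropped).
    """
    out_probe: list = []
    out_score: list = []
    n_dropped = 0
    for chrom, sub in manifest.groupby("chrom", sort=False):
        t = track[track["chrom"] == chrom].sort_values("start")
        if t.empty:
            n_dropped += len(sub)
            continue
        starts = t["start"].to_numpy(dtype=np.int64)
        ends = t["end"].to_numpy(dtype=np.int64)
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"overlapping track intervals on {chrom}")
        scores = t["score"].to_numpy(dtype=float)
        pos0 = sub["pos"].to_numpy(dtype=np.int64) - 1
        idx = np.searchsorted(starts, pos0, side="right") - 1
        hit = (idx >= 0) & (pos0 < ends[np.clip(idx, 0, None)])
        n_dropped += int((~hit).sum())
        out_probe.extend(sub["probe"].to_numpy()[hit])
        out_score.extend(scores[idx[hit]])
    return pd.DataFrame({"probe": out_probe, "score": out_score}), n_dropped


def nonneg_filter(annotated: pd.DataFrame) -> pd.DataFrame:
    """Keep probes with GERP-RS score >= 0 (zero is retained)."""
    kept = annotated[annotated["score"] >= 0].reset_index(drop=True)
    if kept.empty:
        warnings.warn("all probes have negative conservation scores", stacklevel=2)
    return kept


def annotate_quartiles(annotated: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Add a Q1..Q4 quartile label column from the score distribution."""
    labels, bounds = quartile_bin(annotated["score"].to_numpy(dtype=float))
    out = annotated.copy()
    out["quartile"] = [QUARTILE_LABELS[i] for i in labels]
    return out, bounds


@dataclass(frozen=True)
class QuartileTrend:
    per_quartile: list[dict]
    test: OneWayResult
    monotone_decreasing: bool

    def to_dict(self) -> dict:
        return {
            "per_quartile": self.per_quartile,
            "welch_oneway": self.test.to_dict(),
            "monotone_decreasing": self.monotone_decreasing,
        }


def mv_by_quartile(mv_table: pd.DataFrame, annotated: pd.DataFrame) -> QuartileTrend:
    """Summarise MV per conservation quartile and test for a trend.

    ``annotated`` must carry probe + quartile (from :func:`annotate_quartiles`);
    ``mv_table`` carries probe + mv. The monotone flag reports whether the
    quartile MV medians are non-increasing from Q1 to Q4 — the pattern
    expected when evolutionary constraint suppresses methylation
    variability.
    """
    merged = annotated.merge(mv_table[["probe", "mv"]], on="probe", how="inner")
    if len(merged) < 4:
        raise ValueError("fewer than 4 probes shared between MV table and annotation")
    groups = []
    summaries = []
    for q in QUARTILE_LABELS:
        vals = merged.loc[merged["quartile"] == q, "mv"].to_numpy(dtype=float)
        if vals.size < 2:
            raise ValueError(f"quartile {q} has fewer than 2 probes after filtering")
        groups.append(vals)
        summaries.append(
            {"quartile": q, "n": int(vals.size), "median_mv": float(np.median(vals)), "mean_mv": float(vals.mean())}
        )
    test = welch_oneway(groups)
    medians = [s["median_mv"] for s in summaries]
    monotone = all(medians[i] >= medians[i + 1] for i in range(3))
    return QuartileTrend(per_quartile=summaries, test=test, monotone_decreasing=monotone)
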