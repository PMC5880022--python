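"""CpG cluster discovery and HC/IC/LC density classification.

Genomic regions are classed by the Price-style criteria on three measures:
GC content, observed/expected CpG ratio and length. High-density clusters
(HC) require GC > 0.55, Obs/Exp > 0.75 and length > 500 bp; intermediate
clusters (IC) require GC > 0.50, Obs/Exp > 0.48 and length > 200 bp.
Everything outside an HC/IC region is low density (LC). Inequalities are
strict; a region exactly at a boundary fails that criterion.

Discovery is a deterministic seed-merge-reclassify scan: 200-bp windows
stepped by 50 bp seed a region when they meet the IC minima on GC and
Obs/Exp; touching seeds merge, and the merged span is re-measured in full
before classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pyfaidx import Fasta

__all__ = [
    "DensityRegion",
    "gc_content",
    "obs_exp_ratio",
    "classify_region",
    "measure_sequence",
    "find_cpg_clusters",
    "assign_density",
]

HC_CRITERIA = {"gc": 0.55, "obs_exp": 0.75, "length": 500}
IC_CRITERIA = {"gc": 0.50, "obs_exp": 0.48, "length": 200}

WINDOW = 200
STEP = 50


@dataclass(frozen=True)
class DensityRegion:
    """A CpG cluster: 0-based half-open interval with its density class."""

    chrom: str
    start: int
    end: int
    gc_content: float
    obs_exp: float
    klass: str  # "HC" or "IC"

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("region end must exceed start")
        if self.klass not in ("HC", "IC"):
            raise ValueError(f"invalid density class {self.klass!r}")


def _counts(seq: str) -> tuple[int, int, int, int]:
    """(n_C, n_G, n_CpG, effective_length) with N bases excluded."""
    s = seq.upper()
    n_c = s.count("C")
    n_g = s.count("G")
    n_cg = s.count("CG")
    eff = len(s) - s.count("N")
    return n_c, n_g, n_cg, eff


def gc_content(seq: str) -> float:
    """Fraction of C+G among non-N bases; 0 for an all-N sequence."""
    if len(seq) == 0:
        raise ValueError("empty sequence")
    n_c, n_g, _, eff = _counts(seq)
    return (n_c + n_g) / eff if eff else 0.0


def obs_exp_ratio(seq: str) -> float:
    """Gardiner-Garden-style Obs/Exp CpG ratio: N_CpG * L / (N_C * N_G).

    L is the effective (non-N) length. Returns 0 when the sequence has no
    C or no G, where the expectation is undefined.
    """
    if len(seq) == 0:
        raise ValueError("empty sequence")
    n_c, n_g, n_cg, eff = _counts(seq)
    if n_c == 0 or n_g == 0:
        return 0.0
    return n_cg * eff / (n_c * n_g)


def classify_region(gc: float, obs_exp: float, length: int) -> str | None:
    """HC / IC / None by the strict three-criterion rules."""
    if not (np.isfinite(gc) and np.isfinite(obs_exp)):
        raise ValueError("gc and obs_exp must be finite")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc content must lie in [0,1]")
    if length < 0:
        raise ValueError("length must be non-negative")
    hc = HC_CRITERIA
    ic = IC_CRITERIA
    if gc > hc["gc"] and obs_exp > hc["obs_exp"] and length > hc["length"]:
        return "HC"
    if gc > ic["gc"] and obs_exp > ic["obs_exp"] and length > ic["length"]:
        return "IC"
    return None


def measure_sequence(seq: str) -> tuple[float, float, int]:
    """(gc_content, obs_exp, genomic span length) for a sequence."""
    return gc_content(seq), obs_exp_ratio(seq), len(seq)


def _window_scan(seq: str) -> list[tuple[int, int]]:
    """Seed windows (start, end) passing the IC minima on gc and obs/exp."""
    s = seq.upper()
    L = len(s)
    if L < WINDOW:
        return []
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(np.int64)
    is_g = (arr == ord("G")).astype(np.int64)
    is_n = (arr == ord("N")).astype(np.int64)
    is_cg = np.zeros(L, dtype=np.int64)
    if L > 1:
        is_cg[:-1] = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))

    def cum(x):
        c = np.zeros(L + 1, dtype=np.int64)
        np.cumsum(x, out=c[1:])
        return c

    cc, cg_, cn, ccg = cum(is_c), cum(is_g), cum(is_n), cum(is_cg)
    starts = np.arange(0, L - WINDOW + 1, STEP)
    ends = starts + WINDOW
    n_c = cc[ends] - cc[starts]
    n_g = cg_[ends] - cg_[starts]
    n_n = cn[ends] - cn[starts]
    # CpGs counted within the window only (a CG straddling the window end
    # belongs to the next window)
    n_cg = ccg[ends - 1] - ccg[starts]
    eff = WINDOW - n_n
    with np.errstate(divide="ignore", invalid="ignore"):
        gc = np.where(eff > 0, (n_c + n_g) / eff, 0.0)
        oe = np.where((n_c > 0) & (n_g > 0), n_cg * eff / (n_c * n_g), 0.0)
    keep = (gc > IC_CRITERIA["gc"]) & (oe > IC_CRITERIA["obs_exp"])
    return [(int(s0), int(s0) + WINDOW) for s0 in starts[keep]]


def _merge(windows: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or adjacent intervals into maximal runs."""
    merged: list[list[int]] = []
    for s, e in windows:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def find_cpg_clusters(fasta_path) -> list[DensityRegion]:
    """Scan a FASTA for CpG clusters and classify each HC or IC.

    Merged candidate spans are re-measured in full; spans classifying to
    neither HC nor IC are dropped. Output is sorted by (chrom, start) and
    non-overlapping within a chromosome.
    """
    try:
        fa = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    except Exception as exc:  # pragma: no cover - I/O failure path
        raise IOError(f"cannot open FASTA {fasta_path}: {exc}") from exc
    regions: list[DensityRegion] = []
    for chrom in sorted(fa.keys()):
        seq = str(fa[chrom][:])
        for start, end in _merge(_window_scan(seq)):
            sub = seq[start:end]
            gc, oe, span = measure_sequence(sub)
            klass = classify_region(gc, oe, span)
            if klass is not None:
                regions.append(DensityRegion(chrom, start, end, gc, oe, klass))
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def assign_density(regions: list[DensityRegion], manifest: pd.DataFrame) -> pd.Series:
    """Assign each probe HC / IC / LC by containment in the region list.

    ``manifest`` needs columns ``probe``, ``chrom``, ``pos`` (1-based); the
    probe position is converted to 0-based and tested against the half-open
    regions. Probes inside no region are LC. Returns a Series indexed by
    probe ID.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for chrom in {r.chrom for r in regions}:
        rs = [r for r in regions if r.chrom == chrom]
        rs.sort(key=lambda r: r.start)
        starts = np.array([r.start for r in rs])
        ends = np.array([r.end for r in rs])
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"overlapping regions on {chrom}")
        by_chrom[chrom] = (starts, ends, [r.klass for r in rs])

    out = np.full(len(manifest), "LC", dtype=object)
    pos0 = manifest["pos"].to_numpy(dtype=np.int64) - 1
    chroms = manifest["chrom"].to_numpy()
    for chrom, (starts, ends, classes) in by_chrom.items():
        sel = np.flatnonzero(chroms == chrom)
        if sel.size == 0:
            continue
        idx = np.searchsorted(starts, pos0[sel], side="right") - 1
        ok = (idx >= 0) & (pos0[sel] < ends[np.clip(idx, 0, None)])
        for i, j in zip(sel[ok], idx[ok]):
            out[i] = classes[j]
    return pd.Series(out, index=pd.Index(manifest["probe"], name="probe"), name="density_class")
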