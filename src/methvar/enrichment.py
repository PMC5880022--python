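"""Promoter-level gene ranking and preranked gene-set enrichment.

Probes are mapped to genes whose transcription start site (TSS) lies
within a symmetric flank (default +/-1500 bp); per-gene MV is the mean of
its promoter probes; gene values are standardised to z-scores and ranked
descending. Enrichment of a gene set in either tail of that ranking is
scored with the weighted Kolmogorov-Smirnov running-sum statistic
(enrichment score, ES) and a gene-set permutation null: random same-size
gene sets give the nominal p, the sign-matched normalisation gives the
NES, and pooling null NES values over all tested sets gives the FDR q.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "map_probes_to_promoters",
    "gene_mv",
    "zscore_rank",
    "enrichment_score",
    "gsea_preranked",
    "significant_sets",
    "EnrichmentResult",
]


def map_probes_to_promoters(
    annotation: pd.DataFrame, manifest: pd.DataFrame, flank: int = 1500
) -> pd.DataFrame:
    """Assign probes to genes with |probe_pos - TSS| <= flank.

    ``annotation`` has columns gene, chrom, tss (1-based), strand; the
    window is symmetric regardless of strand. A probe inside two genes'
    windows is assigned to both. Returns DataFrame (probe, gene).
    """
    rows_probe: list = []
    rows_gene: list = []
    for chrom, genes in annotation.groupby("chrom", sort=False):
        sub = manifest[manifest["chrom"] == chrom]
        if sub.empty:
            continue
        ppos = sub["pos"].to_numpy(dtype=np.int64)
        order = np.argsort(ppos, kind="stable")
        ppos_sorted = ppos[order]
        probes_sorted = sub["probe"].to_numpy()[order]
        for gene, tss in zip(genes["gene"], genes["tss"].astype(np.int64)):
            lo = np.searchsorted(ppos_sorted, tss - flank, side="left")
            hi = np.searchsorted(ppos_sorted, tss + flank, side="right")
            if hi > lo:
                rows_probe.extend(probes_sorted[lo:hi])
                rows_gene.extend([gene] * (hi - lo))
    return pd.DataFrame({"probe": rows_probe, "gene": rows_gene})


def gene_mv(assignments: pd.DataFrame, mv_table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Per-gene mean MV over promoter probes.

    Genes none of whose probes survive into the MV table are dropped;
    the count of dropped genes is returned alongside the table
    (gene, X, n_probes).
    """
    merged = assignments.merge(mv_table[["probe", "mv"]], on="probe", how="left")
    n_genes_in = merged["gene"].nunique()
    kept = merged.dropna(subset=["mv"])
    agg = kept.groupby("gene")["mv"].agg(X="mean", n_probes="size").reset_index()
    n_dropped = n_genes_in - len(agg)
    return agg, int(n_dropped)


def zscore_rank(gene_mv_table: pd.DataFrame) -> pd.DataFrame:
    """z = (X - mu) / sigma per gene, ranked descending.

    mu and sigma are the mean and sample standard deviation of the
    gene-level MV values. Ties in z are broken alphabetically by gene
    symbol so the ranking is reproducible.
    """
    if len(gene_mv_table) < 2:
        raise ValueError("need at least 2 genes to standardise")
    x = gene_mv_table["X"].to_numpy(dtype=float)
    sigma = x.std(ddof=1)
    if sigma == 0:
        raise ValueError("all gene MV values identical; z-scores undefined")
    out = gene_mv_table.copy()
    out["z"] = (x - x.mean()) / sigma
    out = out.sort_values(["z", "gene"], ascending=[False, True], kind="stable")
    return out.reset_index(drop=True)


def enrichment_score(hits: np.ndarray, scores: np.ndarray, weight: float = 1.0) -> tuple[float, int]:
    """Weighted KS running-sum ES for one gene set.

    ``hits`` is a boolean mask over the ranked list (descending scores);
    hit steps add |score|^weight normalised by the in-set total, miss
    steps subtract 1/(N - N_hits). Returns (ES, index of the extremum).
    """
    n = hits.size
    nh = int(hits.sum())
    if nh == 0 or nh == n:
        raise ValueError("gene set must hit a proper nonempty subset of the list")
    w = np.where(hits, np.abs(scores) ** weight, 0.0)
    total = w.sum()
    if total == 0:  # all in-set scores exactly zero: fall back to equal steps
        w = hits.astype(float)
        total = w.sum()
    run = np.cumsum(w / total - (~hits) / (n - nh))
    i = int(np.argmax(np.abs(run)))
    return float(run[i]), i


@dataclass(frozen=True)
class EnrichmentResult:
    name: str
    size: int
    es: float
    nes: float
    p_value: float
    fdr_q: float
    direction: str  # "high-MV tail" or "low-MV tail"
    leading_edge: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "set": self.name,
            "size": self.size,
            "es": self.es,
            "nes": self.nes,
            "nom_p": self.p_value,
            "fdr_q": self.fdr_q,
            "direction": self.direction,
            "leading_edge": list(self.leading_edge),
        }


def _null_es(
    n: int, size: int, scores: np.ndarray, weight: float, n_perm: int,
    rng: np.random.Generator, exhaustive: bool,
) -> np.ndarray:
    if exhaustive:
        if math.comb(n, size) > 200_000:
            raise ValueError("exhaustive null infeasible for this list/set size")
        idx_sets = combinations(range(n), size)
        out = []
        for idx in idx_sets:
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            out.append(enrichment_score(mask, scores, weight)[0])
        return np.asarray(out)
    out = np.empty(n_perm)
    for b in range(n_perm):
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=size, replace=False)] = True
        out[b] = enrichment_score(mask, scores, weight)[0]
    return out


def gsea_preranked(
    ranked: pd.DataFrame,
    sets: dict[str, list[str]],
    weight: float = 1.0,
    n_perm: int = 1000,
    min_size: int = 3,
    max_size: int = 500,
    seed: int = 0,
    exhaustive: bool = False,
) -> list[EnrichmentResult]:
    """Preranked enrichment over a collection of gene sets.

    ``ranked`` is the output of :func:`zscore_rank` (columns gene, z,
    descending). Sets are restricted to genes present in the list; those
    with fewer than ``min_size`` or more than ``max_size`` surviving
    members, or covering the whole list, are skipped with a warning. The
    null for each distinct set size is ``n_perm`` random same-size gene
    sets (or every same-size subset with ``exhaustive=True``); nominal p
    is the fraction of same-sign null ES at least as extreme as the
    observed ES, NES divides ES by the mean same-sign |null ES|, and FDR q
    compares each NES against the pooled normalised null over all tested
    sets.
    """
    if ranked.empty:
        raise ValueError("ranked list is empty")
    genes = ranked["gene"].to_numpy()
    scores = ranked["z"].to_numpy(dtype=float)
    n = genes.size
    gene_pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    tested: list[tuple[str, int, float, int, np.ndarray]] = []
    null_cache: dict[int, np.ndarray] = {}
    for name, members in sets.items():
        idx = sorted(gene_pos[g] for g in set(members) if g in gene_pos)
        size = len(idx)
        if size == 0:
            warnings.warn(f"gene set {name!r} has no overlap with the ranked list", stacklevel=2)
            continue
        if size < min_size or size > max_size or size == n:
            warnings.warn(f"gene set {name!r} skipped (size {size})", stacklevel=2)
            continue
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        es, peak = enrichment_score(mask, scores, weight)
        if size not in null_cache:
            null_cache[size] = _null_es(n, size, scores, weight, n_perm, rng, exhaustive)
        tested.append((name, size, es, peak, mask))

    # per-set nominal p and NES against the size-matched null
    results_raw = []
    pooled_null_nes: list[np.ndarray] = []
    for name, size, es, peak, mask in tested:
        null = null_cache[size]
        pos = null[null >= 0]
        neg = null[null < 0]
        if es >= 0:
            same = pos
            p = float((same >= es).sum() / max(1, same.size))
            denom = same.mean() if same.size else np.nan
        else:
            same = neg
            p = float((same <= es).sum() / max(1, same.size))
            denom = np.abs(same).mean() if same.size else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else float("nan")
        results_raw.append((name, size, es, nes, p, peak, mask))
    for size, null in null_cache.items():
        pos = null[null >= 0]
        neg = null[null < 0]
        norm = np.empty_like(null)
        norm[null >= 0] = null[null >= 0] / (pos.mean() if pos.size else np.nan)
        norm[null < 0] = null[null < 0] / (np.abs(neg).mean() if neg.size else np.nan)
        pooled_null_nes.append(norm)
    pooled = np.concatenate(pooled_null_nes) if pooled_null_nes else np.array([])
    obs_nes = np.array([r[3] for r in results_raw])

    results: list[EnrichmentResult] = []
    for name, size, es, nes, p, peak, mask in results_raw:
        if np.isnan(nes):
            q = float("nan")
        elif nes >= 0:
            null_frac = (pooled >= nes).sum() / max(1, (pooled >= 0).sum())
            obs_frac = (obs_nes >= nes).sum() / max(1, (obs_nes >= 0).sum())
            q = min(1.0, float(null_frac / obs_frac)) if obs_frac > 0 else 1.0
        else:
            null_frac = (pooled <= nes).sum() / max(1, (pooled < 0).sum())
            obs_frac = (obs_nes <= nes).sum() / max(1, (obs_nes < 0).sum())
            q = min(1.0, float(null_frac / obs_frac)) if obs_frac > 0 else 1.0
        hit_idx = np.flatnonzero(mask)
        if es >= 0:
            lead = genes[hit_idx[hit_idx <= peak]]
        else:
            lead = genes[hit_idx[hit_idx >= peak]][::-1]
        results.append(
            EnrichmentResult(
                name=name,
                size=size,
                es=es,
                nes=float(nes),
                p_value=p,
                fdr_q=q,
                direction="high-MV tail" if es >= 0 else "low-MV tail",
                leading_edge=tuple(lead),
            )
        )
    return results


def significant_sets(
    results: list[EnrichmentResult], p_max: float = 0.01, q_max: float = 0.25
) -> dict[str, list[EnrichmentResult]]:
    """Sets passing both the nominal-p and FDR-q cutoffs, split by tail."""
    keep = [r for r in results if r.p_value <= p_max and r.fdr_q <= q_max]
    return {
        "high": [r for r in keep if r.direction == "high-MV tail"],
        "low": [r for r in keep if r.direction == "low-MV tail"],
    }
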