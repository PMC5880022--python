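"""Cohort selection, probe filtering and the methylation-variability table.

The analysis cohort is an equal number of healthy males and females,
age-matched by greedy nearest-age pairing. Probes are retained only when
autosomal, free of SNP overlap and cross-reactivity, and complete-case
across the selected samples; the per-probe MV statistic is the sample
standard deviation of beta-values (n-1 denominator). An optional
cell-composition screen flags probes that differ between purified blood
cell types and PBMC; it reports flags without removing probes, matching
an analysis run without white-blood-cell correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "select_cohort",
    "filter_probes",
    "compute_mv",
    "cell_composition_flags",
    "FilterReport",
]

SEX_CHROMS = ("chrX", "chrY")


def select_cohort(
    metadata: pd.DataFrame,
    n_per_sex: int = 83,
    age_min: int = 36,
    age_max: int = 65,
) -> list[str]:
    """Healthy males and females, age-matched in equal numbers.

    Pairing is greedy on the global age gap: among all remaining
    male-female pairs the one with the smallest absolute age difference is
    taken first (ties broken by sample ID), until ``n_per_sex`` pairs or
    exhaustion. Returns the selected sample IDs (all males then all
    females of the chosen pairs, each list in pairing order).
    """
    if metadata.empty:
        raise ValueError("metadata is empty")
    elig = metadata[
        (metadata["status"] == "healthy")
        & (metadata["age"] >= age_min)
        & (metadata["age"] <= age_max)
    ]
    males = elig[elig["sex"] == "M"]
    females = elig[elig["sex"] == "F"]
    if males.empty or females.empty:
        raise ValueError("no eligible samples for at least one sex")

    pairs = [
        (abs(int(am) - int(af)), sm, sf)
        for sm, am in zip(males["sample"], males["age"])
        for sf, af in zip(females["sample"], females["age"])
    ]
    pairs.sort()
    used_m: list[str] = []
    used_f: list[str] = []
    taken_m: set = set()
    taken_f: set = set()
    for _, sm, sf in pairs:
        if len(used_m) == n_per_sex:
            break
        if sm in taken_m or sf in taken_f:
            continue
        taken_m.add(sm)
        taken_f.add(sf)
        used_m.append(sm)
        used_f.append(sf)
    if len(used_m) < n_per_sex:
        logger.warning(
            "only %d age-matched pairs available (requested %d)", len(used_m), n_per_sex
        )
    return used_m + used_f


@dataclass(frozen=True)
class FilterReport:
    retained: list[str]
    tally: dict[str, int]

    def to_dict(self) -> dict:
        return {"n_retained": len(self.retained), "tally": dict(self.tally)}


def filter_probes(
    manifest: pd.DataFrame,
    beta: pd.DataFrame,
    sex_chroms=SEX_CHROMS,
    samples=None,
) -> FilterReport:
    """Retain autosomal, non-SNP, non-cross-reactive, complete-case probes.

    ``beta`` is probes x samples with NaN marking missing values;
    ``samples`` optionally restricts the completeness check to the
    selected cohort. The tally counts every probe under each exclusion
    reason it triggers, so reasons can sum to more than the number of
    excluded probes.
    """
    missing_manifest = set(beta.index) - set(manifest["probe"])
    if missing_manifest:
        raise ValueError(f"probes absent from manifest: {sorted(missing_manifest)[:5]}")
    m = manifest.set_index("probe").loc[beta.index]
    sub = beta if samples is None else beta.loc[:, list(samples)]

    on_sex = m["chrom"].isin(sex_chroms).to_numpy()
    snp = m["snp_overlap"].astype(bool).to_numpy()
    xreact = m["cross_reactive"].astype(bool).to_numpy()
    incomplete = sub.isna().any(axis=1).to_numpy()

    excluded = on_sex | snp | xreact | incomplete
    tally = {
        "sex_chromosome": int(on_sex.sum()),
        "snp_overlap": int(snp.sum()),
        "cross_reactive": int(xreact.sum()),
        "missing_values": int(incomplete.sum()),
        "total_excluded": int(excluded.sum()),
    }
    retained = list(beta.index[~excluded])
    return FilterReport(retained=retained, tally=tally)


def compute_mv(beta: pd.DataFrame, probe_ids, samples=None) -> pd.DataFrame:
    """Per-probe mean, sample variance and MV (sample SD, n-1 denominator).

    Probes must be complete-case over the selected samples; any remaining
    missing value is a contract violation and raises.
    """
    sub = beta.loc[list(probe_ids)]
    if samples is not None:
        sub = sub.loc[:, list(samples)]
    if sub.shape[1] < 2:
        raise ValueError("variance undefined with fewer than 2 samples")
    if sub.isna().any().any():
        raise ValueError("MV input contains missing values; filter probes first")
    vals = sub.to_numpy(dtype=float)
    mean = vals.mean(axis=1)
    var = vals.var(axis=1, ddof=1)
    return pd.DataFrame(
        {"probe": sub.index, "mean": mean, "variance": var, "mv": np.sqrt(var)}
    ).reset_index(drop=True)


def cell_composition_flags(
    panel_beta: pd.DataFrame,
    groups: pd.Series,
    p_threshold: float = 1e-7,
    delta_threshold: float = 0.05,
) -> pd.DataFrame:
    """Probes differing between any purified cell type and PBMC.

    For each probe and each non-PBMC group a two-group linear model
    (pooled-variance t-test on beta) is fitted against the PBMC samples; a
    probe is flagged when p < ``p_threshold`` and the absolute mean
    difference exceeds ``delta_threshold`` for at least one cell type.
    Flags are reported, not applied: downstream filtering stays off by
    default.

    Returns a DataFrame (probe, flagged, cell_types) where ``cell_types``
    lists the groups driving the flag.
    """
    labels = groups.loc[panel_beta.columns]
    if "PBMC" not in set(labels):
        raise ValueError("panel must include a PBMC group")
    pbmc = panel_beta.loc[:, labels[labels == "PBMC"].index].to_numpy(dtype=float)
    if pbmc.shape[1] < 2:
        raise ValueError("PBMC group has fewer than 2 samples")
    hits: dict[str, list[str]] = {p: [] for p in panel_beta.index}
    for cell in sorted(set(labels) - {"PBMC"}):
        grp = panel_beta.loc[:, labels[labels == cell].index].to_numpy(dtype=float)
        if grp.shape[1] < 2:
            raise ValueError(f"group {cell!r} has fewer than 2 samples")
        res = sps.ttest_ind(grp, pbmc, axis=1, equal_var=True)
        delta = np.abs(grp.mean(axis=1) - pbmc.mean(axis=1))
        flag = (res.pvalue < p_threshold) & (delta > delta_threshold)
        for probe in panel_beta.index[flag]:
            hits[probe].append(cell)
    return pd.DataFrame(
        {
            "probe": list(panel_beta.index),
            "flagged": [len(hits[p]) > 0 for p in panel_beta.index],
            "cell_types": [",".join(hits[p]) for p in panel_beta.index],
        }
    )
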