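"""Synthetic inputs for the whole pipeline, with planted couplings.

The generator emulates everything the analysis consumes: a genome with
planted CpG-dense clusters, a 450K-style beta-value matrix with sample
metadata and a probe manifest, a base-resolution conservation track, a
SNP table carrying the twelve recent-selection statistics, TSS annotation
and gene sets. Effects are planted so each downstream stage has a known
truth: HC probes disperse less than IC less than LC, conserved sites
disperse less (scaled by score), probes near selected SNPs disperse less
(``rsp_mv_shrink``), and two designated gene sets have promoters with
boosted / damped dispersion.

Beta-values are drawn from a Beta(m*kappa, (1-m)*kappa) distribution.
With kappa = 1/(4 s^2) - 1 the standard deviation is exactly
2*s*sqrt(m*(1-m)): the class dispersion parameter s controls spread
directly, and the sqrt(m(1-m)) factor reproduces the empirical pattern
that intermediate-methylation CpGs vary most between individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .density import DensityRegion, classify_region, measure_sequence
from .selection import STAT_COLUMNS, SelectionThresholds

__all__ = ["SimulationConfig", "SyntheticTruth", "simulate_genome", "simulate_betas",
           "simulate_selection_inputs", "simulate_all"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset (defaults are the
    packaged desk-scale conditions; see docs/methods.md)."""

    seed: int = 1
    n_samples: int = 50
    n_probes: int = 5000
    genome_length: int = 3_000_000
    n_hc: int = 350
    n_ic: int = 400
    hc_mv_sd: float = 0.03
    ic_mv_sd: float = 0.06
    lc_mv_sd: float = 0.10
    frac_missing: float = 0.01
    n_genes: int = 300
    n_snps: int = 600
    frac_selected_snps: float = 0.25
    rsp_mv_shrink: float = 0.77
    conserved_frac: float = 0.5
    gerp_mv_slope: float = 0.7
    dispersion_noise_sd: float = 0.5

    # structural knobs (rarely touched)
    probes_per_cluster: int = 2
    hc_len: tuple[int, int] = (600, 900)
    ic_len: tuple[int, int] = (250, 400)
    hc_gc: float = 0.66
    ic_gc: float = 0.58
    background_gc: float = 0.30
    min_gap: int = 1000
    sex_contig_length: int = 20_000
    frac_sex_probes: float = 0.03
    frac_snp_overlap: float = 0.02
    frac_cross_reactive: float = 0.02
    frac_other_status: float = 0.1
    half_window: int = 1000
    promoter_flank: int = 1500
    n_random_sets: int = 8
    planted_set_size: int = 20
    random_set_size: tuple[int, int] = (10, 40)
    high_set_factor: float = 1.6
    low_set_factor: float = 0.5

    def __post_init__(self):
        for name in ("n_samples", "n_probes", "genome_length", "n_genes", "n_snps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("frac_missing", "frac_selected_snps", "conserved_frac",
                     "frac_sex_probes", "frac_snp_overlap", "frac_cross_reactive"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1]")
        if self.frac_missing >= 1.0:
            raise ValueError("frac_missing must be below 1")
        if not (0.0 < self.hc_mv_sd < self.ic_mv_sd < self.lc_mv_sd < 0.5):
            raise ValueError("dispersions must satisfy 0 < hc < ic < lc < 0.5")
        if not 0.0 < self.rsp_mv_shrink <= 1.0:
            raise ValueError("rsp_mv_shrink must lie in (0,1]")
        if not 0.0 <= self.gerp_mv_slope <= 1.0:
            raise ValueError("gerp_mv_slope must lie in [0,1]")
        if self.genome_length < 10 * max(self.hc_len[1], self.ic_len[1]):
            raise ValueError("genome_length must be >= 10x the largest cluster length")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """Ground truth recorded while generating, for parameter recovery."""

    config: SimulationConfig
    genome: dict[str, str] = field(default_factory=dict)
    regions: list[DensityRegion] = field(default_factory=list)
    probes: pd.DataFrame | None = None  # probe,chrom,pos,true_class,score,rsp,true_mean,dispersion
    genes: pd.DataFrame | None = None  # gene,chrom,tss,strand
    gene_sets: dict[str, list[str]] = field(default_factory=dict)
    planted_direction: dict[str, str] = field(default_factory=dict)
    snps: pd.DataFrame | None = None

    def summary(self) -> dict:
        out = {
            "n_regions": len(self.regions),
            "n_hc_regions": sum(r.klass == "HC" for r in self.regions),
            "n_ic_regions": sum(r.klass == "IC" for r in self.regions),
        }
        if self.probes is not None:
            out["n_probes"] = int(len(self.probes))
            out["class_counts"] = self.probes["true_class"].value_counts().to_dict()
            out["n_rsp_probes"] = int(self.probes["rsp"].sum())
        if self.snps is not None:
            out["n_snps"] = int(len(self.snps))
            out["n_selected_snps"] = int(self.snps["selected"].sum())
        return out


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p)


def _make_block(rng: np.random.Generator, length: int, gc: float, want: str) -> np.ndarray:
    """Draw an i.i.d. block and verify it satisfies its density triple."""
    for _ in range(100):
        block = _random_seq(rng, length, gc)
        seq = block.tobytes().decode("ascii")
        klass = classify_region(*measure_sequence(seq))
        if klass == want:
            return block
    raise RuntimeError(f"could not realise a {want} block of length {length}")


def simulate_genome(config: SimulationConfig) -> tuple[dict[str, str], SyntheticTruth]:
    """Genome with planted HC and IC clusters on an AT-rich background.

    Returns the genome (chrom -> sequence, with chr1 carrying the planted
    clusters and small chrX/chrY contigs for the sex-probe quota) and a
    truth object whose region list records every planted interval.
    """
    rng = np.random.default_rng(config.seed)
    blocks: list[tuple[str, np.ndarray]] = []
    for _ in range(config.n_hc):
        length = int(rng.integers(config.hc_len[0], config.hc_len[1] + 1))
        blocks.append(("HC", _make_block(rng, length, config.hc_gc, "HC")))
    for _ in range(config.n_ic):
        length = int(rng.integers(config.ic_len[0], config.ic_len[1] + 1))
        blocks.append(("IC", _make_block(rng, length, config.ic_gc, "IC")))
    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]

    total = sum(len(b) for _, b in blocks)
    k = len(blocks)
    free = config.genome_length - total - (k + 1) * config.min_gap
    if free < 0:
        raise ValueError("clusters cannot fit in genome_length with the minimum gaps")
    extra = rng.multinomial(free, np.full(k + 1, 1.0 / (k + 1))) if k else np.array([free])

    chunks: list[np.ndarray] = []
    truth_regions: list[DensityRegion] = []
    cursor = 0
    for i in range(k):
        gap = config.min_gap + int(extra[i])
        chunks.append(_random_seq(rng, gap, config.background_gc))
        cursor += gap
        klass, block = blocks[i]
        seq = block.tobytes().decode("ascii")
        gc, oe, span = measure_sequence(seq)
        truth_regions.append(DensityRegion("chr1", cursor, cursor + len(block), gc, oe, klass))
        chunks.append(block)
        cursor += len(block)
    chunks.append(_random_seq(rng, config.genome_length - cursor, config.background_gc))

    genome = {
        "chr1": np.concatenate(chunks).tobytes().decode("ascii"),
        "chrX": _random_seq(rng, config.sex_contig_length, 0.40).tobytes().decode("ascii"),
        "chrY": _random_seq(rng, config.sex_contig_length, 0.40).tobytes().decode("ascii"),
    }
    truth = SyntheticTruth(config=config, genome=genome, regions=truth_regions)
    return genome, truth


def _cpg_positions(seq: str) -> np.ndarray:
    """1-based positions of the C of each CpG dinucleotide."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    hits = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
    return hits + 1


def _place_probes(config: SimulationConfig, truth: SyntheticTruth,
                  rng: np.random.Generator) -> pd.DataFrame:
    pos1 = _cpg_positions(truth.genome["chr1"])
    klass = np.full(pos1.size, "LC", dtype=object)
    for r in truth.regions:
        inside = (pos1 - 1 >= r.start) & (pos1 - 1 < r.end)
        klass[inside] = r.klass

    n_sex = int(round(config.frac_sex_probes * config.n_probes))
    n_auto = config.n_probes - n_sex
    # cluster regions are probed sparsely (arrays tile islands with a
    # handful of probes, not every CpG): at most probes_per_cluster per
    # planted region, background CpGs fill the remainder
    cluster_take: list[np.ndarray] = []
    for r in truth.regions:
        in_r = np.flatnonzero((pos1 - 1 >= r.start) & (pos1 - 1 < r.end))
        want = min(config.probes_per_cluster, in_r.size)
        if want:
            cluster_take.append(rng.choice(in_r, size=want, replace=False))
    n_cluster = sum(t.size for t in cluster_take)
    lc_pool = np.flatnonzero(klass == "LC")
    n_lc = n_auto - n_cluster
    if n_lc < 0:
        raise ValueError("n_probes too small for the planted cluster quota")
    if n_lc > lc_pool.size:
        raise ValueError("not enough background CpG positions for the probe count")
    take_lc = rng.choice(lc_pool, size=n_lc, replace=False)
    idx = np.sort(np.concatenate(cluster_take + [take_lc]))

    rows = {
        "chrom": ["chr1"] * idx.size,
        "pos": pos1[idx].tolist(),
        "true_class": klass[idx].tolist(),
    }
    # sex-chromosome quota, split between chrX and chrY
    for i, chrom in enumerate(("chrX", "chrY")):
        want = n_sex // 2 + (n_sex % 2 if i == 0 else 0)
        cp = _cpg_positions(truth.genome[chrom])
        sel = np.sort(rng.choice(cp, size=min(want, cp.size), replace=False))
        rows["chrom"].extend([chrom] * sel.size)
        rows["pos"].extend(sel.tolist())
        rows["true_class"].extend(["LC"] * sel.size)

    df = pd.DataFrame(rows)
    df["probe"] = [f"cg{i:07d}" for i in range(1, len(df) + 1)]
    df["snp_overlap"] = rng.random(len(df)) < config.frac_snp_overlap
    df["cross_reactive"] = rng.random(len(df)) < config.frac_cross_reactive
    return df[["probe", "chrom", "pos", "true_class", "snp_overlap", "cross_reactive"]]


def _draw_snp_stats(rng: np.random.Generator, n: int, passing: bool) -> dict[str, np.ndarray]:
    """Statistic values strictly inside (passing) the twelve criteria.

    Failing records are derived afterwards by perturbing one statistic.
    """
    return {
        "DAF": rng.uniform(0.06, 0.90, n),
        "GFHOM1": rng.uniform(0.01, 0.50, n),
        "GFHET": rng.uniform(0.06, 0.50, n),
        "HWE2": rng.uniform(0.001, 1.0, n),
        "HET": rng.uniform(0.05, 0.45, n),
        "PI": rng.uniform(0.01, 0.45, n),
        "DDAF": rng.uniform(0.25, 0.80, n),
        "TD": rng.uniform(-2.5, -0.1, n),
        "FST1": rng.uniform(0.06, 0.50, n),
        "UIHS": rng.uniform(1.6, 4.0, n),
        "UXPEHH": rng.uniform(1.1, 4.0, n),
        "XPCLR": rng.uniform(5.5, 60.0, n),
    }


_FAIL_DRAW = {
    "DAF": (0.0, 0.05), "GFHOM1": (0.0, 0.001), "GFHET": (0.0, 0.05),
    "HWE2": (0.0, 0.0001), "HET": (0.5, 1.0), "PI": (0.5, 1.0),
    "DDAF": (0.0, 0.2), "TD": (0.0, 2.0), "FST1": (0.0, 0.05),
    "UIHS": (0.0, 1.5), "UXPEHH": (0.0, 1.0), "XPCLR": (0.0, 5.0),
}


def _make_snps(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_snps
    n_sel = int(round(config.frac_selected_snps * n))
    stats = _draw_snp_stats(rng, n, passing=True)
    selected = np.zeros(n, dtype=bool)
    selected[:n_sel] = True
    # failing SNPs: perturb exactly one randomly chosen statistic past its cutoff
    names = list(STAT_COLUMNS)
    for i in range(n_sel, n):
        name = names[int(rng.integers(len(names)))]
        lo, hi = _FAIL_DRAW[name]
        stats[name][i] = rng.uniform(lo, hi)
    df = pd.DataFrame(stats)
    df.insert(0, "pos", rng.integers(1, config.genome_length + 1, size=n))
    df.insert(0, "chrom", "chr1")
    df.insert(0, "rsid", [f"rs{i:06d}" for i in range(1, n + 1)])
    df["selected"] = selected
    # construction contract check
    got = SelectionThresholds().passes(df)
    assert bool(np.all(got == selected)), "SNP construction violated the filter contract"
    return df


def draw_beta_values(
    mean: np.ndarray, dispersion: np.ndarray, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-probe beta draws with SD = 2*dispersion*sqrt(mean*(1-mean)).

    A dispersion of exactly zero yields identical values across samples
    (every individual shares the probe's true mean), so downstream MV is 0.
    """
    mean = np.asarray(mean, dtype=float)
    disp = np.asarray(dispersion, dtype=float)
    if np.any(disp >= 0.5) or np.any(disp < 0):
        raise ValueError("dispersion must lie in [0, 0.5)")
    out = np.repeat(mean[:, None], n_samples, axis=1)
    live = disp > 0
    if live.any():
        kappa = 1.0 / (4.0 * disp[live] ** 2) - 1.0
        out[live] = rng.beta(
            np.outer(mean[live] * kappa, np.ones(n_samples)),
            np.outer((1.0 - mean[live]) * kappa, np.ones(n_samples)),
        )
    return out


def simulate_betas(
    config: SimulationConfig, truth: SyntheticTruth
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Beta matrix, sample metadata and probe manifest.

    Also enriches ``truth`` with the probe table (class, conservation
    score, RSP flag, true mean and dispersion), the gene/TSS table, the
    gene-set collection and the SNP table, so that
    :func:`simulate_selection_inputs` can materialise consistent tracks.
    """
    if not truth.regions and (config.n_hc or config.n_ic):
        raise ValueError("truth has no regions; run simulate_genome first")
    rng = np.random.default_rng(config.seed + 1)
    probes = _place_probes(config, truth, rng)
    n = len(probes)

    # genes: TSS at randomly chosen autosomal probe positions
    auto = probes[probes["chrom"] == "chr1"]
    tss_idx = rng.choice(len(auto), size=min(config.n_genes, len(auto)), replace=False)
    genes = pd.DataFrame(
        {
            "gene": [f"GENE{i:04d}" for i in range(1, len(tss_idx) + 1)],
            "chrom": "chr1",
            "tss": np.sort(auto["pos"].to_numpy()[tss_idx]),
            "strand": rng.choice(["+", "-"], size=len(tss_idx)),
        }
    )

    # gene sets: one planted high-MV, one planted low-MV, plus random fillers
    shuffled = list(rng.permutation(genes["gene"].to_numpy()))
    k = config.planted_set_size
    gene_sets = {
        "PLANTED_HIGH_MV": sorted(shuffled[:k]),
        "PLANTED_LOW_MV": sorted(shuffled[k : 2 * k]),
    }
    rest = shuffled[2 * k :]
    for j in range(config.n_random_sets):
        size = int(rng.integers(config.random_set_size[0], config.random_set_size[1] + 1))
        gene_sets[f"RANDOM_SET_{j + 1:02d}"] = sorted(
            rng.choice(rest, size=min(size, len(rest)), replace=False).tolist()
        )
    planted_direction = {"PLANTED_HIGH_MV": "high", "PLANTED_LOW_MV": "low"}

    snps = _make_snps(config, rng)

    # conservation: conserved_frac of probes get positive scores
    conserved = rng.random(n) < config.conserved_frac
    score = np.where(conserved, rng.uniform(0.1, 6.18, n), rng.uniform(-8.0, -0.1, n))

    # RSP flag: within half_window of a selected SNP (chr1 only)
    sel_pos = np.sort(snps.loc[snps["selected"], "pos"].to_numpy(dtype=np.int64))
    rsp = np.zeros(n, dtype=bool)
    if sel_pos.size:
        on1 = probes["chrom"].to_numpy() == "chr1"
        ppos = probes["pos"].to_numpy(dtype=np.int64)
        lo = np.searchsorted(sel_pos, ppos - config.half_window, side="left")
        hi = np.searchsorted(sel_pos, ppos + config.half_window, side="right")
        rsp = on1 & (hi > lo)

    # promoter membership of the planted sets
    tss_by_set = {
        name: np.sort(genes.set_index("gene").loc[members, "tss"].to_numpy(dtype=np.int64))
        for name, members in (("PLANTED_HIGH_MV", gene_sets["PLANTED_HIGH_MV"]),
                              ("PLANTED_LOW_MV", gene_sets["PLANTED_LOW_MV"]))
    }

    def _near(tss_sorted: np.ndarray) -> np.ndarray:
        ppos = probes["pos"].to_numpy(dtype=np.int64)
        lo = np.searchsorted(tss_sorted, ppos - config.promoter_flank, side="left")
        hi = np.searchsorted(tss_sorted, ppos + config.promoter_flank, side="right")
        return (probes["chrom"].to_numpy() == "chr1") & (hi > lo)

    in_high = _near(tss_by_set["PLANTED_HIGH_MV"])
    in_low = _near(tss_by_set["PLANTED_LOW_MV"])

    # true mean beta per probe, class-dependent
    klass = probes["true_class"].to_numpy()
    mean = np.empty(n)
    for c, (a, b) in {"HC": (1.0, 6.0), "IC": (2.0, 2.0), "LC": (2.5, 1.2)}.items():
        sel = klass == c
        mean[sel] = rng.beta(a, b, size=int(sel.sum()))
    mean = np.clip(mean, 0.02, 0.98)

    # dispersion: class level, scaled by planted couplings
    base = np.select([klass == "HC", klass == "IC"], [config.hc_mv_sd, config.ic_mv_sd],
                     default=config.lc_mv_sd)
    disp = base.astype(float)
    disp[in_high] *= config.high_set_factor
    disp[in_low] *= config.low_set_factor
    disp[rsp] *= config.rsp_mv_shrink
    cons_factor = 1.0 - config.gerp_mv_slope * np.clip(score, 0.0, None) / 6.18
    disp *= cons_factor
    # iid per-probe heterogeneity: real MV distributions are heavy-tailed and
    # probe-to-probe spread within a class dwarfs the class medians; the
    # median multiplier is 1 so class ordering is preserved
    if config.dispersion_noise_sd > 0:
        disp *= np.exp(rng.normal(0.0, config.dispersion_noise_sd, size=n))
    disp = np.clip(disp, 1e-4, 0.49)

    betas = draw_beta_values(mean, disp, config.n_samples, rng)
    if config.frac_missing > 0:
        mask = rng.random(betas.shape) < config.frac_missing
        betas = np.where(mask, np.nan, betas)

    sample_ids = [f"S{i:03d}" for i in range(1, config.n_samples + 1)]
    beta_df = pd.DataFrame(betas, index=pd.Index(probes["probe"], name="probe"),
                           columns=sample_ids)
    metadata = pd.DataFrame(
        {
            "sample": sample_ids,
            "sex": ["M" if i % 2 == 0 else "F" for i in range(config.n_samples)],
            "age": rng.integers(30, 71, size=config.n_samples),
            "status": np.where(rng.random(config.n_samples) < config.frac_other_status,
                               "other", "healthy"),
        }
    )
    manifest = probes[["probe", "chrom", "pos", "snp_overlap", "cross_reactive"]].copy()

    probe_truth = probes[["probe", "chrom", "pos", "true_class"]].copy()
    probe_truth["score"] = score
    probe_truth["rsp"] = rsp
    probe_truth["in_high_set"] = in_high
    probe_truth["in_low_set"] = in_low
    probe_truth["true_mean"] = mean
    probe_truth["dispersion"] = disp
    truth.probes = probe_truth
    truth.genes = genes
    truth.gene_sets = gene_sets
    truth.planted_direction = planted_direction
    truth.snps = snps
    return beta_df, metadata, manifest


def simulate_selection_inputs(
    config: SimulationConfig, truth: SyntheticTruth
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict[str, list[str]]]:
    """Materialise the conservation track, SNP table, TSS table and gene sets.

    Returns (gerp_track, snp_table, tss_annotation, gene_sets); the track
    has one single-base interval per probe carrying its true score.
    """
    if truth.probes is None:
        raise ValueError("truth has no probe table; run simulate_betas first")
    p = truth.probes.sort_values(["chrom", "pos"])
    track = pd.DataFrame(
        {
            "chrom": p["chrom"].to_numpy(),
            "start": p["pos"].to_numpy(dtype=np.int64) - 1,
            "end": p["pos"].to_numpy(dtype=np.int64),
            "score": p["score"].to_numpy(dtype=float),
        }
    ).reset_index(drop=True)
    snp_cols = ["rsid", "chrom", "pos", *STAT_COLUMNS]
    return track, truth.snps[snp_cols].copy(), truth.genes.copy(), dict(truth.gene_sets)


def simulate_all(config: SimulationConfig):
    """Run the three generator stages and return everything plus truth."""
    genome, truth = simulate_genome(config)
    beta, metadata, manifest = simulate_betas(config, truth)
    track, snps, tss, gene_sets = simulate_selection_inputs(config, truth)
    return {
        "genome": genome,
        "beta": beta,
        "metadata": metadata,
        "manifest": manifest,
        "gerp_track": track,
        "snps": snps,
        "tss": tss,
        "gene_sets": gene_sets,
        "truth": truth,
    }
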