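"""End-to-end orchestration: simulate -> preprocess -> density ->
conservation -> recent selection -> enrichment, with a machine-readable
report.

Each stage writes its outputs under the run directory and contributes a
section to the JSON report; any stage listed in ``config["skip"]`` is
omitted (downstream stages that need it are then skipped too). The
report's run timestamp lives in its own field so that two runs with the
same configuration and seed produce otherwise identical JSON.
"""

from __future__ import annotations

import copy
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import conservation as cons
from . import density as dens
from . import enrichment as enr
from . import io
from . import preprocess as prep
from . import selection as sel
from .simulate import SimulationConfig, simulate_all
from .stats import decile_bin, format_p, summarize_bins, welch_oneway

logger = logging.getLogger("methvar")

__all__ = ["DEFAULT_CONFIG", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "skip": [],
    "alpha": 0.05,
    "simulate": {},
    "preprocess": {"n_per_sex": 20, "age_min": 30, "age_max": 70},
    "recent": {"half_window": 1000, "B": 10_000, "pool": "all"},
    "enrich": {"flank": 1500, "n_perm": 1000, "min_size": 3, "max_size": 500,
               "weight": 1.0, "p_max": 0.01, "q_max": 0.25},
}

STAGES = ("simulate", "preprocess", "density", "conserve", "recent", "enrich")


def _merge_config(user: dict | None) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for key, val in (user or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    unknown = set(cfg) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return cfg


def run_pipeline(config: dict | None, outdir, seed: int | None = None) -> dict:
    """Run the full synthetic analysis and write a report.

    ``config`` holds per-stage sections (see :data:`DEFAULT_CONFIG`);
    ``seed`` overrides the simulation seed and seeds every stochastic
    stage. Returns the report dict (also written to report.json and
    report.md in ``outdir``).
    """
    cfg = _merge_config(config)
    skip = set(cfg["skip"])
    bad = skip - set(STAGES)
    if bad:
        raise ValueError(f"unknown stages in skip list: {sorted(bad)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    alpha = float(cfg["alpha"])

    sim_kwargs = dict(cfg["simulate"])
    if seed is not None:
        sim_kwargs["seed"] = int(seed)
    sim_cfg = SimulationConfig(**sim_kwargs)
    report: dict = {
        "config": {**cfg, "simulate": sim_cfg.to_dict()},
        "seed_registry": {"simulate": sim_cfg.seed,
                          "bootstrap": sim_cfg.seed + 1000,
                          "gsea": sim_cfg.seed + 2000},
        "alpha": alpha,
    }

    if "simulate" in skip:
        raise ValueError("the packaged pipeline needs the simulate stage; "
                         "use the CLI subcommands to run on external files")
    logger.info("stage simulate: generating synthetic dataset (seed=%d)", sim_cfg.seed)
    data = simulate_all(sim_cfg)
    truth = data["truth"]
    io.write_fasta(data["genome"], outdir / "genome.fa")
    io.write_beta(data["beta"], outdir / "beta.tsv")
    io.write_metadata(data["metadata"], outdir / "metadata.tsv")
    io.write_manifest(data["manifest"], outdir / "manifest.csv")
    io.write_bedgraph(data["gerp_track"], outdir / "gerp.bedGraph")
    io.write_snps(data["snps"], outdir / "snps.tsv")
    io.write_tss_bed(data["tss"], outdir / "tss.bed")
    io.write_gmt(data["gene_sets"], outdir / "gene_sets.gmt")
    io.write_json(truth.summary(), outdir / "truth.json")
    report["simulate"] = truth.summary()

    if "preprocess" in skip:
        _finish(report, outdir)
        return report
    logger.info("stage preprocess: cohort selection and probe filtering")
    pp = cfg["preprocess"]
    cohort = prep.select_cohort(data["metadata"], n_per_sex=pp["n_per_sex"],
                                age_min=pp["age_min"], age_max=pp["age_max"])
    filt = prep.filter_probes(data["manifest"], data["beta"], samples=cohort)
    mv = prep.compute_mv(data["beta"], filt.retained, samples=cohort)
    io.write_mv_table(mv, outdir / "mv.tsv")
    io.write_json(filt.to_dict(), outdir / "filter_report.json")
    labels, _ = decile_bin(mv["mean"].to_numpy())
    deciles = summarize_bins(labels, mv["mv"].to_numpy(), "D")
    report["preprocess"] = {
        "n_cohort": len(cohort),
        "filter": filt.to_dict(),
        "n_mv_probes": int(len(mv)),
        "mv_deciles": [vars(b) for b in deciles],
    }

    if "density" in skip:
        _finish(report, outdir)
        return report
    logger.info("stage density: CpG cluster discovery and classification")
    regions = dens.find_cpg_clusters(outdir / "genome.fa")
    io.write_regions_bed(regions, outdir / "regions.bed")
    assign = dens.assign_density(regions, data["manifest"])
    assign.to_frame().to_csv(outdir / "density_assignment.tsv", sep="\t")
    mv_cls = mv.merge(assign.rename("density_class"), left_on="probe", right_index=True)
    groups = [mv_cls.loc[mv_cls["density_class"] == c, "mv"].to_numpy()
              for c in ("HC", "IC", "LC")]
    dens_test = welch_oneway(groups)
    report["density"] = {
        "n_regions": len(regions),
        "class_counts": {c: int((mv_cls["density_class"] == c).sum())
                         for c in ("HC", "IC", "LC")},
        "welch_oneway": dens_test.to_dict(),
        "median_mv": {c: float(np.median(g))
                      for c, g in zip(("HC", "IC", "LC"), groups)},
        "significant": bool(dens_test.p_value < alpha),
    }

    annotated_all = None
    if "conserve" not in skip:
        logger.info("stage conserve: GERP-RS quartile trend")
        annotated_all, n_dropped = cons.gerp_lookup(data["gerp_track"], data["manifest"])
        nonneg = cons.nonneg_filter(annotated_all)
        nonneg = nonneg[nonneg["probe"].isin(mv["probe"])].reset_index(drop=True)
        annotated_q, bounds = cons.annotate_quartiles(nonneg)
        annotated_q.to_csv(outdir / "gerp_annotated.tsv", sep="\t", index=False,
                           float_format="%.6g")
        trend = cons.mv_by_quartile(mv, annotated_q)
        report["conserve"] = {
            "n_uncovered_probes": int(n_dropped),
            "n_nonneg_probes": int(len(nonneg)),
            "quartile_boundaries": [float(b) for b in bounds],
            **trend.to_dict(),
            "significant": bool(trend.test.p_value < alpha),
        }

    if "recent" not in skip:
        logger.info("stage recent: SNP filter, RSP windows and bootstrap")
        rc = cfg["recent"]
        passing = sel.filter_dbpshp(data["snps"])
        io.write_snps(passing, outdir / "snps_passing.tsv")
        rsp = sel.define_rsp_cpgs(passing, data["manifest"],
                                  half_window=rc["half_window"])
        rsp.to_csv(outdir / "rsp_assignment.tsv", sep="\t", index=False)
        rsp_ids = rsp.loc[rsp["rsp"], "probe"]
        rsp_ids = [p for p in rsp_ids if p in set(mv["probe"])]
        boot = sel.bootstrap_mean_test(mv, rsp_ids, B=rc["B"],
                                       seed=report["seed_registry"]["bootstrap"],
                                       pool=rc["pool"])
        io.write_json(boot.to_dict(), outdir / "bootstrap.json")
        section = {
            "n_snps_passing": int(len(passing)),
            "n_rsp_probes": len(rsp_ids),
            "bootstrap": {**boot.to_dict(), "p_display": format_p(boot.p_value)},
        }
        if annotated_all is not None:
            section["gerp_ttest"] = sel.gerp_compare_groups(annotated_all, rsp)
        report["recent"] = section

    if "enrich" not in skip:
        logger.info("stage enrich: promoter gene ranking and preranked GSEA")
        ec = cfg["enrich"]
        assign_pg = enr.map_probes_to_promoters(data["tss"], data["manifest"],
                                                flank=ec["flank"])
        gmv, n_gene_dropped = enr.gene_mv(assign_pg, mv)
        ranked = enr.zscore_rank(gmv)
        io.write_rnk(ranked, outdir / "gene_mv.rnk")
        results = enr.gsea_preranked(ranked, data["gene_sets"], weight=ec["weight"],
                                     n_perm=ec["n_perm"], min_size=ec["min_size"],
                                     max_size=ec["max_size"],
                                     seed=report["seed_registry"]["gsea"])
        res_df = pd.DataFrame([r.to_dict() for r in results]).drop(columns="leading_edge")
        res_df.to_csv(outdir / "enrichment.tsv", sep="\t", index=False,
                      float_format="%.6g")
        sig = enr.significant_sets(results, p_max=ec["p_max"], q_max=ec["q_max"])
        report["enrich"] = {
            "n_genes_ranked": int(len(ranked)),
            "n_genes_dropped": int(n_gene_dropped),
            "n_sets_tested": len(results),
            "significant_high": [r.name for r in sig["high"]],
            "significant_low": [r.name for r in sig["low"]],
            "results": [
                {k: v for k, v in r.to_dict().items() if k != "leading_edge"}
                for r in results
            ],
        }

    _finish(report, outdir)
    return report


def _finish(report: dict, outdir: Path) -> None:
    io.write_json(report, outdir / "report.json")
    stamped = {"timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")}
    (outdir / "report.md").write_text(_render_markdown(report, stamped["timestamp"]))


def _render_markdown(report: dict, timestamp: str) -> str:
    lines = ["# Methylation variability analysis report", "",
             f"Generated: {timestamp}", ""]
    if "simulate" in report:
        s = report["simulate"]
        lines += ["## Synthetic dataset",
                  f"- probes: {s.get('n_probes')}, planted regions: {s['n_regions']} "
                  f"(HC {s['n_hc_regions']}, IC {s['n_ic_regions']})", ""]
    if "preprocess" in report:
        p = report["preprocess"]
        lines += ["## Preprocessing",
                  f"- cohort size: {p['n_cohort']}",
                  f"- probes retained for MV: {p['n_mv_probes']}",
                  f"- exclusion tally: {p['filter']['tally']}", ""]
    if "density" in report:
        d = report["density"]
        med = d["median_mv"]
        lines += ["## CpG cluster density",
                  f"- class counts: {d['class_counts']}",
                  f"- median MV: HC {med['HC']:.4f}, IC {med['IC']:.4f}, LC {med['LC']:.4f}",
                  f"- Welch one-way p: {d['welch_oneway']['p_display']}", ""]
    if "conserve" in report:
        c = report["conserve"]
        meds = ", ".join(f"{q['quartile']} {q['median_mv']:.4f}" for q in c["per_quartile"])
        lines += ["## Ancient selective pressure (GERP-RS)",
                  f"- median MV by quartile: {meds}",
                  f"- monotone decreasing: {c['monotone_decreasing']}",
                  f"- Welch one-way p: {c['welch_oneway']['p_display']}", ""]
    if "recent" in report:
        r = report["recent"]
        b = r["bootstrap"]
        lines += ["## Recent selective pressure",
                  f"- SNPs passing all 12 criteria: {r['n_snps_passing']}",
                  f"- RSP-CpGs: {r['n_rsp_probes']}",
                  f"- mean MV: RSP {b['rsp_mean_mv']:.4f} vs non-RSP {b['non_rsp_mean_mv']:.4f}",
                  f"- bootstrap p ({b['n_resamples']} resamples): {b['p_display']}", ""]
    if "enrich" in report:
        e = report["enrich"]
        lines += ["## Promoter-level enrichment",
                  f"- genes ranked: {e['n_genes_ranked']}",
                  f"- significant high-MV sets: {e['significant_high']}",
                  f"- significant low-MV sets: {e['significant_low']}", ""]
    return "\n".join(lines)
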