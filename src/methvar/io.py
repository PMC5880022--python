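"""Readers and writers for the plain-text formats the pipeline exchanges.

All writers use fixed float formats and newline conventions so that a run
with the same configuration and seed is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .density import DensityRegion

__all__ = [
    "write_fasta", "write_beta", "read_beta", "write_metadata", "read_metadata",
    "write_manifest", "read_manifest", "write_bedgraph", "read_bedgraph",
    "write_snps", "read_snps", "write_tss_bed", "read_tss_bed",
    "write_gmt", "read_gmt", "write_mv_table", "read_mv_table",
    "write_regions_bed", "read_regions_bed", "write_rnk", "write_json",
]

_NA = "NA"


def write_fasta(genome: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_beta(beta: pd.DataFrame, path) -> None:
    beta.to_csv(path, sep="\t", na_rep=_NA, float_format="%.6f", index_label="probe")


def read_beta(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe", na_values=[_NA])


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_manifest(manifest: pd.DataFrame, path) -> None:
    out = manifest.copy()
    out["snp_overlap"] = out["snp_overlap"].astype(int)
    out["cross_reactive"] = out["cross_reactive"].astype(int)
    out.to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["snp_overlap"] = df["snp_overlap"].astype(bool)
    df["cross_reactive"] = df["cross_reactive"].astype(bool)
    return df


def write_bedgraph(track: pd.DataFrame, path) -> None:
    track.to_csv(path, sep="\t", header=False, index=False,
                 float_format="%.4f", columns=["chrom", "start", "end", "score"])


def read_bedgraph(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end", "score"])


def write_snps(snps: pd.DataFrame, path) -> None:
    snps.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_snps(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tss_bed(tss: pd.DataFrame, path) -> None:
    """BED6: chrom, start(0-based), end, gene, score 0, strand."""
    out = pd.DataFrame(
        {
            "chrom": tss["chrom"],
            "start": tss["tss"].astype(np.int64) - 1,
            "end": tss["tss"].astype(np.int64),
            "gene": tss["gene"],
            "score": 0,
            "strand": tss["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_tss_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "gene", "score", "strand"])
    return pd.DataFrame(
        {"gene": bed["gene"], "chrom": bed["chrom"],
         "tss": bed["start"].astype(np.int64) + 1, "strand": bed["strand"]}
    )


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name in sets:
            fh.write("\t".join([name, "synthetic"] + list(sets[name])) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = parts[2:]
    return sets


def write_mv_table(mv: pd.DataFrame, path) -> None:
    mv.to_csv(path, sep="\t", index=False, float_format="%.8g",
              columns=["probe", "mean", "variance", "mv"])


def read_mv_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_regions_bed(regions: list[DensityRegion], path) -> None:
    """BED4: chrom, start, end, class."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.klass}\n")


def read_regions_bed(path) -> list[DensityRegion]:
    out = []
    with open(path) as fh:
        for line in fh:
            chrom, start, end, klass = line.rstrip("\n").split("\t")[:4]
            out.append(DensityRegion(chrom, int(start), int(end),
                                     float("nan"), float("nan"), klass))
    return out


def write_rnk(ranked: pd.DataFrame, path) -> None:
    ranked.to_csv(path, sep="\t", header=False, index=False,
                  float_format="%.8g", columns=["gene", "z"])


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, Path):
        return str(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
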