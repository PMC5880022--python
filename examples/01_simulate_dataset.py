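"""Generate a complete synthetic methylation study and look at its truth.

Builds the default desk-scale dataset: a 3 Mb genome with planted CpG
clusters, a 5000-probe x 50-sample beta matrix, a conservation track, a
SNP table with the twelve selection statistics, TSS annotation and gene
sets. The printed summary shows what was planted — the ground truth every
downstream example tries to recover.
"""

from methvar import SimulationConfig, simulate_all

config = SimulationConfig(seed=1)
data = simulate_all(config)

summary = data["truth"].summary()
print("planted regions :", summary["n_regions"],
      f"({summary['n_hc_regions']} HC, {summary['n_ic_regions']} IC)")
print("probes per class:", summary["class_counts"])
print("beta matrix     :", data["beta"].shape[0], "probes x",
      data["beta"].shape[1], "samples")
print("selected SNPs   :", summary["n_selected_snps"], "of", summary["n_snps"])
print("RSP probes      :", summary["n_rsp_probes"],
      "(within 1 kb of a selected SNP; their beta spread is shrunk)")
print("gene sets       :", ", ".join(data["gene_sets"]))
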