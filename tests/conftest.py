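import numpy as np
import pandas as pd
import pytest

from methvar.pipeline import run_pipeline
from methvar.simulate import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the packaged default configuration."""
    outdir = tmp_path_factory.mktemp("default_run")
    report = run_pipeline(None, outdir, seed=1)
    return report, outdir


@pytest.fixture(scope="session")
def small_config():
    """Reduced conditions for replicate-heavy tests."""
    return SimulationConfig(
        seed=11,
        n_samples=20,
        n_probes=600,
        genome_length=400_000,
        n_hc=45,
        n_ic=50,
        n_snps=80,
        frac_selected_snps=0.25,
        n_genes=40,
        planted_set_size=3,
        random_set_size=(5, 10),
        frac_missing=0.0,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_all(small_config)


def random_manifest(rng, n, chroms=("chr1", "chr2"), span=100_000):
    """Random probe manifest for oracle-equivalence tests."""
    return pd.DataFrame(
        {
            "probe": [f"cg{i:05d}" for i in range(n)],
            "chrom": rng.choice(chroms, size=n),
            "pos": rng.integers(1, span, size=n),
            "snp_overlap": np.zeros(n, dtype=bool),
            "cross_reactive": np.zeros(n, dtype=bool),
        }
    )
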