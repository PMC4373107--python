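import numpy as np
import pandas as pd
import pytest

from snowballpipe import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Compact planted cohort: 4 modules of 20 genes (2 responsive), 400 loci."""
    config = SimulationConfig(
        n_genes=120, n_modules=4, module_size=20, n_responsive_modules=2,
        n_loci=400, frac_hypo=0.1, seed=11,
    )
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def default_cohort():
    """The default planted scenario (n=30+30, 2 responsive modules of 20,
    mean_shift=1.5, 100 hypomethylated loci at delta beta -0.25 among 10,000)."""
    return simulate_cohort(SimulationConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def write_tsv(path, text):
    path.write_text(text.replace(" | ", "\t"))
    return path


@pytest.fixture()
def toy_expression_tsv(tmp_path):
    return write_tsv(
        tmp_path / "expr.tsv",
        "gene | S1 | S2 | S3 | S4\n"
        "GENE1 | 0.0 | 2.5 | 4.0 | 6.0\n"
        "GENE2 | 1.0 | 1.0 | 9.0 | 9.0\n"
        "GENE3 | 5.5 | 0.0 | 2.0 | 3.0\n",
    )


@pytest.fixture()
def toy_methylation_tsv(tmp_path):
    return write_tsv(
        tmp_path / "beta.tsv",
        "locus | S1 | S2 | S3 | S4\n"
        "cg0001 | 0.10 | 0.20 | 0.80 | 0.90\n"
        "cg0002 | 0.50 | 0.55 | 0.45 | 0.40\n"
        "cg0003 | 0.00 | 1.00 | 0.30 | 0.60\n"
        "cg0004 | 0.25 |  | 0.75 | 0.5\n"
        "cg0005 | 0.33 | 0.66 | 0.99 | 0.01\n",
    )


@pytest.fixture()
def toy_mutations():
    return pd.DataFrame(
        {
            "sample_id": ["A", "C", "C", "D"],
            "gene": ["BRAF", "BRAF", "NRAS", "BRAF"],
            "protein_change": ["V600E", "V600E", "Q61K", "V600K"],
        }
    )
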