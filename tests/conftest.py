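"""Shared simulated fixtures (session-scoped; all data generated in memory)."""

from __future__ import annotations

import numpy as np
import pytest

import polyrisk as pr


@pytest.fixture(scope="session")
def sparse_cohort():
    """Ascertained case-control cohort with a sparse h2 = 0.5 architecture."""
    cfg = pr.SimulationConfig(
        n_pool=4000, m=300, n_cases=400, n_controls=400, h2=0.5,
        prevalence_K=0.25, pi=(0.9, 0.05, 0.03, 0.02), seed=42,
        palindromic_fraction=0.0,
    )
    dataset, pheno, model = pr.simulate_dataset(cfg)
    return cfg, dataset, pheno, model


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with zero heritability: any predictive signal is leakage."""
    cfg = pr.SimulationConfig(
        n_pool=2000, m=200, n_cases=300, n_controls=300, h2=0.0,
        prevalence_K=0.3, seed=7, palindromic_fraction=0.0,
    )
    dataset, pheno, model = pr.simulate_dataset(cfg)
    return cfg, dataset, pheno, model


@pytest.fixture(scope="session")
def toy_dataset():
    """Tiny hand-checkable dataset: 4 samples x 3 SNPs, no missingness."""
    import pandas as pd

    dosages = np.array(
        [
            [0.0, 1.0, 2.0],
            [2.0, 1.0, 0.0],
            [1.0, 0.0, 1.0],
            [1.0, 2.0, 1.0],
        ]
    )
    samples = pd.DataFrame({"fid": list("FFFF"), "iid": ["a", "b", "c", "d"]})
    snps = pd.DataFrame(
        {
            "snp": ["s1", "s2", "s3"],
            "chrom": [1, 1, 1],
            "pos": [100, 200, 300],
            "a1": ["A", "T", "G"],
            "a2": ["G", "C", "A"],
        }
    )
    return pr.GenotypeDataset(dosages, samples, snps)
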