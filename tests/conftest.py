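import numpy as np
import pandas as pd
import pytest

from coexkit.containers import CountMatrix
from coexkit.simulate import SimConfig, simulate_mutant_experiment, simulate_tissue_experiment


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """Two tissues x two replicates, four genes, hand-checkable numbers."""
    samples = ["A_r1", "A_r2", "B_r1", "B_r2"]
    counts = pd.DataFrame(
        [[10, 12, 40, 36], [5, 4, 5, 6], [0, 0, 0, 0], [85, 84, 55, 58]],
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene"),
        columns=samples,
    )
    sample_map = pd.DataFrame(
        {"tissue": ["A", "A", "B", "B"], "genotype": "wild_type", "replicate": [1, 2, 1, 2]},
        index=pd.Index(samples, name="sample"),
    )
    lengths = pd.Series([1000, 500, 2000, 1000], index=counts.index, name="length_bp")
    return CountMatrix(counts=counts, sample_map=sample_map, gene_lengths=lengths)


@pytest.fixture(scope="session")
def module_sim():
    """Planted-module tissue design: 5 x 30-gene modules, 11 tissues, phi=0.05."""
    cfg = SimConfig(
        n_genes=2000,
        n_modules=5,
        module_size=30,
        dispersion=0.05,
        n_planted_de_per_tissue=20,
        regulator_targets=(30, 40, 50, 50),
        seed=11,
    )
    cm, truth = simulate_tissue_experiment(cfg)
    return cfg, cm, truth


@pytest.fixture(scope="session")
def mutant_sim():
    """Paired-mutant design: |log2FC| = 2, phi = 0.1, 3 replicates."""
    cfg = SimConfig(
        n_genes=5000,
        n_modules=5,
        module_size=30,
        dispersion=0.1,
        planted_log2fc=2.0,
        n_planted_de_per_tissue=50,
        regulator_targets=(112, 115, 501, 470),
        seed=7,
    )
    cm, truth = simulate_mutant_experiment(cfg)
    return cfg, cm, truth
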