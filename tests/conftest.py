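import numpy as np
import pandas as pd
import pytest

import endoscope as es


def small_sim_config(seed: int = 1, **overrides) -> es.SimulationConfig:
    """Reduced cohort for fast unit tests (structure, not power)."""
    base = dict(
        n_patients=150,
        n_genes_expressed=500,
        n_low_expression_genes=50,
        n_sex_linked_genes=25,
        module_size_per_endotype=25,
        n_prognostic_genes=10,
        seed=seed,
    )
    base.update(overrides)
    return es.SimulationConfig(**base)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size default cohort shared across the suite (seed 1)."""
    cfg = es.SimulationConfig(seed=1)
    counts, cohort, truth = es.simulate_cohort(cfg)
    return cfg, counts, cohort, truth


@pytest.fixture(scope="session")
def default_processed(default_cohort):
    cfg, counts, cohort, truth = default_cohort
    expr, size_factors, filtered = es.preprocess_counts(counts)
    return cfg, counts, cohort, truth, expr, size_factors


@pytest.fixture(scope="session")
def small_cohort():
    cfg = small_sim_config(seed=3)
    counts, cohort, truth = es.simulate_cohort(cfg)
    return cfg, counts, cohort, truth


def toy_counts(values, chromosomes=None, gene_ids=None, patient_ids=None) -> es.CountMatrix:
    values = np.asarray(values)
    genes = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    patients = patient_ids or [f"p{j}" for j in range(values.shape[1])]
    chrom = pd.Series(chromosomes or ["1"] * len(genes), index=genes)
    return es.CountMatrix(pd.DataFrame(values, index=genes, columns=patients), chrom)
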