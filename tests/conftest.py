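import numpy as np
import pandas as pd
import pytest

from hdbrain import dge, preprocess, simulate


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort shared across tests (400 genes, 10 vs 12)."""
    cfg = simulate.SimulationConfig(n_genes=400, n_cases=10, n_controls=12,
                                    seed=7)
    counts, samples, truth = simulate.simulate_counts(cfg)
    return cfg, counts, samples, truth


@pytest.fixture(scope="session")
def small_de(small_cohort):
    """Preprocessed counts and DE table for the small cohort."""
    _, counts, samples, _ = small_cohort
    groups = samples["condition"]
    filtered, _ = preprocess.filter_low_signal(counts, groups)
    trimmed = preprocess.trim_outlier_counts(filtered, groups)
    table = dge.nb_wald_test(trimmed, samples)
    return trimmed, samples, table


@pytest.fixture
def toy_counts():
    """4 cases / 4 controls enumerated toy matrix for the filter rule."""
    cols = [f"HD_{i}" for i in range(4)] + [f"C_{i}" for i in range(4)]
    data = {
        "all_zero":     [0, 0, 0, 0, 0, 0, 0, 0],
        "all_nonzero":  [5, 3, 8, 2, 4, 6, 1, 9],
        "two_case_one_ctrl": [3, 4, 0, 0, 2, 0, 0, 0],
        "one_case_one_ctrl": [3, 0, 0, 0, 2, 0, 0, 0],
    }
    counts = pd.DataFrame(data, index=cols).T
    groups = pd.Series(["HD"] * 4 + ["control"] * 4, index=cols)
    return counts, groups
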