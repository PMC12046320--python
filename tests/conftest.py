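import numpy as np
import pandas as pd
import pytest

import carsx


@pytest.fixture(scope="session")
def small_cohort():
    """A small paired cohort with a planted signature (shared across tests)."""
    cfg = carsx.SimConfig.cross_species_defaults(
        seed=11, n_genes=300, n_signature=10,
        n_samples_per_group_per_species=10)
    expr_h, expr_m, truth = carsx.simulate_cross_species_cohort(cfg)
    return expr_h, expr_m, truth


@pytest.fixture(scope="session")
def small_cohort_de(small_cohort):
    expr_h, expr_m, truth = small_cohort
    de_h = carsx.moderated_two_group(
        expr_h, carsx.group_series(truth, expr_h.samples),
        "responder", "nonresponder")
    de_m = carsx.moderated_two_group(
        expr_m, carsx.group_series(truth, expr_m.samples),
        "responder", "nonresponder")
    return de_h, de_m, truth


@pytest.fixture(scope="session")
def regulon_population():
    """A small regulon-structured population with planted truth."""
    cfg = carsx.SimConfig.regulon_defaults(
        seed=13, n_genes=60, n_drivers=2, targets_per_driver=8,
        n_samples_per_group_per_species=150)
    expr, truth = carsx.simulate_regulon_population(cfg)
    return expr, truth


@pytest.fixture()
def random_expression():
    rng = np.random.default_rng(7)
    df = pd.DataFrame(rng.normal(5, 2, (40, 12)),
                      index=[f"G{i:03d}" for i in range(40)],
                      columns=[f"s{i:02d}" for i in range(12)])
    return carsx.ExpressionMatrix(df)
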