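"""Shared fixtures: small synthetic studies reused across test modules."""

import warnings

import numpy as np
import pandas as pd
import pytest

from tmenet import (
    ExpressionMatrix, SimConfig, log_tpm_normalize, qc_filter_cells,
    rank_markers, select_ccmgs, simulate_bulk_cohort, simulate_single_cell,
)
from tmenet.pipeline import batch_adjust


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced-size study: fast enough for unit tests, same structure."""
    return SimConfig(cells_per_type=80, n_genes=600, markers_per_type=15,
                     n_bulk_samples=200, seed=7)


@pytest.fixture(scope="session")
def sc_study(small_cfg):
    counts, ann, truth = simulate_single_cell(small_cfg)
    return counts, ann, truth


@pytest.fixture(scope="session")
def sc_normalized(sc_study):
    counts, ann, truth = sc_study
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        counts = qc_filter_cells(counts)
    expr = log_tpm_normalize(counts)
    return expr, ann.loc[counts.columns], truth


@pytest.fixture(scope="session")
def ccmg_catalog(sc_normalized):
    expr, ann, truth = sc_normalized
    table = rank_markers(expr, ann)
    return select_ccmgs(table), truth


@pytest.fixture(scope="session")
def bulk_study(small_cfg):
    bulk, surv, batches, truth = simulate_bulk_cohort(small_cfg)
    return bulk, surv, batches, truth


@pytest.fixture(scope="session")
def adjusted_bulk(bulk_study):
    bulk, surv, batches, truth = bulk_study
    log = ExpressionMatrix(np.log2(bulk.values + 1.0), "log2tpm1")
    return batch_adjust(log, batches), surv, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def exp_survival(rng, x, beta, censor_frac=0.3, scale=100.0):
    """Exponential survival with log-hazard beta*x and uniform censoring."""
    lam = np.exp(beta * np.asarray(x, dtype=float)) / scale
    t_event = rng.exponential(1.0 / lam)
    if censor_frac > 0:
        c = rng.uniform(0, np.quantile(t_event, 1 - censor_frac) * 2, size=len(x))
    else:
        c = np.full(len(x), np.inf)
    time = np.minimum(t_event, c)
    event = (t_event <= c).astype(int)
    return pd.DataFrame({"time": np.maximum(time, 1e-9), "event": event},
                        index=[f"s{i}" for i in range(len(x))])
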