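import numpy as np
import pandas as pd
import pytest

import ppidqol as pq


@pytest.fixture(scope="session")
def final24() -> pq.InstrumentDefinition:
    return pq.load_instrument("ppid-final-24")


@pytest.fixture(scope="session")
def survey37() -> pq.InstrumentDefinition:
    return pq.load_instrument("ppid-survey-37")


@pytest.fixture(scope="session")
def planted12() -> pq.InstrumentDefinition:
    return pq.planted_bank()


def best_answers(instrument: pq.InstrumentDefinition) -> dict[str, str]:
    return {
        it.item_id: min(it.options, key=lambda o: o.score).label
        for it in instrument.items
    }


def worst_answers(instrument: pq.InstrumentDefinition) -> dict[str, str]:
    return {
        it.item_id: max(it.options, key=lambda o: o.score).label
        for it in instrument.items
    }


@pytest.fixture(scope="session")
def default_cohort() -> pq.CohortTable:
    """One seeded survey-bank cohort shared across tests."""
    return pq.simulate_cohort(pq.default_params(), seed=11)


@pytest.fixture(scope="session")
def scored_final_frame(final24) -> pd.DataFrame:
    """Covariates + HRQoL for one seeded final-tool cohort."""
    cohort = pq.simulate_cohort(pq.final_tool_params(), seed=7)
    return pq.analysis_frame(cohort, final24)


def random_score_matrix(rng: np.random.Generator, n_rows: int, n_items: int) -> pd.DataFrame:
    """Correlated integer score matrix for oracle comparisons."""
    shared = rng.standard_normal(n_rows)
    cols = {
        f"i{j}": np.clip(
            np.round(shared * rng.uniform(0, 1.5) + rng.standard_normal(n_rows) * rng.uniform(0.5, 2)),
            -3,
            3,
        )
        for j in range(n_items)
    }
    return pd.DataFrame(cols)
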