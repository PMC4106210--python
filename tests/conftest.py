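import numpy as np
import pandas as pd
import pytest

import nlgxe as n


@pytest.fixture
def make_table():
    """Build a CellMeansTable whose environmental index equals ``x`` exactly.

    The target genotype G01 carries the supplied responses; a complementary
    genotype G02 with responses 2x - y makes the column means equal x, so
    the table satisfies the index invariant without overriding anything.
    """

    def _make(x, y, n_reps=1):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        table = n.CellMeansTable.from_means(
            np.vstack([y, 2.0 * x - y]), n_reps=n_reps
        )
        assert np.allclose(table.env_index, x)
        return table

    return _make


@pytest.fixture
def small_met():
    """A small deterministic linear MET with replication."""
    return n.simulate_met(
        n.MetSimConfig(
            n_genotypes=8, n_environments=10, n_blocks=2,
            family="linear", noise_sd=0.2, seed=11,
        )
    )


def records_from_matrix(values, env_index=None, year="y1"):
    """Long-format single-replicate records from a genotype x env matrix."""
    values = np.asarray(values, float)
    g, e = values.shape
    rows = []
    for i in range(g):
        for j in range(e):
            rows.append(
                {
                    "year": year, "environment": f"E{j+1}", "block": "B1",
                    "genotype": f"G{i+1}", "value": values[i, j],
                }
            )
    return pd.DataFrame(rows)
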