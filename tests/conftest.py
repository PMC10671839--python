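import numpy as np
import pandas as pd
import pytest

from prgscreen import ExpressionMatrix, CohortPair
from prgscreen.synthetic_data import build_paper_fixture


@pytest.fixture(scope="session")
def paper_fixture():
    """The deterministic reference bundle (built once per session)."""
    return build_paper_fixture()


@pytest.fixture(scope="session")
def fixture_screen_result(paper_fixture):
    """Candidate table from the full screen on the reference bundle."""
    import pandas as pd

    from prgscreen.consensus_screen import candidate_screen, rank_and_select_prgs
    from prgscreen.diffexpr import de_table_for_cohorts
    from prgscreen.expression_core import quantile_normalize

    fx = paper_fixture
    tables = []
    for pair in fx.pairs:
        cols = list(pair.sensitive_samples) + list(pair.resistant_samples)
        sub = quantile_normalize(fx.cell_matrix.subset_samples(cols))
        tables.append(de_table_for_cohorts(sub, [pair]))
    de = pd.concat(tables, ignore_index=True)
    table = candidate_screen(de, fx.config)
    return rank_and_select_prgs(table, fx.config), de


def random_matrix(rng, n_genes=20, n_samples=6, index=None):
    vals = rng.normal(8, 2, (n_genes, n_samples))
    idx = index if index is not None else [f"G{i}" for i in range(n_genes)]
    cols = [f"S{j}" for j in range(n_samples)]
    return ExpressionMatrix(pd.DataFrame(vals, index=idx, columns=cols))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_arm_pair():
    return CohortPair("c1", ("S0", "S1", "S2"), ("S3", "S4", "S5"))
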