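import numpy as np
import pandas as pd
import pytest

from cernet import simdata
from cernet.seqio import ExpressionMatrix


def make_matrix(rows: dict[str, list[int]], rna_class: str = "mRNA",
                n_case: int | None = None) -> ExpressionMatrix:
    """Small ExpressionMatrix helper: first half of columns A-ED, rest NC."""
    counts = pd.DataFrame(rows).T
    n = counts.shape[1]
    n_case = n // 2 if n_case is None else n_case
    samples = [f"A{i}" for i in range(n_case)] + [f"N{i}" for i in range(n - n_case)]
    counts.columns = samples
    groups = pd.Series(["A-ED"] * n_case + ["NC"] * (n - n_case), index=samples)
    return ExpressionMatrix(counts=counts.astype(np.int64), groups=groups,
                            rna_class=rna_class)


@pytest.fixture(scope="session")
def reference_config():
    """The reference simulation condition used across the suite."""
    return simdata.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def reference_dataset(reference_config):
    lnc, mir, mrna, truth = simdata.simulate_counts(reference_config)
    targets = simdata.simulate_target_table(reference_config, truth)
    return lnc, mir, mrna, truth, targets
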