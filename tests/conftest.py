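import numpy as np
import pandas as pd
import pytest

from symbionet import ExpressionMatrix, SampleTable, SimConfig, simulate
from symbionet.simulate import Block


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(7)
    data = pd.DataFrame(
        rng.integers(0, 200, size=(6, 8)).astype(float),
        index=[f"g{i}" for i in range(6)],
        columns=[f"s{j}" for j in range(8)],
    )
    return ExpressionMatrix("SOL", data)


@pytest.fixture
def four_culture_sheet():
    rows = []
    for culture, status in (("5L", True), ("5S", True), ("5Pi", False), ("5Tk", False)):
        for rep in (1, 2, 3, 4):
            rows.append(
                {"sample_id": f"{culture}_r{rep}", "culture": culture,
                 "ctput_status": status, "replicate": rep}
            )
    return SampleTable(pd.DataFrame(rows))


@pytest.fixture
def tiny_sim():
    """Scaled-down simulation: fast enough for unit tests."""
    cfg = SimConfig(
        n_genes={"host": 60, "SOL": 30, "cTPut": 20},
        blocks=[
            Block("host", (0, 10), "SOL", (0, 4), sign=1, loading=0.9),
            Block("host", (10, 18), "SOL", (4, 8), sign=-1, loading=0.9),
            Block("host", (18, 24), "cTPut", (0, 4), sign=1, loading=0.9),
            Block("host", (24, 34), "SOL", (8, 12), sign=1, loading=0.9,
                  condition="ctput_positive"),
        ],
        pathway_size=10,
        seed=11,
    )
    return simulate(cfg)
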