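import numpy as np
import pytest

from seednet.datasets import ExpressionDataset, SymbolRegistry


@pytest.fixture
def registry():
    return SymbolRegistry()


@pytest.fixture
def tiny_dataset():
    """4 genes x 5 time points; g2 tracks g1, g3 mirrors g1, g4 is flat."""
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0, 5.0],
            [2.0, 4.0, 6.0, 8.0, 10.0],
            [5.0, 4.0, 3.0, 2.0, 1.0],
            [7.0, 7.0, 7.0, 7.0, 7.0],
        ]
    )
    return ExpressionDataset(
        dataset_id="T1",
        platform="continuous",
        genes=["g1", "g2", "g3", "g4"],
        conditions=["t1", "t2", "t3", "t4", "t5"],
        values=values,
    )


def make_dataset(rows: dict, dataset_id="D", platform="continuous"):
    genes = list(rows)
    values = np.array([rows[g] for g in genes], dtype=float)
    conditions = [f"t{i+1}" for i in range(values.shape[1])]
    return ExpressionDataset(
        dataset_id=dataset_id, platform=platform, genes=genes,
        conditions=conditions, values=values,
    )
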