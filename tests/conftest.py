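import numpy as np
import pandas as pd
import pytest

from sigreverse.signatures import ExpressionMatrix, RankedList


def make_ranked(n: int, stats=None) -> RankedList:
    """Ranked list g1..gn top to bottom, descending statistic by default."""
    genes = np.array([f"g{i}" for i in range(1, n + 1)], dtype=object)
    if stats is None:
        stats = np.arange(n, 0, -1, dtype=float)
    return RankedList(genes, np.asarray(stats, dtype=float))


def matrix_from_rows(rows: dict, samples: list[str]) -> ExpressionMatrix:
    return ExpressionMatrix(
        pd.DataFrame.from_dict(rows, orient="index", columns=samples, dtype=float)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
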