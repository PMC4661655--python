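import numpy as np
import pytest

from miwas import (
    ClusteringConfig,
    SampleTable,
    gb3838_standards,
)


@pytest.fixture
def standards():
    return gb3838_standards()


@pytest.fixture
def small_raw_table():
    """4 samples x 4 indicators, all within the grade-V standard."""
    values = np.array(
        [
            [7.9, 7.6, 1.9, 0.10],
            [8.1, 6.5, 3.0, 0.30],
            [7.7, 5.2, 5.5, 0.80],
            [8.3, 3.5, 9.0, 1.20],
        ]
    )
    return SampleTable(
        values=values,
        indicator_names=["pH", "DO", "COD", "NH3-N"],
        site=np.array(["A", "A", "B", "B"], dtype=object),
    )


@pytest.fixture
def base_config():
    return ClusteringConfig(n_clusters=5, seed=0)


def naive_lloyd(X, init_c, max_iter=100):
    """Independent equal-weight K-means oracle: plain loops, lowest-index
    tie-break, stops when labels repeat."""
    X = np.asarray(X, dtype=float)
    c = np.array(init_c, dtype=float, copy=True)
    k = c.shape[0]
    prev = None
    for _ in range(max_iter):
        labels = np.array(
            [int(np.argmin(((x - c) ** 2).sum(axis=1))) for x in X]
        )
        if prev is not None and (labels == prev).all():
            return labels, c, True
        prev = labels
        for kk in range(k):
            members = X[labels == kk]
            if len(members):
                c[kk] = members.mean(axis=0)
    return prev, c, False
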