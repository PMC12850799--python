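import numpy as np
import pytest

from ccegrade.agreement import ContingencyTable

# Published 2x2 cross-tabulations of overall acceptability (rows = algorithm,
# columns = readers), for the mean and median summary statistics.
TABLE2_MEAN = np.array([[26, 24], [196, 596]])
TABLE2_MEDIAN = np.array([[30, 29], [192, 591]])


@pytest.fixture
def table2_mean() -> ContingencyTable:
    return ContingencyTable(TABLE2_MEAN)


@pytest.fixture
def table2_median() -> ContingencyTable:
    return ContingencyTable(TABLE2_MEDIAN)


def quantile_oracle(values, q, method="linear"):
    """Sort-based quantile, independent of numpy.percentile.

    Linear: rank h = (n-1) q, interpolate between floor(h) and ceil(h).
    Nearest: the order statistic at round(h) (half away from zero).
    """
    xs = sorted(float(v) for v in values)
    n = len(xs)
    h = (n - 1) * (q / 100.0)
    lo = int(np.floor(h))
    hi = int(np.ceil(h))
    if method == "linear":
        return xs[lo] + (h - lo) * (xs[hi] - xs[lo])
    if method == "nearest":
        frac = h - lo
        idx = lo if frac < 0.5 else hi
        return xs[idx]
    raise ValueError(method)


def kappa_oracle(counts, weights=None):
    """Brute-force weighted kappa by explicit double sums."""
    counts = np.asarray(counts, dtype=float)
    k = counts.shape[0]
    n = counts.sum()
    if weights is None:
        weights = [[1.0 if i == j else 0.0 for j in range(k)] for i in range(k)]
    po = 0.0
    pe = 0.0
    for i in range(k):
        for j in range(k):
            o_ij = counts[i, j] / n
            e_ij = (counts[i, :].sum() / n) * (counts[:, j].sum() / n)
            po += weights[i][j] * o_ij
            pe += weights[i][j] * e_ij
    return (po - pe) / (1.0 - pe)


def random_table(rng, k, max_count=60):
    """A random k x k count table guaranteed non-degenerate (pe < 1)."""
    while True:
        t = rng.integers(0, max_count, (k, k))
        if t.sum() == 0:
            continue
        p = t / t.sum()
        pe = float(np.sum(p.sum(axis=1) * p.sum(axis=0)))
        if pe < 1.0 - 1e-9:
            return t
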