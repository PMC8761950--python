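import numpy as np
import pandas as pd
import pytest


def long_table(values: np.ndarray, traits: list[str] | None = None) -> pd.DataFrame:
    """Tidy table from a genotypes x blocks (x traits) array."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    g_n, r, t = arr.shape
    traits = traits or [f"trait{k + 1}" for k in range(t)]
    rows = [
        (f"g{i + 1}", f"b{j + 1}", traits[k], arr[i, j, k])
        for i in range(g_n)
        for j in range(r)
        for k in range(t)
    ]
    return pd.DataFrame(rows, columns=["genotype", "block", "trait", "value"])


def brute_force_strata(y: np.ndarray) -> tuple[float, float, float]:
    """Textbook double-loop RCBD sums of squares (genotype, block, error)."""
    y = np.asarray(y, dtype=float)
    g_n, r = y.shape
    grand = sum(y[i, j] for i in range(g_n) for j in range(r)) / (g_n * r)
    ss_t = ss_g = ss_b = 0.0
    for i in range(g_n):
        gm = sum(y[i, j] for j in range(r)) / r
        for j in range(r):
            bm = sum(y[k, j] for k in range(g_n)) / g_n
            ss_t += (y[i, j] - grand) ** 2
            ss_g += (gm - grand) ** 2
            ss_b += (bm - grand) ** 2
    return ss_g, ss_b, ss_t - ss_g - ss_b


@pytest.fixture
def toy_table() -> pd.DataFrame:
    """3 genotypes x 2 blocks with MS_G = 8, MS_B = 6, MS_E = 0 by hand."""
    return long_table(np.array([[2.0, 4.0], [4.0, 6.0], [6.0, 8.0]]))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
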