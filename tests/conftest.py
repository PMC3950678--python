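import numpy as np
import pytest

from causanet.data_io import PhenotypeLabels


@pytest.fixture
def balanced_labels():
    """Factory for two balanced phenotype groups labelled A/B."""

    def make(n1: int, n2: int | None = None) -> PhenotypeLabels:
        n2 = n1 if n2 is None else n2
        ids = [f"s{i:03d}" for i in range(n1 + n2)]
        return PhenotypeLabels(ids, ["A"] * n1 + ["B"] * n2)

    return make


def exact_corr_pair(rng: np.random.Generator, n: int, rho: float) -> tuple[np.ndarray, np.ndarray]:
    """Two vectors with *exactly* the requested empirical Pearson correlation.

    Built by orthonormalizing two random vectors (after centering) and
    mixing them, so the sample correlation equals rho to machine precision.
    """
    a = rng.normal(size=n)
    b = rng.normal(size=n)
    a = a - a.mean()
    a = a / np.linalg.norm(a)
    b = b - b.mean()
    b = b - (b @ a) * a
    b = b / np.linalg.norm(b)
    x = a
    y = rho * a + np.sqrt(1 - rho**2) * b
    return x, y
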