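import numpy as np
import pandas as pd
import pytest

from refstab.datamodel import CtMatrix


def random_ct_matrix(
    rng: np.random.Generator, n_genes: int, n_units: int
) -> CtMatrix:
    """A complete random Ct matrix with realistic baselines and noise."""
    base = rng.uniform(18, 32, size=n_genes)
    vals = base[:, None] + rng.normal(0, 1.0, size=(n_genes, n_units))
    genes = [f"g{i:02d}" for i in range(n_genes)]
    units = [f"u{j:02d}" for j in range(n_units)]
    return CtMatrix(pd.DataFrame(vals, index=genes, columns=units))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def small_matrix(rng) -> CtMatrix:
    return random_ct_matrix(rng, 5, 6)


def as_rows(cm: CtMatrix) -> dict[str, list[float]]:
    """CtMatrix -> plain dict-of-lists for the brute-force oracles."""
    return {g: [float(v) for v in cm.values.loc[g]] for g in cm.genes}
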