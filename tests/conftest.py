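import numpy as np
import pandas as pd
import pytest

from thermoherd.pedigree import Pedigree


@pytest.fixture
def trio() -> Pedigree:
    """Sire, dam (unrelated founders) and one offspring."""
    return Pedigree.from_frame(
        pd.DataFrame({"animal": ["S", "D", "O"], "sire": ["0", "0", "S"], "dam": ["0", "0", "D"]})
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)


def random_pd(rng: np.random.Generator, n: int, scale: float = 1.0) -> np.ndarray:
    """A random symmetric positive-definite matrix."""
    a = rng.standard_normal((n, n))
    return scale * (a @ a.T + n * np.eye(n))


@pytest.fixture
def tiny_records() -> pd.DataFrame:
    """A handful of insemination records across two herds and two parities."""
    return pd.DataFrame(
        {
            "cow": ["O", "O", "O", "O", "O"],
            "parity": [1, 1, 1, 2, 2],
            "herd": ["H1", "H1", "H2", "H1", "H2"],
            "date": ["2014-06-01", "2014-06-01", "2014-06-02", "2015-06-01", "2015-06-02"],
            "dim": [45, 80, 120, 60, 200],
            "outcome": [1, 0, 0, 1, 0],
            "f_thi": [0.0, 0.0, 4.0, 2.5, 0.0],
        }
    )
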