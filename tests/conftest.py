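import numpy as np
import pytest

from lungspectra import ExpressionMatrix, SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset() -> ExpressionMatrix:
    """A full-size synthetic matrix under the shipped defaults."""
    return generate_dataset(SynthConfig(seed=7))


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """2 genes x 3 subjects, both classes present."""
    return ExpressionMatrix(
        values=np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]),
        labels=np.array(["Adeno", "Adeno", "Meso"], dtype=object),
    )


@pytest.fixture
def separable_blobs():
    """Well-separated 2-D blobs: 40 Adeno around (+2,+2), 20 Meso around (−2,−2)."""
    rng = np.random.default_rng(42)
    Xa = rng.normal([2.0, 2.0], 0.3, (40, 2))
    Xm = rng.normal([-2.0, -2.0], 0.3, (20, 2))
    X = np.vstack([Xa, Xm])
    y = np.array(["Adeno"] * 40 + ["Meso"] * 20, dtype=object)
    return X, y
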