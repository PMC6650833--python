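import numpy as np
import pytest

from playaffect.model import ModelConfig
from playaffect.simulate import neutral_face_template


@pytest.fixture(scope="session")
def template():
    """The packaged neutral 68-point face."""
    return neutral_face_template()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fast_model_cfg():
    """Tiny search for unit tests where the optimizer itself is not under test."""
    return ModelConfig(search_iterations=2, cv_folds=3, cv_repeats=1,
                       max_epochs=150, hidden_sizes=(4, 8), seed=0)


def separable_samples(n_per_class=40, n_features=4, separation=10.0, seed=0,
                      games=("game1", "game2", "game3")):
    """Two Gaussian clusters separated by `separation` sigma, spread over games."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for label, center in (("boredom", 0.0), ("stress", separation)):
        X = rng.standard_normal((n_per_class, n_features)) + center
        for i in range(n_per_class):
            rows.append(
                {**{f"F{j + 1}": X[i, j] for j in range(n_features)},
                 "label": label, "subject": 1, "source": games[i % len(games)],
                 "window_start_s": float(i)}
            )
    return pd.DataFrame(rows)
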