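import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import steppediv as sd

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def make_dataset(
    counts: np.ndarray,
    treatment: str = "grazed",
    subplot_id: str = "s1",
    quadrat_size: float = 0.5,
    env: pd.DataFrame | None = None,
) -> sd.SurveyDataset:
    """Build a SurveyDataset from a (rows, cols, n_species) count array."""
    rows, cols, n_sp = counts.shape
    index = pd.MultiIndex.from_product([range(rows), range(cols)], names=["row", "col"])
    ab = pd.DataFrame(
        counts.reshape(rows * cols, n_sp),
        index=index,
        columns=[f"sp{i:02d}" for i in range(n_sp)],
    )
    if env is not None:
        env = env.set_axis(index, axis=0)
    return sd.SurveyDataset(
        subplot_id=subplot_id,
        treatment=treatment,
        grid_shape=(rows, cols),
        abundance=ab,
        env=env,
        quadrat_size=quadrat_size,
    )


def random_dataset(
    rng: np.random.Generator,
    rows: int = 6,
    cols: int = 6,
    n_species: int = 8,
    lam: float = 1.5,
    **kwargs,
) -> sd.SurveyDataset:
    return make_dataset(rng.poisson(lam, size=(rows, cols, n_species)), **kwargs)


@pytest.fixture(scope="session")
def survey():
    """One full simulated survey: 3 grazed + 3 fenced subplots, 25 species."""
    return sd.simulate_community(sd.steppe_preset(seed=11))


@pytest.fixture(scope="session")
def grazed(survey):
    return [d for d in survey if d.treatment == "grazed"]


@pytest.fixture(scope="session")
def fenced(survey):
    return [d for d in survey if d.treatment == "fenced"]
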