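import numpy as np
import pytest

import srfusion as sf


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny planted cohort (n=24, K=3) for fast pipeline-level tests."""
    spec = sf.SimSpec(
        n_samples=24,
        n_clusters=2,
        cluster_proportions=(0.5, 0.5),
        views=[sf.ViewSpec(n_features=60) for _ in range(3)],
        hazards=(0.004, 0.001),
        seed=11,
    )
    return sf.simulate(spec)


@pytest.fixture(scope="session")
def strong_cohort():
    """The reference planted-partition cohort: n=90, 3 equal clusters, K=3,
    mean shift 3x the noise sd on half the features."""
    return sf.simulate(sf.SimSpec(seed=20240501 % 2**31))


@pytest.fixture(scope="session")
def strong_fit(strong_cohort):
    views, truth, survival = strong_cohort
    model = sf.SRF(views, sf.RunConfig(n_clusters=3, random_seed=5), survival=survival)
    return model, model.fit(), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_view(values, name="toy"):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return sf.OmicsView(
        name=name,
        samples=[f"s{i}" for i in range(n)],
        features=[f"f{j}" for j in range(m)],
        values=values,
    )
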