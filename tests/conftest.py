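import numpy as np
import pytest
from hypothesis import settings

from mimofilter import default_network, simulate
from mimofilter.data import Dataset, FeatureMatrix, TargetSet
from mimofilter.meta_protocols import StudyCollection

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_instance(rng, n_features=6, n_samples=40, m_targets=2):
    """A small random dataset with valid binary targets (>= 3 per class)."""
    X = FeatureMatrix.from_raw(rng.standard_normal((n_samples, n_features)))
    def draw():
        while True:
            y = (rng.standard_normal(n_samples) > 0).astype(int)
            if min(y.sum(), n_samples - y.sum()) >= 3:
                return y
    targets = TargetSet(primary=draw(), secondaries=[draw() for _ in range(m_targets - 1)])
    return X, targets


def make_collection(seed, n_studies=3, n_per=120, sigma=0.1, shuffle=False):
    """Cohorts drawn from one shared causal network (same weights, new
    samples), mimicking a multi-study design with a common biology.
    With ``shuffle=True`` the targets are permuted per study, severing
    every feature-target association (a null control)."""
    spec = default_network(seed, sigma)
    rng = np.random.default_rng(seed + 1)
    studies = []
    for s in range(n_studies):
        ds = simulate(spec, n_per, seed + 100 + s)
        if shuffle:
            perm = rng.permutation(n_per)
            ds = Dataset(
                features=ds.features,
                targets=TargetSet(
                    primary=ds.targets.primary[perm],
                    secondaries=[t[perm] for t in ds.targets.secondaries],
                ),
                truth=ds.truth,
                name=f"study{s}",
            )
        else:
            ds.name = f"study{s}"
        studies.append(ds)
    return StudyCollection(studies=studies, names=[f"study{s}" for s in range(n_studies)])


@pytest.fixture
def small_sim():
    spec = default_network(5, 0.1)
    return simulate(spec, 100, 55)
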