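import pytest

from delta import load_dataset, make_analytic_world, make_world, prepare_baseline
from delta.synthetic_fixtures import WorldSpec


@pytest.fixture(scope="session")
def analytic_dir(tmp_path_factory):
    """The fixed closed-form world (2 groups, 3 items), written once."""
    return make_analytic_world(tmp_path_factory.mktemp("analytic"))


@pytest.fixture(scope="session")
def analytic_dataset(analytic_dir):
    return load_dataset(analytic_dir)


@pytest.fixture(scope="session")
def analytic_shares(analytic_dataset):
    return prepare_baseline(analytic_dataset)


@pytest.fixture(scope="session")
def mini_world(tmp_path_factory):
    """Factory: seeded mini world directory, cached per seed."""
    cache = {}

    def factory(seed: int = 0, **kwargs):
        key = (seed, tuple(sorted(kwargs.items())))
        if key not in cache:
            out = tmp_path_factory.mktemp(f"mini{seed}")
            cache[key] = make_world(WorldSpec(seed=seed, shape="mini", **kwargs), out)
        return cache[key]

    return factory
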