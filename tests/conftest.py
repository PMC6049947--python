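import pytest
from hypothesis import HealthCheck, settings

from memodel.builder import build_me_model
from memodel.solver import bisect_max_growth
from memodel.toy import generate_toy_organism

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_bundle(tmp_path_factory):
    """Full-difficulty toy organism, seed 1, 10 coding genes."""
    directory = tmp_path_factory.mktemp("toy_full")
    return generate_toy_organism(directory, n_genes=10, seed=1, difficulty="full")


@pytest.fixture(scope="session")
def toy_model(toy_bundle):
    return build_me_model(toy_bundle.build_inputs())


@pytest.fixture(scope="session")
def toy_model_11(tmp_path_factory):
    """Full toy with one filler gene that belongs to no complex."""
    directory = tmp_path_factory.mktemp("toy_11")
    bundle = generate_toy_organism(directory, n_genes=11, seed=1, difficulty="full")
    return build_me_model(bundle.build_inputs())


@pytest.fixture(scope="session")
def toy_minimal(tmp_path_factory):
    directory = tmp_path_factory.mktemp("toy_min")
    bundle = generate_toy_organism(directory, n_genes=3, seed=1,
                                   difficulty="minimal")
    return build_me_model(bundle.build_inputs())


@pytest.fixture(scope="session")
def toy_solution(toy_model):
    """Bisection solution of the seed-1 toy at tight tolerance."""
    return bisect_max_growth(toy_model, 0.0, 2.0, 1e-9)
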