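import pytest

from germscreen import SimConfig, build_dc_matrix, evaluate, generate_screen


@pytest.fixture(scope="session")
def default_screen():
    """One default two-replicate synthetic screen, fixed seed."""
    return generate_screen(SimConfig(rng_seed=123))


@pytest.fixture(scope="session")
def dc_rep1(default_screen):
    return build_dc_matrix(default_screen, 1)


@pytest.fixture(scope="session")
def ev_rep1(dc_rep1):
    return evaluate(dc_rep1)
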