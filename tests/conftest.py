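import numpy as np
import pytest

from ernoed import (NetworkModel, ReactionSpec, ReactorConfig, FlowProfile,
                    assemble_salvage_network)


@pytest.fixture(scope="session")
def salvage_model():
    model = assemble_salvage_network()
    model.compiled  # compile kinetics once for the whole session
    return model


@pytest.fixture(scope="session")
def reactor():
    return ReactorConfig()


@pytest.fixture(scope="session")
def nominal(salvage_model):
    return salvage_model.nominal_parameters()


@pytest.fixture(scope="session")
def three_segment_profile(reactor):
    """Short three-segment schedule exercising all positive pump levels."""
    low, mid, high = reactor.positive_levels
    return FlowProfile.from_segments([
        (30.0, [low, low, low, mid, high, mid]),
        (30.0, [high, mid, low, low, mid, low]),
        (30.0, [mid, high, mid, low, low, low]),
    ])


@pytest.fixture(scope="session")
def toy_model():
    """Single-reaction toy sharing the reactor's six inlet substrates."""
    species = ("uracil", "GMP", "adenine", "ATP", "PEP", "PRPP",
               "UMP", "PPi")
    rxn = ReactionSpec(
        id="UPRT", enzyme="UPRT",
        substrates={"uracil": 1, "PRPP": 1}, products={"UMP": 1, "PPi": 1},
        reversible=False, rate_law="irreversible_mm",
        sites=(
            (("uracil", "UPRT.Km_uracil"), ("UMP", "UPRT.Km_UMP")),
            (("PRPP", "UPRT.Km_PRPP"), ("PPi", "UPRT.Km_PPi")),
        ),
    )
    model = NetworkModel(species, ("UPRT",), (rxn,))
    model.compiled
    return model


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def truth_cache(salvage_model, reactor):
    """Memoised ground-truth factory (draws are deterministic per seed)."""
    from ernoed import make_ground_truth
    cache = {}

    def get(seed):
        if seed not in cache:
            cache[seed] = make_ground_truth(seed, salvage_model, reactor)
        return cache[seed]

    return get
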