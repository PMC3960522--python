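"""Shared fixtures: expensive simulations are session-scoped."""

import numpy as np
import pytest

import methanokin as mk


@pytest.fixture(scope="session")
def network():
    return mk.default_network()


@pytest.fixture(scope="session")
def methanol_alloc():
    return mk.load_allocation("methanol")


@pytest.fixture(scope="session")
def methanol_tc():
    """Methanol growth over 400 h under the default study conditions."""
    return mk.run(mk.Scenario(duration_h=400.0, sample_h=0.5))


@pytest.fixture(scope="session")
def acetate_tc():
    """Acetate growth over 400 h under the default study conditions."""
    return mk.run(mk.Scenario.acetate(duration_h=400.0, sample_h=0.5))


@pytest.fixture(scope="session")
def methanol_exhaustion_tc():
    """Methanol run integrated all the way to substrate exhaustion."""
    return mk.run(mk.Scenario(duration_h=30000.0, sample_h=10.0))


@pytest.fixture(scope="session")
def methanol_ranking():
    """Enzyme sensitivity ranking for methanol growth (peak growth rate)."""
    from methanokin.sensitivity import rank_enzymes

    enzymes = ["Mcr", "Mtr", "Rnf", "Fpo", "MtaCBA2", "HdrDE", "Mer",
               "MtaCBA1"]
    return rank_enzymes(mk.Scenario(duration_h=400.0, sample_h=1.0), enzymes)


@pytest.fixture(scope="session")
def acetate_ranking():
    from methanokin.sensitivity import rank_enzymes

    enzymes = ["Mer", "Mcr", "HdrDE", "Rnf", "Mtr"]
    return rank_enzymes(mk.Scenario.acetate(duration_h=400.0, sample_h=1.0),
                        enzymes)


@pytest.fixture(scope="session")
def random_states(network):
    """Random positive state vectors for algebraic derivative checks."""
    model = mk.KineticGrowthModel(scenario=mk.Scenario())
    rng = np.random.default_rng(42)
    n = len(model.dynamic_species)
    states = rng.uniform(0.0, 5.0, size=(100, n + 1))
    states[:, -1] = rng.uniform(0.05, 2.0, 100)  # cell mass, mg
    return model, states
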