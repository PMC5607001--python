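import numpy as np
import pytest

from lamdec.rates import smoothed_rates
from lamdec.synthetic import GeneratorConfig, generate_session
from lamdec.visuomotor import visuomotor_index


@pytest.fixture(scope="session")
def demo_session():
    """A mid-sized synthetic session shared across test modules."""
    return generate_session(GeneratorConfig(n_trials=400, units_per_archetype=(10, 6, 8), seed=42))


@pytest.fixture(scope="session")
def demo_vm_results(demo_session):
    rng = np.random.default_rng(0)
    return [
        visuomotor_index(
            demo_session.spike_times(u.unit_id), demo_session.trials,
            n_boot=500, rng=rng, unit_id=u.unit_id,
        )
        for u in demo_session.units
    ]


@pytest.fixture(scope="session")
def demo_cue_matrices(demo_session):
    return [
        smoothed_rates(demo_session.spike_times(u.unit_id), demo_session.trials, "cue", 50,
                       unit_id=u.unit_id)
        for u in demo_session.units
    ]


@pytest.fixture(scope="session")
def demo_move_matrices(demo_session):
    return [
        smoothed_rates(demo_session.spike_times(u.unit_id), demo_session.trials, "move", 50,
                       unit_id=u.unit_id)
        for u in demo_session.units
    ]
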