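import numpy as np
import pytest

from ersdif import (
    FOCAL,
    REFERENCE,
    ItemParams,
    Persons,
    PopulationSpec,
    sample_persons,
    simulate_responses,
)

STUDY_TAU = (-0.6, 0.0, 0.6)


@pytest.fixture
def symmetric_item():
    """Four-category item with symmetric thresholds centered at delta=0."""
    return ItemParams(beta=1.0, delta=0.0, tau=STUDY_TAU)


@pytest.fixture
def two_group_persons():
    """500 + 500 simulees, no group difference in trait or response style."""
    rng = np.random.default_rng(1234)
    spec = PopulationSpec(n=500, log_omega_mean=0.0, log_omega_var=0.6)
    return Persons.concat(
        sample_persons(spec, rng, group=REFERENCE),
        sample_persons(spec, rng, group=FOCAL),
    )


@pytest.fixture
def null_dataset(two_group_persons):
    """Ten DIF-free items answered by the two equal-style groups."""
    rng = np.random.default_rng(99)
    from ersdif import sample_item_params

    items = sample_item_params(10, rng)
    return simulate_responses(two_group_persons, items, rng)
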