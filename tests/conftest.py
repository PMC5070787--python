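import numpy as np
import pytest

from semitdp.inputs import BinaryImageSet
from semitdp.runner import TopologyConfig, build
from semitdp.sem import SEMParams
from semitdp.synth import DigitFixtureSpec, VoterFixtureSpec, make_digits, make_voters


@pytest.fixture(scope="session")
def voter_fixture():
    """Small logical-model fixture: 3 voters + gate, 4 classes, 4 samples
    per class, discriminability 0.7."""
    return make_voters(VoterFixtureSpec(seed=0))


@pytest.fixture(scope="session")
def digit_dataset():
    """Small synthetic digit task on a 16x16 canvas (supersampled 32x32)."""
    spec = DigitFixtureSpec(samples_per_class=12, image_side=16, flip_rate=0.08, seed=0)
    images, labels = make_digits(spec)
    return BinaryImageSet.from_raw(images, labels)


@pytest.fixture(scope="session")
def quiet_sem_params():
    """Deterministic-noise SEM parameters for reproducible circuit tests."""
    return SEMParams(ou_enabled=False)


@pytest.fixture(scope="session")
def trained_net(digit_dataset, quiet_sem_params):
    """A briefly trained supervised-gating ensemble plus its spike record."""
    config = TopologyConfig(
        n_members=3, gating_mode="supervised", sem=quiet_sem_params
    )
    net = build(digit_dataset, config, seed=7)
    record = net.train(rounds=1)
    return net, record
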