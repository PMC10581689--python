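import numpy as np
import pytest

from hybridarm import ArmMorphology
from hybridarm.cli import default_rom_bounds
from hybridarm.synthmove import SynergyParams, generate_rom_sweep_session, generate_session
from hybridarm.targets import estimate_rom, sample_plausible_targets


@pytest.fixture(scope="session")
def morph():
    return ArmMorphology(upper_arm_len=0.30, forearm_len=0.25, hand_len=0.08)


@pytest.fixture(scope="session")
def rom(morph):
    sweep = generate_rom_sweep_session(default_rom_bounds(), morph, seed=0)
    return estimate_rom(sweep)


@pytest.fixture(scope="session")
def plausible_targets_50(rom, morph):
    return sample_plausible_targets(rom, morph, n=50, seed=3)


@pytest.fixture(scope="session")
def small_session(plausible_targets_50, morph):
    """A ~65 s pick-and-place session over 50 targets (about 5.8k samples)."""
    return generate_session(plausible_targets_50, morph, SynergyParams(), seed=4)


@pytest.fixture(scope="session")
def random_postures(rom):
    rng = np.random.default_rng(12)
    return rng.uniform(rom.bounds[:, 0], rom.bounds[:, 1], size=(1000, 7))
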