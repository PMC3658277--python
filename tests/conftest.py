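"""Shared fixtures: a default synthetic world and PWMs rebuilt from it."""

from __future__ import annotations

import numpy as np
import pytest

from sh3map.pwm import PWM, AlignedPeptideSet, build_pwm
from sh3map.simulate import WorldConfig, gen_world

WORLD_SEED = 1


@pytest.fixture(scope="session")
def world():
    """Default synthetic world at the documented conditions, fixed seed."""
    return gen_world(WorldConfig(), seed=WORLD_SEED)


@pytest.fixture(scope="session")
def rebuilt_pwms(world):
    """PWMs re-estimated from the world's phage peptide tables."""
    return {s.domain_id: build_pwm(s) for s in world.peptide_sets}


@pytest.fixture
def sharp_pwm():
    """One-hot 4-column PWM (consensus PPLP) built from identical peptides."""
    return build_pwm(AlignedPeptideSet("sharp", tuple(["PPLP"] * 50)))


@pytest.fixture
def uniform_pwm():
    return PWM.uniform(5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
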