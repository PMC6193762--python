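import numpy as np
import pytest

from flysin import (AnalysisConfig, ArenaSpec, BarrierSpec, CouplingParams,
                    Trajectory, simulate_dyad)


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()

@pytest.fixture(scope="session")
def arena():
    return ArenaSpec()


@pytest.fixture(scope="session")
def coupled_dyad():
    """A strongly coupled simulated dyad (fixed seed, desk-scale length)."""
    params = CouplingParams(seed=7, immobile_prob=0.0)
    return simulate_dyad(params, BarrierSpec.from_type("open_clear"), n_frames=3000)


def make_trajectory(x, y, fly_id="f0", compartment="left", fps=29.9, valid=None,
                    day=1, session=1, arena_id="arena0"):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if valid is None:
        valid = np.isfinite(x) & np.isfinite(y)
    return Trajectory(fly_id=fly_id, day=day, session=session, arena_id=arena_id,
                      compartment=compartment, frame=np.arange(len(x)),
                      x=x, y=y, valid=valid, fps=fps)
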