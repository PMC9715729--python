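import numpy as np
import pytest

from fibrilsorb.regions import BlockRegion
from fibrilsorb.simulate import TrapSimConfig
from fibrilsorb.trajio import ROLE_FIBRIL_CARBON, ROLE_WATER_OXYGEN, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


def make_trajectory(n_frames=5, n_waters=4, n_carbons=0, box=(10.0, 10.0, 10.0), seed=0, dt=10.0):
    """Small random trajectory with wrapped coordinates."""
    r = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    n = n_carbons + n_waters
    positions = r.random((n_frames, n, 3)) * box
    positions[:, :n_carbons] = positions[0, :n_carbons]  # static carbons
    roles = np.array([ROLE_FIBRIL_CARBON] * n_carbons + [ROLE_WATER_OXYGEN] * n_waters)
    mols = np.concatenate([np.arange(n_carbons), np.arange(n_waters)])
    return Trajectory(
        times=np.arange(n_frames) * dt,
        box=box,
        positions=positions,
        roles=roles,
        mol_index=mols,
    )


def make_block_config(**overrides):
    """Small block-trap simulator config for fast tests."""
    kw = dict(
        box=(4.0, 4.0, 8.0),
        n_waters=300,
        n_frames=300,
        region=BlockRegion((1.4, 1.4, 3.0), (2.6, 2.6, 5.0)),
        seed=11,
    )
    kw.update(overrides)
    return TrapSimConfig(**kw)
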