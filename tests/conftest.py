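import numpy as np
import pytest

from ringff import synth
from ringff.io import AtomRecord, MoleculeTopology, TrajectoryFrame


@pytest.fixture
def diatomic():
    mol, frame = synth.gen_toy_molecule("diatomic")
    return mol


@pytest.fixture
def benzene_like():
    mol, frame = synth.gen_toy_molecule("benzene_like")
    return mol


@pytest.fixture
def random_neutral_molecule():
    """5 random atoms with charges summing to zero, positive masses."""
    rng = np.random.default_rng(42)
    pos = rng.normal(0.0, 0.2, size=(5, 3))
    q = rng.normal(0.0, 0.3, size=5)
    q -= q.mean()
    atoms = [
        AtomRecord(i + 1, f"A{i + 1}", "C", pos[i], float(q[i]), 1, 12.0 + i)
        for i in range(5)
    ]
    return MoleculeTopology("rand5", atoms)


@pytest.fixture
def single_frame():
    return TrajectoryFrame(
        time=0.0,
        coordinates=np.array([[0.1, 0.2, 0.3], [0.4, 0.5, 0.6], [0.7, 0.8, 0.9]]),
        box=np.array([2.0, 2.0, 2.0]),
    )
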