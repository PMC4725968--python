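import numpy as np
import pytest

import rigidnet as rn


@pytest.fixture(scope="session")
def helix20():
    return rn.make_helix(20)


@pytest.fixture(scope="session")
def planted_dimer():
    """Toy dimer with two interchain H-bonds and one salt bridge."""
    return rn.make_toy_dimer(
        12,
        planted_interactions=[((5, 5), "hbond", -3.0),
                              ((8, 8), "hbond", -1.0),
                              ((2, 2), "salt_bridge", -10.0)],
        planted_cb_pairs=[((12, 12), 3.83)],
    )


def random_rotation(seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def transformed(structure, seed=0, shift=(5.0, -3.0, 11.0)):
    """Rigid-body rotated/translated copy of a structure."""
    rot = random_rotation(seed)
    out = structure.copy()
    out.set_coords(structure.coords() @ rot.T + np.asarray(shift))
    return out
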