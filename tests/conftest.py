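import numpy as np
import pytest

from nohcg.cg_mapping import BeadTypeTable, build_noh_map
from nohcg.synthetic_systems import ToySpec, make_toy_molecule


@pytest.fixture(scope="session")
def standard_table():
    return BeadTypeTable.standard_protein()


@pytest.fixture(scope="session")
def dimer_spec():
    """Harmonic-bond dimer with methyl-like hydrogen shells."""
    return ToySpec(n_heavy=2, h_counts=(3, 3), bond_k=60.0, lj_epsilon=0.0)


@pytest.fixture(scope="session")
def chain_spec():
    """Five-site chain with mixed hydrogen counts, angles and LJ contacts."""
    return ToySpec(n_heavy=5, h_counts=(3, 2, 1, 2, 3), bond_r0=2.5)


@pytest.fixture()
def dimer_system(dimer_spec, standard_table):
    topo, frame = make_toy_molecule(dimer_spec)
    cg_map = build_noh_map(topo, standard_table)
    return topo, frame, cg_map


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng):
    """Haar-random proper rotation matrix."""
    a = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(a)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
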