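import numpy as np
import pytest

from ionscape.core import Atom, Topology, Trajectory
from ionscape.synthetic import build_duplex


@pytest.fixture(scope="session")
def b_duplex():
    return build_duplex(form="B-DNA")


@pytest.fixture(scope="session")
def z_duplex():
    return build_duplex(form="Z-DNA")


@pytest.fixture(scope="session")
def a_rna():
    return build_duplex(form="A-RNA")


def make_ion_gas(n_ions, box, n_frames, seed, dt=10.0, site_atom=True):
    """Uniform ideal-gas ions, optionally with one static site atom at the
    box center (index 0)."""
    rng = np.random.default_rng(seed)
    atoms = []
    coords_parts = []
    if site_atom:
        atoms.append(Atom("O6", "O", 1, "G", "A", 0.0))
        coords_parts.append(np.full((n_frames, 1, 3), box / 2.0))
    atoms += [Atom("Na", "Na", i + 2, "", "X", 1.0) for i in range(n_ions)]
    coords_parts.append(rng.uniform(0.0, box, size=(n_frames, n_ions, 3)))
    coords = np.concatenate(coords_parts, axis=1)
    offset = 1 if site_atom else 0
    return Trajectory(
        Topology(atoms),
        coords,
        np.array([box] * 3),
        dt=dt,
        species={"Na+": np.arange(offset, offset + n_ions)},
    )
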