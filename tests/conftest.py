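import numpy as np
import pytest

import motifdock as md
from motifdock import fftdock, fixtures, motiflib


@pytest.fixture(scope="session")
def default_spec():
    return md.FixtureSpec(seed=11)


@pytest.fixture(scope="session")
def planted(default_spec):
    """(receptor, native peptide, truth transform) for the standard fixture."""
    return md.make_planted_complex(default_spec)


@pytest.fixture(scope="session")
def receptor(planted):
    return planted[0]


@pytest.fixture(scope="session")
def native_peptide(planted):
    return planted[1]


@pytest.fixture(scope="session")
def native_frag(default_spec):
    return fixtures.native_fragment(default_spec)


@pytest.fixture(scope="session")
def db150(default_spec):
    return md.make_fragment_database(default_spec)


@pytest.fixture(scope="session")
def receptor_grids(receptor, native_frag):
    diam = float(np.ptp(native_frag.backbone_flat(), axis=0).max()) * np.sqrt(3)
    spec = fftdock.auto_grid_spec(receptor, diam, spacing=1.0)
    return fftdock.make_receptor_grids(receptor, spec)


@pytest.fixture(scope="session")
def coarse_rotations():
    return fftdock.generate_rotations(16, seed=3)


def random_fragment(rng, length=5):
    """A FragmentRecord with random coordinates (for metric/cluster tests)."""
    bb = rng.normal(0.0, 4.0, size=(length, 4, 3))
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), length))
    return motiflib.FragmentRecord(source_id="rnd", chain_id="A", start=0,
                                   sequence=seq, backbone=bb)
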