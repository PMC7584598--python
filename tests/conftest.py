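import numpy as np
import pytest

from dynhelix import synthetic as syn
from dynhelix import topology as top
from dynhelix.structures import DomainMap, OligomerFrame


@pytest.fixture(scope="session")
def domain_map():
    return DomainMap()


@pytest.fixture(scope="session")
def wt_helix():
    """Noiseless single-frame 56-monomer wild-type helix plus ground truth."""
    return syn.build_helix(syn.SyntheticHelixSpec())


@pytest.fixture(scope="session")
def wt_helix_topology(wt_helix):
    traj, _ = wt_helix
    return top.assign_topology(traj.frames[0], (0.0, 0.0, 1.0))


@pytest.fixture(scope="session")
def mutant_helix():
    return syn.build_helix(syn.SyntheticHelixSpec(genotype_pattern=syn.ALL_MUTANT))


@pytest.fixture(scope="session")
def wt_dimer():
    return syn.build_dimer("WT", "WT")


@pytest.fixture(scope="session")
def fm_dimer():
    return syn.build_dimer("R465W", "R465W", interface_mode=syn.TIGHT)


def single_monomer_frame(monomer, resolution="coarse_grained"):
    return OligomerFrame(0, [monomer], resolution=resolution)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
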