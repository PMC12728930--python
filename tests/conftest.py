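import numpy as np
import pytest

from glycograft.fixtures import make_toy_pocket, make_toy_pyranose
from glycograft.grafting import ReactiveCenter, ScaffoldComplex, graft
from glycograft.moiety_library import MoietySpec, build_moiety_3d
from glycograft.structio import MolecularStructure


@pytest.fixture(scope="session")
def pyranose():
    return make_toy_pyranose()


@pytest.fixture(scope="session")
def methyl_moiety():
    return build_moiety_3d(MoietySpec("methyl", "C", 0), seed=11)


@pytest.fixture(scope="session")
def phenyl_moiety():
    return build_moiety_3d(MoietySpec("phenyl", "c1ccccc1", 0), seed=12)


@pytest.fixture(scope="session")
def ethanol_moiety():
    return build_moiety_3d(MoietySpec("ethanol", "OCC", 1), seed=13)


@pytest.fixture(scope="session")
def pocket():
    return make_toy_pocket(seed=5, n_atoms=24)


@pytest.fixture()
def grafted_methyl(pyranose, methyl_moiety, pocket):
    scaffold, _centers = pyranose
    sc = ScaffoldComplex(receptor=pocket, scaffold=scaffold.copy())
    center = ReactiveCenter.resolve(sc.scaffold, "O3")
    return graft(sc, center, methyl_moiety)


@pytest.fixture()
def grafted_ethanol(pyranose, ethanol_moiety, pocket):
    scaffold, _centers = pyranose
    sc = ScaffoldComplex(receptor=pocket, scaffold=scaffold.copy())
    center = ReactiveCenter.resolve(sc.scaffold, "O3")
    return graft(sc, center, ethanol_moiety)


@pytest.fixture()
def empty_receptor():
    return MolecularStructure(provenance="empty")
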