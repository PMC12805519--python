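"""Shared fixtures: small molecules, solvent shells, mean-field references."""

import numpy as np
import pytest

from solvgw.embedding import QMRegion, run_coupled_scf, mo_three_center
from solvgw.fixtures import FixtureSpec, generate_solvent_cluster, water_geometry
from solvgw.mm import MMSite, MMTopology


@pytest.fixture(scope="session")
def he_mf_631g():
    qm = QMRegion(["He"], np.zeros((1, 3)), basis="6-31g")
    mf, _ = run_coupled_scf(qm, None)
    return mf


@pytest.fixture(scope="session")
def he_X_mo(he_mf_631g):
    return mo_three_center(he_mf_631g)


@pytest.fixture(scope="session")
def h2_mf_631g():
    qm = QMRegion(["H", "H"], [[0, 0, 0], [0, 0, 1.4]], basis="6-31g")
    mf, _ = run_coupled_scf(qm, None)
    return mf


def make_water_cluster(model: str, seed: int = 7, n: int = 3) -> MMTopology:
    return generate_solvent_cluster(FixtureSpec(seed=seed, n_solvent_molecules=n), model)


@pytest.fixture
def fq_cluster():
    return make_water_cluster("FQ")


@pytest.fixture
def fqfmu_cluster():
    return make_water_cluster("FQFMU")


def make_custom_water(model: str, center, mol_id: int, chi=(0.84, 0.0),
                      eta=(1.4, 1.0), alpha=(1.0, 0.4), fixed=(0.0, 0.0)):
    """Water-like molecule with explicit parameters for limit studies."""
    coords = water_geometry() + np.asarray(center, float)
    out = []
    for k, xyz in enumerate(coords):
        i = 0 if k == 0 else 1
        out.append(MMSite(xyz, mol_id, fixed_charge=fixed[i], chi=chi[i],
                          eta=eta[i], alpha=alpha[i]))
    return out
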