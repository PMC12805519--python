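"""Static reaction-field correction dv_res in the auxiliary fitting basis.

The environment's linear response to a QM test charge induces a reaction
potential dv_res(r, r') that adds to the bare Coulomb interaction.  Projected
onto the auxiliary fitting functions f_P it becomes a symmetric matrix

    dv_res_PQ = - kC^2 [V0 V1] B [V0 V1]^T |_PQ

where V0/V1 are potential/field integrals of the fitting functions at the
polarizable sites and B is the blockwise inverse of the constrained response
system.  The global sign is fixed by the finite-difference oracle below
(re-solving the classical ground state with an explicit test charge): a
reaction field must stabilize the perturbing charge, so the diagonal of
dv_res is non-positive for every model.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_KC
from .mm import (
    BlockResponseSystem,
    EmbeddingModel,
    MMTopology,
    assemble_response_system,
    kernel_T0,
    kernel_T1,
    polarization_potential_at,
    solve_ground_polarization,
)
from .qm import AuxBasis, boys_f0, boys_f1

__all__ = [
    "AuxSiteIntegrals",
    "ReactionMatrix",
    "aux_site_potential_integrals",
    "aux_site_field_integrals",
    "compute_aux_site_integrals",
    "build_reaction_matrix",
    "finite_difference_reaction_oracle",
    "finite_difference_reaction_matrix",
]


@dataclass
class AuxSiteIntegrals:
    """Potential (V0) and field (V1) integrals of fitting functions at MM sites.

    V0[P, t] = int f_P(r) / |r - r_t| dr
    V1[P, t, a] = int f_P(r) (r_a - r_{t,a}) / |r - r_t|^3 dr
    """

    V0: np.ndarray
    V1: np.ndarray


def aux_site_potential_integrals(aux: AuxBasis, sites: np.ndarray) -> np.ndarray:
    """V0[P, t]: Coulomb potential of each fitting function at each site.

    For an s-Gaussian N exp(-a |r-A|^2) this is N (2 pi / a) F0(a |A - r_t|^2),
    finite in the coincident limit (2 sqrt(a/pi) for a unit-charge function).
    """
    sites = np.atleast_2d(np.asarray(sites, float))
    a = aux.exponents[:, None]
    R2 = np.sum((aux.centers[:, None, :] - sites[None, :, :]) ** 2, axis=-1)
    return aux.norms[:, None] * (2 * np.pi / a) * boys_f0(a * R2)


def aux_site_field_integrals(aux: AuxBasis, sites: np.ndarray) -> np.ndarray:
    """V1[P, t, :]: projection of the dipole kernel T1 onto each fitting function.

    Equals the gradient of V0 with respect to the site position:
    for an s-Gaussian, 4 pi N (A - r_t) F1(a |A - r_t|^2).
    """
    sites = np.atleast_2d(np.asarray(sites, float))
    a = aux.exponents[:, None]
    d = aux.centers[:, None, :] - sites[None, :, :]
    R2 = np.sum(d ** 2, axis=-1)
    f1 = boys_f1(a * R2)
    return 4 * np.pi * aux.norms[:, None, None] * d * f1[:, :, None]


def compute_aux_site_integrals(aux: AuxBasis, topology: MMTopology) -> AuxSiteIntegrals:
    """Integrals at the charge-carrying and dipole-carrying sites of a topology."""
    pos = topology.positions
    qi = topology.charge_site_indices
    di = topology.dipole_site_indices
    V0 = aux_site_potential_integrals(aux, pos[qi]) if len(qi) else np.zeros((len(aux), 0))
    V1 = (aux_site_field_integrals(aux, pos[di]) if len(di)
          else np.zeros((len(aux), 0, 3)))
    return AuxSiteIntegrals(V0=V0, V1=V1)


@dataclass
class ReactionMatrix:
    """dv_res projected on the fitting basis; symmetric, zero for EE."""

    matrix: np.ndarray
    model: EmbeddingModel
    kC: float = DEFAULT_KC

    @property
    def n_aux(self) -> int:
        return self.matrix.shape[0]

    def save(self, path) -> None:
        np.savez(path, matrix=self.matrix, model=self.model.value, kC=self.kC)

    @classmethod
    def load(cls, path) -> "ReactionMatrix":
        data = np.load(path, allow_pickle=False)
        return cls(matrix=data["matrix"], model=EmbeddingModel(str(data["model"])),
                   kC=float(data["kC"]))

    def topology_hash(self, topology: MMTopology) -> str:
        h = hashlib.sha256()
        h.update(topology.positions.tobytes())
        h.update(topology.model.value.encode())
        return h.hexdigest()[:16]


def build_reaction_matrix(
    integrals: AuxSiteIntegrals,
    system: BlockResponseSystem | None,
    model: EmbeddingModel | str,
    kC: float = DEFAULT_KC,
    n_aux: int | None = None,
) -> ReactionMatrix:
    """dv_res = -kC^2 [V0 V1] B [V0 V1]^T, model-appropriate blocks only.

    FQ uses the charge block Bqq, DRF the dipole block Bmm, FQFmu all four
    (the cross blocks carry the charge-dipole response channel).  EE gives an
    exactly zero matrix.
    """
    model = EmbeddingModel(model)
    if model is EmbeddingModel.EE:
        if n_aux is None:
            n_aux = integrals.V0.shape[0] if integrals is not None else 0
        return ReactionMatrix(np.zeros((n_aux, n_aux)), model, kC)
    if system is None:
        raise ValueError("a BlockResponseSystem is required for polarizable models")

    V0 = integrals.V0
    V1 = integrals.V1.reshape(integrals.V1.shape[0], -1)
    if V0.shape[1] != system.n_charges or V1.shape[1] != 3 * system.n_dipoles:
        raise ValueError("integrals and response system built from different topologies")

    naux = V0.shape[0]
    M = np.zeros((naux, naux))
    if system.n_charges:
        M += V0 @ system.Bqq @ V0.T
    if system.n_dipoles:
        M += V1 @ system.Bmm @ V1.T
    if system.n_charges and system.n_dipoles:
        cross = V0 @ system.Bqm @ V1.T
        M += cross + cross.T
    M = -(kC ** 2) * M
    return ReactionMatrix(0.5 * (M + M.T), model, kC)


def _explicit_charge_ground_state(topology: MMTopology, position: np.ndarray,
                                  charge: float, kC: float):
    """Classical ground state with an explicit point charge added at ``position``."""
    pos = topology.positions
    n = topology.n_sites
    V = np.zeros(n)
    E = np.zeros((n, 3))
    if charge != 0.0:
        for t in range(n):
            V[t] = charge * kernel_T0(pos[t], position)
            E[t] = charge * kernel_T1(pos[t], position)
    return solve_ground_polarization(topology, V, E, kC=kC)


def finite_difference_reaction_oracle(
    topology: MMTopology,
    r: np.ndarray,
    r_prime: np.ndarray,
    deltaQ: float = 1e-4,
    kC: float = DEFAULT_KC,
) -> float:
    """Reference value of dv_res(r, r') by explicit re-solve.

    Solves the classical stationarity with and without a point charge deltaQ
    at r', evaluates the change of the induced potential at r, divides by
    deltaQ.  Entirely independent of the B-block route; defines the physical
    sign (stabilizing, i.e. dv_res(r, r) <= 0).
    """
    if topology.model is EmbeddingModel.EE:
        return 0.0
    base = _explicit_charge_ground_state(topology, r_prime, 0.0, kC)
    pert = _explicit_charge_ground_state(topology, r_prime, deltaQ, kC)
    v1 = polarization_potential_at(topology, pert, r, kC)
    v0 = polarization_potential_at(topology, base, r, kC)
    return (v1 - v0) / deltaQ


def finite_difference_reaction_matrix(
    topology: MMTopology,
    aux: AuxBasis,
    deltaQ: float = 1e-4,
    kC: float = DEFAULT_KC,
) -> np.ndarray:
    """FD oracle at the matrix level: perturb with the charge density of each
    fitting function (scaled by deltaQ), project the induced potential change
    back on every fitting function."""
    if topology.model is EmbeddingModel.EE:
        return np.zeros((len(aux), len(aux)))
    qi = topology.charge_site_indices
    di = topology.dipole_site_indices
    pos = topology.positions
    n = topology.n_sites
    V0all = aux_site_potential_integrals(aux, pos)
    V1d = aux_site_field_integrals(aux, pos[di]) if len(di) else None
    base = solve_ground_polarization(topology, kC=kC)

    out = np.zeros((len(aux), len(aux)))
    for Q in range(len(aux)):
        V = deltaQ * V0all[Q]
        E = np.zeros((n, 3))
        if V1d is not None:
            # field of the fitting-function charge cloud at the dipole sites:
            # E(r_t) = int f_Q(r)(r_t - r)/|r_t - r|^3 dr = -V1[Q, t]
            E[di] = -deltaQ * V1d[Q]
        pert = solve_ground_polarization(topology, V, E, kC=kC)
        dq = pert.charges - base.charges
        dmu = (pert.dipoles - base.dipoles).reshape(-1)
        col = np.zeros(len(aux))
        if len(qi):
            Vp = aux_site_potential_integrals(aux, pos[qi])
            col += Vp @ dq
        if len(di):
            V1p = aux_site_field_integrals(aux, pos[di]).reshape(len(aux), -1)
            col += V1p @ dmu
        out[:, Q] = kC * col / deltaQ
    return out
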