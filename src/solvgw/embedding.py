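"""Embedded mean field: restricted HF solved with a classical polarizable shell.

The QM region sees the environment through a one-electron embedding operator
(fixed charges plus the current polarization sources); the environment
re-polarizes in the potential and field of the QM nuclei and electron
density.  The two problems are alternated (macro-iterations) until both the
total energy and the polarization state are stationary; for these convex
classical responses the macro-cycle converges to the same stationary point a
fused update would.

The Coulomb constant kC scales the QM<->MM coupling of the *polarizable*
sources only; fixed multipoles couple with the plain Coulomb interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_KC
from .mm import (
    EmbeddingModel,
    MMTopology,
    PolarizationState,
    assemble_response_system,
    kernel_T0,
    kernel_T1,
    solve_ground_polarization,
)
from .qm import AOIntegrals, Molecule, compute_integrals, point_charge_matrix, \
    point_dipole_matrix, rhf

__all__ = [
    "QMRegion",
    "MeanFieldReference",
    "embedding_operator",
    "run_coupled_scf",
    "mo_three_center",
]


@dataclass
class QMRegion:
    """Closed-shell QM subsystem definition (coordinates in Bohr)."""

    symbols: list[str]
    coords: np.ndarray
    charge: int = 0
    multiplicity: int = 1
    basis: str = "sto-3g"
    functional: str = "hf"

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, float))
        if self.multiplicity != 1:
            raise ValueError("only restricted closed-shell references are supported")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("QM coordinates must be finite")
        if self.functional.lower() != "hf":
            raise ValueError(
                "the self-contained backend provides a Hartree-Fock reference only"
            )

    def molecule(self) -> Molecule:
        return Molecule(self.symbols, self.coords, self.charge)


@dataclass
class MeanFieldReference:
    """Embedded SCF reference for the GW step.

    ``vxc_diag`` holds the diagonal exchange(-correlation) potential in the MO
    basis — the embedding operator is *not* part of it, so the GW quasiparticle
    equation uses the plain Sigma_x - vxc difference.
    """

    mo_energy: np.ndarray
    mo_coeff: np.ndarray
    mo_occ: np.ndarray
    vxc_diag: np.ndarray
    e_tot: float
    converged: bool
    ints: AOIntegrals
    n_macro: int = 1

    @property
    def n_electrons(self) -> int:
        return int(round(self.mo_occ.sum()))

    @property
    def homo_index(self) -> int:
        return int(np.where(self.mo_occ > 0)[0].max())

    @property
    def nmo(self) -> int:
        return len(self.mo_energy)


def embedding_operator(polstate: PolarizationState | None, topology: MMTopology,
                       ints: AOIntegrals, kC: float = DEFAULT_KC) -> np.ndarray:
    """One-electron matrix of fixed multipoles plus current polarization sources.

    For electrons (charge -1) a positive MM charge q contributes
    -q <mu|1/|r - r_t||nu>; induced dipoles analogously via the dipole-potential
    integrals.  kC multiplies the polarizable contributions only.
    """
    nao = ints.nao
    v = np.zeros((nao, nao))
    for s in topology.sites:
        if s.fixed_charge != 0.0:
            v -= s.fixed_charge * point_charge_matrix(ints.shells, s.position)
    if polstate is not None:
        for q, i in zip(polstate.charges, polstate.charge_sites):
            if q != 0.0:
                v -= kC * q * point_charge_matrix(ints.shells, topology.sites[i].position)
        for mu, i in zip(polstate.dipoles, polstate.dipole_sites):
            if np.any(mu != 0.0):
                dmat = point_dipole_matrix(ints.shells, topology.sites[i].position)
                v -= kC * np.einsum("a,amn->mn", mu, dmat)
    return v


def qm_potential_field_at_sites(ints: AOIntegrals, dm: np.ndarray,
                                topology: MMTopology) -> tuple[np.ndarray, np.ndarray]:
    """Potential and field of QM nuclei + electron density at every MM site."""
    mol = ints.mol
    n = topology.n_sites
    V = np.zeros(n)
    E = np.zeros((n, 3))
    for t, s in enumerate(topology.sites):
        for z, xyz in zip(mol.charges, mol.coords):
            V[t] += z * kernel_T0(s.position, xyz)
            E[t] += z * kernel_T1(s.position, xyz)
        vmat = point_charge_matrix(ints.shells, s.position)
        V[t] -= np.sum(dm * vmat)
        dmat = point_dipole_matrix(ints.shells, s.position)
        # electrons carry charge -1; their field at the site is +D.V1
        E[t] += np.einsum("amn,mn->a", dmat, dm)
    return V, E


def _nuclear_mm_energy(mol: Molecule, topology: MMTopology,
                       polstate: PolarizationState, kC: float) -> float:
    e = 0.0
    for z, xyz in zip(mol.charges, mol.coords):
        for s in topology.sites:
            if s.fixed_charge != 0.0:
                e += z * s.fixed_charge * kernel_T0(xyz, s.position)
        for q, i in zip(polstate.charges, polstate.charge_sites):
            e += kC * z * q * kernel_T0(xyz, topology.sites[i].position)
        for mu, i in zip(polstate.dipoles, polstate.dipole_sites):
            e += kC * z * float(mu @ kernel_T1(xyz, topology.sites[i].position))
    return e


def _mm_internal_energy(topology: MMTopology, polstate: PolarizationState,
                        system) -> float:
    """chi.q + 1/2 D.A.D + fixed<->polarizable coupling + fixed-fixed Coulomb."""
    e = 0.0
    sites = topology.sites
    # fixed-fixed, intermolecular
    for a in range(len(sites)):
        for b in range(a + 1, len(sites)):
            if sites[a].molecule_id == sites[b].molecule_id:
                continue
            if sites[a].fixed_charge and sites[b].fixed_charge:
                e += (sites[a].fixed_charge * sites[b].fixed_charge
                      * kernel_T0(sites[a].position, sites[b].position))
    if system is None:
        return e
    nq, nmol = system.n_charges, system.n_constraints
    D = np.concatenate([polstate.charges, np.zeros(nmol), polstate.dipoles.ravel()])
    A = system.system_matrix
    e += 0.5 * float(D @ A @ D)
    from .mm import _fixed_source_potential_field
    Vfix, Efix = _fixed_source_potential_field(topology)
    qi, di = polstate.charge_sites, polstate.dipole_sites
    if len(qi):
        chi = np.array([sites[i].chi for i in qi])
        e += float(chi @ polstate.charges) + float(Vfix[qi] @ polstate.charges)
    if len(di):
        e -= float(np.sum(Efix[di] * polstate.dipoles))
    return e


def run_coupled_scf(qm: QMRegion, topology: MMTopology | None = None,
                    kC: float = DEFAULT_KC, conv_tol: float = 1e-8,
                    max_macro: int = 60,
                    clamp_polarization: PolarizationState | None = None,
                    ) -> tuple[MeanFieldReference, PolarizationState]:
    """Alternate SCF cycles with classical re-polarization until stationary.

    Convergence requires both the total energy (<= conv_tol Ha) and the
    polarization state (<= conv_tol max norm) to be stationary between macro
    cycles.  ``clamp_polarization`` freezes the classical sources (used for
    variational checks); an empty/absent MM region reduces to vacuum SCF.
    """
    mol = qm.molecule()
    ints = compute_integrals(mol, qm.basis)

    if topology is None or topology.n_sites == 0:
        res = rhf(ints)
        mf = _pack(res, ints)
        empty = PolarizationState(np.zeros(0), np.zeros((0, 3)), np.zeros(0))
        return mf, empty

    polarizable = topology.model is not EmbeddingModel.EE
    system = assemble_response_system(topology) if polarizable else None
    polstate = PolarizationState.zero(topology)
    if clamp_polarization is not None:
        polstate = clamp_polarization

    e_prev = np.inf
    res = None
    converged = False
    n_macro = 0
    for macro in range(max_macro):
        n_macro = macro + 1
        v_emb = embedding_operator(polstate, topology, ints, kC)
        e_nuc_mm = _nuclear_mm_energy(mol, topology, polstate, kC)
        e_mm = _mm_internal_energy(topology, polstate, system if polarizable else None)
        res = rhf(ints, v_ext=v_emb, extra_e_nuc=e_nuc_mm + e_mm)
        if not polarizable or clamp_polarization is not None:
            converged = res.converged
            break
        V, E = qm_potential_field_at_sites(ints, res.dm, topology)
        new_state = solve_ground_polarization(topology, V, E, system=system, kC=kC)
        dpol = 0.0
        if len(new_state.charges):
            dpol = max(dpol, np.max(np.abs(new_state.charges - polstate.charges)))
        if len(new_state.dipoles):
            dpol = max(dpol, np.max(np.abs(new_state.dipoles - polstate.dipoles)))
        de = abs(res.e_tot - e_prev)
        polstate = new_state
        e_prev = res.e_tot
        if de < conv_tol and dpol < conv_tol and macro > 0:
            converged = True
            # final SCF with the converged sources so orbitals match the state
            v_emb = embedding_operator(polstate, topology, ints, kC)
            e_nuc_mm = _nuclear_mm_energy(mol, topology, polstate, kC)
            e_mm = _mm_internal_energy(topology, polstate, system)
            res = rhf(ints, v_ext=v_emb, extra_e_nuc=e_nuc_mm + e_mm)
            break
    if not converged and polarizable and clamp_polarization is None:
        raise RuntimeError(
            f"coupled SCF did not converge in {max_macro} macro-iterations "
            f"(last dE={abs(res.e_tot - e_prev):.3e})"
        )
    return _pack(res, ints, n_macro), polstate


def _pack(res, ints: AOIntegrals, n_macro: int = 1) -> MeanFieldReference:
    _, K = ints.jk(res.dm)
    vxc = -0.5 * np.einsum("mn,mp,nq->pq", K, res.mo_coeff, res.mo_coeff).diagonal()
    return MeanFieldReference(
        mo_energy=res.mo_energy,
        mo_coeff=res.mo_coeff,
        mo_occ=res.mo_occ,
        vxc_diag=np.asarray(vxc, float).copy(),
        e_tot=res.e_tot,
        converged=res.converged,
        ints=ints,
        n_macro=n_macro,
    )


def mo_three_center(mf: MeanFieldReference) -> np.ndarray:
    """(pq|P) three-center factors transformed to the MO basis."""
    C = mf.mo_coeff
    return np.einsum("mp,nq,mnP->pqP", C, C, mf.ints.X3c, optimize=True)
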