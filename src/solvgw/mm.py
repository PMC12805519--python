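"""Classical polarizable environments: fluctuating charges and induced dipoles.

The environment is a set of atom-centered sites carrying fixed charges
(electrostatic embedding, EE), fluctuating charges governed by
electronegativity equalization (FQ), induced point dipoles (DRF), or both
(FQFmu).  The polarizable degrees of freedom D = (q, mu) minimize a quadratic
energy

    E[D] = 1/2 D^T A D + D^T (chi-like linear terms + external couplings)

subject to one total-charge constraint per molecule.  Ground-state
polarization and the linear response to an infinitesimal QM test charge are
both solutions of the same constrained linear system; the response defines
the reaction field that later modifies the screened Coulomb interaction.

Positions are stored in Bohr; chi (electronegativity), eta (hardness) and
alpha (isotropic polarizability) are in atomic units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .constants import DEFAULT_KC

__all__ = [
    "EmbeddingModel",
    "MMSite",
    "MMTopology",
    "BlockResponseSystem",
    "PolarizationState",
    "kernel_T0",
    "kernel_T1",
    "dipole_interaction_tensor",
    "assemble_response_system",
    "solve_ground_polarization",
    "response_to_test_charge",
    "polarization_potential_at",
]


class EmbeddingModel(str, Enum):
    EE = "EE"
    FQ = "FQ"
    DRF = "DRF"
    FQFMU = "FQFMU"

    @property
    def has_charges(self) -> bool:
        return self in (EmbeddingModel.FQ, EmbeddingModel.FQFMU)

    @property
    def has_dipoles(self) -> bool:
        return self in (EmbeddingModel.DRF, EmbeddingModel.FQFMU)


@dataclass
class MMSite:
    """One classical site: position (Bohr) plus force-field parameters (a.u.)."""

    position: np.ndarray
    molecule_id: int
    fixed_charge: float = 0.0
    chi: float = 0.0
    eta: float = 0.0
    alpha: float = 0.0
    atom_type: str = ""

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("site position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("site position must be finite")
        if self.alpha < 0:
            raise ValueError("polarizability alpha must be >= 0")


@dataclass
class MMTopology:
    """Ordered collection of MM sites plus the embedding model tag."""

    sites: list[MMSite]
    model: EmbeddingModel = EmbeddingModel.EE
    total_charge_per_molecule: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        self.model = EmbeddingModel(self.model)
        if self.model.has_charges:
            for s in self.sites:
                if s.eta <= 0:
                    raise ValueError(
                        f"model {self.model.value} requires eta > 0 on every site"
                    )
        if self.model.has_dipoles:
            for s in self.sites:
                if s.alpha < 0:
                    raise ValueError("alpha must be >= 0")

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.sites]) if self.sites else np.zeros((0, 3))

    @property
    def molecule_ids(self) -> list[int]:
        return sorted({s.molecule_id for s in self.sites})

    def molecule_charge(self, mol_id: int) -> float:
        return self.total_charge_per_molecule.get(mol_id, 0.0)

    @property
    def charge_site_indices(self) -> np.ndarray:
        """Indices of sites carrying a fluctuating charge."""
        if not self.model.has_charges:
            return np.zeros(0, dtype=int)
        return np.arange(self.n_sites)

    @property
    def dipole_site_indices(self) -> np.ndarray:
        """Indices of sites carrying an induced dipole (alpha > 0)."""
        if not self.model.has_dipoles:
            return np.zeros(0, dtype=int)
        return np.array([i for i, s in enumerate(self.sites) if s.alpha > 0], dtype=int)

    def fixed_charges(self) -> np.ndarray:
        return np.array([s.fixed_charge for s in self.sites]) if self.sites else np.zeros(0)


@dataclass
class PolarizationState:
    """Fluctuating charges, induced dipoles and constraint multipliers (a.u.)."""

    charges: np.ndarray
    dipoles: np.ndarray  # (n_dipole_sites, 3)
    lagrange: np.ndarray
    charge_sites: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    dipole_sites: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    @classmethod
    def zero(cls, topology: MMTopology) -> "PolarizationState":
        cq = topology.charge_site_indices
        cd = topology.dipole_site_indices
        nmol = len(topology.molecule_ids) if topology.model.has_charges else 0
        return cls(
            charges=np.zeros(len(cq)),
            dipoles=np.zeros((len(cd), 3)),
            lagrange=np.zeros(nmol),
            charge_sites=cq,
            dipole_sites=cd,
        )


@dataclass
class BlockResponseSystem:
    """Constrained response operator A and the blocks of its inverse.

    Degree-of-freedom ordering follows [charges | constraints | dipoles].
    B blocks are the physical-subspace restrictions of the full constrained
    inverse; Bqq is the charge-charge response, Bmm the dipole-dipole one.
    """

    topology: MMTopology
    system_matrix: np.ndarray
    n_charges: int
    n_constraints: int
    n_dipoles: int
    Bqq: np.ndarray
    Bqm: np.ndarray
    Bmq: np.ndarray
    Bmm: np.ndarray

    @property
    def dimension(self) -> int:
        return self.n_charges + self.n_constraints + 3 * self.n_dipoles


def kernel_T0(probe: np.ndarray, site: np.ndarray) -> float:
    """Coulomb kernel 1/|probe - site| between two points (Bohr)."""
    d = np.asarray(probe, float) - np.asarray(site, float)
    r = np.linalg.norm(d)
    if r < 1e-12:
        raise ValueError("kernel_T0: coincident probe and site")
    return 1.0 / r


def kernel_T1(probe: np.ndarray, site: np.ndarray) -> np.ndarray:
    """Dipole kernel (probe - site)/|probe - site|^3."""
    d = np.asarray(probe, float) - np.asarray(site, float)
    r = np.linalg.norm(d)
    if r < 1e-12:
        raise ValueError("kernel_T1: coincident probe and site")
    return d / r**3


def dipole_interaction_tensor(r_ts: np.ndarray, thole_a: float | None = None,
                              alpha_t: float = 0.0, alpha_s: float = 0.0) -> np.ndarray:
    """Point dipole-dipole interaction tensor (delta r^2 - 3 r x r) / r^5.

    With ``thole_a`` set, applies linear Thole damping with the conventional
    scaled distance u = r / (alpha_t * alpha_s)^(1/6); default is undamped.
    """
    r_ts = np.asarray(r_ts, float)
    r = np.linalg.norm(r_ts)
    if r < 1e-12:
        raise ValueError("dipole tensor: coincident sites")
    lam3 = lam5 = 1.0
    if thole_a is not None and alpha_t > 0 and alpha_s > 0:
        u = r / (alpha_t * alpha_s) ** (1.0 / 6.0)
        v = thole_a * u
        if v < 1.0:
            lam3 = 4 * v**3 - 3 * v**4
            lam5 = v**4
    return (lam3 * np.eye(3) * r**2 - 3.0 * lam5 * np.outer(r_ts, r_ts)) / r**5


def _charge_blocks(topology: MMTopology) -> tuple[np.ndarray, np.ndarray]:
    """Tqq (eta on the diagonal, bare Coulomb off it) and the constraint rows."""
    idx = topology.charge_site_indices
    n = len(idx)
    pos = topology.positions[idx]
    eta = np.array([topology.sites[i].eta for i in idx])
    Tqq = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            Tqq[a, b] = Tqq[b, a] = kernel_T0(pos[a], pos[b])
    Tqq[np.diag_indices(n)] = eta
    mols = topology.molecule_ids
    C = np.zeros((n, len(mols)))
    for a, i in enumerate(idx):
        C[a, mols.index(topology.sites[i].molecule_id)] = 1.0
    return Tqq, C


def _dipole_block(topology: MMTopology, thole_a: float | None = None) -> np.ndarray:
    """Tmumu: alpha^-1 identity on site-diagonal blocks, dipole tensor off."""
    idx = topology.dipole_site_indices
    n = len(idx)
    T = np.zeros((3 * n, 3 * n))
    for a in range(n):
        sa = topology.sites[idx[a]]
        T[3 * a:3 * a + 3, 3 * a:3 * a + 3] = np.eye(3) / sa.alpha
        for b in range(a + 1, n):
            sb = topology.sites[idx[b]]
            blk = dipole_interaction_tensor(
                sa.position - sb.position, thole_a, sa.alpha, sb.alpha
            )
            T[3 * a:3 * a + 3, 3 * b:3 * b + 3] = blk
            T[3 * b:3 * b + 3, 3 * a:3 * a + 3] = blk.T
    return T


def _charge_dipole_block(topology: MMTopology) -> np.ndarray:
    """Tqmu[j, 3t+a] = T1_a(r_j; r_t): charge j at r_j against dipole site t.

    Convention: interaction energy of charge q at r_j with dipole mu at r_t is
    q * mu . (r_j - r_t)/|r_j - r_t|^3 = q * mu . T1(r_j; site r_t).
    """
    qi = topology.charge_site_indices
    di = topology.dipole_site_indices
    T = np.zeros((len(qi), 3 * len(di)))
    for a, j in enumerate(qi):
        rj = topology.sites[j].position
        for b, t in enumerate(di):
            rt = topology.sites[t].position
            if np.linalg.norm(rj - rt) < 1e-12:
                continue  # charge and dipole on the same site do not self-interact
            T[a, 3 * b:3 * b + 3] = kernel_T1(rj, rt)
    return T


def assemble_response_system(topology: MMTopology,
                             thole_a: float | None = None) -> BlockResponseSystem:
    """Build the constrained response matrix A and its blockwise inverse.

    Ordering [q | lambda | mu].  FQ: [[Tqq, 1], [1^T, 0]].  FQFmu adds the
    dipole block and the charge-dipole coupling; DRF has dipoles only (no
    constraint rows).  Raises on EE (no polarizable degrees of freedom).
    """
    model = topology.model
    if model is EmbeddingModel.EE:
        raise ValueError("EE has no polarizable degrees of freedom")

    nq = len(topology.charge_site_indices)
    nd = len(topology.dipole_site_indices)
    nmol = len(topology.molecule_ids) if model.has_charges else 0
    dim = nq + nmol + 3 * nd
    A = np.zeros((dim, dim))

    if model.has_charges:
        Tqq, C = _charge_blocks(topology)
        A[:nq, :nq] = Tqq
        A[:nq, nq:nq + nmol] = C
        A[nq:nq + nmol, :nq] = C.T
    if model.has_dipoles:
        off = nq + nmol
        A[off:, off:] = _dipole_block(topology, thole_a)
        if model.has_charges:
            Tqm = _charge_dipole_block(topology)
            A[:nq, off:] = Tqm
            A[off:, :nq] = Tqm.T

    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        block = "Tqq/constraints" if model.has_charges else "Tmumu"
        raise np.linalg.LinAlgError(
            f"singular response system (block {block}): {exc}"
        ) from exc

    off = nq + nmol
    return BlockResponseSystem(
        topology=topology,
        system_matrix=A,
        n_charges=nq,
        n_constraints=nmol,
        n_dipoles=nd,
        Bqq=Ainv[:nq, :nq].copy(),
        Bqm=Ainv[:nq, off:].copy(),
        Bmq=Ainv[off:, :nq].copy(),
        Bmm=Ainv[off:, off:].copy(),
    )


def _fixed_source_potential_field(topology: MMTopology) -> tuple[np.ndarray, np.ndarray]:
    """Potential/field at every site from the *fixed* charges of other molecules.

    Same-molecule fixed sources are excluded (standard intramolecular
    exclusion; bare Coulomb at bond distances would be unphysical).
    """
    n = topology.n_sites
    V = np.zeros(n)
    E = np.zeros((n, 3))
    for t in range(n):
        st = topology.sites[t]
        for s in range(n):
            ss = topology.sites[s]
            if ss.fixed_charge == 0.0 or ss.molecule_id == st.molecule_id:
                continue
            V[t] += ss.fixed_charge * kernel_T0(st.position, ss.position)
            # field at r_t from charge q at r_s: q (r_t - r_s)/|r_t - r_s|^3
            E[t] += ss.fixed_charge * kernel_T1(st.position, ss.position)
    return V, E


def solve_ground_polarization(
    topology: MMTopology,
    qm_potential_at_sites: np.ndarray | None = None,
    qm_field_at_sites: np.ndarray | None = None,
    system: BlockResponseSystem | None = None,
    kC: float = DEFAULT_KC,
) -> PolarizationState:
    """Ground-state polarization: stationary point of the classical energy.

    Charge rows:   Tqq q + Tqmu mu + C lam = -(chi + kC V_qm + V_fixed)
    Dipole rows:   Tmuq q + Tmumu mu       = +(kC E_qm + E_fixed)
    Constraints:   sum of charges per molecule = molecular total charge.

    The QM potential/field arrays are per-site (kC is applied here, on the
    QM<->MM polarizable coupling).  EE returns the zero state.
    """
    n = topology.n_sites
    if qm_potential_at_sites is None:
        qm_potential_at_sites = np.zeros(n)
    if qm_field_at_sites is None:
        qm_field_at_sites = np.zeros((n, 3))
    qm_potential_at_sites = np.asarray(qm_potential_at_sites, float)
    qm_field_at_sites = np.asarray(qm_field_at_sites, float)
    if qm_potential_at_sites.shape != (n,) or qm_field_at_sites.shape != (n, 3):
        raise ValueError("QM potential/field arrays must be sized to the topology")

    if topology.model is EmbeddingModel.EE:
        return PolarizationState.zero(topology)

    if system is None:
        system = assemble_response_system(topology)
    nq, nmol, nd = system.n_charges, system.n_constraints, system.n_dipoles
    Vfix, Efix = _fixed_source_potential_field(topology)

    rhs = np.zeros(system.dimension)
    if nq:
        qi = topology.charge_site_indices
        chi = np.array([topology.sites[i].chi for i in qi])
        rhs[:nq] = -(chi + kC * qm_potential_at_sites[qi] + Vfix[qi])
        mols = topology.molecule_ids
        rhs[nq:nq + nmol] = [topology.molecule_charge(m) for m in mols]
    if nd:
        di = topology.dipole_site_indices
        off = nq + nmol
        rhs[off:] = (kC * qm_field_at_sites[di] + Efix[di]).ravel()

    try:
        sol = np.linalg.solve(system.system_matrix, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular polarization system: {exc}") from exc

    state = PolarizationState(
        charges=sol[:nq].copy(),
        dipoles=sol[nq + nmol:].reshape(nd, 3).copy(),
        lagrange=sol[nq:nq + nmol].copy(),
        charge_sites=topology.charge_site_indices,
        dipole_sites=topology.dipole_site_indices,
    )
    resid = system.system_matrix @ sol - rhs
    if np.max(np.abs(resid), initial=0.0) > 1e-10:
        raise RuntimeError("classical stationarity residual exceeds 1e-10")
    return state


def _coupling_vectors(system: BlockResponseSystem, test_position: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """T(0) at charge sites and flattened T(1) at dipole sites for a unit probe."""
    topo = system.topology
    t0 = np.array([
        kernel_T0(test_position, topo.sites[i].position)
        for i in topo.charge_site_indices
    ])
    t1 = np.array([
        kernel_T1(test_position, topo.sites[i].position)
        for i in topo.dipole_site_indices
    ]).reshape(-1)
    return t0, t1


def response_to_test_charge(
    system: BlockResponseSystem | None,
    topology: MMTopology,
    test_position: np.ndarray,
    kC: float = DEFAULT_KC,
) -> PolarizationState:
    """Linear response (dq, dmu) per unit test charge placed at ``test_position``.

        dq  = -kC (Bqq  T0 + Bqmu  T1)
        dmu = -kC (Bmuq T0 + Bmumu T1)

    Signs follow the consistent energy derivation (a positive test charge
    induces dipoles pointing along its field, and the resulting reaction
    potential stabilizes the test charge); see the finite-difference oracle
    in :mod:`solvgw.reaction`.
    """
    test_position = np.asarray(test_position, float)
    if topology.model is EmbeddingModel.EE:
        return PolarizationState.zero(topology)
    if system is None:
        system = assemble_response_system(topology)
    for s in topology.sites:
        if np.linalg.norm(s.position - test_position) < 1e-10:
            raise ValueError("test charge coincident with an MM site")

    t0, t1 = _coupling_vectors(system, test_position)
    nq, nd = system.n_charges, system.n_dipoles
    dq = np.zeros(nq)
    dmu = np.zeros(3 * nd)
    if nq:
        dq = -kC * (system.Bqq @ t0)
        if nd:
            dq -= kC * (system.Bqm @ t1)
    if nd:
        dmu = -kC * (system.Bmm @ t1)
        if nq:
            dmu -= kC * (system.Bmq @ t0)
    return PolarizationState(
        charges=dq,
        dipoles=dmu.reshape(nd, 3),
        lagrange=np.zeros(system.n_constraints),
        charge_sites=topology.charge_site_indices,
        dipole_sites=topology.dipole_site_indices,
    )


def polarization_potential_at(topology: MMTopology, state: PolarizationState,
                              point: np.ndarray, kC: float = DEFAULT_KC) -> float:
    """Potential at ``point`` generated by the polarization sources, scaled by kC."""
    v = 0.0
    for q, i in zip(state.charges, state.charge_sites):
        v += q * kernel_T0(point, topology.sites[i].position)
    for mu, i in zip(state.dipoles, state.dipole_sites):
        v += float(mu @ kernel_T1(point, topology.sites[i].position))
    return kC * v
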