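"""Minimal Gaussian-orbital restricted Hartree-Fock backend.

Self-contained integral engine for *s-type* contracted Gaussians (closed-form
overlap, kinetic, nuclear-attraction, electron-repulsion and point-multipole
potential integrals via the Boys function), plus a density-fitted RHF solver.
The quantum region is therefore limited to H and He; that is sufficient for
every desk-scale validation target of the embedded-GW pipeline, where the
physics under test lives in the screening, not in the orbital basis.

The auxiliary (density-fitting) basis is an even-tempered set of s-Gaussians
built from pairwise sums of the orbital primitive exponents: on a single
atom this spans the orbital product space exactly, making DF exact for
atomic systems (He), which anchors the Hartree-Fock self-consistency checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

__all__ = [
    "Molecule",
    "BasisShell",
    "AuxBasis",
    "AOIntegrals",
    "build_basis",
    "build_aux_basis",
    "compute_integrals",
    "rhf",
    "RHFResult",
]

_ELEMENT_Z = {"H": 1, "He": 2}

# Published s-only contracted bases (exponents / contraction coefficients).
BASIS_LIBRARY: dict[str, dict[str, list[tuple[list[float], list[float]]]]] = {
    "sto-3g": {
        "H": [([3.42525091, 0.62391373, 0.16885540],
               [0.15432897, 0.53532814, 0.44463454])],
        "He": [([6.36242139, 1.15892300, 0.31364979],
                [0.15432897, 0.53532814, 0.44463454])],
    },
    "6-31g": {
        "H": [([18.7311370, 2.8253937, 0.6401217],
               [0.03349460, 0.23472695, 0.81375733]),
              ([0.1612778], [1.0])],
        "He": [([38.421634, 5.778030, 1.241774],
                [0.04013974, 0.26124610, 0.79318462]),
               ([0.297964], [1.0])],
    },
}


def boys_f0(x: np.ndarray) -> np.ndarray:
    """Boys function F0; series branch keeps the x->0 limit smooth."""
    x = np.asarray(x, dtype=float)
    small = x < 1e-12
    xs = np.where(small, 1.0, x)
    out = 0.5 * np.sqrt(np.pi / xs) * erf(np.sqrt(xs))
    return np.where(small, 1.0 - x / 3.0, out)


def boys_f1(x: np.ndarray) -> np.ndarray:
    """Boys function F1 = (F0(x) - exp(-x)) / (2x)."""
    x = np.asarray(x, dtype=float)
    small = x < 1e-10
    xs = np.where(small, 1.0, x)
    out = (boys_f0(xs) - np.exp(-xs)) / (2.0 * xs)
    return np.where(small, 1.0 / 3.0 - x / 5.0, out)


@dataclass
class Molecule:
    symbols: list[str]
    coords: np.ndarray  # (natom, 3), Bohr
    charge: int = 0

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        unknown = [s for s in self.symbols if s not in _ELEMENT_Z]
        if unknown:
            raise ValueError(
                f"unsupported elements {unknown}: the s-Gaussian backend covers H, He"
            )

    @property
    def charges(self) -> np.ndarray:
        return np.array([_ELEMENT_Z[s] for s in self.symbols], dtype=float)

    @property
    def n_electrons(self) -> int:
        return int(self.charges.sum()) - self.charge

    def nuclear_repulsion(self) -> float:
        e = 0.0
        z, r = self.charges, self.coords
        for i in range(len(z)):
            for j in range(i + 1, len(z)):
                e += z[i] * z[j] / np.linalg.norm(r[i] - r[j])
        return e


@dataclass
class BasisShell:
    """Contracted s shell: L2-normalized primitives, contraction renormalized."""

    center: np.ndarray
    exponents: np.ndarray
    coefficients: np.ndarray

    def __post_init__(self):
        self.center = np.asarray(self.center, float)
        self.exponents = np.asarray(self.exponents, float)
        c = np.asarray(self.coefficients, float) * (2 * self.exponents / np.pi) ** 0.75
        # renormalize the contraction to unit self-overlap
        a = self.exponents
        ss = np.sum(
            c[:, None] * c[None, :]
            * (np.pi / (a[:, None] + a[None, :])) ** 1.5
        )
        self.coefficients = c / np.sqrt(ss)


def build_basis(mol: Molecule, basis_name: str) -> list[BasisShell]:
    name = basis_name.lower()
    if name not in BASIS_LIBRARY:
        raise ValueError(f"unknown basis '{basis_name}' (have {list(BASIS_LIBRARY)})")
    shells = []
    for sym, xyz in zip(mol.symbols, mol.coords):
        for exps, coefs in BASIS_LIBRARY[name][sym]:
            shells.append(BasisShell(xyz, exps, coefs))
    return shells


@dataclass
class AuxBasis:
    """Single-primitive s-Gaussian fitting set.

    ``norms`` are the prefactors of exp(-a r^2); ``normalization`` records the
    convention ('l2' for density fitting, 'charge' for unit-total-charge
    probe functions used in the reaction-field tests).
    """

    centers: np.ndarray  # (naux, 3)
    exponents: np.ndarray
    norms: np.ndarray
    normalization: str = "l2"

    def __len__(self) -> int:
        return len(self.exponents)

    @classmethod
    def from_gaussians(cls, centers, exponents, normalization: str = "l2") -> "AuxBasis":
        centers = np.atleast_2d(np.asarray(centers, float))
        exponents = np.asarray(exponents, float)
        if normalization == "l2":
            norms = (2 * exponents / np.pi) ** 0.75
        elif normalization == "charge":
            norms = (exponents / np.pi) ** 1.5
        else:
            raise ValueError("normalization must be 'l2' or 'charge'")
        return cls(centers, exponents, norms, normalization)


def build_aux_basis(mol: Molecule, basis_name: str) -> AuxBasis:
    """Even-tempered auxiliary set: pairwise sums of orbital primitive exponents."""
    name = basis_name.lower()
    centers, exps = [], []
    for sym, xyz in zip(mol.symbols, mol.coords):
        prim = sorted({a for sh in BASIS_LIBRARY[name][sym] for a in sh[0]})
        pair = sorted({round(prim[i] + prim[j], 10)
                       for i in range(len(prim)) for j in range(i, len(prim))})
        # prune near-duplicates (ratio < 1.15)
        kept: list[float] = []
        for a in pair:
            if not kept or a / kept[-1] > 1.15:
                kept.append(a)
        for a in kept:
            centers.append(xyz)
            exps.append(a)
    return AuxBasis.from_gaussians(np.array(centers), np.array(exps))


# ---------------------------------------------------------------------------
# Primitive integral kernels (vectorized over contracted pairs)

def _pair_arrays(shells: list[BasisShell]):
    """Flatten primitives: exponents a, coefficients c, centers A, shell map."""
    a, c, A, idx = [], [], [], []
    for i, sh in enumerate(shells):
        for e, cc in zip(sh.exponents, sh.coefficients):
            a.append(e); c.append(cc); A.append(sh.center); idx.append(i)
    return (np.array(a), np.array(c), np.array(A), np.array(idx, dtype=int))


def overlap_kinetic(shells: list[BasisShell]) -> tuple[np.ndarray, np.ndarray]:
    a, c, A, idx = _pair_arrays(shells)
    n = len(shells)
    p = a[:, None] + a[None, :]
    mu = a[:, None] * a[None, :] / p
    ab2 = np.sum((A[:, None, :] - A[None, :, :]) ** 2, axis=-1)
    K = np.exp(-mu * ab2)
    s_prim = (np.pi / p) ** 1.5 * K
    t_prim = mu * (3.0 - 2.0 * mu * ab2) * s_prim
    w = c[:, None] * c[None, :]
    S = np.zeros((n, n)); T = np.zeros((n, n))
    np.add.at(S, (idx[:, None], idx[None, :]), w * s_prim)
    np.add.at(T, (idx[:, None], idx[None, :]), w * t_prim)
    return S, T


def point_charge_matrix(shells: list[BasisShell], point: np.ndarray) -> np.ndarray:
    """<mu| 1/|r - point| |nu> for all contracted pairs."""
    a, c, A, idx = _pair_arrays(shells)
    n = len(shells)
    p = a[:, None] + a[None, :]
    mu = a[:, None] * a[None, :] / p
    ab2 = np.sum((A[:, None, :] - A[None, :, :]) ** 2, axis=-1)
    K = np.exp(-mu * ab2)
    P = (a[:, None, None] * A[:, None, :] + a[None, :, None] * A[None, :, :]) / p[..., None]
    pc2 = np.sum((P - np.asarray(point, float)) ** 2, axis=-1)
    v_prim = (2 * np.pi / p) * K * boys_f0(p * pc2)
    w = c[:, None] * c[None, :]
    V = np.zeros((n, n))
    np.add.at(V, (idx[:, None], idx[None, :]), w * v_prim)
    return V


def point_dipole_matrix(shells: list[BasisShell], point: np.ndarray) -> np.ndarray:
    """<mu| (r - point)/|r - point|^3 |nu>: gradient of the point-charge integral
    with respect to the point position.  Shape (3, nao, nao)."""
    a, c, A, idx = _pair_arrays(shells)
    n = len(shells)
    p = a[:, None] + a[None, :]
    mu = a[:, None] * a[None, :] / p
    ab2 = np.sum((A[:, None, :] - A[None, :, :]) ** 2, axis=-1)
    K = np.exp(-mu * ab2)
    P = (a[:, None, None] * A[:, None, :] + a[None, :, None] * A[None, :, :]) / p[..., None]
    d = P - np.asarray(point, float)
    pc2 = np.sum(d ** 2, axis=-1)
    f1 = boys_f1(p * pc2)
    v_prim = 4 * np.pi * K * f1  # times (P - C)_alpha
    w = c[:, None] * c[None, :]
    out = np.zeros((3, n, n))
    for al in range(3):
        M = np.zeros((n, n))
        np.add.at(M, (idx[:, None], idx[None, :]), w * v_prim * d[..., al])
        out[al] = M
    return out


def three_center(shells: list[BasisShell], aux: AuxBasis) -> np.ndarray:
    """(mu nu | P) Coulomb integrals against the auxiliary s-Gaussians."""
    a, c, A, idx = _pair_arrays(shells)
    n = len(shells)
    p = a[:, None] + a[None, :]
    mu = a[:, None] * a[None, :] / p
    ab2 = np.sum((A[:, None, :] - A[None, :, :]) ** 2, axis=-1)
    K = np.exp(-mu * ab2)
    P = (a[:, None, None] * A[:, None, :] + a[None, :, None] * A[None, :, :]) / p[..., None]
    w = c[:, None] * c[None, :]
    naux = len(aux)
    X = np.zeros((n, n, naux))
    for q in range(naux):
        cq, aq = aux.centers[q], aux.exponents[q]
        pq2 = np.sum((P - cq) ** 2, axis=-1)
        alpha = p * aq / (p + aq)
        prim = (2 * np.pi ** 2.5 / (p * aq * np.sqrt(p + aq))
                * K * boys_f0(alpha * pq2))
        # aux prefactor: norms[q] times (pi/aq)^{0} already in formula for
        # unnormalized exp(-aq r^2); multiply by the stored norm
        M = np.zeros((n, n))
        np.add.at(M, (idx[:, None], idx[None, :]), w * prim)
        X[:, :, q] = aux.norms[q] * M
    return X


def aux_metric(aux: AuxBasis) -> np.ndarray:
    """(P|Q) two-center Coulomb metric of the auxiliary set."""
    a = aux.exponents
    C = aux.centers
    p = a[:, None]; q = a[None, :]
    r2 = np.sum((C[:, None, :] - C[None, :, :]) ** 2, axis=-1)
    alpha = p * q / (p + q)
    J = 2 * np.pi ** 2.5 / (p * q * np.sqrt(p + q)) * boys_f0(alpha * r2)
    return J * aux.norms[:, None] * aux.norms[None, :]


def exact_eri(shells: list[BasisShell]) -> np.ndarray:
    """Full (ss|ss) electron-repulsion tensor; only used for validation."""
    a, c, A, idx = _pair_arrays(shells)
    n = len(shells)
    p = a[:, None] + a[None, :]
    mu = a[:, None] * a[None, :] / p
    ab2 = np.sum((A[:, None, :] - A[None, :, :]) ** 2, axis=-1)
    K = np.exp(-mu * ab2)
    P = (a[:, None, None] * A[:, None, :] + a[None, :, None] * A[None, :, :]) / p[..., None]
    w = c[:, None] * c[None, :]
    npair = len(a)
    eri_prim = np.zeros((npair, npair, npair, npair))
    for i in range(npair):
        for j in range(npair):
            pij, Pij, Kij = p[i, j], P[i, j], K[i, j]
            qkl = p
            alpha = pij * qkl / (pij + qkl)
            pq2 = np.sum((Pij - P) ** 2, axis=-1)
            eri_prim[i, j] = (2 * np.pi ** 2.5
                              / (pij * qkl * np.sqrt(pij + qkl))
                              * Kij * K * boys_f0(alpha * pq2))
    W = np.einsum("i,j,k,l,ijkl->ijkl", c, c, c, c, eri_prim)
    out = np.zeros((n, n, n, n))
    np.add.at(out, (idx[:, None, None, None], idx[None, :, None, None],
                    idx[None, None, :, None], idx[None, None, None, :]), W)
    return out


@dataclass
class AOIntegrals:
    """One- and two-electron integrals plus the density-fitting factors."""

    mol: Molecule
    shells: list[BasisShell]
    aux: AuxBasis
    S: np.ndarray
    T: np.ndarray
    Vne: np.ndarray
    X3c: np.ndarray      # (nao, nao, naux), bare-Coulomb three-center
    J2c: np.ndarray      # (naux, naux) fitting metric
    J2c_inv: np.ndarray = field(init=False)

    def __post_init__(self):
        self.J2c_inv = np.linalg.inv(self.J2c)

    @property
    def nao(self) -> int:
        return self.S.shape[0]

    def df_eri(self) -> np.ndarray:
        """Density-fitted (mu nu | kappa lam)."""
        t = np.einsum("mnP,PQ->mnQ", self.X3c, self.J2c_inv)
        return np.einsum("mnQ,klQ->mnkl", t, self.X3c)

    def jk(self, dm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Coulomb and exchange matrices from the DF factors."""
        dP = np.einsum("klP,kl->P", self.X3c, dm)
        J = np.einsum("mnP,P->mn", self.X3c, self.J2c_inv @ dP)
        t = np.einsum("mkP,kl->mlP", self.X3c, dm)
        K = np.einsum("mlP,PQ,nlQ->mn", t, self.J2c_inv, self.X3c)
        return J, K


def compute_integrals(mol: Molecule, basis_name: str,
                      aux: AuxBasis | None = None) -> AOIntegrals:
    shells = build_basis(mol, basis_name)
    if aux is None:
        aux = build_aux_basis(mol, basis_name)
    S, T = overlap_kinetic(shells)
    Vne = np.zeros_like(S)
    for z, xyz in zip(mol.charges, mol.coords):
        Vne -= z * point_charge_matrix(shells, xyz)
    X3c = three_center(shells, aux)
    J2c = aux_metric(aux)
    return AOIntegrals(mol, shells, aux, S, T, Vne, X3c, J2c)


@dataclass
class RHFResult:
    mo_energy: np.ndarray
    mo_coeff: np.ndarray
    mo_occ: np.ndarray
    e_tot: float
    e_elec: float
    dm: np.ndarray
    fock: np.ndarray
    converged: bool
    n_iter: int


def rhf(ints: AOIntegrals, v_ext: np.ndarray | None = None,
        use_df: bool = True, conv_tol: float = 1e-10,
        max_cycle: int = 200, extra_e_nuc: float = 0.0) -> RHFResult:
    """Restricted Hartree-Fock with DIIS.

    ``v_ext`` is an additional one-electron operator (the embedding operator);
    ``extra_e_nuc`` a density-independent energy shift (nucleus-environment).
    """
    mol = ints.mol
    nelec = mol.n_electrons
    if nelec % 2:
        raise ValueError("restricted closed-shell backend requires an even electron count")
    nocc = nelec // 2
    hcore = ints.T + ints.Vne
    if v_ext is not None:
        hcore = hcore + v_ext
    # symmetric orthogonalization
    w, U = np.linalg.eigh(ints.S)
    Xo = U @ np.diag(w ** -0.5) @ U.T
    eri = None if use_df else exact_eri(ints.shells)

    dm = np.zeros_like(ints.S)
    e_old = 0.0
    diis_F, diis_err = [], []
    mo_energy = np.zeros(ints.nao); C = np.eye(ints.nao)
    converged = False
    for it in range(max_cycle):
        if use_df:
            J, K = ints.jk(dm)
        else:
            J = np.einsum("mnkl,kl->mn", eri, dm)
            K = np.einsum("mknl,kl->mn", eri, dm)
        F = hcore + J - 0.5 * K
        if it > 0:
            err = F @ dm @ ints.S - ints.S @ dm @ F
            diis_F.append(F.copy()); diis_err.append(err.ravel())
            if len(diis_F) > 8:
                diis_F.pop(0); diis_err.pop(0)
            if len(diis_F) > 1:
                m = len(diis_F)
                Bm = -np.ones((m + 1, m + 1)); Bm[-1, -1] = 0.0
                for i in range(m):
                    for j in range(m):
                        Bm[i, j] = diis_err[i] @ diis_err[j]
                rhs = np.zeros(m + 1); rhs[-1] = -1.0
                try:
                    coef = np.linalg.solve(Bm, rhs)[:m]
                    F = sum(ci * Fi for ci, Fi in zip(coef, diis_F))
                except np.linalg.LinAlgError:
                    pass
        Fp = Xo.T @ F @ Xo
        mo_energy, Cp = np.linalg.eigh(Fp)
        C = Xo @ Cp
        dm = 2.0 * C[:, :nocc] @ C[:, :nocc].T
        e_elec = 0.5 * np.sum(dm * (hcore + F))
        if abs(e_elec - e_old) < conv_tol and it > 1:
            converged = True
            break
        e_old = e_elec

    occ = np.zeros(ints.nao)
    occ[:nocc] = 2.0
    e_tot = e_elec + mol.nuclear_repulsion() + extra_e_nuc
    return RHFResult(mo_energy, C, occ, e_tot, e_elec, dm, F, converged, it + 1)
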