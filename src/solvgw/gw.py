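"""Diagonal G0W0 on the imaginary frequency axis with environment screening.

The screened interaction is built in the auxiliary (density-fitting) basis
from the independent-particle polarizability chi0 and an effective Coulomb
interaction v~ = v + dv_res, where dv_res is the static reaction-field
correction of a polarizable classical environment.  The correlation
self-energy is evaluated by Gauss-Legendre quadrature on the imaginary axis,
analytically continued to real energies with a Thiele/Pade interpolant, and
the quasiparticle equation is solved selecting the smallest-slope root.

Conventions: closed-shell spin-summed chi0 carries a factor 4; self-energy is
partitioned as Sigma = Sigma_x[v] + Sigma_stat[dv_res] + Sigma_c[W - v~],
the static environment exchange-like term being switchable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import mpmath as mp

from .constants import HARTREE_EV

__all__ = [
    "FrequencyGrid",
    "make_frequency_grid",
    "Chi0Set",
    "compute_chi0",
    "ScreenedInteraction",
    "compute_screened_interaction",
    "exchange_self_energy",
    "static_self_energy",
    "SigmaCSamples",
    "correlation_self_energy",
    "pade_continuation",
    "QPEntry",
    "QPSolution",
    "solve_qp",
    "g0w0",
    "ionization_potential",
]


@dataclass
class FrequencyGrid:
    """Imaginary-frequency quadrature nodes and weights (a.u.)."""

    points: np.ndarray
    weights: np.ndarray
    scale: float = 1.0

    @property
    def n(self) -> int:
        return len(self.points)


def make_frequency_grid(n: int = 25, scale: float = 1.0) -> FrequencyGrid:
    """Gauss-Legendre nodes mapped from (-1, 1) to (0, inf).

    omega = scale (1 + x) / (1 - x); the Jacobian 2 scale / (1 - x)^2 is folded
    into the weights, preserving the exactness of the underlying rule for
    integrands decaying like the GW convolution kernels.
    """
    if n < 8:
        raise ValueError("frequency grid needs n >= 8")
    if scale <= 0:
        raise ValueError("grid scale must be positive")
    x, w = np.polynomial.legendre.leggauss(n)
    pts = scale * (1 + x) / (1 - x)
    wts = w * 2 * scale / (1 - x) ** 2
    order = np.argsort(pts)
    return FrequencyGrid(points=pts[order], weights=wts[order], scale=scale)


@dataclass
class Chi0Set:
    """chi0(i omega_k) projected on the fitting basis (raw v.chi0.v form)."""

    grid: FrequencyGrid
    matrices: np.ndarray  # (n_freq, naux, naux), symmetric, negative semidefinite


def _split_occ_virt(mo_occ: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mo_occ = np.asarray(mo_occ)
    return np.where(mo_occ > 0)[0], np.where(mo_occ == 0)[0]


def compute_chi0(mo_energy: np.ndarray, mo_occ: np.ndarray,
                 X_mo: np.ndarray, grid: FrequencyGrid) -> Chi0Set:
    """Independent-particle polarizability, spin-summed closed shell.

    chi0_PQ(i omega) = -4 sum_ia (ia|P)(ia|Q) D_ia / (D_ia^2 + omega^2),
    with D_ia = eps_a - eps_i and (ia|P) the MO-transformed three-center
    Coulomb factors.
    """
    occ, virt = _split_occ_virt(mo_occ)
    naux = X_mo.shape[-1]
    out = np.zeros((grid.n, naux, naux))
    if len(occ) == 0 or len(virt) == 0:
        return Chi0Set(grid, out)
    delta = np.asarray(mo_energy)[virt][None, :] - np.asarray(mo_energy)[occ][:, None]
    if delta.min() <= 1e-10:
        raise ValueError("degenerate occupied/virtual gap: metallic reference unsupported")
    X_ov = X_mo[np.ix_(occ, virt)]  # (no, nv, naux)
    for k, om in enumerate(grid.points):
        fac = delta / (delta ** 2 + om ** 2)
        out[k] = -4.0 * np.einsum("iaP,iaQ,ia->PQ", X_ov, X_ov, fac, optimize=True)
    return Chi0Set(grid, out)


@dataclass
class ScreenedInteraction:
    """v~ = v + dv_res and the correlation part Wc(i omega) = W0 - v~."""

    v: np.ndarray
    dv_res: np.ndarray
    Wc: np.ndarray  # (n_freq, naux, naux)
    grid: FrequencyGrid

    @property
    def v_tilde(self) -> np.ndarray:
        return self.v + self.dv_res


def compute_screened_interaction(chi0: Chi0Set, v: np.ndarray,
                                 dv_res: np.ndarray | None = None) -> ScreenedInteraction:
    """Solve the Dyson equation W = v~ + v~ chi0 W per frequency.

    chi0 enters in its raw (v chi0 v) representation, so the fitted operator
    is J^-1 chi0_raw J^-1 with J the bare fitting metric; the environment
    correction shifts only the interaction, never the metric.
    """
    naux = v.shape[0]
    dv = np.zeros_like(v) if dv_res is None else dv_res
    vt = v + dv
    Jinv = np.linalg.inv(v)
    Wc = np.zeros_like(chi0.matrices)
    eye = np.eye(naux)
    for k in range(chi0.grid.n):
        M = vt @ Jinv @ chi0.matrices[k] @ Jinv
        try:
            W = np.linalg.solve(eye - M, vt)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular (I - v~ chi0) at omega={chi0.grid.points[k]:.6g}"
            ) from exc
        Wck = W - vt
        Wc[k] = 0.5 * (Wck + Wck.T)
    return ScreenedInteraction(v=v, dv_res=dv, Wc=Wc, grid=chi0.grid)


def exchange_self_energy(X_mo: np.ndarray, J2c: np.ndarray,
                         mo_occ: np.ndarray) -> np.ndarray:
    """Sigma_x_nn = - sum_{i occ} (ni|P) [J^-1]_PQ (Q|in), per orbital."""
    occ, _ = _split_occ_virt(mo_occ)
    Jinv = np.linalg.inv(J2c)
    n = X_mo.shape[0]
    sx = np.zeros(n)
    for nn in range(n):
        for i in occ:
            x = X_mo[nn, i]
            sx[nn] -= x @ Jinv @ x
    return sx


def static_self_energy(X_mo: np.ndarray, J2c: np.ndarray, dv_res: np.ndarray,
                       mo_occ: np.ndarray) -> np.ndarray:
    """Exchange-like static environment term: -sum_{i occ} <ni|dv_res|in>."""
    occ, _ = _split_occ_virt(mo_occ)
    Jinv = np.linalg.inv(J2c)
    n = X_mo.shape[0]
    out = np.zeros(n)
    for nn in range(n):
        for i in occ:
            c = Jinv @ X_mo[nn, i]
            out[nn] -= c @ dv_res @ c
    return out


@dataclass
class SigmaCSamples:
    """Sigma_c(i nu) samples for one orbital, relative to the Fermi level mu_F."""

    points: np.ndarray   # complex, i*nu
    values: np.ndarray   # complex
    mu_F: float


def correlation_self_energy(mo_energy: np.ndarray, mo_occ: np.ndarray,
                            X_mo: np.ndarray, J2c: np.ndarray,
                            W: ScreenedInteraction,
                            target_orbitals) -> list[SigmaCSamples]:
    """Quadrature convolution of G0 with Wc on the imaginary axis.

    Sigma_c_n(i nu) = -(1/pi) sum_m int_0^inf domega <nm|Wc(i omega)|mn>
                       z_m / (z_m^2 + omega^2),  z_m = i nu + mu_F - eps_m,

    sampled at the quadrature nodes nu = omega_j themselves.
    """
    mo_energy = np.asarray(mo_energy)
    nmo = len(mo_energy)
    occ, virt = _split_occ_virt(mo_occ)
    if len(virt):
        mu_F = 0.5 * (mo_energy[occ].max() + mo_energy[virt].min())
    else:
        mu_F = mo_energy[occ].max() + 0.5
    Jinv = np.linalg.inv(J2c)
    grid = W.grid
    out = []
    for n in list(target_orbitals):
        if n < 0 or n >= nmo:
            raise IndexError(f"orbital index {n} out of range")
        c_nm = X_mo[n] @ Jinv  # (nmo, naux) fitted coefficients
        # w_nm(k) = c_nm Wc_k c_nm for every m
        w = np.einsum("mP,kPQ,mQ->km", c_nm, W.Wc, X_mo[n] @ Jinv.T, optimize=True)
        nus = grid.points
        vals = np.zeros(grid.n, dtype=complex)
        for j, nu in enumerate(nus):
            z = 1j * nu + mu_F - mo_energy  # (nmo,)
            kern = z[None, :] / (z[None, :] ** 2 + grid.points[:, None] ** 2)
            vals[j] = -(1.0 / np.pi) * np.sum(grid.weights[:, None] * w * kern)
        out.append(SigmaCSamples(points=1j * nus, values=vals, mu_F=mu_F))
    return out


def pade_continuation(points: np.ndarray, values: np.ndarray, dps: int = 60):
    """Thiele continued-fraction interpolant through all samples.

    Returns a callable of a complex argument (same variable as ``points``,
    i.e. energy relative to mu_F for self-energy samples).  Divided-difference
    breakdown truncates the fraction with a warning; exactly-reproduced
    rational inputs truncate quietly once the coefficients vanish.
    """
    points = np.asarray(points, dtype=complex)
    values = np.asarray(values, dtype=complex)
    if len(points) < 1:
        raise ValueError("need at least one sample")
    scale = max(float(np.max(np.abs(values))), 1e-300)
    if np.max(np.abs(values - values[0])) <= 1e-15 * scale:
        c0 = complex(values[0])
        return lambda z: c0
    with mp.workdps(dps):
        zs = [mp.mpc(p) for p in points]
        g = [mp.mpc(v) for v in values]
        n = len(zs)
        a = [g[0]]
        work = list(g)
        for k in range(1, n):
            prev = a[k - 1]
            new = [mp.mpc(0)] * n
            broke = False
            for j in range(k, n):
                denom = (zs[j] - zs[k - 1]) * work[j]
                if abs(work[j]) < 1e-250:
                    broke = True
                    break
                new[j] = (prev - work[j]) / denom
            if broke:
                warnings.warn(
                    f"Pade breakdown at level {k}; truncating to {k} coefficients"
                )
                break
            if abs(new[k]) * scale < 1e-30 * scale and all(
                abs(new[j]) < 1e-25 for j in range(k, n)
            ):
                break  # rational function already reproduced exactly
            a.append(new[k])
            work = new
        coeffs = [mp.mpc(c) for c in a]
        nodes = [mp.mpc(z) for z in zs[: len(coeffs)]]

    def evaluate(z) -> complex:
        with mp.workdps(dps):
            zz = mp.mpc(z)
            val = mp.mpc(1)
            for k in range(len(coeffs) - 1, 0, -1):
                if val == 0:
                    val = mp.mpc(1e-250)
                val = 1 + coeffs[k] * (zz - nodes[k - 1]) / val
            if val == 0:
                val = mp.mpc(1e-250)
            res = coeffs[0] / val
            return complex(res)

    return evaluate


@dataclass
class QPEntry:
    orbital: int
    eps: float
    sigma_x: float
    sigma_stat: float
    vxc: float
    qp_energy: float
    sigma_c_at_qp: float
    slope: float
    z_factor: float
    n_roots_found: int
    selected_root_index: int
    fallback: bool


def solve_qp(eps_n: float, sigma_x_nn: float, sigma_c_fn, vxc_nn: float,
             sigma_stat_nn: float = 0.0, mu_F: float = 0.0,
             window: float = 2.0, step: float = 0.01, delta: float = 1e-3,
             orbital: int = 0) -> QPEntry:
    """Solve E = eps_n + Sigma_x + Sigma_stat + Re Sigma_c(E) - vxc.

    Scans a real-energy window around eps_n for sign changes, polishes each
    root by Newton iteration, and selects the root where |d Sigma_c / dE| is
    smallest (the quasiparticle; steeper roots are satellites).
    Z = 1 / (1 - d Sigma/dE).  If no root lies in the window, returns the
    linearized one-shot estimate flagged as fallback.
    """
    def sig_c(E: float) -> float:
        return sigma_c_fn(complex(E - mu_F, delta)).real

    const = sigma_x_nn + sigma_stat_nn - vxc_nn

    def f(E: float) -> float:
        return E - eps_n - const - sig_c(E)

    def slope_at(E: float, h: float = 1e-4) -> float:
        return (sig_c(E + h) - sig_c(E - h)) / (2 * h)

    energies = np.arange(eps_n - window, eps_n + window + 0.5 * step, step)
    fvals = np.array([f(E) for E in energies])
    roots: list[float] = []
    for i in range(len(energies) - 1):
        if np.sign(fvals[i]) != np.sign(fvals[i + 1]) and np.isfinite(fvals[i]):
            E = 0.5 * (energies[i] + energies[i + 1])
            for _ in range(50):  # Newton with numeric derivative
                df = 1.0 - slope_at(E)
                if df == 0:
                    break
                dE = f(E) / df
                E -= dE
                if abs(dE) < 1e-12:
                    break
            if energies[i] - step <= E <= energies[i + 1] + step and abs(f(E)) < 1e-6:
                if not any(abs(E - r) < 1e-8 for r in roots):
                    roots.append(E)

    if roots:
        slopes = [slope_at(E) for E in roots]
        isel = int(np.argmin(np.abs(slopes)))
        E = roots[isel]
        sl = slopes[isel]
        fallback = False
    else:
        sl = slope_at(eps_n)
        z0 = 1.0 / (1.0 - sl)
        E = eps_n + z0 * (const + sig_c(eps_n))
        isel = -1
        fallback = True

    z = 1.0 / (1.0 - sl)
    return QPEntry(
        orbital=orbital, eps=eps_n, sigma_x=sigma_x_nn, sigma_stat=sigma_stat_nn,
        vxc=vxc_nn, qp_energy=E, sigma_c_at_qp=sig_c(E), slope=sl, z_factor=z,
        n_roots_found=len(roots), selected_root_index=isel, fallback=fallback,
    )


@dataclass
class QPSolution:
    """Per-orbital quasiparticle results and the derived frontier quantities."""

    entries: dict[int, QPEntry]
    homo_index: int
    mu_F: float = 0.0
    meta: dict = field(default_factory=dict)

    @property
    def homo(self) -> QPEntry:
        if self.homo_index not in self.entries:
            raise KeyError("HOMO was not among the solved orbitals")
        return self.entries[self.homo_index]

    def qp_energy(self, n: int) -> float:
        return self.entries[n].qp_energy

    def to_dict(self) -> dict:
        return {
            "homo_index": self.homo_index,
            "mu_F": self.mu_F,
            "orbitals": {
                str(n): {
                    "eps": e.eps, "sigma_x": e.sigma_x, "sigma_stat": e.sigma_stat,
                    "vxc": e.vxc, "qp_energy": e.qp_energy,
                    "sigma_c_at_qp": e.sigma_c_at_qp, "slope": e.slope,
                    "z_factor": e.z_factor, "n_roots_found": e.n_roots_found,
                    "selected_root_index": e.selected_root_index,
                    "fallback": e.fallback,
                }
                for n, e in self.entries.items()
            },
            **self.meta,
        }


def g0w0(mo_energy, mo_occ, X_mo, J2c, vxc_diag,
         dv_res: np.ndarray | None = None,
         n_freq: int = 25, grid_scale: float = 1.0,
         include_static: bool = True,
         target_orbitals=None,
         window: float = 2.0, step: float = 0.01, delta: float = 1e-3) -> QPSolution:
    """One-shot diagonal GW on the imaginary axis for the requested orbitals.

    ``X_mo`` are the MO-transformed three-center factors (nmo, nmo, naux);
    ``dv_res`` the reaction-field matrix in the same auxiliary basis (None or
    zeros for a vacuum/EE run).  Only diagonal self-energy elements are used.
    """
    mo_energy = np.asarray(mo_energy, float)
    mo_occ = np.asarray(mo_occ, float)
    occ, _ = _split_occ_virt(mo_occ)
    homo = int(occ.max())
    if target_orbitals is None:
        target_orbitals = list(range(len(mo_energy)))
    target_orbitals = list(target_orbitals)

    grid = make_frequency_grid(n_freq, grid_scale)
    chi0 = compute_chi0(mo_energy, mo_occ, X_mo, grid)
    W = compute_screened_interaction(chi0, J2c, dv_res)
    sx = exchange_self_energy(X_mo, J2c, mo_occ)
    if dv_res is not None and include_static:
        sstat = static_self_energy(X_mo, J2c, dv_res, mo_occ)
    else:
        sstat = np.zeros_like(sx)
    samples = correlation_self_energy(mo_energy, mo_occ, X_mo, J2c, W, target_orbitals)

    entries = {}
    mu_F = samples[0].mu_F if samples else 0.0
    for n, smp in zip(target_orbitals, samples):
        fn = pade_continuation(smp.points, smp.values)
        entries[n] = solve_qp(
            mo_energy[n], sx[n], fn, float(np.asarray(vxc_diag)[n]),
            sigma_stat_nn=sstat[n], mu_F=smp.mu_F,
            window=window, step=step, delta=delta, orbital=n,
        )
    return QPSolution(entries=entries, homo_index=homo, mu_F=mu_F,
                      meta={"n_freq": n_freq, "grid_scale": grid_scale,
                            "include_static": include_static})


def ionization_potential(qp: QPSolution) -> float:
    """IP = -E_HOMO^GW in eV."""
    e = qp.homo
    if e.fallback:
        raise RuntimeError("quasiparticle equation for the HOMO did not converge to a root")
    return -e.qp_energy * HARTREE_EV
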