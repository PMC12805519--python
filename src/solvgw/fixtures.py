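"""Deterministic synthetic test systems: solvent shells and low-dimensional
GW models with independent brute-force references.

Parameter presets are *synthetic*: plausible electronegativity/hardness/
polarizability values for a rigid water-like solvent, chosen once so that
(i) the constrained response matrix stays positive definite with undamped
Coulomb kernels at intramolecular distances, and (ii) the kC-scaled
equilibrium FQ charges of an isolated molecule reproduce the fixed-charge
electrostatics seen by the QM region (fixed charges couple with plain
Coulomb, fluctuating ones with kC) — which makes EE and FQ runs
electrostatically equivalent at leading order, isolating the screening
effect.
They do not reproduce any published force-field parametrization.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import cos, radians, sin

import numpy as np

from .constants import BOHR_PER_ANGSTROM
from .embedding import QMRegion
from .mm import EmbeddingModel, MMSite, MMTopology

__all__ = [
    "FixtureSpec",
    "PARAMETER_PRESETS",
    "water_geometry",
    "generate_solvent_cluster",
    "generate_snapshot",
    "two_level_qm_model",
    "brute_force_gw_reference",
]

#: synthetic water-like parameter presets (a.u.); see module docstring.
#: chi is calibrated per polarizable model so that the kC-scaled electrostatic
#: moments of an *isolated* molecule reproduce the fixed-charge set: for FQ the
#: equilibrium charges themselves (q_O = -0.68/kC), for FQFmu the total
#: molecular dipole (charges plus the intramolecularly induced atomic dipoles).
#: This makes EE the matched non-polarizable baseline of each model, so that
#: EE-vs-polarizable comparisons probe the reaction-field screening rather
#: than accidental electrostatic offsets.
PARAMETER_PRESETS: dict[str, dict[str, dict[str, float]]] = {
    "water-synthetic": {
        "OW": {"chi": 0.8391504378389062, "chi_fqfmu": 1.148706451832682,
               "eta": 1.4, "alpha": 1.0, "fixed_charge": -0.68},
        "HW": {"chi": 0.0, "chi_fqfmu": 0.0, "eta": 1.0, "alpha": 0.4,
               "fixed_charge": 0.34},
    },
}

_ROH = 0.9572 * BOHR_PER_ANGSTROM
_HALF_HOH = radians(104.52) / 2.0


def water_geometry() -> np.ndarray:
    """Rigid 3-site water-like molecule (O, H, H), O at the origin, Bohr."""
    return np.array([
        [0.0, 0.0, 0.0],
        [_ROH * sin(_HALF_HOH), _ROH * cos(_HALF_HOH), 0.0],
        [-_ROH * sin(_HALF_HOH), _ROH * cos(_HALF_HOH), 0.0],
    ])


@dataclass
class FixtureSpec:
    """Seeded solvent-shell specification (distances in Angstrom)."""

    seed: int = 0
    n_solvent_molecules: int = 3
    shell_inner: float = 2.6
    shell_outer: float = 4.5
    min_distance: float = 1.9
    preset: str = "water-synthetic"
    max_attempts: int = 5000

    def __post_init__(self):
        if self.min_distance <= 0:
            raise ValueError("minimum intersite distance must be positive")
        if self.shell_outer <= self.shell_inner:
            raise ValueError("shell radii must be increasing")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def generate_solvent_cluster(spec: FixtureSpec,
                             model: EmbeddingModel | str = EmbeddingModel.FQ,
                             center: np.ndarray | None = None) -> MMTopology:
    """Place rigid water-like molecules in a spherical shell around ``center``.

    Orientations and shell positions are drawn from a seeded generator;
    placements violating the minimum intersite distance (to previously placed
    sites and to the shell center) are rejected.  Deterministic per seed.
    """
    model = EmbeddingModel(model)
    params = PARAMETER_PRESETS[spec.preset]
    center = np.zeros(3) if center is None else np.asarray(center, float)
    rng = np.random.default_rng(spec.seed)
    base = water_geometry()
    mindist = spec.min_distance * BOHR_PER_ANGSTROM
    r_in = spec.shell_inner * BOHR_PER_ANGSTROM
    r_out = spec.shell_outer * BOHR_PER_ANGSTROM

    placed: list[np.ndarray] = []
    molecules: list[np.ndarray] = []
    attempts = 0
    while len(molecules) < spec.n_solvent_molecules:
        attempts += 1
        if attempts > spec.max_attempts:
            raise RuntimeError(
                f"could not place {spec.n_solvent_molecules} molecules in "
                f"{spec.max_attempts} attempts; enlarge the shell"
            )
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        radius = (r_in ** 3 + rng.random() * (r_out ** 3 - r_in ** 3)) ** (1 / 3)
        R = _random_rotation(rng)
        cog = center + radius * u
        coords = cog + base @ R.T
        ok = all(np.linalg.norm(c - center) >= mindist for c in coords)
        if ok and placed:
            prev = np.vstack(placed)
            d = np.linalg.norm(coords[:, None, :] - prev[None, :, :], axis=-1)
            ok = d.min() >= mindist
        if not ok:
            continue
        molecules.append(coords)
        placed.extend(coords)

    sites: list[MMSite] = []
    use_fixed = model in (EmbeddingModel.EE, EmbeddingModel.DRF)
    chi_key = "chi_fqfmu" if model is EmbeddingModel.FQFMU else "chi"
    for mol_id, coords in enumerate(molecules):
        for atype, xyz in zip(("OW", "HW", "HW"), coords):
            p = params[atype]
            sites.append(MMSite(
                position=xyz, molecule_id=mol_id,
                fixed_charge=p["fixed_charge"] if use_fixed else 0.0,
                chi=p.get(chi_key, p["chi"]), eta=p["eta"], alpha=p["alpha"],
                atom_type=atype,
            ))
    return MMTopology(sites=sites, model=model)


def generate_snapshot(spec: FixtureSpec,
                      model: EmbeddingModel | str = EmbeddingModel.FQ,
                      solute: str = "He", basis: str = "6-31g",
                      ) -> tuple[QMRegion, MMTopology]:
    """A QM solute at the origin inside a seeded solvent shell."""
    qm = QMRegion(symbols=[solute], coords=np.zeros((1, 3)), basis=basis)
    topo = generate_solvent_cluster(spec, model)
    return qm, topo


@dataclass
class TwoLevelModel:
    """One occupied / one virtual orbital with a single auxiliary function.

    (ia|P) = coupling; vxc = 0.  Closed-form references:
    chi0(i omega) = -4 d^2 Delta / (Delta^2 + omega^2), and a one-pole
    screened interaction with excitation Omega = sqrt(Delta (Delta + 4 d^2)).
    """

    gap: float
    coupling: float

    def __post_init__(self):
        if self.gap <= 0:
            raise ValueError("gap must be positive")
        self.mo_energy = np.array([-self.gap / 2, self.gap / 2])
        self.mo_occ = np.array([2.0, 0.0])
        self.vxc_diag = np.zeros(2)
        X = np.zeros((2, 2, 1))
        X[0, 1, 0] = X[1, 0, 0] = self.coupling
        self.X_mo = X
        self.J2c = np.eye(1)

    @property
    def omega_rpa(self) -> float:
        return np.sqrt(self.gap * (self.gap + 4 * self.coupling ** 2))

    def sigma_c_exact(self, E: complex, n: int = 0) -> complex:
        """Analytic one-pole GW correlation self-energy for orbital n."""
        om = self.omega_rpa
        d, g = self.coupling, self.gap
        # residue of <01|Wc|10> at the RPA pole: (ia|P)^2 * 4 d^2 Delta / (2 Omega)
        v2 = 2 * d ** 4 * g / om
        if n == 0:  # HOMO couples to the virtual level (m = 1)
            return v2 / (E - self.mo_energy[1] - om)
        return v2 / (E - self.mo_energy[0] + om)


def two_level_qm_model(gap: float, coupling: float) -> TwoLevelModel:
    return TwoLevelModel(gap=gap, coupling=coupling)


def brute_force_gw_reference(mo_energy, mo_occ, X_mo, J2c, vxc_diag,
                             dv_res=None, window: float = 2.0,
                             scan_step: float = 5e-4) -> dict:
    """Dense real-axis sum-over-states G0W0 — the independent oracle.

    Diagonalizes the (direct) RPA screening exactly, builds the pole-sum
    self-energy, and solves the quasiparticle equation graphically on a dense
    real-energy scan with bisection polishing and smallest-slope selection.
    No frequency quadrature and no analytic continuation are involved.
    """
    mo_energy = np.asarray(mo_energy, float)
    mo_occ = np.asarray(mo_occ, float)
    nmo = len(mo_energy)
    if nmo > 10:
        raise ValueError("brute-force reference is limited to <= 10 orbitals")
    occ = np.where(mo_occ > 0)[0]
    virt = np.where(mo_occ == 0)[0]
    naux = J2c.shape[0]

    w, U = np.linalg.eigh(J2c)
    Jm12 = U @ np.diag(w ** -0.5) @ U.T
    Jinv = U @ np.diag(1.0 / w) @ U.T
    B = np.einsum("pqP,PQ->pqQ", X_mo, Jm12)  # metric-dressed factors

    sigma_x = np.zeros(nmo)
    sigma_stat = np.zeros(nmo)
    for n in range(nmo):
        for i in occ:
            sigma_x[n] -= B[n, i] @ B[n, i]
            if dv_res is not None:
                c = Jinv @ X_mo[n, i]
                sigma_stat[n] -= c @ dv_res @ c

    # exact dRPA diagonalization in the particle-hole space
    pairs = [(i, a) for i in occ for a in virt]
    if pairs:
        delta = np.array([mo_energy[a] - mo_energy[i] for i, a in pairs])
        Bov = np.array([B[i, a] for i, a in pairs])  # (nov, naux)
        K = Bov @ Bov.T
        sq = np.sqrt(delta)
        C = np.diag(delta ** 2) + 4.0 * (sq[:, None] * K * sq[None, :])
        om2, Z = np.linalg.eigh(C)
        omega_s = np.sqrt(np.maximum(om2, 0.0))
        # residue vectors w_s = 2 Bov^T (sqrt(delta) z_s)
        Wres = 2.0 * Bov.T @ (sq[:, None] * Z)  # (naux, n_s)
    else:
        omega_s = np.zeros(0)
        Wres = np.zeros((naux, 0))

    def sigma_c(nidx: int, E: float) -> float:
        val = 0.0
        for s in range(len(omega_s)):
            oms = omega_s[s]
            if oms < 1e-12:
                continue
            for m in range(nmo):
                v2 = float(B[nidx, m] @ Wres[:, s]) ** 2 / (2 * oms)
                if v2 == 0.0:
                    continue
                if mo_occ[m] > 0:
                    val += v2 / (E - mo_energy[m] + oms)
                else:
                    val += v2 / (E - mo_energy[m] - oms)
        return val

    def sigma_c_slope(nidx: int, E: float) -> float:
        val = 0.0
        for s in range(len(omega_s)):
            oms = omega_s[s]
            if oms < 1e-12:
                continue
            for m in range(nmo):
                v2 = float(B[nidx, m] @ Wres[:, s]) ** 2 / (2 * oms)
                if v2 == 0.0:
                    continue
                pole = mo_energy[m] - oms if mo_occ[m] > 0 else mo_energy[m] + oms
                val -= v2 / (E - pole) ** 2
        return val

    qp = np.zeros(nmo)
    slopes = np.zeros(nmo)
    for n in range(nmo):
        const = sigma_x[n] + sigma_stat[n] - np.asarray(vxc_diag)[n]

        def f(E, n=n, const=const):
            return E - mo_energy[n] - const - sigma_c(n, E)

        Es = np.arange(mo_energy[n] - window, mo_energy[n] + window, scan_step)
        with np.errstate(divide="ignore", invalid="ignore"):
            fv = np.array([f(E) for E in Es])
            roots = []
            for i in range(len(Es) - 1):
                if np.sign(fv[i]) != np.sign(fv[i + 1]):
                    lo, hi = Es[i], Es[i + 1]
                    for _ in range(80):
                        mid = 0.5 * (lo + hi)
                        if np.sign(f(mid)) == np.sign(f(lo)):
                            lo = mid
                        else:
                            hi = mid
                    mid = 0.5 * (lo + hi)
                    if abs(f(mid)) < 1e-5:  # discard pole crossings
                        roots.append(mid)
        if roots:
            sl = [sigma_c_slope(n, E) for E in roots]
            k = int(np.argmin(np.abs(sl)))
            qp[n], slopes[n] = roots[k], sl[k]
        else:
            qp[n] = mo_energy[n] + const + sigma_c(n, mo_energy[n])
            slopes[n] = sigma_c_slope(n, mo_energy[n])

    return {
        "qp_energy": qp,
        "sigma_x": sigma_x,
        "sigma_stat": sigma_stat,
        "slopes": slopes,
        "omega_rpa": omega_s,
        "homo_index": int(occ.max()),
    }
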