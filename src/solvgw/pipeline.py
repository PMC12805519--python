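"""Snapshot-ensemble orchestration: IO, per-snapshot GW runs, CBS, statistics.

A snapshot is a geometry file (XYZ, extended XYZ with a molecule-id column,
or PDB) partitioned into a QM solute and an MM solvent shell by a cutoff
rule: a solvent molecule belongs to the MM region when its center of
geometry lies within the cutoff radius of the QM region.  Each snapshot is
run through the coupled SCF -> reaction kernel -> GW chain for every
requested embedding model and basis, two-point CBS-extrapolated, and the
ensemble is summarized as mean/std and shift against the vacuum reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .constants import BOHR_PER_ANGSTROM, DEFAULT_KC
from .embedding import QMRegion, run_coupled_scf, mo_three_center
from .gw import g0w0, ionization_potential
from .mm import EmbeddingModel, MMSite, MMTopology, assemble_response_system
from .reaction import build_reaction_matrix, compute_aux_site_integrals

__all__ = [
    "RunConfig",
    "SnapshotRecord",
    "EnsembleSummary",
    "load_parameters",
    "read_xyz",
    "read_snapshot",
    "cbs_extrapolate",
    "ensemble_summary",
    "run_snapshot",
    "run_vacuum",
]


@dataclass
class RunConfig:
    """Run settings; distances in Angstrom, model names as in EmbeddingModel."""

    qm_indices: list[int] = field(default_factory=lambda: [0])
    cutoff: float = 5.0
    models: list[str] = field(default_factory=lambda: ["EE", "FQ", "FQFMU"])
    basis_pair: tuple[str, str] = ("sto-3g", "6-31g")
    n_freq: int = 25
    grid_scale: float = 1.0
    kC: float = DEFAULT_KC
    functional: str = "hf"
    charge: int = 0
    include_static: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        for m in self.models:
            EmbeddingModel(m)
        if self.basis_pair[0] == self.basis_pair[1]:
            raise ValueError("basis pair must be distinct")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "basis_pair" in data:
            data["basis_pair"] = tuple(data["basis_pair"])
        return cls(**data)


def load_parameters(path) -> dict[str, dict[str, float]]:
    """Atom-type parameter file: YAML mapping type -> chi/eta/alpha/fixed_charge."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    types = data.get("types", data)
    out = {}
    for name, p in types.items():
        out[str(name)] = {
            "chi": float(p.get("chi", 0.0)),
            "eta": float(p.get("eta", 0.0)),
            "alpha": float(p.get("alpha", 0.0)),
            "fixed_charge": float(p.get("fixed_charge", 0.0)),
        }
    return out


def read_xyz(path) -> tuple[list[str], np.ndarray, list[int] | None]:
    """Plain or extended XYZ; a 5th column is read as the molecule id.

    Returns symbols, coordinates in Angstrom, and molecule ids (or None).
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    try:
        natom = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path}: line 1: bad atom count") from exc
    symbols, coords, molids = [], [], []
    has_ids = None
    for k in range(natom):
        ln = 2 + k
        if ln >= len(lines):
            raise ValueError(f"{path}: line {ln + 1}: unexpected end of file")
        parts = lines[ln].split()
        if len(parts) < 4:
            raise ValueError(f"{path}: line {ln + 1}: malformed coordinate line")
        try:
            xyz = [float(x) for x in parts[1:4]]
        except ValueError as exc:
            raise ValueError(f"{path}: line {ln + 1}: malformed coordinate line") from exc
        symbols.append(parts[0])
        coords.append(xyz)
        if len(parts) >= 5:
            if has_ids is False:
                raise ValueError(f"{path}: line {ln + 1}: inconsistent molecule-id column")
            has_ids = True
            molids.append(int(parts[4]))
        else:
            if has_ids:
                raise ValueError(f"{path}: line {ln + 1}: inconsistent molecule-id column")
            has_ids = False
    return symbols, np.array(coords), (molids if has_ids else None)


def _read_pdb(path) -> tuple[list[str], np.ndarray, list[int]]:
    import biotite.structure.io.pdb as pdb

    arr = pdb.PDBFile.read(str(path)).get_structure(model=1)
    symbols = [e.capitalize() for e in arr.element]
    # residue ids as molecule ids
    return symbols, np.asarray(arr.coord, float), [int(r) for r in arr.res_id]


def _infer_molecules(symbols: list[str], coords_ang: np.ndarray,
                     bond_cutoff: float = 1.8) -> list[int]:
    """Union-find molecule assignment by a covalent distance cutoff (Angstrom)."""
    n = len(symbols)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(coords_ang[i] - coords_ang[j]) < bond_cutoff:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    roots = {}
    out = []
    for i in range(n):
        r = find(i)
        out.append(roots.setdefault(r, len(roots)))
    return out


def read_snapshot(path, config: RunConfig,
                  parameters: dict[str, dict[str, float]],
                  model: EmbeddingModel | str | None = None,
                  ) -> tuple[QMRegion, MMTopology]:
    """Partition a snapshot into QM region and cutoff-selected MM topology.

    Solvent molecules are included whole: a molecule enters the MM region iff
    its center of geometry is within ``config.cutoff`` (Angstrom) of the
    nearest QM atom.  Parameters attach by atom type (element symbol lookup).
    """
    path = str(path)
    if path.endswith(".pdb"):
        symbols, coords, molids = _read_pdb(path)
    else:
        symbols, coords, molids = read_xyz(path)
    model = EmbeddingModel(model if model is not None else config.models[0])

    qm_idx = list(config.qm_indices)
    if not qm_idx:
        raise ValueError("QM selection is empty")
    mm_idx = [i for i in range(len(symbols)) if i not in set(qm_idx)]
    if molids is None:
        inferred = _infer_molecules([symbols[i] for i in mm_idx], coords[mm_idx])
        molids_mm = dict(zip(mm_idx, inferred))
    else:
        molids_mm = {i: molids[i] for i in mm_idx}

    qm_coords_ang = coords[qm_idx]
    groups: dict[int, list[int]] = {}
    for i in mm_idx:
        groups.setdefault(molids_mm[i], []).append(i)

    use_fixed = model in (EmbeddingModel.EE, EmbeddingModel.DRF)
    sites = []
    next_id = 0
    for mol_id in sorted(groups):
        members = groups[mol_id]
        cog = coords[members].mean(axis=0)
        dist = np.min(np.linalg.norm(qm_coords_ang - cog, axis=1))
        if dist > config.cutoff:
            continue
        for i in members:
            atype = symbols[i] if symbols[i] in parameters else symbols[i].upper()
            if atype not in parameters:
                raise KeyError(f"no parameters for atom type '{symbols[i]}'")
            p = parameters[atype]
            sites.append(MMSite(
                position=coords[i] * BOHR_PER_ANGSTROM,
                molecule_id=next_id,
                fixed_charge=p["fixed_charge"] if use_fixed else 0.0,
                chi=p["chi"], eta=p["eta"], alpha=p["alpha"], atom_type=atype,
            ))
        next_id += 1

    qm = QMRegion(
        symbols=[symbols[i] for i in qm_idx],
        coords=coords[qm_idx] * BOHR_PER_ANGSTROM,
        charge=config.charge,
        basis=config.basis_pair[0],
        functional=config.functional,
    )
    return qm, MMTopology(sites=sites, model=model)


def cbs_extrapolate(e_small: float, e_large: float,
                    n_small: int, n_large: int) -> float:
    """Two-point extrapolation weighted by the actual basis dimensions."""
    if n_small <= 0 or n_large <= n_small:
        raise ValueError("basis sizes must satisfy n_large > n_small > 0")
    return (n_large * e_large - n_small * e_small) / (n_large - n_small)


@dataclass
class SnapshotRecord:
    snapshot_id: int
    model: str
    basis_values: dict[str, float]     # basis label -> IP (eV)
    basis_sizes: dict[str, int]
    cbs: float | None
    converged: bool
    details: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


@dataclass
class EnsembleSummary:
    n: int
    mean_ip: float
    std_ip: float
    shift_vs_vacuum: float | None


def _single_gw_ip(qm: QMRegion, topology: MMTopology | None, model: str,
                  basis: str, config: RunConfig) -> tuple[float, int, dict]:
    """Coupled SCF + reaction kernel + GW for one model/basis; IP in eV."""
    qm = QMRegion(qm.symbols, qm.coords, qm.charge, 1, basis, qm.functional)
    topo = None
    if topology is not None and topology.n_sites:
        topo = MMTopology(
            sites=topology.sites, model=EmbeddingModel(model),
            total_charge_per_molecule=topology.total_charge_per_molecule,
        )
    mf, polstate = run_coupled_scf(qm, topo, kC=config.kC)

    dv = None
    if topo is not None and topo.model is not EmbeddingModel.EE:
        system = assemble_response_system(topo)
        ints = compute_aux_site_integrals(mf.ints.aux, topo)
        dv = build_reaction_matrix(ints, system, topo.model, kC=config.kC).matrix

    X_mo = mo_three_center(mf)
    qp = g0w0(
        mf.mo_energy, mf.mo_occ, X_mo, mf.ints.J2c, mf.vxc_diag,
        dv_res=dv, n_freq=config.n_freq, grid_scale=config.grid_scale,
        include_static=config.include_static,
        target_orbitals=[mf.homo_index],
    )
    ip = ionization_potential(qp)
    details = {
        "e_tot": mf.e_tot,
        "eps_homo": float(mf.mo_energy[mf.homo_index]),
        "qp_homo": qp.homo.qp_energy,
        "z_factor": qp.homo.z_factor,
        "n_macro": mf.n_macro,
    }
    return ip, mf.nmo, details


def run_snapshot(config: RunConfig, qm: QMRegion, topology: MMTopology | None,
                 model: str, snapshot_id: int = 0) -> SnapshotRecord:
    """Run one snapshot for one embedding model over the basis pair + CBS."""
    values: dict[str, float] = {}
    sizes: dict[str, int] = {}
    details: dict = {}
    converged = True
    for basis in config.basis_pair:
        try:
            ip, nbas, det = _single_gw_ip(qm, topology, model, basis, config)
        except Exception as exc:
            raise RuntimeError(
                f"snapshot {snapshot_id}, model {model}, basis {basis}: {exc}"
            ) from exc
        values[basis] = ip
        sizes[basis] = nbas
        details[basis] = det
    cbs = None
    if converged:
        b0, b1 = config.basis_pair
        small, large = (b0, b1) if sizes[b0] <= sizes[b1] else (b1, b0)
        cbs = cbs_extrapolate(values[small], values[large], sizes[small], sizes[large])
    return SnapshotRecord(
        snapshot_id=snapshot_id, model=model, basis_values=values,
        basis_sizes=sizes, cbs=cbs, converged=converged, details=details,
    )


def run_vacuum(config: RunConfig, qm: QMRegion, snapshot_id: int = -1) -> SnapshotRecord:
    return run_snapshot(config, qm, None, "EE", snapshot_id=snapshot_id)


def ensemble_summary(records: list[SnapshotRecord],
                     vacuum_reference: float | None = None,
                     use_cbs: bool = True) -> EnsembleSummary:
    """Mean, sample standard deviation and solvatochromic shift of the IPs."""
    vals = []
    for r in records:
        if not r.converged:
            continue
        if use_cbs and r.cbs is not None:
            vals.append(r.cbs)
        else:
            vals.append(list(r.basis_values.values())[-1])
    if len(vals) < 2:
        raise ValueError("ensemble summary needs at least 2 converged records")
    arr = np.array(vals)
    shift = None if vacuum_reference is None else float(arr.mean() - vacuum_reference)
    return EnsembleSummary(n=len(arr), mean_ip=float(arr.mean()),
                           std_ip=float(arr.std(ddof=1)), shift_vs_vacuum=shift)
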