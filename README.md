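# solvgw

One-shot GW quasiparticle calculations coupled to classical polarizable
environments: **G0W0/EE, G0W0/FQ, G0W0/DRF and G0W0/FQFμ**.

## The problem

The ionization potential (IP) of a molecule changes substantially between gas
phase and solution, because the environment both polarizes the ground-state
electronic structure (*implicit* effect) and screens the electron–electron
interaction felt by the created hole (*explicit* effect).  Non-polarizable
QM/MM embeddings capture only the first; dielectric-continuum models miss the
atomistic structure of the solvent shell.  `solvgw` targets computational
chemists who want quasiparticle energies of a solvated chromophore from
snapshot ensembles, with the solvent described by an atomistic polarizable
force field whose linear response enters the GW screening itself.

## The model

The environment is a set of atom-centered sites carrying fixed multipoles
**M** and polarizable degrees of freedom **D**:

| model | **M**        | **D**                    |
|-------|--------------|--------------------------|
| EE    | fixed q      | —                        |
| FQ    | —            | fluctuating charges q    |
| DRF   | fixed q      | induced dipoles μ        |
| FQFμ  | —            | q and μ, cross-coupled   |

Fluctuating charges follow electronegativity equalization: with per-site
electronegativity χ and hardness η, **D** minimizes the quadratic energy
½ **D**ᵀA**D** + **D**ᵀ(χ + couplings) under one total-charge constraint per
molecule.  An infinitesimal test charge dQ at **r**′ in the QM region induces

    dD = −kC · B · [T⁽⁰⁾(r′); T⁽¹⁾(r′)] dQ,

where B is the blockwise inverse of the constrained response matrix,
T⁽⁰⁾ = 1/|r′−r_t| and T⁽¹⁾ = (r′−r_t)/|r′−r_t|³ are the charge and dipole
kernels, and kC = 0.7853 a.u. scales the QM↔MM polarizable coupling.  The
induced back-potential defines a static reaction-field correction

    dv_res(r, r′) = −kC² [T⁽⁰⁾(r); T⁽¹⁾(r)]ᵀ B [T⁽⁰⁾(r′); T⁽¹⁾(r′)],

a negative-semidefinite (stabilizing) modification of the bare Coulomb
interaction.  Projected on the auxiliary density-fitting basis it enters the
screened interaction through the Dyson equation

    ṽ = v + dv_res,      W₀(iω) = ṽ + ṽ χ₀(iω) W₀(iω),

with χ₀ the independent-particle polarizability of the QM region.  The
diagonal G0W0 quasiparticle equation

    Eₙ = εₙ + [Σx + Σstat + Σc(Eₙ) − vxc]ₙₙ,      IP = −E_HOMO

is solved on the imaginary frequency axis (25-point Gauss–Legendre grid by
default), with the correlation self-energy continued to real energies by a
Thiele/Padé interpolant and the physical root selected by the
smallest-slope rule, Z = 1/(1 − ∂Σ/∂E).  Σstat = −Σᵢ⟨ni|dv_res|in⟩ is the
static exchange-like environment term (switchable).

The QM reference is a self-contained density-fitted restricted Hartree–Fock
backend over s-type Gaussians (H and He; STO-3G and 6-31G), solved
self-consistently with the classical polarization.  Every reaction-field
matrix is verifiable against a finite-difference oracle that re-solves the
classical ground state with an explicit test charge.

## Worked example

```python
import numpy as np
from solvgw import QMRegion, RunConfig, run_snapshot
from solvgw.fixtures import FixtureSpec, generate_snapshot
from solvgw.pipeline import run_vacuum

cfg = RunConfig()                      # sto-3g/6-31g pair, 25-point grid
qm = QMRegion(["He"], np.zeros((1, 3)))
vac = run_vacuum(cfg, qm)
print(f"vacuum IP (CBS): {vac.cbs:.4f} eV")

spec = FixtureSpec(seed=1, n_solvent_molecules=3)   # water-like shell
for model in ("EE", "FQ", "DRF", "FQFMU"):
    qm, topo = generate_snapshot(spec, model=model)
    rec = run_snapshot(cfg, qm, topo, model)
    print(f"{model:6s} IP (CBS): {rec.cbs:.4f} eV")
```

prints

```
vacuum IP (CBS): 23.5387 eV
EE     IP (CBS): 23.7091 eV
FQ     IP (CBS): 23.6722 eV
DRF    IP (CBS): 23.6721 eV
FQFMU  IP (CBS): 23.6554 eV
```

For this snapshot the fixed-charge environment *raises* the helium IP by
0.17 eV (pure electrostatics), while every polarizable model pulls it back
down — the reaction field stabilizes the cation, and FQFμ, with both charge
and dipole response channels, screens the most.  That ordering
(EE > FQ ≈ DRF > FQFμ) is the qualitative signature of environment-screened
GW.

A CLI mirrors the library:
`solvgw vacuum`, `solvgw snapshot geometry.xyz --params params.yaml`,
`solvgw ensemble`, `solvgw classical-check` (finite-difference oracle suite)
and `solvgw fixtures` (emit seeded XYZ + parameter files).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch: the gas-phase G0W0 IP of helium,
a seeded 3-snapshot ensemble of water-like shells run through coupled
SCF → reaction kernel → G0W0 for all four embedding models with two-point
CBS extrapolation, ensemble means/standard deviations and solvatochromic
shifts, and the classical reaction-field oracle check.  Progress and all
computed numbers go to stderr and to `results/acceptance.details.json`.
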