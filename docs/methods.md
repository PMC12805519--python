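# Methods

## Scope and architecture

`solvgw` computes diagonal one-shot GW (G0W0) quasiparticle energies for a
small closed-shell QM region embedded in a classical environment whose linear
response modifies the screened Coulomb interaction.  Four embedding models
are supported: electrostatic embedding (EE, fixed charges), fluctuating
charges (FQ), a discrete reaction field of induced point dipoles on fixed
charges (DRF), and fluctuating charges plus fluctuating dipoles (FQFμ).

The chain is: coupled SCF (mean field polarized by the environment) →
classical response system and reaction-field matrix dv_res in the auxiliary
basis → χ₀, W₀ and self-energy on the imaginary frequency axis → Padé
analytic continuation → quasiparticle equation → IP and snapshot-ensemble
statistics.

## Classical response

Sites carry electronegativity χ, hardness η and isotropic polarizability α
(atomic units; positions are read in Å and converted to Bohr).  The
polarizable degrees of freedom minimize

E[q, μ] = χᵀq + ½qᵀT_qq q + qᵀT_qμ μ + ½μᵀT_μμ μ − μᵀE_ext + qᵀV_ext,

subject to one total-charge constraint per molecule (Lagrange multipliers;
default molecular charge 0).  T_qq has η on the diagonal and the bare
Coulomb kernel off it; T_μμ has α⁻¹·I site-diagonal blocks and the undamped
point-dipole tensor off-site (a linear Thole damping switch exists but
defaults off); T_qμ is the bare charge–dipole kernel with same-site terms
excluded.  Degrees of freedom are ordered [q | λ | μ] and the blockwise
inverse B is read off the inverse of the full constrained matrix.

**Stability constraint.** With undamped kernels the physical block of the
response matrix must be positive definite; at water-like intramolecular
distances this bounds η from below (η_O ≳ 1.2 a.u. for the synthetic preset)
and α from above (α_O α_H ≲ r⁶/4).  The shipped preset respects both; a
violated bound manifests as a positive eigenvalue in dv_res, i.e. an
unphysical destabilizing reaction field.

**Sign conventions.** All signs are fixed by one energy expression
(charge–dipole interaction U = q·μ·(r_q − r_μ)/|r_q − r_μ|³ on both the
perturbation and evaluation side), which yields dD = −kC·B·U(r′) and

dv_res(r, r′) = −kC²·U(r)ᵀ B U(r′),   U = [T⁽⁰⁾; T⁽¹⁾].

This is symmetric (reciprocity) and negative semidefinite whenever the
response system is stable — a reaction field must stabilize the perturbing
charge.  The finite-difference oracle (an explicit δQ = 10⁻⁴ re-solve of the
classical ground state, exact here because the energy is quadratic) is the
arbiter of these signs and is tested element-by-element against the
analytic matrix.

**The Coulomb constant kC = 0.7853 a.u.** scales the QM↔MM coupling of the
*polarizable* sources — linearly in the response right-hand side and in the
embedding operator, hence quadratically in dv_res.  It does not scale MM–MM
blocks, nor the coupling of fixed multipoles (EE therefore reduces to
textbook electrostatic embedding).  Whether kC should also scale MM–MM
interactions is not derivable from the formalism we implement; the choice
made here is the one consistent with the finite-difference oracle.

## Embedded mean field

The QM backend is a self-contained density-fitted restricted Hartree–Fock
implementation over contracted s-type Gaussians (H, He; STO-3G and 6-31G),
with closed-form overlap/kinetic/Coulomb/point-multipole integrals via the
Boys function.  The auxiliary basis is an even-tempered set built from
pairwise sums of orbital primitive exponents; on a single atom it spans the
orbital product space, making the density fitting essentially exact there
(the He total energy reproduces the reference value −2.8077840 Ha).  DFT
functionals are not provided: the reference is HF, for which the
vxc-consistency ε + Σx − vxc = ε holds to 10⁻⁹ Ha and anchors the Σ
partition.  Restricting to s-functions limits QM solutes to H/He — ample for
validating the embedding and screening machinery, which lives entirely in
the auxiliary basis and the classical layer.

SCF and classical polarization are alternated (macro-iterations): solve RHF
in the current embedding operator, evaluate the potential and field of QM
nuclei + electron density at the MM sites, re-solve the classical
stationarity, repeat until the total energy and the polarization are
stationary to 10⁻⁸.  For these convex classical responses the macro-cycle
and a fused update converge to the same stationary point; macro-cycling
keeps the SCF backend-agnostic.

## GW on the imaginary axis

* χ₀(iω) is spin-summed closed-shell: χ₀ = −4 Σ_ia (ia|P)(ia|Q) Δ/(Δ²+ω²)
  in the raw (metric-contracted) auxiliary representation; the factor 4 is
  the restricted reduction of the spin-orbital expression.
* The frequency grid maps n Gauss–Legendre nodes from (−1,1) to (0,∞) via
  ω = s(1+x)/(1−x); default n = 25, s = 1 a.u.
* W₀ solves (I − ṽ J⁻¹χ₀ J⁻¹) W = ṽ per frequency with ṽ = J + dv_res; the
  fitting metric J stays the bare Coulomb metric — the environment shifts
  the interaction, never the metric.  dv_res is static (classical response),
  so it enters ṽ at every frequency.
* Σ = Σx[v] + Σstat[dv_res] + Σc[W−ṽ].  Σstat = −Σ_i⟨ni|dv_res|in⟩ is
  included by default and switchable (`include_static`), since the partition
  between a static term and the W-modification is a formal choice; both
  routes are available and reduce identically in the vacuum limit.
* Σc(iν) = −(1/π) Σ_m ∫₀^∞ dω ⟨nm|Wc(iω)|mn⟩ · z/(z²+ω²) with
  z = iν + μ_F − ε_m, quadratured on the same grid and sampled at the grid
  points.  μ_F is the mid-gap.  No positive infinitesimal η is materialized
  on the imaginary axis; real-axis evaluation uses a fixed broadening
  δ = 10⁻³ a.u.
* Padé: Thiele continued fractions with mpmath at 60 decimal digits
  (doubling the precision changes continued values by <10⁻⁸ on
  well-conditioned input); divided-difference breakdown truncates the
  fraction with a warning, exactly-reproduced rational input truncates
  quietly.
* Quasiparticle equation: scan ε_n ± 2 Ha in 0.01 Ha steps, Newton-polish
  each sign change, select the root with the smallest |∂Σc/∂E|
  (satellites are steeper); Z = 1/(1−∂Σ/∂E).  If no root lies in the
  window, the linearized estimate is returned flagged as a fallback and the
  IP accessor refuses it.

**Accuracy envelope.** Against a dense real-axis sum-over-states reference
(exact dRPA diagonalization + pole-sum self-energy, no quadrature, no Padé),
quasiparticle energies agree to ≤10⁻⁴ meV for He (both bases) and H₂
(minimal basis), and frontier orbitals of H₂/6-31G to <1 meV.  High-lying
virtual orbitals are the known weak regime of analytic continuation: the
convolution quadrature is exact at small iν but carries ~1% relative error
around ν ≈ 5 a.u. at n = 25, and continuation ~1.5 Ha above the Fermi level
amplifies this to ~10 meV.  Frontier quantities (the IP) change by
≤10⁻⁴ meV between 25 and 50 grid points.

## Pipeline

Snapshots are XYZ (plain or extended with a molecule-id column; molecules
are otherwise inferred by a 1.8 Å covalent union-find) or PDB (via biotite,
residues as molecules).  A solvent molecule joins the MM region when its
center of geometry lies within the cutoff of the nearest QM atom — whole
molecules only, no split dipoles.  The CBS value is the two-point
extrapolation (n_l E_l − n_s E_s)/(n_l − n_s) using the actual basis
dimensions, not nominal cardinal numbers.  The vacuum reference uses the
identical QM geometry and settings so the solvatochromic shift isolates the
environment.  Runs are deterministic: identical inputs give byte-identical
JSON records.

## Synthetic fixtures and what a green test establishes

The solvent generator places rigid 3-site water-like molecules (OH 0.9572 Å,
HOH 104.52°) at seeded random positions/orientations in a spherical shell
(default 2.6–4.5 Å, minimum intersite distance 1.9 Å), rejecting clashes.
The parameter preset is synthetic: η_O = 1.4, η_H = 1.0, α_O = 1.0,
α_H = 0.4 a.u., fixed charges ∓0.68/0.34 e.  χ is calibrated per polarizable
model so that the kC-scaled electrostatic moments of an *isolated* molecule
reproduce the fixed-charge set — equilibrium charges for FQ
(q_O = −0.68/kC), the total molecular dipole (charges plus intramolecularly
induced atomic dipoles) for FQFμ.  This makes EE the matched non-polarizable
baseline of each model, so EE-vs-polarizable comparisons probe the
reaction-field screening rather than accidental electrostatic offsets.

The fixtures emulate the *structure* of a first solvation shell, not real
water: no thermal sampling, no hydrogen-bond network, no published
force-field parameters, and a helium solute whose screening response is
orders of magnitude weaker than a chromophore's.  A green direction check
(IP_FQ < IP_EE per snapshot) therefore establishes the sign and mechanism of
the environment screening, not its magnitude for any real system.  Even so,
solvent–solvent mutual polarization makes the implicit electrostatics of
polarizable and fixed-charge ground states differ snapshot by snapshot; with
the moment-matched preset this residual stays below the explicit screening
term (Σstat alone is 40–165 meV toward lower IP on the shipped fixtures).

## Numerical choices and limitations

- Linear solves are dense LAPACK; system sizes are tiny (≤200 unknowns).
  Singular systems raise with the offending block named.
- Coincident probe/site distances below 10⁻¹² Bohr are degenerate-input
  errors; aux-function-on-site potentials use the finite erf limit.
- ReactionMatrix serializes to `.npz` with model and kC metadata.
- Open-shell references, DFT functionals, energy gradients, periodic
  boundary conditions, parameter fitting, COSMO, eigenvalue-self-consistent
  GW flavors and BSE are out of scope.
- The brute-force reference is guarded to ≤10 orbitals; it shares the
  integrals with the production path but no screening, quadrature or
  continuation code.
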