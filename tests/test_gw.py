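"""GW engine: grid, chi0, screening, self-energies, Pade, QP solver, IP."""

import numpy as np
import pytest

from solvgw.constants import HARTREE_EV
from solvgw.embedding import QMRegion, run_coupled_scf, mo_three_center
from solvgw.fixtures import brute_force_gw_reference, two_level_qm_model
from solvgw.gw import (
    compute_chi0,
    compute_screened_interaction,
    correlation_self_energy,
    exchange_self_energy,
    g0w0,
    ionization_potential,
    make_frequency_grid,
    pade_continuation,
    solve_qp,
    static_self_energy,
)


class TestFrequencyGrid:
    def test_points_increasing_positive_weights(self):
        g = make_frequency_grid(25, 1.0)
        assert g.n == 25
        assert np.all(np.diff(g.points) > 0) and np.all(g.points > 0)
        assert np.all(g.weights > 0)

    def test_lorentzian_quadrature(self):
        """(2/pi) * int_0^inf domega 1/(1+omega^2) = 1 (arctan closed form)."""
        g = make_frequency_grid(25, 1.0)
        val = (2 / np.pi) * np.sum(g.weights / (1 + g.points ** 2))
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            make_frequency_grid(4)
        with pytest.raises(ValueError):
            make_frequency_grid(25, -1.0)


class TestChi0:
    def test_two_level_closed_form(self):
        """chi0(i omega) = -4 d^2 Delta/(Delta^2 + omega^2)."""
        m = two_level_qm_model(gap=1.0, coupling=0.3)
        g = make_frequency_grid(12, 0.7)
        chi0 = compute_chi0(m.mo_energy, m.mo_occ, m.X_mo, g)
        exact = -4 * 0.3 ** 2 * 1.0 / (1.0 + g.points ** 2)
        assert np.abs(chi0.matrices[:, 0, 0] - exact).max() < 1e-12

    def test_zero_coupling_zero_chi0(self):
        m = two_level_qm_model(gap=1.0, coupling=0.0)
        g = make_frequency_grid(8)
        chi0 = compute_chi0(m.mo_energy, m.mo_occ, m.X_mo, g)
        assert np.all(chi0.matrices == 0.0)

    def test_high_frequency_decay(self, he_mf_631g, he_X_mo):
        mf = he_mf_631g
        g0 = make_frequency_grid(8, 1e-6)   # lowest point ~ static
        ginf = make_frequency_grid(8, 1e6)
        c0 = compute_chi0(mf.mo_energy, mf.mo_occ, he_X_mo, g0).matrices[0]
        cinf = compute_chi0(mf.mo_energy, mf.mo_occ, he_X_mo, ginf).matrices[-1]
        assert np.abs(cinf).max() < 1e-9 * np.abs(c0).max()

    def test_matches_explicit_sum_over_states(self, he_mf_631g, he_X_mo):
        """Independent loop-based sum over all occ-virt pairs."""
        mf = he_mf_631g
        g = make_frequency_grid(8)
        chi0 = compute_chi0(mf.mo_energy, mf.mo_occ, he_X_mo, g)
        occ = np.where(mf.mo_occ > 0)[0]
        virt = np.where(mf.mo_occ == 0)[0]
        naux = he_X_mo.shape[-1]
        for k, om in enumerate(g.points):
            ref = np.zeros((naux, naux))
            for i in occ:
                for a in virt:
                    d = mf.mo_energy[a] - mf.mo_energy[i]
                    ref -= 4 * np.outer(he_X_mo[i, a], he_X_mo[i, a]) \
                        * d / (d ** 2 + om ** 2)
            assert np.abs(chi0.matrices[k] - ref).max() < 1e-12

    def test_degenerate_gap_rejected(self):
        g = make_frequency_grid(8)
        with pytest.raises(ValueError):
            compute_chi0(np.array([0.0, 0.0]), np.array([2.0, 0.0]),
                         np.zeros((2, 2, 1)), g)


class TestScreenedInteraction:
    def test_zero_chi0_gives_zero_wc(self):
        m = two_level_qm_model(1.0, 0.0)
        g = make_frequency_grid(8)
        chi0 = compute_chi0(m.mo_energy, m.mo_occ, m.X_mo, g)
        W = compute_screened_interaction(chi0, m.J2c)
        assert np.all(W.Wc == 0.0)

    def test_scalar_dyson_formula(self):
        """1x1 case: W = v/(1 - v chi0) with the fitted chi0 = raw/v^2."""
        m = two_level_qm_model(1.0, 0.3)
        g = make_frequency_grid(8)
        v = np.array([[2.5]])
        chi0 = compute_chi0(m.mo_energy, m.mo_occ, m.X_mo, g)
        W = compute_screened_interaction(chi0, v)
        for k in range(g.n):
            x = chi0.matrices[k][0, 0] / v[0, 0] ** 2  # fitted polarizability
            expected = v[0, 0] / (1 - v[0, 0] * x) - v[0, 0]
            assert W.Wc[k][0, 0] == pytest.approx(expected, rel=1e-12)

    def test_dv_res_zero_reduction_bitwise(self, he_mf_631g, he_X_mo):
        mf = he_mf_631g
        g = make_frequency_grid(10)
        chi0 = compute_chi0(mf.mo_energy, mf.mo_occ, he_X_mo, g)
        W0 = compute_screened_interaction(chi0, mf.ints.J2c)
        W1 = compute_screened_interaction(chi0, mf.ints.J2c,
                                          np.zeros_like(mf.ints.J2c))
        assert np.array_equal(W0.Wc, W1.Wc)

    def test_wc_decays_at_high_frequency(self, he_mf_631g, he_X_mo):
        mf = he_mf_631g
        g = make_frequency_grid(25)
        chi0 = compute_chi0(mf.mo_energy, mf.mo_occ, he_X_mo, g)
        W = compute_screened_interaction(chi0, mf.ints.J2c)
        # 1/omega^2 decay of chi0: at the outermost node (~450 a.u.) the
        # screening has fallen by >4 orders of magnitude
        assert np.abs(W.Wc[-1]).max() < 1e-4 * np.abs(W.Wc[0]).max()


class TestSelfEnergies:
    def test_no_occupied_zero_exchange(self):
        X = np.zeros((2, 2, 1)); X[0, 1, 0] = 0.4
        sx = exchange_self_energy(X, np.eye(1), np.array([0.0, 0.0]))
        np.testing.assert_array_equal(sx, 0.0)

    def test_hf_self_consistency(self, he_mf_631g, he_X_mo):
        """With an HF reference, Sigma_x equals vxc: eps_QP = eps_HF when
        correlation vanishes."""
        mf = he_mf_631g
        sx = exchange_self_energy(he_X_mo, mf.ints.J2c, mf.mo_occ)
        assert np.abs(sx - mf.vxc_diag).max() < 1e-9

    def test_exchange_negative_for_homo(self, h2_mf_631g):
        mf = h2_mf_631g
        sx = exchange_self_energy(mo_three_center(mf), mf.ints.J2c, mf.mo_occ)
        assert sx[mf.homo_index] < 0

    def test_static_term_sign(self, he_mf_631g, he_X_mo):
        """A negative-semidefinite dv_res gives Sigma_stat >= 0 (the removal
        hole is stabilized, the IP decreases)."""
        mf = he_mf_631g
        naux = mf.ints.J2c.shape[0]
        rng = np.random.default_rng(0)
        A = rng.normal(size=(naux, naux))
        dv = -(A @ A.T)  # NSD
        ss = static_self_energy(he_X_mo, mf.ints.J2c, dv, mf.mo_occ)
        assert ss[mf.homo_index] >= 0

    def test_sigma_c_zero_when_wc_zero(self):
        m = two_level_qm_model(1.0, 0.0)
        g = make_frequency_grid(8)
        chi0 = compute_chi0(m.mo_energy, m.mo_occ, m.X_mo, g)
        W = compute_screened_interaction(chi0, m.J2c)
        smp = correlation_self_energy(m.mo_energy, m.mo_occ, m.X_mo, m.J2c,
                                      W, [0])[0]
        assert np.abs(smp.values).max() == 0.0

    def test_sigma_c_conjugation_symmetry(self, he_mf_631g, he_X_mo):
        """Sigma_c(-i nu) = conj(Sigma_c(i nu)): evaluate the convolution at
        mirrored points explicitly."""
        mf = he_mf_631g
        g = make_frequency_grid(10)
        chi0 = compute_chi0(mf.mo_energy, mf.mo_occ, he_X_mo, g)
        W = compute_screened_interaction(chi0, mf.ints.J2c)
        smp = correlation_self_energy(mf.mo_energy, mf.mo_occ, he_X_mo,
                                      mf.ints.J2c, W, [0])[0]
        # the sampled kernel z/(z^2+w^2) maps nu -> -nu onto its conjugate
        occ = mf.mo_energy[mf.mo_occ > 0].max()
        virt = mf.mo_energy[mf.mo_occ == 0].min()
        mu = 0.5 * (occ + virt)
        Jinv = np.linalg.inv(mf.ints.J2c)
        c = he_X_mo[0] @ Jinv
        w = np.einsum("mP,kPQ,mQ->km", c, W.Wc, c)
        for j, nu in enumerate(g.points[:3]):
            z = -1j * nu + mu - mf.mo_energy
            kern = z[None, :] / (z[None, :] ** 2 + g.points[:, None] ** 2)
            mirrored = -(1 / np.pi) * np.sum(g.weights[:, None] * w * kern)
            assert abs(mirrored - np.conj(smp.values[j])) < 1e-10

    def test_one_pole_model_closed_form(self):
        """Quadrature Sigma_c matches the analytic one-pole GW expression."""
        m = two_level_qm_model(gap=1.0, coupling=0.3)
        g = make_frequency_grid(25)
        chi0 = compute_chi0(m.mo_energy, m.mo_occ, m.X_mo, g)
        W = compute_screened_interaction(chi0, m.J2c)
        errs = {}
        for n in (0, 1):
            smp = correlation_self_energy(m.mo_energy, m.mo_occ, m.X_mo,
                                          m.J2c, W, [n])[0]
            exact = np.array([m.sigma_c_exact(complex(z) + smp.mu_F, n)
                              for z in smp.points])
            errs[n] = np.abs(smp.values - exact).max()
            assert errs[n] < 5e-4
        # quadrature error shrinks with grid size
        g2 = make_frequency_grid(50)
        chi2 = compute_chi0(m.mo_energy, m.mo_occ, m.X_mo, g2)
        W2 = compute_screened_interaction(chi2, m.J2c)
        smp2 = correlation_self_energy(m.mo_energy, m.mo_occ, m.X_mo,
                                       m.J2c, W2, [0])[0]
        exact2 = np.array([m.sigma_c_exact(complex(z) + smp2.mu_F, 0)
                           for z in smp2.points])
        assert np.abs(smp2.values - exact2).max() < 0.5 * errs[0]

    def test_orbital_out_of_range(self, he_mf_631g, he_X_mo):
        mf = he_mf_631g
        g = make_frequency_grid(8)
        chi0 = compute_chi0(mf.mo_energy, mf.mo_occ, he_X_mo, g)
        W = compute_screened_interaction(chi0, mf.ints.J2c)
        with pytest.raises(IndexError):
            correlation_self_energy(mf.mo_energy, mf.mo_occ, he_X_mo,
                                    mf.ints.J2c, W, [99])


class TestPade:
    def test_constant_function(self):
        zs = 1j * make_frequency_grid(10).points
        f = pade_continuation(zs, np.full(10, 1.7 - 0.2j))
        assert f(0.5 + 0.01j) == pytest.approx(1.7 - 0.2j, abs=1e-14)

    def test_rational_exactness(self):
        """1/(z+2) through 12 imaginary nodes is reproduced exactly at 50
        off-grid complex points."""
        zs = 1j * make_frequency_grid(12).points
        f = pade_continuation(zs, 1.0 / (zs + 2.0))
        probes = np.linspace(-1.5, 3.0, 50) + 0.3j
        err = max(abs(f(z) - 1 / (z + 2)) for z in probes)
        assert err < 1e-8

    def test_precision_stability(self, he_mf_631g, he_X_mo):
        """Doubling the working precision leaves continued values unchanged
        on well-conditioned input."""
        mf = he_mf_631g
        g = make_frequency_grid(25)
        chi0 = compute_chi0(mf.mo_energy, mf.mo_occ, he_X_mo, g)
        W = compute_screened_interaction(chi0, mf.ints.J2c)
        smp = correlation_self_energy(mf.mo_energy, mf.mo_occ, he_X_mo,
                                      mf.ints.J2c, W, [0])[0]
        f1 = pade_continuation(smp.points, smp.values, dps=60)
        f2 = pade_continuation(smp.points, smp.values, dps=120)
        probes = np.linspace(-1.2, -0.2, 20) + 1e-3j
        err = max(abs(f1(z - smp.mu_F) - f2(z - smp.mu_F)) for z in probes)
        assert err < 1e-8


class TestQPSolver:
    def test_constant_sigma_exact(self):
        entry = solve_qp(-0.5, -0.8, lambda z: 0.05 + 0j, -0.7)
        assert entry.qp_energy == pytest.approx(-0.5 - 0.8 + 0.05 + 0.7,
                                                abs=1e-10)
        assert not entry.fallback and entry.z_factor == pytest.approx(1.0)

    def test_linear_sigma_closed_form(self):
        """Sigma_c(E) = a E with |a| < 1: E = (eps + Sx - vxc)/(1 - a).

        The solver works in the variable z = E - mu_F + i delta."""
        a, eps, sx, vxc, mu = 0.3, -0.4, -0.6, -0.5, 0.0
        fn = lambda z: a * z  # z = E - mu_F (+ i delta)
        entry = solve_qp(eps, sx, fn, vxc, mu_F=mu)
        assert entry.qp_energy == pytest.approx((eps + sx - vxc) / (1 - a),
                                                abs=1e-6)
        assert entry.z_factor == pytest.approx(1 / (1 - a), rel=1e-4)

    def test_smallest_slope_selection(self):
        """Constructed two-root self-energy: the flatter root is the QP."""
        # Sigma(E) = c/(E - p): roots of E - eps - c/(E - p) = 0
        eps, p, c = -0.5, 0.0, 0.01
        fn = lambda z: c / (z - p) if abs(z - p) > 1e-12 else 1e12
        entry = solve_qp(eps, 0.0, fn, 0.0, mu_F=0.0, delta=0.0)
        # roots: E = (eps + p ± sqrt((eps-p)^2 + 4c))/2 -> near eps and near p
        e_qp = (eps + p - np.sqrt((eps - p) ** 2 + 4 * c)) / 2
        assert entry.n_roots_found == 2
        assert entry.qp_energy == pytest.approx(e_qp, abs=1e-8)
        # exhaustive scan confirms the selected root has the smaller |slope|
        other = (eps + p + np.sqrt((eps - p) ** 2 + 4 * c)) / 2
        slope = lambda E: -c / (E - p) ** 2
        assert abs(slope(entry.qp_energy)) < abs(slope(other))

    def test_no_root_fallback_flagged(self):
        entry = solve_qp(-0.5, 0.0, lambda z: 10.0 + z * 0, 0.0, window=0.1)
        assert entry.fallback


class TestFullStack:
    def test_unit_conversion(self):
        """E_HOMO = -0.3 Ha -> IP = 8.1634 eV."""
        from solvgw.gw import QPEntry, QPSolution
        e = QPEntry(0, -0.3, 0, 0, 0, -0.3, 0, 0, 1.0, 1, 0, False)
        qp = QPSolution(entries={0: e}, homo_index=0)
        assert ionization_potential(qp) == pytest.approx(8.1634, abs=1e-3)

    def test_translation_invariance(self):
        shift = np.array([1.3, -0.7, 2.1])
        ips = []
        for origin in (np.zeros(3), shift):
            qm = QMRegion(["He"], origin[None, :], basis="6-31g")
            mf, _ = run_coupled_scf(qm, None)
            X = mo_three_center(mf)
            qp = g0w0(mf.mo_energy, mf.mo_occ, X, mf.ints.J2c, mf.vxc_diag,
                      target_orbitals=[mf.homo_index])
            ips.append(ionization_potential(qp))
        assert ips[0] == pytest.approx(ips[1], abs=1e-9)

    def test_helium_vs_brute_force(self, he_mf_631g, he_X_mo):
        """Imaginary axis + Pade vs dense real-axis sum over states: <= 1 meV."""
        mf = he_mf_631g
        qp = g0w0(mf.mo_energy, mf.mo_occ, he_X_mo, mf.ints.J2c, mf.vxc_diag)
        ref = brute_force_gw_reference(mf.mo_energy, mf.mo_occ, he_X_mo,
                                       mf.ints.J2c, mf.vxc_diag)
        for n, e in qp.entries.items():
            assert abs(e.qp_energy - ref["qp_energy"][n]) * HARTREE_EV < 1e-3
        assert 0 < qp.homo.z_factor <= 1.0

    def test_h2_frontier_vs_brute_force(self, h2_mf_631g):
        """Frontier quasiparticles match the pole-sum oracle to < 1 meV; high
        virtuals degrade gracefully (analytic continuation far above the Fermi
        level is the method's known weak regime)."""
        mf = h2_mf_631g
        X = mo_three_center(mf)
        qp = g0w0(mf.mo_energy, mf.mo_occ, X, mf.ints.J2c, mf.vxc_diag)
        ref = brute_force_gw_reference(mf.mo_energy, mf.mo_occ, X,
                                       mf.ints.J2c, mf.vxc_diag)
        homo = mf.homo_index
        for n in (homo, homo + 1):
            assert abs(qp.entries[n].qp_energy
                       - ref["qp_energy"][n]) * HARTREE_EV < 1e-3
        for n, e in qp.entries.items():
            assert abs(e.qp_energy - ref["qp_energy"][n]) * HARTREE_EV < 25e-3

    def test_unconverged_homo_raises(self):
        from solvgw.gw import QPEntry, QPSolution
        e = QPEntry(0, -0.3, 0, 0, 0, -0.3, 0, 0, 1.0, 0, -1, True)
        qp = QPSolution(entries={0: e}, homo_index=0)
        with pytest.raises(RuntimeError):
            ionization_potential(qp)
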