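"""Metric tensors, DVR grids, PODVR contraction, the direct-product
Hamiltonian and sparse eigensolution."""

import numpy as np
import pytest

from nnvib.dvr import (CurvilinearModel, SingularMetricError,
                       build_hamiltonian, fourier_dvr, gmatrix_numeric,
                       podvr_1d, podvr_levels, sine_dvr, solve_levels)
from nnvib.oracles import Morse1D, toy_dimer_3d
from nnvib.units import HARTREE_CM


@pytest.fixture(scope="module")
def morse():
    return Morse1D(D_e=0.18, a=1.2, r_e=1.75, mass=1600.0)


def com_preserving_diatomic(m1=1837.0, m2=34631.0):
    """Bond-length coordinate that keeps the centre of mass fixed."""
    M = m1 + m2

    def mapping(q):
        r = q[0]
        return np.array([[0.0, 0.0, -m2 / M * r],
                         [0.0, 0.0, m1 / M * r]])

    return CurvilinearModel(["r"], [(1.0, 4.0)], mapping,
                            np.array([m1, m2]))


class TestGMatrix:

    def test_diatomic_reduced_mass(self):
        model = com_preserving_diatomic()
        mt = gmatrix_numeric(model, np.array([2.0]))
        mu = 1837.0 * 34631.0 / (1837.0 + 34631.0)
        assert mt.g[0, 0] == pytest.approx(mu, rel=1e-8)
        assert mt.G[0, 0] == pytest.approx(1.0 / mu, rel=1e-8)

    def test_atom_diatom_jacobi_distances(self):
        """Jacobi distance coordinates: g is diagonal with the known
        reduced masses (diatom bond and atom-to-com separations)."""
        mA, mB, mC = 1837.0, 1837.0, 21874.0
        mAB = mA + mB

        def mapping(q):
            r, R = q  # diatom bond, atom-to-diatom-com distance
            # keep total COM fixed along z; bond along x
            zc = -mAB / (mAB + mC) * R
            zab = mC / (mAB + mC) * R
            return np.array([
                [-mB / mAB * r, 0.0, zab],
                [mA / mAB * r, 0.0, zab],
                [0.0, 0.0, zc]])

        model = CurvilinearModel(["r", "R"], [(1, 3), (2, 8)], mapping,
                                 np.array([mA, mB, mC]))
        mt = gmatrix_numeric(model, np.array([1.4, 4.0]))
        mu_r = mA * mB / mAB
        mu_R = mAB * mC / (mAB + mC)
        assert mt.g[0, 0] == pytest.approx(mu_r, rel=1e-8)
        assert mt.g[1, 1] == pytest.approx(mu_R, rel=1e-8)
        assert abs(mt.g[0, 1]) < 1e-6

    def test_G_times_g_identity(self):
        o = toy_dimer_3d()
        model = CurvilinearModel(o.reference["coordinate_names"],
                                 o.reference["ranges"],
                                 o.reference["map_to_cartesian"],
                                 o.reference["masses_au"])
        rng = np.random.default_rng(0)
        for _ in range(5):
            q = np.array([rng.uniform(4.5, 7.0), rng.uniform(0.9, 2.2),
                          rng.uniform(0.9, 2.2)])
            mt = gmatrix_numeric(model, q)
            np.testing.assert_allclose(mt.G @ mt.g, np.eye(3), atol=1e-10)

    def test_singular_metric_reported(self):
        def mapping(q):  # coordinate that moves nothing
            return np.zeros((1, 3))

        model = CurvilinearModel(["dead"], [(0, 1)], mapping,
                                 np.array([1000.0]))
        with pytest.raises(SingularMetricError):
            gmatrix_numeric(model, np.array([0.5]))


class TestGrids1D:

    def test_harmonic_levels_machine_accurate(self):
        """(n+1/2)ω ladder to 1e-6 cm-1 with 50 sine-DVR points."""
        m, w = 2000.0, 0.01
        L = 8.0 * np.sqrt(1.0 / (m * w))
        grid = sine_dvr(50, -L, L)
        H = -0.5 / m * grid.d2 + np.diag(0.5 * m * w * w * grid.points ** 2)
        vals = np.linalg.eigvalsh(H)
        expect = w * (np.arange(4) + 0.5)
        np.testing.assert_allclose((vals[:4] - vals[0] + expect[0]) * HARTREE_CM,
                                   expect * HARTREE_CM, atol=1e-6)

    def test_morse_levels_match_closed_form(self, morse):
        levels = podvr_levels(morse.V, morse.mass, (0.8, 6.5),
                              n_primitive=150, n_states=5)
        expect = morse.level_cm(np.arange(5))
        np.testing.assert_allclose(levels, expect, atol=0.01)

    def test_grid_convergence_monotone(self, morse):
        errs = []
        for n in (20, 40, 80):
            lv = podvr_levels(morse.V, morse.mass, (0.8, 6.5),
                              n_primitive=n, n_states=4)
            errs.append(np.abs(lv - morse.level_cm(np.arange(4))).max())
        assert errs[0] > errs[1] > errs[2]

    def test_fourier_derivative_on_plane_wave(self):
        grid = fourier_dvr(31)
        f = np.sin(3 * grid.points)
        np.testing.assert_allclose(grid.d1 @ f, 3 * np.cos(3 * grid.points),
                                   atol=1e-10)
        np.testing.assert_allclose(grid.d2 @ f, -9 * f, atol=1e-9)


class TestPODVR:

    def test_full_rank_podvr_equals_primitive(self, morse):
        n = 40
        prim = sine_dvr(n, 0.9, 5.5)
        po = podvr_1d(morse.V, morse.mass, (0.9, 5.5), n_primitive=n,
                      n_podvr=n)
        Hp = -0.5 / morse.mass * prim.d2 + np.diag(morse.V(prim.points))
        Ho = -0.5 / morse.mass * po.d2 + np.diag(morse.V(po.points))
        vp = np.linalg.eigvalsh(0.5 * (Hp + Hp.T))
        # full-rank PODVR: same spectrum apart from the (exact) potential
        # re-evaluation at the PODVR points being a unitary transform away
        vo = np.linalg.eigvalsh(0.5 * (Ho + Ho.T))
        np.testing.assert_allclose(vo[:10], vp[:10], atol=2e-5)

    def test_contracted_podvr_low_levels(self, morse):
        """A 16-point PODVR reproduces the low-lying spectrum of a
        150-point primitive grid to better than 0.1 cm-1."""
        po = podvr_1d(morse.V, morse.mass, (0.8, 6.5), n_primitive=150,
                      n_podvr=16)
        H = -0.5 / morse.mass * po.d2 + np.diag(morse.V(po.points))
        vals = np.linalg.eigvalsh(0.5 * (H + H.T))
        expect = morse.level_cm(np.arange(4))
        got = vals[:4] * HARTREE_CM   # oracle potential minimum is 0
        np.testing.assert_allclose(got, expect, atol=0.1)

    def test_unbound_cut_flagged(self):
        with pytest.raises(ValueError, match="unbound"):
            podvr_1d(lambda x: -0.05 * x, 2000.0, (0.0, 5.0),
                     n_primitive=60, n_podvr=8)

    def test_points_inside_primitive_range(self, morse):
        po = podvr_1d(morse.V, morse.mass, (0.8, 6.5), 100, 10)
        assert po.points.min() > 0.8 and po.points.max() < 6.5


class TestProductHamiltonian:

    def separable_2d(self):
        m = 2000.0
        w1, w2 = 0.010, 0.013

        def mapping(q):
            return np.array([[q[0], 0, 0], [q[1], 0, 0]])

        L1 = 9.0 * np.sqrt(1 / (m * w1))
        L2 = 9.0 * np.sqrt(1 / (m * w2))
        model = CurvilinearModel(["x", "y"], [(-L1, L1), (-L2, L2)], mapping,
                                 np.array([m, m]))

        def pot(q):
            return 0.5 * m * (w1 ** 2 * q[0] ** 2 + w2 ** 2 * q[1] ** 2)

        grids = [sine_dvr(48, -L1, L1), sine_dvr(48, -L2, L2)]
        return model, grids, pot, (w1, w2)

    def test_separable_harmonic_sum_spectrum(self):
        model, grids, pot, (w1, w2) = self.separable_2d()
        H = build_hamiltonian(model, grids, pot)
        lv = solve_levels(H, 5)
        expect = np.sort(np.array([w1, w2, 2 * w1, w1 + w2, 2 * w2])) \
            * HARTREE_CM
        np.testing.assert_allclose(np.sort(lv.excitations_cm), expect,
                                   atol=1e-5)

    def test_hermitian(self):
        model, grids, pot, _ = self.separable_2d()
        H = build_hamiltonian(model, grids, pot)
        d = abs(H - H.T)
        assert d.max() < 1e-9

    def test_double_well_splitting_vs_dense_grid(self):
        """Tunneling splittings of a 1D quartic double well match a
        2000-point dense-grid reference to 1e-4 cm-1."""
        m = 1800.0
        V0, x0 = 0.004, 0.45

        def V(x):
            return V0 * (x ** 2 - x0 ** 2) ** 2 / x0 ** 4

        dense = sine_dvr(2000, -1.6, 1.6)
        Hd = -0.5 / m * dense.d2 + np.diag(V(dense.points))
        ref = np.linalg.eigvalsh(Hd)[:4]
        grid = sine_dvr(120, -1.6, 1.6)
        H = -0.5 / m * grid.d2 + np.diag(V(grid.points))
        vals = np.linalg.eigvalsh(H)[:4]
        ref_split = (ref[1] - ref[0]) * HARTREE_CM
        split = (vals[1] - vals[0]) * HARTREE_CM
        assert split == pytest.approx(ref_split, abs=1e-4)
        assert (vals[3] - vals[2]) * HARTREE_CM == pytest.approx(
            (ref[3] - ref[2]) * HARTREE_CM, abs=1e-4)

    def test_double_well_first_excitation_below_single_well(self):
        """Splitting physics: the lowest excitation of a symmetric double
        well lies below that of a single well of the same curvature."""
        m = 1800.0
        V0, x0 = 0.004, 0.45
        curv = 8.0 * V0 / x0 ** 2   # second derivative at each minimum

        def Vdw(x):
            return V0 * (x ** 2 - x0 ** 2) ** 2 / x0 ** 4

        def Vsw(x):
            return 0.5 * curv * (x - x0) ** 2

        grid = sine_dvr(300, -1.8, 1.8)
        for V, out in ((Vdw, "dw"), (Vsw, "sw")):
            H = -0.5 / m * grid.d2 + np.diag(V(grid.points))
            vals = np.linalg.eigvalsh(H)
            if out == "dw":
                e_dw = (vals[1] - vals[0]) * HARTREE_CM
            else:
                e_sw = (vals[1] - vals[0]) * HARTREE_CM
        assert e_dw < e_sw

    def test_constraint_consistency(self):
        """For a separable 2D system, constraining one coordinate (1D model
        with the other frozen) reproduces the 2D ladder of the active
        mode."""
        model, grids, pot, (w1, w2) = self.separable_2d()
        H2 = build_hamiltonian(model, grids, pot)
        lv2 = solve_levels(H2, 8)
        m = 2000.0
        L1 = 9.0 * np.sqrt(1 / (m * w1))

        def map1(q):
            return np.array([[q[0], 0, 0], [0, 0, 0]])

        model1 = CurvilinearModel(["x"], [(-L1, L1)], map1,
                                  np.array([m, m]))
        H1 = build_hamiltonian(model1, [grids[0]],
                               lambda q: 0.5 * m * w1 ** 2 * q[0] ** 2)
        lv1 = solve_levels(H1, 3)
        ladder2 = [e for e in lv2.excitations_cm
                   if any(abs(e - k * w1 * HARTREE_CM) < 1.0
                          for k in (1, 2, 3))]
        np.testing.assert_allclose(lv1.excitations_cm[:2], ladder2[:2],
                                   atol=1e-6)

    def test_memory_guard(self):
        model, grids, pot, _ = self.separable_2d()
        with pytest.raises(MemoryError):
            build_hamiltonian(model, grids, pot, product_cap=100)

    def test_deterministic_solver(self):
        model, grids, pot, _ = self.separable_2d()
        H = build_hamiltonian(model, grids, pot)
        a = solve_levels(H, 6).excitations_cm
        b = solve_levels(H, 6).excitations_cm
        np.testing.assert_allclose(a, b, atol=1e-10)


class TestDimerModel:

    def test_3d_levels_near_harmonic_estimates(self):
        """Fundamentals of the 3D dimer oracle lie near (below, for the
        Morse stretch) the harmonic frequencies from the metric + force
        constants."""
        o = toy_dimer_3d()
        ref = o.reference
        model = CurvilinearModel(ref["coordinate_names"], ref["ranges"],
                                 ref["map_to_cartesian"], ref["masses_au"])
        grids = [sine_dvr(22, 4.3, 8.0), sine_dvr(17, 0.75, np.pi - 0.75),
                 sine_dvr(17, 0.75, np.pi - 0.75)]
        H = build_hamiltonian(model, grids, ref["energy_q"])
        lv = solve_levels(H, 4)
        mt = gmatrix_numeric(model, np.array([o.params["R_e"], np.pi / 2,
                                              np.pi / 2]))
        wR = o.params["a_R"] * np.sqrt(2 * o.params["D_R"] / mt.g[0, 0]) \
            * HARTREE_CM
        w1 = np.sqrt(o.params["k_theta1"] / mt.g[1, 1]) * HARTREE_CM
        w2 = np.sqrt(o.params["k_theta2"] / mt.g[2, 2]) * HARTREE_CM
        exc = np.sort(lv.excitations_cm[:3])
        harm = np.sort([wR, w1, w2])
        assert np.all(np.abs(exc - harm) < 0.1 * harm)  # anharmonic but close
        assert exc[0] < harm[0]   # Morse stretch red-shifts

    def test_double_well_doublets_and_barrier_trend(self):
        """With the double-well option on θ1, levels appear as split
        doublets whose splitting shrinks monotonically as the barrier
        grows (1D cut along θ1)."""
        splittings = []
        for barrier in (0.002, 0.004, 0.008):
            o = toy_dimer_3d(barrier=barrier, delta=0.5)
            ref = o.reference
            model = CurvilinearModel(ref["coordinate_names"], ref["ranges"],
                                     ref["map_to_cartesian"],
                                     ref["masses_au"])
            mt = gmatrix_numeric(model, np.array([o.params["R_e"],
                                                  np.pi / 2, np.pi / 2]))
            grid = sine_dvr(150, 0.65, np.pi - 0.65)

            def cut(t):
                return ref["energy_q"](np.array([o.params["R_e"], t,
                                                 np.pi / 2]))

            V = np.array([cut(t) for t in grid.points])
            H = -0.5 / mt.g[1, 1] * grid.d2 + np.diag(V)
            vals = np.linalg.eigvalsh(H)
            splittings.append((vals[1] - vals[0]) * HARTREE_CM)
        assert splittings[0] > splittings[1] > splittings[2]

    def test_barrierless_single_well_ladder(self):
        o = toy_dimer_3d(barrier=0.0)
        assert o.params["barrier"] == 0.0
        # 1D cut at equilibrium reproduces the harmonic curvature
        ref = o.reference
        t = np.pi / 2
        h = 1e-3
        cut = lambda th: ref["energy_q"](np.array([o.params["R_e"], th,
                                                   np.pi / 2]))
        curv = (cut(t + h) - 2 * cut(t) + cut(t - h)) / h ** 2
        assert curv == pytest.approx(o.params["k_theta1"], rel=1e-4)


class TestFullStackRegression:
    """Train a potential on samples of the 3D dimer oracle and compare
    variational (DVR) fundamentals of the trained surface against the
    oracle's own — the end-to-end check that descriptor, training,
    force-field and DVR machinery compose correctly."""

    def test_trained_potential_dvr_fundamentals_within_10_cm(self):
        import time
        from nnvib.descriptors import ACSFConfig
        from nnvib.model import NNPModel
        from nnvib.oracles import sample_structures
        from nnvib.structures import Dataset
        from nnvib.training import TrainingConfig, fit
        from nnvib.units import BOHR_ANGSTROM

        o = toy_dimer_3d()
        ref = o.reference
        rng = np.random.default_rng(11)
        # candidate-generation channels: the variational product grid
        # region plus near-equilibrium normal-mode displacements
        structs = []
        while len(structs) < 900:
            q = np.array([rng.uniform(4.4, 7.6),
                          rng.uniform(0.8, np.pi - 0.8),
                          rng.uniform(0.8, np.pi - 0.8)])
            x = ref["map_to_cartesian"](q) * BOHR_ANGSTROM
            s = o.equilibrium.with_coordinates(x)
            s.energy = o.energy(s)
            s.tag = "grid"
            structs.append(s)
        ds_nm = sample_structures(o, 300, amplitude=1.0, seed=13,
                                  scheme="normal-mode", max_energy=0.03)
        ds = Dataset(structs + ds_nm.structures).set_reference_to_minimum()
        acsf = ACSFConfig(
            elements=["O", "N", "H"],
            radial_params=[(e, 0.0) for e in np.geomspace(0.002, 0.3, 4)],
            angular_params=[(0.001, 1.0, 1.0), (0.001, 4.0, -1.0),
                            (0.05, 1.0, -1.0), (0.05, 4.0, 1.0)])
        model = NNPModel.create(acsf, hidden=(10, 10), seed=0)
        model, hist = fit(model, ds, TrainingConfig(optimizer="kalman",
                                                    epochs=4, seed=0))
        assert hist["test_rmse_mev_atom"].min() < 3.0

        cmodel = CurvilinearModel(ref["coordinate_names"], ref["ranges"],
                                  ref["map_to_cartesian"], ref["masses_au"])
        grids = [sine_dvr(16, 4.4, 7.6),
                 sine_dvr(12, 0.8, np.pi - 0.8),
                 sine_dvr(12, 0.8, np.pi - 0.8)]
        lv0 = solve_levels(build_hamiltonian(cmodel, grids,
                                             ref["energy_q"]), 4)
        template = o.equilibrium

        def pot_q(q):
            x = ref["map_to_cartesian"](q) * BOHR_ANGSTROM
            return model.total_energy(template.with_coordinates(x))

        lvn = solve_levels(build_hamiltonian(cmodel, grids, pot_q), 4)
        dev = lvn.excitations_cm - lv0.excitations_cm
        assert np.abs(dev).max() < 10.0
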