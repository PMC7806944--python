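"""MBAR, TI-GQ, the analytic TR release, and block uncertainties."""

import numpy as np
import pytest
from scipy import integrate

from abfekit import freenergy, synthsampler
from abfekit.freenergy import (
    EstimatorError, ReducedPotentialMatrix, TRReleaseSpec, WindowSamples,
    analytic_tr_release, block_sigma, combine_sigma_quadrature,
    gauss_legendre_01, kt, mbar_delta_g, mbar_free_energies,
    reduced_potentials, split_blocks, ti_gauss_quadrature,
    tr_release_stiff_limit,
)
from abfekit.restraintgen import HarmonicRestraint, RestraintSet, WindowSchedule

UNIT_BETA_T = 1.0 / freenergy.R_KCAL  # temperature at which kT = 1 kcal/mol


def _one_restraint(k=1.0, x0=0.0, kind="distance"):
    atoms = {"distance": (0, 1), "angle": (0, 1, 2), "dihedral": (0, 1, 2, 3)}
    return RestraintSet(
        [HarmonicRestraint(kind, atoms[kind], k, x0, "R1")], "ligand_TR")


class TestReducedPotentials:
    def test_zero_attach_row_is_zero(self):
        sched = WindowSchedule(attach_rest=[0.0, 100.0])
        wins = [WindowSamples(0, np.ones((4, 1))),
                WindowSamples(1, np.ones((4, 1)))]
        rpm = reduced_potentials(wins, sched, _one_restraint(k=5.0))
        np.testing.assert_allclose(rpm.u[0], 0.0)

    def test_unit_case(self):
        # k = 1, displacement 1, kT = 1: the reduced potential is exactly 1
        sched = WindowSchedule(attach_rest=[0.0, 100.0])
        wins = [WindowSamples(0, np.array([[1.0]])),
                WindowSamples(1, np.array([[1.0]]))]
        rpm = reduced_potentials(wins, sched, _one_restraint(k=1.0),
                                 temperature=UNIT_BETA_T)
        assert rpm.u[1, 0] == pytest.approx(1.0)

    def test_matches_per_term_summation(self):
        rng = np.random.default_rng(0)
        terms = [
            HarmonicRestraint("distance", (0, 1), 2.0, 1.0, "D"),
            HarmonicRestraint("angle", (0, 1, 2), 30.0, 95.0, "A"),
            HarmonicRestraint("dihedral", (0, 1, 2, 3), 10.0, 170.0, "T"),
        ]
        rset = RestraintSet(terms, "ligand_TR")
        sched = WindowSchedule(attach_rest=[0.0, 40.0, 100.0])
        wins = [
            WindowSamples(i, np.column_stack([
                rng.normal(1.0, 0.3, 5), rng.normal(95, 8, 5),
                rng.uniform(-180, 180, 5),
            ]))
            for i in range(3)
        ]
        rpm = reduced_potentials(wins, sched, rset)
        beta = 1.0 / kt()
        x = np.vstack([w.samples for w in wins])
        for i, pct in enumerate([0.0, 40.0, 100.0]):
            for n in range(x.shape[0]):
                u = 0.0
                for r, t in enumerate(terms):
                    d = x[n, r] - t.x0
                    if t.kind == "dihedral":
                        d = (d + 180) % 360 - 180
                    if t.kind != "distance":
                        d = np.radians(d)
                    u += (pct / 100) * t.k * d * d
                assert rpm.u[i, n] == pytest.approx(beta * u, rel=1e-12)

    def test_dimension_mismatch_errors(self):
        sched = WindowSchedule(attach_rest=[0.0, 100.0])
        wins = [WindowSamples(0, np.ones((4, 2))),
                WindowSamples(1, np.ones((4, 2)))]
        with pytest.raises(EstimatorError):
            reduced_potentials(wins, sched, _one_restraint())


class TestMBAR:
    def test_identical_windows_give_zero(self):
        rng = np.random.default_rng(1)
        u_row = rng.uniform(0, 2, 100)
        rpm = ReducedPotentialMatrix(np.vstack([u_row, u_row]), [50, 50])
        g = mbar_free_energies(rpm)
        assert g[1] - g[0] == pytest.approx(0.0, abs=1e-9)

    def test_recovers_harmonic_attachment_free_energy(self):
        """MBAR on 50k exact Gaussian samples per window recovers the
        closed-form partition-function ratio within 3 standard errors."""
        spec = synthsampler.HarmonicSystemSpec(
            k_sys=5.0, x_sys=0.0, k_win=10.0, x0=0.3, seed=42, n_samples=50000)
        sched = WindowSchedule(attach_rest=[0.0, 100.0])
        wins = synthsampler.sample_attach_windows(spec, sched)
        rpm = reduced_potentials(wins, sched, _one_restraint(k=10.0, x0=0.3))
        dg, analysis = freenergy.mbar_with_blocks(rpm, 10)
        exact = synthsampler.analytic_window_dg(spec, 0.0, 100.0)
        se = freenergy.block_standard_error(analysis)
        assert abs(dg - exact) < 3 * max(se, 1e-4)

    def test_bracketed_by_zwanzig_estimates(self):
        """Forward and reverse exponential averages bracket the MBAR value
        (two-window case; independent estimator)."""
        spec = synthsampler.HarmonicSystemSpec(
            k_sys=4.0, x_sys=0.0, k_win=12.0, x0=0.0, seed=9, n_samples=20000)
        sched = WindowSchedule(attach_rest=[0.0, 100.0])
        wins = synthsampler.sample_attach_windows(spec, sched)
        rpm = reduced_potentials(wins, sched, _one_restraint(k=12.0))
        dg = mbar_delta_g(rpm)
        kT = kt()
        du = rpm.u[1] - rpm.u[0]
        n0 = wins[0].count
        forward = -kT * (np.log(np.mean(np.exp(-du[:n0]))))
        reverse = kT * (np.log(np.mean(np.exp(du[n0:]))))
        lo, hi = sorted([forward, reverse])
        assert lo - 0.01 <= dg <= hi + 0.01

    def test_gauge_and_permutation_invariance(self):
        rng = np.random.default_rng(2)
        u = rng.uniform(0, 3, size=(3, 90))
        rpm = ReducedPotentialMatrix(u, [30, 30, 30])
        g0 = mbar_free_energies(rpm)
        # adding a constant to every row leaves the differences unchanged
        g1 = mbar_free_energies(ReducedPotentialMatrix(u + 7.0, [30, 30, 30]))
        np.testing.assert_allclose(g1 - g1[0], g0 - g0[0], atol=1e-7)
        # permuting samples within a window leaves the solution unchanged
        perm = np.concatenate([rng.permutation(30),
                               30 + rng.permutation(30),
                               60 + rng.permutation(30)])
        g2 = mbar_free_energies(ReducedPotentialMatrix(u[:, perm], [30, 30, 30]))
        np.testing.assert_allclose(g2, g0, atol=1e-9)

    def test_nonconvergence_reports_residual(self):
        rng = np.random.default_rng(5)
        u = np.vstack([rng.uniform(0, 1, 20), rng.uniform(4, 9, 20)])
        rpm = ReducedPotentialMatrix(u, [10, 10])
        with pytest.raises(freenergy.ConvergenceError, match="residual"):
            mbar_free_energies(rpm, max_iter=1)


class TestTIGQ:
    def test_constant_integrand(self):
        nodes, weights = gauss_legendre_01(12)
        assert ti_gauss_quadrature(nodes, weights, np.full(12, 3.7)) == (
            pytest.approx(3.7))

    def test_twelve_nodes_for_order_twelve(self):
        nodes, weights = gauss_legendre_01(12)
        assert len(nodes) == 12 and len(weights) == 12
        assert weights.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("degree", [0, 5, 11, 17, 23])
    def test_exact_for_polynomials_to_degree_23(self, degree):
        rng = np.random.default_rng(degree)
        coeffs = rng.uniform(-2, 2, degree + 1)
        poly = np.polynomial.Polynomial(coeffs)
        nodes, weights = gauss_legendre_01(12)
        got = ti_gauss_quadrature(nodes, weights, poly(nodes))
        exact = poly.integ()(1.0) - poly.integ()(0.0)
        assert got == pytest.approx(exact, rel=1e-12, abs=1e-12)

    def test_weight_sum_enforced(self):
        with pytest.raises(EstimatorError):
            ti_gauss_quadrature([0.5], [0.7], [1.0])


class TestAnalyticTRRelease:
    SPEC = TRReleaseSpec(k_d=10.0, k_a=50.0, r0=5.0, theta0=90.0, Theta0=85.0)

    def test_matches_brute_force_grid(self):
        """Two 3-D trapezoidal grids (translation and orientation blocks)
        reproduce the factorised quadrature to 1e-3 kcal/mol."""
        spec = self.SPEC
        kT = kt(spec.temperature)
        beta = 1.0 / kT
        r = np.linspace(3.0, 7.0, 120)
        th = np.linspace(1e-4, np.pi - 1e-4, 120)
        ph = np.linspace(-np.pi, np.pi, 121)
        ur = spec.k_d * (r - spec.r0) ** 2
        uth = spec.k_a * (th - np.radians(spec.theta0)) ** 2
        f = (np.exp(-beta * ur[:, None, None] - beta * uth[None, :, None]
                    - beta * spec.k_a * ph[None, None, :] ** 2)
             * (r ** 2)[:, None, None] * np.sin(th)[None, :, None])
        i_trans = np.trapezoid(np.trapezoid(np.trapezoid(f, ph), th), r)
        uTH = spec.k_a * (th - np.radians(spec.Theta0)) ** 2
        g = (np.exp(-beta * uTH[:, None, None]
                    - beta * spec.k_a * ph[None, :, None] ** 2
                    - beta * spec.k_a * ph[None, None, :] ** 2)
             * np.sin(th)[:, None, None])
        i_orient = np.trapezoid(np.trapezoid(np.trapezoid(g, ph), ph), th)
        oracle = (kT * np.log(1.0 / spec.standard_volume / (8 * np.pi**2))
                  + kT * np.log(i_trans) + kT * np.log(i_orient))
        assert analytic_tr_release(spec) == pytest.approx(oracle, abs=1e-3)

    def test_stiff_spring_closed_form(self):
        for k in (100.0, 300.0, 1000.0):
            spec = TRReleaseSpec(k_d=k, k_a=k, r0=5.0, theta0=90.0, Theta0=90.0)
            assert abs(analytic_tr_release(spec)
                       - tr_release_stiff_limit(spec)) < 0.01

    def test_standard_volume_shift_is_kt_ln2(self):
        a = analytic_tr_release(self.SPEC)
        halved = TRReleaseSpec(
            k_d=self.SPEC.k_d, k_a=self.SPEC.k_a, r0=5.0, theta0=90.0,
            Theta0=85.0, standard_volume=self.SPEC.standard_volume / 2)
        assert analytic_tr_release(halved) - a == pytest.approx(
            kt() * np.log(2.0), abs=1e-9)

    def test_nonpositive_spring_errors(self):
        with pytest.raises(EstimatorError):
            TRReleaseSpec(k_d=0.0, k_a=10.0)

    def test_magnitude_grows_with_each_spring(self):
        # tighter restraints cost more to release: ΔG moves further below
        # the pure standard-state term as either spring stiffens
        for attr in ("k_d", "k_a"):
            vals = []
            for k in (5.0, 20.0, 80.0, 320.0):
                kw = {"k_d": 10.0, "k_a": 50.0}
                kw[attr] = k
                vals.append(analytic_tr_release(TRReleaseSpec(**kw)))
            assert vals == sorted(vals, reverse=True)


class TestBlocks:
    def test_equal_blocks_zero_sigma(self):
        assert block_sigma(2.0, [2.0, 2.0, 2.0]).sigma == 0.0

    def test_printed_formula(self):
        assert block_sigma(2.0, [1.0, 3.0]).sigma == pytest.approx(1.0)

    def test_random_case_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        xbar = 1.3
        xs = rng.normal(1.0, 0.5, 7)
        expected = np.sqrt(np.mean((xs - xbar) ** 2))
        assert block_sigma(xbar, xs).sigma == pytest.approx(expected)

    def test_fewer_than_two_blocks_errors(self):
        with pytest.raises(EstimatorError):
            block_sigma(0.0, [1.0])

    @pytest.mark.parametrize("n,nb,sizes", [
        (10, 5, [2, 2, 2, 2, 2]),
        (11, 5, [2, 2, 2, 2, 3]),
        (7, 3, [2, 2, 3]),
    ])
    def test_split_sizes_and_order(self, n, nb, sizes):
        blocks = split_blocks(list(range(n)), nb)
        assert [len(b) for b in blocks] == sizes
        assert [x for b in blocks for x in b] == list(range(n))

    def test_quadrature_combination(self):
        assert combine_sigma_quadrature([3.0, 4.0]) == pytest.approx(5.0)
        assert combine_sigma_quadrature([0.7]) == pytest.approx(0.7)
        assert combine_sigma_quadrature([]) == 0.0


class TestSampleTSV:
    def test_roundtrip(self, tmp_path):
        rng = np.random.default_rng(4)
        wins = [WindowSamples(i, rng.normal(size=(5, 2))) for i in range(3)]
        path = tmp_path / "w.tsv"
        freenergy.write_window_samples(wins, path, columns=["D1", "A1"])
        back = freenergy.read_window_samples(path)
        assert [w.window_index for w in back] == [0, 1, 2]
        for a, b in zip(wins, back):
            np.testing.assert_allclose(a.samples, b.samples, atol=1e-12)
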