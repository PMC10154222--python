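"""WLC looping Monte Carlo: energies, moves, WHAM and J-factor oracles."""

import math

import numpy as np
import pytest
from scipy import stats

from topomech import DsDnaElasticity, loop_mc as lm


class TestBiasSpringConstant:
    def test_printed_formula_value(self):
        # direct hand evaluation of (1.682/25)*exp(-0.008664*100)*(55-0.2*150)
        expected = (1.682 / 25.0) * math.exp(-0.8664) * 25.0
        assert lm.bias_spring_constant(100, 150) == pytest.approx(expected, rel=1e-12)
        assert lm.bias_spring_constant(100, 150) == pytest.approx(0.7072, abs=5e-4)

    def test_angle_ratio_is_exact(self):
        ratio = lm.bias_spring_constant(100, 0) / lm.bias_spring_constant(100, 150)
        assert ratio == pytest.approx(55.0 / 25.0, rel=1e-12)

    def test_boundaries(self):
        with pytest.raises(ValueError):
            lm.bias_spring_constant(100, 275)
        with pytest.raises(ValueError):
            lm.bias_spring_constant(0, 0)


class TestBendingEnergy:
    def test_straight_chain_zero(self, elasticity):
        chain = lm.make_chain(200)
        assert lm.bending_energy(chain, elasticity) == pytest.approx(0.0, abs=1e-12)

    def test_single_joint_definition(self, elasticity):
        chain = lm.make_chain(20)  # 4 segments
        theta = math.radians(25.0)
        v = chain.vertices.copy()
        b = chain.segment_length
        # bend the last joint by theta
        v[-1] = v[-2] + b * np.array([math.cos(theta), math.sin(theta), 0.0])
        chain.vertices = v
        g = elasticity.persistence_length / b
        assert lm.bending_energy(chain, elasticity) == pytest.approx(
            g * (1 - math.cos(theta)), rel=1e-9)

    def test_matches_naive_recomputation(self, elasticity, rng):
        # random 100-joint chain vs an independent brute-force summation
        chain = lm.make_chain(505)
        for _ in range(200):
            chain = lm.pivot_move(chain, rng)
        v = chain.vertices
        b = chain.segment_length
        g = elasticity.persistence_length / b
        naive = 0.0
        for i in range(1, chain.n_segments):
            t1 = v[i] - v[i - 1]
            t2 = v[i + 1] - v[i]
            cosang = float(np.dot(t1, t2) / (np.linalg.norm(t1) * np.linalg.norm(t2)))
            naive += g * (1.0 - cosang)
        assert lm.bending_energy(chain, elasticity) == pytest.approx(naive, rel=1e-9)

    def test_rejects_broken_segments(self, elasticity):
        chain = lm.make_chain(100)
        chain.vertices[3] += 0.5
        with pytest.raises(ValueError):
            lm.bending_energy(chain, elasticity)


class TestPivotMove:
    def test_zero_angle_is_identity(self, rng):
        chain = lm.make_chain(100, bend_angle=150.0)
        prop = lm.pivot_move(chain, rng, max_angle=1e-12)
        assert np.allclose(prop.vertices, chain.vertices, atol=1e-9)

    def test_preserves_segment_lengths_and_bend(self, rng):
        chain = lm.make_chain(150, bend_angle=150.0)
        for _ in range(2000):
            chain = lm.pivot_move(chain, rng)
        seg = np.diff(chain.vertices, axis=0)
        lengths = np.linalg.norm(seg, axis=1)
        assert np.max(np.abs(lengths / chain.segment_length - 1)) < 1e-9
        chain.validate()  # also checks the bend-vertex angle

    def test_angle_distribution_uniform(self, rng):
        # proposal angles must be uniform on [-50, 50] degrees
        chain = lm.make_chain(100)
        angles = np.array([lm.pivot_move(chain, rng, return_details=True)[1][2]
                           for _ in range(20_000)])
        ks = stats.kstest(angles, stats.uniform(loc=-50, scale=100).cdf)
        assert ks.pvalue > 0.01

    def test_never_pivots_at_bend_vertex(self, rng):
        chain = lm.make_chain(100, bend_angle=150.0)
        for _ in range(500):
            _, (i, _, _) = lm.pivot_move(chain, rng, return_details=True)
            assert i != chain.bend_vertex


class TestMetropolis:
    def test_single_joint_boltzmann(self):
        # two-segment chain: P(theta) ~ sin(theta) exp(-g(1-cos theta))
        b_bp = 5.0
        el = DsDnaElasticity(persistence_length=2.0 * 5.0 * 0.338)  # g = 2
        settings = lm.McSettings(n_equil=20_000, n_prod=300_000, seed=3)
        chain = lm.make_chain(2 * b_bp, segment_bp=b_bp)
        win = lm.metropolis_run(chain, settings, lm.UmbrellaWindow(r0=0.0, k=0.0), el)
        assert chain.n_segments == 2
        b = chain.segment_length
        cos_t = np.clip(win.samples ** 2 / (2 * b * b) - 1.0, -1, 1)
        theta = np.arccos(cos_t)[::30]  # thin past the autocorrelation time
        g = 2.0
        edges = np.linspace(0.05, math.pi - 0.05, 25)
        obs, _ = np.histogram(theta, bins=edges)
        grid = np.linspace(edges[0], edges[-1], 4000)
        dens = np.sin(grid) * np.exp(-g * (1 - np.cos(grid)))
        cdf = np.cumsum(dens)
        cdf /= cdf[-1]
        probs = np.diff(np.interp(edges, grid, np.concatenate([[0], cdf[1:]])))
        probs /= probs.sum()
        keep = probs * obs.sum() > 5
        chi2 = np.sum((obs[keep] - probs[keep] * obs.sum()) ** 2
                      / (probs[keep] * obs.sum()))
        pval = stats.chi2.sf(chi2, keep.sum() - 1)
        assert pval > 0.01

    def test_same_seed_bit_identical(self, quick_mc, elasticity):
        chain = lm.make_chain(100, bend_angle=150.0)
        win = lm.UmbrellaWindow(r0=5.0, k=3.0)
        a = lm.metropolis_run(chain, quick_mc, win, elasticity, seed=11)
        b = lm.metropolis_run(chain, quick_mc, win, elasticity, seed=11)
        assert np.array_equal(a.samples, b.samples)

    def test_energy_bookkeeping_consistent(self, quick_mc, elasticity):
        chain = lm.make_chain(150, bend_angle=150.0)
        win = lm.metropolis_run(chain, quick_mc, lm.UmbrellaWindow(r0=5.0, k=3.0),
                                elasticity, seed=2)
        assert win.energy_drift < 1e-6

    def test_negative_bias_stiffness_rejected(self, quick_mc, elasticity):
        chain = lm.make_chain(100)
        with pytest.raises(ValueError):
            lm.metropolis_run(chain, quick_mc, lm.UmbrellaWindow(r0=5.0, k=-1.0),
                              elasticity)


class TestWham:
    def test_single_unbiased_window_is_raw_histogram(self, rng):
        samples = rng.normal(20.0, 3.0, 50_000)
        win = lm.UmbrellaWindow(r0=0.0, k=0.0, samples=samples)
        res = lm.wham_unbias([win])
        counts, edges = np.histogram(samples, bins=len(res.r),
                                     range=(res.r[0] - res.bin_width / 2,
                                            res.r[-1] + res.bin_width / 2))
        dens = counts / counts.sum() / res.bin_width
        assert np.allclose(res.p0, dens, atol=1e-9)

    def test_window_order_invariance(self, rng):
        kT = 0.0138065 * 296.15
        wins = []
        for r0 in (8.0, 12.0, 16.0):
            s = rng.normal(r0, 1.5, 20_000)
            wins.append(lm.UmbrellaWindow(r0=r0, k=0.5 * kT, samples=s))
        p1 = lm.wham_unbias(wins).p0
        p2 = lm.wham_unbias(wins[::-1]).p0
        assert np.allclose(p1, p2, rtol=1e-6)

    def test_disjoint_windows_raise_with_gap(self, rng):
        w1 = lm.UmbrellaWindow(r0=5.0, k=1.0, samples=rng.normal(5, 0.2, 1000))
        w2 = lm.UmbrellaWindow(r0=50.0, k=1.0, samples=rng.normal(50, 0.2, 1000))
        with pytest.raises(ValueError, match="disjoint"):
            lm.wham_unbias([w1, w2])


class TestJFactor:
    def test_uniform_sphere_equals_inverse_avogadro_volume(self):
        # one chain end uniform in a sphere of radius R: P0(r) = 3r^2/R^3,
        # J = 1/(N_A V) exactly, independent of r
        R = 100.0
        r = np.linspace(0.05, R, 2000)
        p0 = 3.0 * r ** 2 / R ** 3
        expected_nM = 1.0 / (6.02214076e23 * (4 / 3) * math.pi * R ** 3 * 1e-24) * 1e9
        got = lm.j_factor_from_p0(p0, r, r_capture=2.0)
        assert got == pytest.approx(expected_nM, rel=1e-3)
        # frozen analytic value: ~396.5 nM for R = 100 nm
        assert got == pytest.approx(396.5, rel=2e-3)

    def test_support_scaling_is_inverse_cube(self):
        R = 50.0
        r = np.linspace(0.05, R, 2000)
        p0 = 3.0 * r ** 2 / R ** 3
        j1 = lm.j_factor_from_p0(p0, r, r_capture=2.0)
        r2 = 2.0 * r
        p02 = 3.0 * r2 ** 2 / (2 * R) ** 3
        j2 = lm.j_factor_from_p0(p02, r2, r_capture=4.0)  # same relative r
        assert j2 == pytest.approx(j1 / 8.0, rel=1e-2)

    def test_zero_density_gives_zero(self):
        r = np.linspace(0.1, 30, 300)
        p0 = np.where(r > 10, 1.0, 0.0)
        p0 /= np.trapezoid(p0, r)
        assert lm.j_factor_from_p0(p0, r, 2.0) == 0.0

    def test_capture_outside_support_raises(self):
        r = np.linspace(10, 30, 100)
        with pytest.raises(ValueError):
            lm.j_factor_from_p0(np.ones(100) / 20, r, 2.0)


class TestJFactorProfiles:
    def test_same_seed_identical_profile(self, elasticity):
        s = lm.McSettings(n_equil=5_000, n_prod=20_000, seed=5)
        p1 = lm.j_factor_profile(100.0, 150.0, s, elasticity)
        p2 = lm.j_factor_profile(100.0, 150.0, s, elasticity)
        assert p1.j_at_capture == p2.j_at_capture
        assert np.array_equal(p1.p0, p2.p0)

    def test_bent_dominates_unbent_for_short_loops(self, elasticity):
        s = lm.McSettings(n_equil=10_000, n_prod=40_000, seed=9)
        for L in (100.0, 150.0, 200.0):
            jb = lm.j_factor_profile(L, 150.0, s, elasticity).j_at_capture
            ju = lm.j_factor_profile(L, 0.0, s, elasticity).j_at_capture
            assert jb >= ju

    def test_stiff_short_unbent_loop_unmeasurable(self, elasticity):
        s = lm.McSettings(n_equil=10_000, n_prod=40_000, seed=1)
        p = lm.j_factor_profile(50.0, 0.0, s, elasticity)
        assert p.j_at_capture == pytest.approx(0.0, abs=1e-3)

    def test_too_few_segments_rejected(self, quick_mc):
        with pytest.raises(ValueError):
            lm.j_factor_curve([10.0], 0.0, quick_mc)


class TestLoopSizePrediction:
    @staticmethod
    def _profiles(Ls, Js):
        return [lm.JFactorProfile(loop_length_bp=L, r=np.array([2.0]),
                                  p0=np.array([1.0]), j_at_capture=J, j_se=0.0)
                for L, J in zip(Ls, Js)]

    def test_recovers_scale_factors(self, rng):
        Ls = np.arange(50, 650, 50, dtype=float)
        ju = np.exp(-((Ls - 450) / 150.0) ** 2)
        jb = np.exp(-((Ls - 100) / 60.0) ** 2)
        counts = rng.poisson(200 * (2.0 * ju + 3.0 * jb))
        a, b, comp, resid = lm.predict_loop_size_distribution(
            self._profiles(Ls, 200 * ju), self._profiles(Ls, 200 * jb), Ls, counts)
        assert a == pytest.approx(2.0, rel=0.15)
        assert b == pytest.approx(3.0, rel=0.15)

    def test_absent_component_fits_to_zero(self, rng):
        Ls = np.arange(50, 650, 50, dtype=float)
        ju = np.exp(-((Ls - 450) / 150.0) ** 2)
        jb = np.exp(-((Ls - 100) / 60.0) ** 2)
        counts = rng.poisson(500 * ju)
        _, b, _, _ = lm.predict_loop_size_distribution(
            self._profiles(Ls, 500 * ju), self._profiles(Ls, 500 * jb), Ls, counts)
        assert b == pytest.approx(0.0, abs=0.2)

    def test_scale_invariance_under_renormalization(self, rng):
        Ls = np.arange(50, 650, 50, dtype=float)
        ju = np.exp(-((Ls - 450) / 150.0) ** 2)
        jb = np.exp(-((Ls - 100) / 60.0) ** 2)
        counts = 200 * (1.5 * ju + 0.5 * jb)
        a1, b1, _, _ = lm.predict_loop_size_distribution(
            self._profiles(Ls, ju), self._profiles(Ls, jb), Ls, counts)
        a2, b2, _, _ = lm.predict_loop_size_distribution(
            self._profiles(Ls, ju), self._profiles(Ls, jb), Ls, 3.0 * counts)
        assert a2 == pytest.approx(3 * a1, rel=1e-6)
        assert b2 == pytest.approx(3 * b1, rel=1e-6)

    def test_all_zero_histogram_rejected(self):
        Ls = np.arange(50, 650, 50, dtype=float)
        prof = self._profiles(Ls, np.ones_like(Ls))
        with pytest.raises(ValueError):
            lm.predict_loop_size_distribution(prof, prof, Ls, np.zeros_like(Ls))
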