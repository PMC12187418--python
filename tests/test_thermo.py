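"""Thermodynamic-efficiency machinery: entropy, Fisher, work, peaks."""

import numpy as np
import pytest

import spinloop as sl
from spinloop.thermo import (
    EfficiencyCurve,
    EntropyCurve,
    FisherCurve,
    kikuchi_entropy,
    link_sum,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(12)


class TestKikuchiEntropy:
    def test_iid_uniform_spins_give_ln2_per_site(self, rng):
        snaps = rng.integers(0, 2, size=(300, 16, 16)).astype(np.int8) * 2 - 1
        k = kikuchi_entropy(snaps)
        assert k.S4 == pytest.approx(4 * np.log(2), abs=2e-3)
        assert k.S2 == pytest.approx(2 * np.log(2), abs=1e-3)
        assert k.S1 == pytest.approx(np.log(2), abs=1e-4)
        assert k.S == pytest.approx(np.log(2), abs=2e-3)

    def test_frozen_snapshots_have_zero_entropy(self):
        snaps = np.ones((10, 8, 8), dtype=np.int8)
        assert kikuchi_entropy(snaps).S == pytest.approx(0.0, abs=1e-12)

    def test_split_bias_correction_tightens_uniform_limit(self, rng):
        snaps = rng.integers(0, 2, size=(400, 8, 8)).astype(np.int8) * 2 - 1
        plain = kikuchi_entropy(snaps).S
        corrected = kikuchi_entropy(snaps, bias_correction="split").S
        assert abs(corrected - np.log(2)) <= abs(plain - np.log(2)) + 1e-4

    def test_matches_exact_marginal_value(self):
        spec = sl.DynamicsSpec(rule="metropolis", J=0.4, seed=21, n_steps=400_000, snapshot_interval=1)
        ss = sl.simulate(spec, 3)
        exact = sl.exact_measures(sl.enumerate_boltzmann(3, 0.4), "metropolis").kikuchi_per_site_nats
        assert kikuchi_entropy(ss.snapshots).S == pytest.approx(exact, abs=0.01)

    def test_mixed_sizes_rejected(self):
        states = [sl.LatticeState(np.ones((4, 4))), sl.LatticeState(np.ones((5, 5)))]
        with pytest.raises(ValueError):
            kikuchi_entropy(states)

    def test_unknown_correction_rejected(self):
        with pytest.raises(ValueError):
            kikuchi_entropy(np.ones((4, 3, 3), dtype=np.int8), bias_correction="bootstrap")


class TestFisherInformation:
    def test_frozen_snapshots_have_zero_information(self):
        assert sl.fisher_information(np.ones((5, 6, 6), dtype=np.int8)) == 0.0

    def test_needs_two_snapshots(self):
        with pytest.raises(ValueError):
            sl.fisher_information(np.ones((1, 4, 4), dtype=np.int8))

    def test_non_negative(self, rng):
        snaps = rng.integers(0, 2, size=(50, 6, 6)).astype(np.int8) * 2 - 1
        assert sl.fisher_information(snaps) >= 0.0

    def test_link_sum_counts_each_link_once(self):
        snaps = np.ones((1, 4, 4), dtype=np.int8)
        assert link_sum(snaps)[0] == 32  # 2 * L^2 links on the torus

    def test_matches_enumeration_oracle(self):
        exact = sl.exact_measures(sl.enumerate_boltzmann(3, 0.3), "glauber").fisher_per_site
        vals = []
        for r in range(6):
            spec = sl.DynamicsSpec(rule="glauber", J=0.3, seed=60 + r, n_steps=200_000, snapshot_interval=1)
            ss = sl.simulate(spec, 3)
            vals.append(sl.fisher_information(ss.snapshots))
        v = np.asarray(vals)
        se = v.std(ddof=1) / np.sqrt(len(v))
        assert abs(v.mean() - exact) < 3 * se


class TestEntropyDerivative:
    def test_constant_curve(self):
        c = EntropyCurve(np.linspace(0.1, 1, 10), np.full(10, 0.3))
        assert np.allclose(sl.entropy_derivative(c), 0.0)

    def test_linear_curve(self):
        g = np.linspace(0.1, 1, 10)
        c = EntropyCurve(g, -0.7 * g)
        assert np.allclose(sl.entropy_derivative(c), -0.7)

    def test_quadratic_exact_at_interior_points(self):
        g = np.linspace(0.0, 1, 11)
        c = EntropyCurve(g, 2 * g**2 - g)
        d = sl.entropy_derivative(c)
        assert np.allclose(d[1:-1], (4 * g - 1)[1:-1])

    def test_smoothing_window_validation(self):
        c = EntropyCurve(np.linspace(0.1, 1, 10), np.zeros(10))
        with pytest.raises(ValueError):
            sl.entropy_derivative(c, smooth=2)

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError):
            EntropyCurve(np.array([0.2, 0.1, 0.3]), np.zeros(3))

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            sl.entropy_derivative(EntropyCurve(np.array([0.1, 0.2]), np.zeros(2)))


class TestWorkIntegral:
    def test_empty_interval(self):
        c = FisherCurve(np.linspace(0.1, 10, 20), np.ones(20))
        assert sl.work_integral(c, 10.0, 10.0) == 0.0

    def test_constant_integrand(self):
        c = FisherCurve(np.linspace(0.0, 10, 101), np.full(101, 2.5))
        assert sl.work_integral(c, 1.0, 10.0) == pytest.approx(2.5 * 9.0)

    def test_piecewise_linear_hand_computed(self):
        c = FisherCurve(np.array([0.0, 1.0, 3.0]), np.array([2.0, 4.0, 0.0]))
        # trapezoids: (2+4)/2 * 1 + (4+0)/2 * 2 = 7
        assert sl.work_integral(c, 0.0, 3.0) == pytest.approx(7.0)

    def test_interpolated_endpoint(self):
        c = FisherCurve(np.array([0.0, 2.0]), np.array([0.0, 4.0]))
        assert sl.work_integral(c, 1.0, 2.0) == pytest.approx(3.0)

    def test_range_violations_rejected(self):
        c = FisherCurve(np.array([0.5, 1.0]), np.ones(2))
        with pytest.raises(ValueError):
            sl.work_integral(c, 0.1, 1.0)
        with pytest.raises(ValueError):
            sl.work_integral(c, 0.9, 0.6)


class TestEfficiency:
    def test_zero_slope_gives_zero_efficiency(self):
        # symmetric (even) entropy curve: the derivative vanishes at 0
        g = np.array([-0.2, 0.0, 0.2])
        entropy = EntropyCurve(g, 0.5 - g**2)
        fisher = FisherCurve(g, np.ones(3))
        eff = sl.efficiency(entropy, fisher, Jstar=0.2)
        assert eff.eta[1] == pytest.approx(0.0, abs=1e-12)

    def test_undefined_where_work_vanishes(self):
        g = np.linspace(0.1, 1.0, 10)
        entropy = EntropyCurve(g, np.exp(-g))
        fisher = FisherCurve(g, np.zeros(10))
        eff = sl.efficiency(entropy, fisher, Jstar=1.0)
        assert not eff.defined.any()
        with pytest.raises(ValueError):
            sl.peak_location(eff)

    def test_grid_mismatch_rejected(self):
        entropy = EntropyCurve(np.array([0.1, 0.2, 0.3]), np.zeros(3))
        fisher = FisherCurve(np.array([0.1, 0.25, 0.3]), np.ones(3))
        with pytest.raises(ValueError):
            sl.efficiency(entropy, fisher, Jstar=0.3)

    def test_fisher_grid_may_extend_beyond_entropy_grid(self):
        entropy = EntropyCurve(np.array([0.1, 0.2, 0.3]), np.array([0.9, 0.7, 0.6]))
        fisher = FisherCurve(np.array([0.1, 0.2, 0.3, 1.0, 10.0]), np.array([1, 1, 1, 0.1, 0.0]))
        eff = sl.efficiency(entropy, fisher, Jstar=10.0)
        assert eff.defined.all()
        assert np.all(eff.eta >= 0)
        assert np.all(np.diff(eff.work_integral) <= 0)


class TestPeakLocation:
    def test_single_peak_recovered(self):
        g = np.linspace(0.1, 1.0, 10)
        eta = -((g - 0.4) ** 2)
        c = EfficiencyCurve(g, np.zeros(10), np.ones(10), eta, Jstar=10.0)
        assert sl.peak_location(c) == pytest.approx(0.4)

    def test_monotone_curve_peaks_at_boundary(self):
        g = np.linspace(0.1, 1.0, 10)
        c = EfficiencyCurve(g, np.zeros(10), np.ones(10), g.copy(), Jstar=10.0)
        assert sl.peak_location(c) == pytest.approx(1.0)

    def test_tie_broken_toward_smaller_coupling(self):
        g = np.array([0.1, 0.2, 0.3])
        c = EfficiencyCurve(g, np.zeros(3), np.ones(3), np.array([1.0, 1.0, 0.5]), Jstar=1.0)
        assert sl.peak_location(c) == pytest.approx(0.1)


class TestSweepThermoTrends:
    def test_entropy_non_increasing_in_coupling(self, desk_sweep):
        for rule in ("glauber", "metropolis"):
            t = desk_sweep.values("entropy", rule, 16)
            m, se = t["mean"].to_numpy(), t["stderr"].to_numpy()
            assert np.all(np.diff(m) <= 2 * (se[:-1] + se[1:]))

    def test_efficiency_non_negative_where_defined(self, desk_sweep):
        for rule in ("glauber", "metropolis"):
            eff = desk_sweep.efficiency_curve(rule, 16)
            assert np.all(eff.eta[eff.defined] >= 0)
            assert np.all(np.diff(eff.work_integral) <= 0)

    def test_entropy_slope_matches_fisher_identity(self, desk_sweep):
        # for the Boltzmann family, -dS/dJ = J * I(J) for the true entropy;
        # the cluster-variation estimate tracks the true entropy through the
        # disordered and critical regions, so the two independently
        # estimated sides must agree there (deep in the ordered phase the
        # symmetric-law cluster entropy deliberately departs from the true
        # tail; see the methods note)
        for rule in ("glauber", "metropolis"):
            ent = desk_sweep.entropy_curve(rule, 16)
            fis = desk_sweep.values("fisher", rule, 16)
            fis = fis[fis["J"].round(9).isin(np.round(ent.J_grid, 9))]["mean"].to_numpy()
            lhs = -sl.entropy_derivative(ent)
            rhs = ent.J_grid * fis
            sel = (ent.J_grid >= 0.15) & (ent.J_grid <= 0.6)
            err = np.abs(lhs[sel] - rhs[sel]) / np.maximum(rhs[sel], 1e-3)
            # central differences smooth the steep critical region; allow
            # a generous band and require the bulk to agree closely
            assert np.median(err) < 0.1
            assert np.all(err < 0.35)
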