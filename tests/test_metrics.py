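"""Selectivity and connectivity statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from balnet.metrics import (TuningCurve, delta_po, membrane_tuning, osi,
                            population_average_tuning, tuning_curves,
                            wbi, wbi_norm, weight_evolution, weight_vs_dpo)


class FakeResult:
    def __init__(self, rates):
        self.rates = np.asarray(rates, dtype=float)


class FakeProbe:
    def __init__(self, orientations):
        class Seg:
            def __init__(self, o):
                self.orientation = o
        self.segments = [Seg(o) for o in orientations]


class TestTuningCurves:
    def test_flat_spiking_gives_flat_curve_zero_sd(self):
        oris = [0.0, 45.0, 90.0, 135.0] * 3   # 3 trials each
        res = FakeResult(np.full((12, 2), 10.0))
        curves = tuning_curves(res, FakeProbe(oris))
        for c in curves:
            np.testing.assert_allclose(c.mean_rate, 10.0)
            np.testing.assert_allclose(c.trial_sd, 0.0)

    def test_trial_order_invariance(self):
        rng = np.random.default_rng(0)
        oris = [0.0, 90.0] * 5
        rates = rng.uniform(0, 20, size=(10, 3))
        c1 = tuning_curves(FakeResult(rates), FakeProbe(oris))
        perm = rng.permutation(10)
        c2 = tuning_curves(FakeResult(rates[perm]),
                           FakeProbe([oris[i] for i in perm]))
        for a, b in zip(c1, c2):
            np.testing.assert_allclose(a.mean_rate, b.mean_rate)
            np.testing.assert_allclose(a.trial_sd, b.trial_sd)

    def test_poisson_counts_recover_rates(self):
        # independent oracle: per-segment spike counts ~ Poisson(r*T)
        rng = np.random.default_rng(3)
        true_rate, T, n_trials = 12.0, 2.0, 400
        oris = [0.0, 90.0] * n_trials
        rates = rng.poisson(true_rate * T, size=(2 * n_trials, 1)) / T
        curves = tuning_curves(FakeResult(rates), FakeProbe(oris))
        se = np.sqrt(true_rate / T / n_trials)
        assert abs(curves[0].mean_rate[0] - true_rate) < 4 * se

    def test_empty_spikes_valid(self):
        curves = tuning_curves(FakeResult(np.zeros((8, 2))),
                               FakeProbe([0.0, 22.5] * 4))
        np.testing.assert_allclose(curves[0].mean_rate, 0.0)


class TestOSI:
    def test_flat_curve_is_untuned(self):
        th = np.arange(8) * 22.5
        assert osi((th, np.full(8, 3.0))) == pytest.approx(0.0, abs=1e-12)

    def test_single_orientation_fully_tuned(self):
        th = np.arange(8) * 22.5
        r = np.zeros(8)
        r[2] = 5.0
        assert osi((th, r)) == pytest.approx(1.0)

    def test_cosine_curve_gives_half_modulation(self):
        th = np.arange(360) * 0.5  # dense sampling of [0, 180)
        for mu in (0.2, 0.6):
            r = 1.0 + mu * np.cos(2 * np.deg2rad(th - 37.0))
            assert osi((th, r)) == pytest.approx(mu / 2, rel=1e-9)

    def test_all_zero_is_nan(self):
        assert np.isnan(osi((np.arange(8) * 22.5, np.zeros(8))))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 100), min_size=4, max_size=16),
           st.floats(0.1, 50))
    def test_range_and_scale_invariance(self, rates, c):
        th = np.linspace(0, 180, len(rates), endpoint=False)
        r = np.asarray(rates)
        if r.sum() <= 0:
            return
        v = osi((th, r))
        assert 0.0 <= v <= 1.0 + 1e-12
        assert osi((th, c * r)) == pytest.approx(v, abs=1e-9)

    def test_rejects_negative_rates_in_curve(self):
        with pytest.raises(ValueError):
            TuningCurve(np.array([0.0, 90.0]), np.array([1.0, -1.0]),
                        np.array([0.0, 0.0]))


class TestPopulationAverage:
    def _curves(self, pos, mu=0.5):
        th = np.arange(8) * 22.5
        return [TuningCurve(th, 5 + 5 * mu * np.cos(
            2 * np.deg2rad(th - po)), np.zeros(8)) for po in pos]

    def test_identical_shifted_neurons_zero_sd(self):
        pos = np.arange(8) * 22.5      # POs on the probe grid
        centers, mean, sd, o = population_average_tuning(
            self._curves(pos), pos, n_bins=8)
        ok = ~np.isnan(mean)
        np.testing.assert_allclose(sd[ok], 0.0, atol=1e-12)
        assert o > 0.2

    def test_shift_equivariance(self):
        pos = np.arange(8) * 22.5
        out1 = population_average_tuning(self._curves(pos), pos)
        delta = 45.0
        shifted = [TuningCurve(c.orientations + delta, c.mean_rate,
                               c.trial_sd) for c in self._curves(pos)]
        out2 = population_average_tuning(shifted, pos + delta)
        np.testing.assert_allclose(out1[1], out2[1], equal_nan=True)

    def test_flat_curves_flat_mean_zero_osi(self):
        th = np.arange(8) * 22.5
        curves = [TuningCurve(th, np.full(8, 2.0), np.zeros(8))
                  for _ in range(5)]
        _, mean, _, o = population_average_tuning(
            curves, np.array([0, 30, 60, 90, 120.0]))
        ok = ~np.isnan(mean)
        np.testing.assert_allclose(mean[ok], 2.0)
        assert o == pytest.approx(0.0, abs=1e-12)


class TestMembraneTuning:
    def test_zero_rate_no_correction(self):
        v = {0.0: np.array([1.0, 3.0])}
        _, u, uf = membrane_tuning(v, {0.0: 0.0})
        assert uf[0] == pytest.approx(u[0]) == pytest.approx(2.0)

    def test_reset_correction_value(self):
        # r = 10 Hz -> correction tau_m * u_th * r = 0.020*20*10 = 4 mV
        v = {0.0: np.zeros(5)}
        _, _, uf = membrane_tuning(v, {0.0: 10.0})
        assert uf[0] == pytest.approx(4.0)

    def test_correction_monotone_in_rate(self):
        v = {o: np.zeros(3) for o in (0.0, 45.0, 90.0)}
        _, _, uf = membrane_tuning(v, {0.0: 1.0, 45.0: 5.0, 90.0: 9.0})
        assert np.all(np.diff(uf) > 0)


class TestWeightVsDPO:
    def test_dpo_circular_and_symmetric(self):
        assert delta_po(10.0, 170.0) == pytest.approx(20.0)
        a = delta_po([0, 40, 100.0], [90, 175, 5.0])
        b = delta_po([90, 175, 5.0], [0, 40, 100.0])
        np.testing.assert_allclose(a, b)
        assert np.all(a <= 90.0)

    def _uniform_net(self, n=40, w=0.5):
        rng = np.random.default_rng(1)
        conn = rng.random((n, n)) < 0.5
        np.fill_diagonal(conn, False)
        W = np.where(conn, w, 0.0)
        PO = 180.0 * np.arange(n) / n
        return W, PO, conn

    def test_uniform_weights_equal_group_means(self):
        W, PO, conn = self._uniform_net()
        rep = weight_vs_dpo(W, PO, np.ones(40, bool), np.ones(40, bool),
                            conn=conn)
        for v in rep.group_means.values():
            assert v == pytest.approx(0.5)
        assert rep.weight_tuning_osi == pytest.approx(0.0, abs=1e-12)

    def test_cosine_squared_weights_decrease_across_groups(self):
        n = 60
        PO = 180.0 * np.arange(n) / n
        d = delta_po(PO[:, None], PO[None, :])
        W = np.cos(np.deg2rad(d)) ** 2
        np.fill_diagonal(W, 0.0)
        conn = ~np.eye(n, dtype=bool)
        rep = weight_vs_dpo(W, PO, np.ones(n, bool), np.ones(n, bool),
                            conn=conn)
        g = rep.group_means
        assert g["similar"] > g["indifferent"] > g["dissimilar"]
        assert rep.weight_tuning_osi > 0.1

    def test_empty_class_gives_nan(self):
        W, PO, conn = self._uniform_net()
        rep = weight_vs_dpo(W, PO, np.zeros(40, bool), np.ones(40, bool),
                            conn=conn)
        assert all(np.isnan(v) for v in rep.group_means.values())


class TestWBI:
    def test_unidirectional_is_zero(self):
        W = np.triu(np.ones((6, 6)), k=1)   # only i<j synapses
        assert wbi(W) == 0.0

    def test_symmetric_unit_weights_pair_fraction(self):
        n = 10
        rng = np.random.default_rng(4)
        up = np.triu(rng.random((n, n)) < 0.4, k=1)
        W = (up | up.T).astype(float)
        frac = up.sum() / (n * (n - 1) / 2)
        assert wbi(W) == pytest.approx(frac)

    def test_scope_mask(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 2.0
        scope = np.array([True, True, False, False])
        assert wbi(W, scope) == pytest.approx(4.0)

    def test_wbi_norm_of_random_matrix_near_one(self):
        vals = []
        for seed in range(4):
            rng = np.random.default_rng(seed)
            n = 60
            conn = rng.random((n, n)) < 0.3
            np.fill_diagonal(conn, False)
            W = np.where(conn, rng.uniform(0.1, 1.0, (n, n)), 0.0)
            vals.append(wbi_norm(W, n_shuffles=100, seed=seed))
        assert 0.95 < np.mean(vals) < 1.05

    def test_all_zero_scope_undefined(self):
        assert np.isnan(wbi_norm(np.zeros((5, 5))))


class TestWeightEvolution:
    def test_identical_snapshots_zero_delta(self):
        W = np.ones((4, 4))
        mask = {"EE": np.ones((4, 4), bool)}
        ev = weight_evolution([W, W.copy(), W.copy()], mask)
        np.testing.assert_allclose(ev["mean_abs_dw"]["EE"], 0.0)

    def test_single_synapse_change_normalization(self):
        W0 = np.ones((3, 3))
        W1 = W0.copy()
        W1[0, 1] += 0.1
        mask = {"EE": np.ones((3, 3), bool)}
        ev = weight_evolution([W0, W1], mask)
        assert ev["mean_abs_dw"]["EE"][0] == pytest.approx(0.1 / 9)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        snaps = [rng.random((5, 5)) for _ in range(3)]
        mask = {"all": np.ones((5, 5), bool)}
        perm = rng.permutation(5)
        snaps_p = [s[np.ix_(perm, perm)] for s in snaps]
        a = weight_evolution(snaps, mask)["mean_abs_dw"]
        b = weight_evolution(snaps_p, mask)["mean_abs_dw"]
        np.testing.assert_allclose(a["all"], b["all"])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weight_evolution([np.ones((3, 3)), np.ones((4, 4))],
                             {"x": np.ones((3, 3), bool)})
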