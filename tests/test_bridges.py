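"""Bridge kinetics: exponential fits, condition comparison, summaries."""

import numpy as np
import pandas as pd
import pytest

from abclock import (BridgeSimConfig, BridgeTrace, abscission_durations,
                     bridge_fraction, compare_conditions, density_trend,
                     fit_exponential, simulate_bridge_widths,
                     simulate_frame_counts)
from abclock.bridges import fit_bridge_table


def make_trace(tau_c=45.0, w0=1.0, w_inf=0.2, t=None, bid="b"):
    if t is None:
        t = np.arange(0.0, 181.0, 5.0)
    w = w_inf + (w0 - w_inf) * np.exp(-t / tau_c)
    return BridgeTrace(bid, t, w)


class TestFitExponential:
    @pytest.mark.parametrize("tau_c", [45.0, 15.0])
    def test_noiseless_recovery(self, tau_c):
        fit = fit_exponential(make_trace(tau_c=tau_c))
        assert fit.converged
        assert fit.tau_c == pytest.approx(tau_c, abs=1e-4)
        assert fit.w0 == pytest.approx(1.0, abs=1e-6)
        assert fit.w_inf == pytest.approx(0.2, abs=1e-4)

    def test_time_rescaling_equivariance(self):
        t = np.arange(0.0, 181.0, 5.0)
        f1 = fit_exponential(make_trace(t=t))
        f2 = fit_exponential(make_trace(t=3.0 * t, tau_c=135.0))
        assert f2.tau_c == pytest.approx(3.0 * f1.tau_c, rel=1e-6)

    def test_constant_trace_rejected(self):
        t = np.arange(0.0, 50.0, 5.0)
        with pytest.raises(ValueError, match="no decay"):
            fit_exponential(BridgeTrace("b", t, np.full(t.size, 0.5)))

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="too few"):
            fit_exponential(BridgeTrace("b", np.arange(3.0),
                                        np.array([1.0, 0.5, 0.3])))

    def test_fixed_plateau_variant(self):
        fit = fit_exponential(make_trace(w_inf=0.0), fix_winf=True)
        assert fit.w_inf == 0.0
        assert fit.tau_c == pytest.approx(45.0, abs=1e-4)

    def test_order_invariance_of_table_fit(self):
        df = simulate_bridge_widths(BridgeSimConfig.naive(seed=8,
                                                          n_curves=5))
        shuffled = df.sample(frac=1.0, random_state=0)
        f1 = fit_bridge_table(df).set_index("bridge_id")
        f2 = fit_bridge_table(shuffled).set_index("bridge_id")
        pd.testing.assert_frame_equal(f1.sort_index(), f2.sort_index())


@pytest.fixture(scope="module")
def datasets():
    a = simulate_bridge_widths(BridgeSimConfig.naive(seed=1))
    b = simulate_bridge_widths(BridgeSimConfig.exiting(seed=2))
    return a, b


class TestCompareConditions:

    def test_f_test_detects_published_difference(self, datasets):
        a, b = datasets
        res = compare_conditions(a, b, method="F")
        assert res["p_value"] < 1e-4
        assert res["tau_a"] == pytest.approx(45.0, rel=0.2)
        assert res["tau_b"] == pytest.approx(15.0, rel=0.2)

    def test_permutation_detects_difference(self, datasets):
        a, b = datasets
        res = compare_conditions(a, b, method="permutation", n_perm=99,
                                 seed=0)
        assert res["p_value"] <= 0.05

    def test_identical_data_permutation_p_one(self):
        a = simulate_bridge_widths(BridgeSimConfig.naive(seed=3,
                                                         n_curves=4))
        res = compare_conditions(a, a.assign(bridge_id=a.bridge_id + "x"),
                                 method="permutation", n_perm=50, seed=1)
        assert res["p_value"] == 1.0

    def test_null_calibration_permutation(self):
        # same tau_c in both groups: permutation p roughly uniform
        hits, n_runs = 0, 40
        for seed in range(n_runs):
            a = simulate_bridge_widths(BridgeSimConfig(
                n_curves=6, tau_c=30.0, seed=seed, condition="a"))
            b = simulate_bridge_widths(BridgeSimConfig(
                n_curves=6, tau_c=30.0, seed=1000 + seed, condition="b"))
            res = compare_conditions(a, b, method="permutation", n_perm=59,
                                     seed=seed)
            hits += res["p_value"] < 0.05
        assert hits / n_runs <= 0.15

    def test_methods_agree_on_generator_defaults(self):
        # F and permutation must agree on reject/accept at alpha=0.05 in
        # at least 90% of runs under the preset difference
        agree, n_runs = 0, 10
        for seed in range(n_runs):
            a = simulate_bridge_widths(BridgeSimConfig.naive(
                seed=seed, n_curves=6))
            b = simulate_bridge_widths(BridgeSimConfig.exiting(
                seed=100 + seed, n_curves=6))
            pf = compare_conditions(a, b, method="F")["p_value"]
            pp = compare_conditions(a, b, method="permutation", n_perm=59,
                                    seed=seed)["p_value"]
            agree += (pf < 0.05) == (pp < 0.05)
        assert agree / n_runs >= 0.9

    def test_permutation_needs_two_traces(self, datasets):
        a, _ = datasets
        single = a[a.bridge_id == a.bridge_id.iloc[0]]
        with pytest.raises(ValueError, match="permutation"):
            compare_conditions(single, a, method="permutation")


class TestAbscissionSummary:
    def test_hand_computed(self):
        s = abscission_durations([1.0, 2.0, 3.0])
        assert s["mean"] == pytest.approx(2.0)
        assert s["sd"] == pytest.approx(1.0)
        assert s["n"] == 3

    def test_two_pass_oracle(self, rng):
        d = rng.uniform(0, 10, 200)
        s = abscission_durations(d)
        mean = sum(d) / len(d)
        sd = (sum((x - mean) ** 2 for x in d) / (len(d) - 1)) ** 0.5
        assert s["mean"] == pytest.approx(mean, abs=1e-12)
        assert s["sd"] == pytest.approx(sd, abs=1e-12)

    def test_single_event_sd_missing(self):
        assert abscission_durations([4.2])["sd"] is None

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            abscission_durations([])


class TestBridgeFraction:
    def test_simple_frames(self):
        counts = pd.DataFrame(dict(frame_id=[0, 1],
                                   n_cells=[10, 4], n_bridges=[0, 2]))
        bf = bridge_fraction(counts)
        np.testing.assert_allclose(bf["fractions"], [0.0, 0.5])

    def test_zero_cell_frame_excluded(self):
        counts = pd.DataFrame(dict(frame_id=[0, 1],
                                   n_cells=[0, 4], n_bridges=[0, 2]))
        with pytest.warns(UserWarning, match="0 cells"):
            bf = bridge_fraction(counts)
        assert bf["n_frames"] == 1

    def test_binomial_recovery(self):
        counts = simulate_frame_counts(500, 100, 0.3, seed=4)
        bf = bridge_fraction(counts)
        assert abs(bf["mean"] - 0.3) < 2 * bf["sem"] + 0.01


class TestDensityTrend:
    def test_strictly_decreasing(self):
        rho, p, defined = density_trend([0.5, 0.4, 0.3, 0.2],
                                        [1.0, 2.0, 3.0, 4.0])
        assert defined and rho == pytest.approx(-1.0)

    def test_constant_fractions(self):
        rho, p, defined = density_trend([0.3, 0.3, 0.3], [1.0, 2.0, 3.0])
        assert not defined and rho == 0.0 and p == 1.0

    def test_shuffled_small_correlation(self, rng):
        f = rng.uniform(0, 1, 200)
        c = rng.uniform(0, 1, 200)
        rho, _, defined = density_trend(f, c)
        assert defined and abs(rho) < 0.2
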