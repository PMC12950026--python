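"""Evaluation metrics against independent brute-force oracles."""

import numpy as np
import pytest

from propriosnn.analysis import (
    ConfusionCounts,
    RateTrace,
    ReferenceRates,
    combined_signal,
    fit_rate_velocity,
    grid_search_adex,
    grid_search_position,
    lag_shift,
    mae_fit,
    mse_traces,
    ramp_response_rates,
    spike_rate,
    velocity_confusion,
    znorm,
)
from propriosnn.neurons import AdExParams, SpikeTrain
from propriosnn.stimuli import JointAngleTrace

DT = 0.25


class TestSpikeRate:
    def test_empty_train_zero_trace(self):
        rt = spike_rate(SpikeTrain([], 100.0), DT)
        assert np.all(rt.rate == 0.0)

    def test_periodic_train_flat_interior(self):
        times = np.arange(10.0, 500.0, 10.0)  # 100 Hz
        rt = spike_rate(SpikeTrain(times, 500.0), DT)
        interior = (rt.t > 20.0) & (rt.t < 480.0)
        assert np.allclose(rt.rate[interior], 100.0)
        assert np.all(rt.rate[rt.t < 9.0] == 0.0)

    def test_boxcar_conserves_spike_count(self):
        rng = np.random.default_rng(1)
        times = np.sort(rng.uniform(100.0, 900.0, 40))
        rt = spike_rate(SpikeTrain(times, 1000.0), DT, "boxcar", width=50.0)
        # integral of rate (Hz) over time (s) returns the spike count
        total = np.sum(rt.rate) * DT / 1000.0
        assert total == pytest.approx(40.0, rel=1e-6)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            spike_rate(SpikeTrain([1.0], 10.0), DT, "gaussian")


class TestZnormAndCombined:
    def test_affine_invariance_and_moments(self):
        rng = np.random.default_rng(2)
        x = rng.normal(5.0, 3.0, 1000)
        z = znorm(x)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0)
        assert np.allclose(znorm(4.0 * x - 7.0), z)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            znorm(np.full(10, 3.0))

    def test_combined_signal_sign_flip(self):
        t = np.arange(100.0)
        a = RateTrace(t, np.sin(t / 10.0) + 2.0)
        b = RateTrace(t, np.cos(t / 10.0) + 2.0)
        fwd = combined_signal(a, b).rate
        rev = combined_signal(b, a).rate
        assert np.allclose(fwd, -rev)
        with pytest.raises(ValueError):
            combined_signal(a, a)


class TestMae:
    def test_identical_tables_zero(self):
        r = ReferenceRates(np.arange(10.0), np.arange(10.0) + 50.0)
        assert mae_fit(r, r) == 0.0

    def test_uniform_offset(self):
        r = ReferenceRates(np.arange(10.0), np.arange(10.0) + 50.0)
        m = ReferenceRates(r.x_ss + 10.0, r.x_max + 10.0)
        assert mae_fit(m, r) == pytest.approx(10.0)

    def test_hand_case(self):
        """One trial off by (4, 6), nine exact: (4+6)/20 = 0.5 Hz."""
        ref = ReferenceRates(np.zeros(10), np.zeros(10))
        model = ReferenceRates(
            np.r_[4.0, np.zeros(9)], np.r_[6.0, np.zeros(9)]
        )
        assert mae_fit(model, ref) == pytest.approx(0.5)

    def test_oracle_equivalence_random(self):
        """Direct loop recomputation on random tables."""
        rng = np.random.default_rng(3)
        for _ in range(300):
            a = ReferenceRates(rng.normal(size=10), rng.normal(size=10))
            b = ReferenceRates(rng.normal(size=10), rng.normal(size=10))
            brute = sum(
                abs(a.x_ss[i] - b.x_ss[i]) + abs(a.x_max[i] - b.x_max[i])
                for i in range(10)
            ) / 20.0
            assert mae_fit(a, b) == pytest.approx(brute)


class TestMse:
    def test_identical_zero_and_symmetry(self):
        rng = np.random.default_rng(4)
        a = znorm(rng.normal(size=500))
        b = znorm(rng.normal(size=500))
        assert mse_traces(a, a).mse == 0.0
        assert mse_traces(a, b).mse == pytest.approx(mse_traces(b, a).mse)

    def test_sign_flipped_znormed_series_gives_four(self):
        """E[(2z)^2] = 4 for a unit-variance series."""
        rng = np.random.default_rng(5)
        z = znorm(rng.normal(size=2000))
        assert mse_traces(-z, z).mse == pytest.approx(4.0)

    def test_oracle_equivalence_random(self):
        """Nested-loop recomputation over steps, joints and trials."""
        rng = np.random.default_rng(6)
        for _ in range(300):
            n_series = rng.integers(1, 5)
            n = rng.integers(3, 20)
            model = [rng.normal(size=n) for _ in range(n_series)]
            ref = [rng.normal(size=n) for _ in range(n_series)]
            brute = np.mean(
                [(m[i] - r[i]) ** 2 for m, r in zip(model, ref) for i in range(n)]
            )
            assert mse_traces(model, ref).mse == pytest.approx(brute)

    def test_per_group_table(self):
        rng = np.random.default_rng(7)
        model = [rng.normal(size=50) for _ in range(4)]
        ref = [rng.normal(size=50) for _ in range(4)]
        groups = [("R1", "alpha"), ("R1", "alpha"), ("L3", "beta"), ("L3", "beta")]
        rep = mse_traces(model, ref, groups)
        assert rep.per_group is not None
        assert set(rep.per_group["joint"]) == {"alpha", "beta"}
        assert rep.per_group["count"].sum() == 4


class TestLagShift:
    def test_identity_and_round_trip(self):
        t = np.arange(400.0)
        x = RateTrace(t, np.sin(t / 30.0))
        assert np.array_equal(lag_shift(x, 0.0).rate, x.rate)
        fwd = lag_shift(x, 0.01)
        back = lag_shift(fwd, -0.01)
        k = 10  # 0.01 s / 1 ms
        assert np.allclose(back.rate, x.rate[k:-k])

    def test_recovers_constructed_lag(self):
        """MSE between a trace and its k-sample delayed copy is minimised
        at a shift of exactly k samples."""
        rng = np.random.default_rng(8)
        x = np.convolve(rng.normal(size=3000), np.ones(50) / 50, mode="same")
        k = 40
        delayed = np.r_[np.zeros(k), x[:-k]]
        t = np.arange(x.size, dtype=float)
        errs = {}
        for shift in (20, 40, 60):
            sh = lag_shift(RateTrace(t, delayed), shift * 1e-3)
            errs[shift] = np.mean((sh.rate - x[: sh.rate.size]) ** 2)
        assert min(errs, key=errs.get) == k

    def test_overlong_shift_rejected(self):
        with pytest.raises(ValueError):
            lag_shift(RateTrace(np.arange(10.0), np.zeros(10)), 1.0)


class TestConfusion:
    def test_reported_count_arithmetic(self):
        """The published confusion counts reproduce TPR 0.913, TNR 0.916
        and ACC 0.914 to three decimals."""
        cc = ConfusionCounts(TP=1627811, FP=155707, FN=155167, TN=1689086)
        assert round(cc.TPR, 3) == 0.913
        assert round(cc.TNR, 3) == 0.916
        assert round(cc.ACC, 3) == 0.914

    def test_all_wrong_phase_zero_accuracy(self):
        t = np.arange(0, 2000.0, DT)
        theta = 90.0 + 50.0 * np.sin(2 * np.pi * t / 1000.0)
        trace = JointAngleTrace(t, theta)
        rising = [100.0, 200.0]  # velocity > 0 in the first quarter period
        falling = [400.0, 600.0]
        vp = SpikeTrain(falling, 2000.0)  # vel_plus firing only on falling
        vm = SpikeTrain(rising, 2000.0)
        cc = velocity_confusion(vp, vm, trace)
        assert cc.ACC == 0.0

    def test_no_spikes_undefined_not_zero(self):
        t = np.arange(0, 1000.0, DT)
        trace = JointAngleTrace(t, np.linspace(0, 90, t.size))
        cc = velocity_confusion(SpikeTrain([], 1000.0), SpikeTrain([], 1000.0), trace)
        assert np.isnan(cc.TPR) and np.isnan(cc.TNR) and np.isnan(cc.ACC)

    def test_stationary_samples_excluded(self):
        t = np.arange(0, 1000.0, DT)
        theta = np.full(t.size, 90.0)  # zero velocity everywhere
        trace = JointAngleTrace(t, theta)
        cc = velocity_confusion(
            SpikeTrain([500.0], 1000.0), SpikeTrain([], 1000.0), trace,
            lowpass_hz=None,
        )
        assert cc.TP == cc.FP == 0

    def test_oracle_equivalence_random(self):
        """Per-spike loop with explicit sign comparison."""
        rng = np.random.default_rng(9)
        t = np.arange(0, 3000.0, DT)
        theta = 90.0 + 40.0 * np.sin(2 * np.pi * t / 1500.0)
        trace = JointAngleTrace(t, theta)
        v = np.gradient(theta, DT)
        for _ in range(50):
            vp_times = np.sort(rng.uniform(10.0, 2990.0, 30))
            vm_times = np.sort(rng.uniform(10.0, 2990.0, 30))
            cc = velocity_confusion(
                SpikeTrain(vp_times, 3000.0),
                SpikeTrain(vm_times, 3000.0),
                trace,
                lowpass_hz=None,
            )
            def brute(times):
                pos = neg = 0
                for s in times:
                    vv = v[min(int(round(s / DT)) - 1, v.size - 1)]
                    if vv >= 1e-6:
                        pos += 1
                    elif vv <= -1e-6:
                        neg += 1
                return pos, neg
            tp, fp = brute(vp_times)
            fn, tn = brute(vm_times)
            assert (cc.TP, cc.FP, cc.FN, cc.TN) == (tp, fp, fn, tn)


class TestRateVelocityFit:
    def test_exact_line(self):
        slope, r2 = fit_rate_velocity([50, 100, 200], [100.0, 200.0, 400.0])
        assert slope == pytest.approx(2.0)
        assert r2 == pytest.approx(1.0)

    def test_flat_rates_zero_slope(self):
        slope, _ = fit_rate_velocity([50, 100, 200], [70.0, 70.0, 70.0])
        assert slope == 0.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_rate_velocity([50, 100], [1.0, 2.0])


class TestGridSearchAdEx:
    def test_self_consistency_argmin(self):
        """A reference generated by the model at a grid cell pins the MAE
        minimum (zero) uniquely to that cell, deterministically."""
        gains = np.linspace(10.0, 150.0, 8)
        bs = np.linspace(50.0, 350.0, 8)
        ref = ramp_response_rates(AdExParams(b=float(bs[5])), float(gains[2]), DT)
        surface, argmin, selected = grid_search_adex(
            ref, steps=8, adex=AdExParams(), dt=DT
        )
        assert selected == (pytest.approx(gains[2]), pytest.approx(bs[5]))
        assert len(argmin) == 1
        assert surface.loc[gains[2], bs[5]] == 0.0
        # deterministic rerun
        surface2, _, selected2 = grid_search_adex(
            ref, steps=8, adex=AdExParams(), dt=DT
        )
        assert selected2 == selected
        assert np.array_equal(surface.to_numpy(), surface2.to_numpy())

    def test_synthetic_reference_loads(self):
        ref = ReferenceRates.synthetic_reference()
        assert len(ref) == 10
        assert np.all(ref.x_max >= ref.x_ss)


class TestGridSearchPosition:
    @pytest.fixture(scope="class")
    def short_trace(self):
        from propriosnn.stimuli import SyntheticGaitParams, synthetic_gait

        return synthetic_gait(
            SyntheticGaitParams(duration=2000.0, dt=DT, seed=21,
                                working_range=(30.0, 150.0))
        )

    def test_single_cell_grid_trivial(self, short_trace):
        surface, best = grid_search_position([120.0], [1.0], [short_trace])
        assert best == (120.0, 1.0)
        assert surface.shape == (1, 1)

    def test_mse_improves_as_omega_decreases(self, short_trace):
        """Smaller synaptic weights reduce overshoot on smooth traces."""
        surface, best = grid_search_position([120.0], [1.0, 10.0], [short_trace])
        assert surface.loc[120.0, 1.0] < surface.loc[120.0, 10.0]
        assert best == (120.0, 1.0)
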