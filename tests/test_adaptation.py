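import math
from dataclasses import replace
from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lpadapt.adaptation import (
    AdaptConfig,
    AdaptState,
    evaluate_batch,
    instantaneous_volume,
    radius_factors,
    step,
    update_hitting_probability,
    update_mean,
    update_radius,
    update_transform,
)
from lpadapt.lpball import LpShape, ProposalState
from lpadapt.oracles import Oracle, folium_oracle, storn_region

from conftest import make_disk_oracle


def resolved(n=2, **kw):
    return AdaptConfig(**kw).resolve(n)


class TestRadiusControl:
    def test_expansion_factor_example(self):
        cfg = replace(resolved(), target_hitting_probability=0.35,
                      radius_expansion_beta=0.2)
        assert update_radius(1.0, True, cfg) == pytest.approx(1.13)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(p=st.floats(0.01, 0.99), beta=st.floats(1e-3, 1.0))
    def test_zero_log_drift_at_target(self, p, beta):
        f_e, f_c = radius_factors(p, beta)
        assert f_e > 1.0 and f_c < 1.0
        assert f_e**p * f_c ** (1.0 - p) == pytest.approx(1.0, abs=1e-12)

    def test_bernoulli_stream_has_zero_mean_log_step(self, rng):
        cfg = replace(resolved(), target_hitting_probability=0.35)
        hits = rng.random(10**4) < 0.35
        r = 1.0
        logs = []
        for h in hits:
            r_new = update_radius(r, bool(h), cfg)
            logs.append(math.log(r_new / r))
            r = r_new
        f_e, f_c = radius_factors(0.35, cfg.radius_expansion_beta)
        step_var = 0.35 * 0.65 * (math.log(f_e) - math.log(f_c)) ** 2
        se = math.sqrt(step_var / len(hits))
        assert abs(np.mean(logs)) < 3 * se

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            update_radius(0.0, True, resolved())


class TestMeanUpdate:
    def test_no_feasible_points_leaves_mean(self):
        mean = np.array([1.0, 2.0])
        out = update_mean(mean, np.empty((0, 2)), resolved())
        np.testing.assert_array_equal(out, mean)

    def test_full_rate_jumps_to_single_point(self):
        cfg = replace(resolved(), mean_learning_rate=1.0)
        out = update_mean(np.zeros(2), np.array([[3.0, -1.0]]), cfg)
        np.testing.assert_allclose(out, [3.0, -1.0])

    def test_half_rate_arithmetic(self):
        cfg = replace(resolved(), mean_learning_rate=0.5)
        out = update_mean(np.zeros(2), np.array([[2.0, 0.0]]), cfg)
        np.testing.assert_allclose(out, [1.0, 0.0])


class TestTransformUpdate:
    def test_zero_rate_is_identity_operation(self):
        cfg = SimpleNamespace(cov_learning_rate=0.0)
        t = np.array([[2.0, 0.0], [0.3, 0.5]])
        np.testing.assert_array_equal(update_transform(t, np.ones((3, 2)), cfg), t)

    def test_no_displacements_is_identity_operation(self):
        cfg = resolved()
        t = np.eye(2)
        np.testing.assert_array_equal(update_transform(t, np.empty((0, 2)), cfg), t)

    def test_rank_one_accumulation_grows_first_axis(self):
        cfg = SimpleNamespace(cov_learning_rate=0.2)
        t = np.eye(2)
        ratios = []
        for _ in range(20):
            t = update_transform(t, np.array([[1.5, 0.0]]), cfg)
            c = t @ t.T
            ratios.append(c[0, 0] / c[1, 1])
        assert np.all(np.diff(ratios) > 0)

    def test_determinant_one_after_update(self, rng):
        cfg = SimpleNamespace(cov_learning_rate=0.3)
        t = np.eye(3)
        for _ in range(50):
            t = update_transform(t, rng.normal(size=(4, 3)), cfg)
            assert abs(np.linalg.det(t) - 1.0) <= 1e-9

    def test_isotropic_input_pulls_toward_identity(self, rng):
        # feed displacements with isotropic unit covariance; the skewed
        # starting shape should relax toward the identity in expectation
        cfg = SimpleNamespace(cov_learning_rate=0.1)
        t = np.diag([4.0, 0.25]).astype(float)
        dist = [np.linalg.norm(t @ t.T - np.eye(2))]
        for _ in range(300):
            t = update_transform(t, rng.normal(size=(8, 2)), cfg)
            dist.append(np.linalg.norm(t @ t.T - np.eye(2)))
        assert dist[-1] < 0.2 * dist[0]

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            update_transform(np.eye(2), np.ones((2, 2)), resolved(),
                             weights=np.array([0.7, 0.7]))


class TestHittingProbability:
    def test_all_hit_stream_increases_to_one(self):
        cfg = replace(resolved(), hit_smoothing_memory=10.0)
        vals = [0.35]
        for _ in range(200):
            vals.append(update_hitting_probability(vals[-1], np.array([1.0]), cfg))
        assert np.all(np.diff(vals) > 0)
        assert vals[-1] > 0.99

    def test_all_miss_stream_decreases_to_zero(self):
        cfg = replace(resolved(), hit_smoothing_memory=10.0)
        vals = [0.35]
        for _ in range(200):
            vals.append(update_hitting_probability(vals[-1], np.array([0.0]), cfg))
        assert np.all(np.diff(vals) < 0)
        assert vals[-1] < 0.01

    def test_bernoulli_long_run_matches_rate(self, rng):
        cfg = replace(resolved(), hit_smoothing_memory=50.0)
        hits = (rng.random(10**4) < 0.35).astype(float)
        est = update_hitting_probability(0.35, hits, cfg)
        # EWMA variance: p(1-p) * alpha / (2 - alpha)
        alpha = 1.0 / 50.0
        se = math.sqrt(0.35 * 0.65 * alpha / (2.0 - alpha))
        assert abs(est - 0.35) < 3 * se


class TestInstantaneousVolume:
    def test_zero_probability_gives_zero(self):
        assert instantaneous_volume(ProposalState.isotropic(np.zeros(2)), 0.0) == 0.0

    def test_full_probability_gives_proposal_volume(self):
        prop = ProposalState.isotropic(np.zeros(2))
        assert instantaneous_volume(prop, 1.0) == pytest.approx(math.pi)

    def test_fixed_disk_over_folium_recovers_overlap(self, rng):
        # folium fits inside the unit disk, so overlap with a radius-3 disk
        # proposal is the folium area pi/2 exactly
        prop = ProposalState.isotropic(np.zeros(2), radius=3.0)
        oracle = folium_oracle()
        count = 10**5
        pts, flags = evaluate_batch(prop, oracle, count, rng)
        p_hat = flags.mean()
        est = instantaneous_volume(prop, p_hat)
        se = 9.0 * math.pi * math.sqrt(p_hat * (1 - p_hat) / count)
        assert abs(est - math.pi / 2.0) < 3 * se


class TestEvaluateBatch:
    def test_always_true_oracle_all_feasible(self, rng):
        oracle = Oracle(lambda x: True, n=2)
        prop = ProposalState.isotropic(np.zeros(2))
        _, flags = evaluate_batch(prop, oracle, 32, rng)
        assert flags.all()
        assert oracle.n_evals == 32

    def test_zero_batch_size_rejected(self, rng):
        with pytest.raises(ValueError):
            evaluate_batch(ProposalState.isotropic(np.zeros(2)),
                           Oracle(lambda x: True, n=2), 0, rng)

    def test_oracle_error_carries_offending_point(self, rng):
        def bad(x):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="oracle failed on point"):
            evaluate_batch(ProposalState.isotropic(np.zeros(2)),
                           Oracle(bad, n=2), 4, rng)

    def test_storn_hit_fraction_matches_overlap_integral(self, rng):
        # unit disk at the arm tip: overlap computed by fine-grid integration
        nx = 4001
        xs = np.linspace(-1, 1, nx)
        xx, yy = np.meshgrid(xs, xs, indexing="ij")
        in_disk = xx**2 + yy**2 <= 1.0
        in_region = ((xx >= 0) & (xx <= 5) & (np.abs(yy) <= 0.1))
        cell = (2.0 / (nx - 1)) ** 2
        overlap = float(np.sum(in_disk & in_region)) * cell
        expected = overlap / math.pi

        oracle = Oracle(storn_region, n=2)
        prop = ProposalState.isotropic(np.zeros(2))
        count = 40_000
        _, flags = evaluate_batch(prop, oracle, count, rng)
        se = math.sqrt(expected * (1 - expected) / count)
        assert abs(flags.mean() - expected) < 3 * se


class TestStep:
    def test_always_true_oracle_grows_radius_strictly(self, rng):
        oracle = Oracle(lambda x: True, n=2)
        cfg = resolved()
        state = AdaptState.initial(np.zeros(2), cfg)
        radii = [state.proposal.radius]
        for _ in range(20):
            state = step(state, oracle, cfg, rng)
            radii.append(state.proposal.radius)
        assert np.all(np.diff(radii) > 0)

    def test_mean_frozen_without_feasible_samples(self, rng):
        start = np.array([100.0, 100.0])
        oracle = Oracle(lambda x: bool(np.array_equal(x, start)), n=2)
        cfg = resolved()
        state = AdaptState.initial(start, cfg)
        for _ in range(10):
            state = step(state, oracle, cfg, rng)
        np.testing.assert_array_equal(state.proposal.mean, start)

    def test_equal_seeds_give_bitwise_identical_traces(self):
        def run():
            oracle = make_disk_oracle()
            cfg = resolved()
            state = AdaptState.initial(np.zeros(2), cfg)
            rng = np.random.default_rng(99)
            for _ in range(50):
                state = step(state, oracle, cfg, rng)
            return state.trace

        a, b = run(), run()
        assert a.eval_index == b.eval_index
        assert a.feasible == b.feasible
        assert a.radius == b.radius
        assert a.volume_estimate == b.volume_estimate
        np.testing.assert_array_equal(np.asarray(a.points), np.asarray(b.points))

    def test_determinant_invariant_along_run(self, rng):
        oracle = make_disk_oracle()
        cfg = resolved()
        state = AdaptState.initial(np.zeros(2), cfg)
        for _ in range(100):
            state = step(state, oracle, cfg, rng)
            assert abs(np.linalg.det(state.proposal.transform) - 1.0) <= 1e-9

    def test_trace_length_equals_oracle_counter(self, rng):
        oracle = make_disk_oracle()
        cfg = resolved()
        state = AdaptState.initial(np.zeros(2), cfg)
        for _ in range(37):
            state = step(state, oracle, cfg, rng)
        assert len(state.trace) == oracle.n_evals

    def test_stationarity_on_unit_disk(self):
        # long-run empirical P near the 0.35 target and volume near pi
        ratios = []
        for seed in range(10):
            oracle = make_disk_oracle()
            cfg = resolved()
            state = AdaptState.initial(np.zeros(2), cfg)
            rng = np.random.default_rng(seed)
            while state.n_evals < 5000:
                state = step(state, oracle, cfg, rng)
            tail = slice(len(state.trace) // 2, None)
            p_tail = float(np.mean(state.trace.empirical_p[tail]))
            assert abs(p_tail - 0.35) < 0.05
            ratios.append(np.mean(state.trace.volume_estimate[tail]) / math.pi)
        assert abs(float(np.mean(ratios)) - 1.0) < 0.10
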