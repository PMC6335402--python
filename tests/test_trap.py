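"""Escape-attempt parsing and adaptation profiles."""

import math
from collections import defaultdict

import numpy as np
import pytest

import cargoquant as cq
from cargoquant.errors import InputError, UndefinedValueError

from conftest import make_piecewise_trace, parse_cohort


class TestDetectAttempts:
    def test_single_failed_attempt_hand_computed(self):
        # ramp 0 -> 150 nm over 1 s, hold 0.8 s, snap to 0 in 10 ms, k = 0.04:
        # peak force 6.0 pN; force >= 3 pN (half max) from t = 0.5 s on the
        # ramp until ~10 ms into the snapback => persistence ~ 1.31 s
        trace = make_piecewise_trace(
            [0.0, 0.2, 1.2, 2.0, 2.01, 2.31],
            [0.0, 0.0, 150.0, 150.0, 0.0, 0.0],
            k=0.04,
        )
        attempts = cq.detect_attempts(trace)
        assert len(attempts) == 1
        a = attempts[0]
        assert a.outcome == "failed"
        assert a.attempt_index == 1
        assert a.peak_force == pytest.approx(6.0, abs=0.01)
        assert a.persistence_time == pytest.approx(1.31, abs=0.02)

    def test_all_zero_trace_yields_no_attempts(self):
        time = np.arange(0, 1, 5e-4)
        trace = cq.ForceTrace(time, np.zeros_like(time), 0.04, 2000.0)
        assert cq.detect_attempts(trace) == []

    def test_crossing_escape_radius_without_return_is_escape(self):
        trace = make_piecewise_trace(
            [0.0, 0.2, 1.2, 1.25], [0.0, 0.0, 210.0, 212.0], k=0.04
        )
        attempts = cq.detect_attempts(trace)
        assert len(attempts) == 1
        assert attempts[0].outcome == "escaped"

    def test_attempts_disjoint_ordered_indexed(self):
        cfg = cq.TrapSimConfig(seed=5, n_experiments=1, n_cargos_per_experiment=4)
        traces, _ = cq.gen_trap_traces(cfg, cq.default_conditions()["WT"])
        for trace in traces:
            attempts = cq.detect_attempts(trace)
            assert [a.attempt_index for a in attempts] == list(range(1, len(attempts) + 1))
            for prev, cur in zip(attempts, attempts[1:]):
                assert cur.start_time >= prev.end_time
            assert all(a.persistence_time > 0 for a in attempts)

    def test_scaling_positions_scales_forces_not_persistence_down(self):
        # doubling all positions doubles every peak force and cannot shorten
        # persistence measured at a fixed fraction of the peak
        trace = make_piecewise_trace(
            [0.0, 0.2, 0.8, 1.6, 1.61, 1.9], [0.0, 0.0, 90.0, 90.0, 0.0, 0.0], k=0.05
        )
        scaled = cq.ForceTrace(
            trace.time, trace.position * 2.0, trace.trap_stiffness, trace.sampling_rate
        )
        base = cq.detect_attempts(trace)
        big = cq.detect_attempts(scaled)
        assert len(base) == len(big)
        for a, b in zip(base, big):
            assert b.peak_force == pytest.approx(2.0 * a.peak_force, rel=1e-6)
            assert b.persistence_time >= a.persistence_time - 1e-9

    def test_non_uniform_sampling_rejected(self):
        time = np.array([0.0, 1e-3, 3e-3, 4e-3, 5e-3])
        with pytest.raises(InputError, match="non-uniform"):
            cq.detect_attempts(cq.ForceTrace(time, np.zeros(5), 0.05, 1000.0))


class TestEscapedFraction:
    @pytest.mark.parametrize(
        "escaped,n,f,se",
        [
            (0, 10, 0.0, 0.0),
            (5, 20, 0.25, math.sqrt(0.25 * 0.75 / 20)),
            (10, 10, 1.0, 0.0),
        ],
    )
    def test_closed_form(self, escaped, n, f, se):
        records = [
            cq.AttemptRecord(f"c{i}", 1, 1.0, 1.0, "escaped" if i < escaped else "failed", 0, 1)
            for i in range(n)
        ]
        got_f, got_se = cq.escaped_fraction(records, 1)
        assert got_f == pytest.approx(f)
        assert got_se == pytest.approx(se)

    def test_no_attempts_at_index_is_undefined(self):
        with pytest.raises(UndefinedValueError):
            cq.escaped_fraction([], 1)

    def test_matches_enumeration_oracle_small_n(self):
        # oracle: SD of the plug-in proportion enumerated over the binomial
        # pmf at p = e/n equals sqrt(f(1-f)/n)
        from scipy.stats import binom

        for n in range(1, 61):
            for e in range(n + 1):
                f, se = cq.escaped_fraction_counts(e, n)
                if e in (0, n):
                    oracle = 0.0
                else:
                    k = np.arange(n + 1)
                    pmf = binom.pmf(k, n, f)
                    oracle = math.sqrt(float((pmf * (k / n - f) ** 2).sum()))
                assert se == pytest.approx(oracle, abs=1e-13)


class TestAdaptationProfile:
    def _records(self, per_experiment):
        out = {}
        for exp, values in per_experiment.items():
            out[exp] = [
                cq.AttemptRecord(f"{exp}_c{i}", idx, v, v, "failed", 0, 1, experiment_id=exp)
                for i, (idx, v) in enumerate(values)
            ]
        return out

    def test_two_experiment_sem(self):
        profile = cq.adaptation_profile(
            self._records({"e1": [(3, 1.0)], "e2": [(3, 2.0)]})
        )
        row = profile.table.loc[3]
        assert row["mean_persistence"] == pytest.approx(1.5)
        assert row["sem_persistence"] == pytest.approx(0.5)

    def test_identical_experiments_have_zero_sem(self):
        profile = cq.adaptation_profile(
            self._records({"e1": [(1, 2.0)], "e2": [(1, 2.0)], "e3": [(1, 2.0)]})
        )
        assert profile.table.loc[1, "sem_persistence"] == 0.0

    def test_single_experiment_flags_sem_unavailable(self):
        profile = cq.adaptation_profile(self._records({"e1": [(1, 2.0), (2, 3.0)]}))
        assert not profile.sem_available
        assert np.isnan(profile.table.loc[1, "sem_persistence"])

    def test_order_invariance(self, conditions):
        cfg = cq.TrapSimConfig(seed=3, n_experiments=2, n_cargos_per_experiment=6)
        traces, _ = cq.gen_trap_traces(cfg, conditions["WT"])
        _, by_exp = parse_cohort(traces)
        shuffled = {
            exp: list(reversed(attempts)) for exp, attempts in reversed(by_exp.items())
        }
        a = cq.adaptation_profile(by_exp, "WT").table
        b = cq.adaptation_profile(shuffled, "WT").table
        assert np.allclose(a.to_numpy(dtype=float), b.to_numpy(dtype=float), equal_nan=True)

    def test_simulated_wt_persistence_rises_significantly(self, conditions):
        cfg = cq.TrapSimConfig(seed=21, n_experiments=5, n_cargos_per_experiment=30)
        traces, _ = cq.gen_trap_traces(cfg, conditions["WT"])
        _, by_exp = parse_cohort(traces)
        profile = cq.adaptation_profile(by_exp, "WT")
        t5, t1 = profile.table.loc[5], profile.table.loc[1]
        assert t5["mean_persistence"] > t1["mean_persistence"]
        assert t5["p_persistence_vs_first"] < 0.05


class TestTrendFit:
    def _profile_from_means(self, means):
        records = {
            exp: [
                cq.AttemptRecord(f"{exp}_c", idx, m, m, "failed", 0, 1, experiment_id=exp)
                for idx, m in enumerate(means, start=1)
            ]
            for exp in ("e1", "e2")
        }
        return cq.adaptation_profile(records)

    def test_unit_slope(self):
        trend = cq.fit_adaptation_trend(self._profile_from_means([5.0, 6.0, 7.0]))
        assert trend.force_slope == pytest.approx(1.0)

    def test_flat_means_zero_slope(self):
        trend = cq.fit_adaptation_trend(self._profile_from_means([4.0, 4.0, 4.0]))
        assert trend.persistence_slope == pytest.approx(0.0)

    def test_single_index_is_undefined(self):
        with pytest.raises(UndefinedValueError):
            cq.fit_adaptation_trend(self._profile_from_means([4.0]))

    def test_noiseless_decreasing_persistence_slope_recovered(self):
        # a noiseless cohort built with a -0.2 s/attempt persistence
        # decrement must return that slope through the full parse+aggregate
        # path (constant loading-rate offsets cancel in the slope)
        cond = cq.SimCondition(
            "custom",
            base_peak_force=3.0,
            force_increment=0.0,
            base_persistence=1.2,
            persistence_increment=-0.2,
            force_noise_sd=0.0,
            persistence_noise_sd=0.0,
            escape_midpoint=float("inf"),
        )
        cfg = cq.TrapSimConfig(
            seed=0, n_experiments=2, n_cargos_per_experiment=3, position_noise_sd=0.0
        )
        traces, _ = cq.gen_trap_traces(cfg, cond)
        _, by_exp = parse_cohort(traces)
        trend = cq.fit_adaptation_trend(cq.adaptation_profile(by_exp))
        assert trend.persistence_slope == pytest.approx(-0.2, abs=0.02)


class TestParameterRecovery:
    def test_counts_and_values_recovered_on_small_cohort(self, conditions):
        cfg = cq.TrapSimConfig(seed=17, n_experiments=2, n_cargos_per_experiment=10)
        traces, truth = cq.gen_trap_traces(cfg, conditions["WT"])
        gt = {(a.cargo_id, a.attempt_index): a for a in truth.attempts}
        gt_counts = defaultdict(int)
        for a in truth.attempts:
            gt_counts[a.cargo_id] += 1
        errs_f, errs_p = [], []
        for trace in traces:
            attempts = cq.detect_attempts(trace)
            assert len(attempts) == gt_counts[trace.cargo_id]
            for a in attempts:
                g = gt[(a.cargo_id, a.attempt_index)]
                assert a.outcome == g.outcome
                errs_f.append(a.peak_force - g.peak_force)
                errs_p.append(a.persistence_time - g.persistence_time)
        assert math.sqrt(np.mean(np.square(errs_f))) <= 0.5
        assert math.sqrt(np.mean(np.square(errs_p))) <= 0.1
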