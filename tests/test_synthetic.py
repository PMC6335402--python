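"""Synthetic generators: determinism, noiseless limits, ground-truth consistency."""

import math

import numpy as np
import pytest

import cargoquant as cq
from cargoquant.errors import ConfigurationError


class TestDeterminism:
    def test_trap_traces_bit_identical(self, conditions):
        cfg = cq.TrapSimConfig(seed=9, n_experiments=1, n_cargos_per_experiment=3)
        t1, g1 = cq.gen_trap_traces(cfg, conditions["WT"])
        t2, g2 = cq.gen_trap_traces(cfg, conditions["WT"])
        for a, b in zip(t1, t2):
            assert np.array_equal(a.position, b.position)
            assert np.array_equal(a.time, b.time)
        assert [(x.cargo_id, x.attempt_index, x.peak_force) for x in g1.attempts] == [
            (x.cargo_id, x.attempt_index, x.peak_force) for x in g2.attempts
        ]

    def test_organelle_stack_bit_identical(self):
        mix = cq.EccentricityMixture(tail_weight=0.1)
        s1, _ = cq.gen_organelle_stack(3, 4, mix, seed=9)
        s2, _ = cq.gen_organelle_stack(3, 4, mix, seed=9)
        assert np.array_equal(s1, s2)

    def test_tracks_bit_identical(self):
        t1, _ = cq.gen_tracks(3, 20.0, seed=9)
        t2, _ = cq.gen_tracks(3, 20.0, seed=9)
        for a, b in zip(t1, t2):
            assert np.array_equal(a.xy, b.xy)

    def test_cell_image_bit_identical(self):
        i1, c1, n1, _ = cq.gen_cell_image(20000, 5000, 0.7, seed=9)
        i2, c2, n2, _ = cq.gen_cell_image(20000, 5000, 0.7, seed=9)
        assert np.array_equal(i1, i2)
        assert np.array_equal(c1, c2)

    def test_different_seeds_differ(self, conditions):
        cfg1 = cq.TrapSimConfig(seed=1, n_experiments=1, n_cargos_per_experiment=1)
        cfg2 = cq.TrapSimConfig(seed=2, n_experiments=1, n_cargos_per_experiment=1)
        t1, _ = cq.gen_trap_traces(cfg1, conditions["WT"])
        t2, _ = cq.gen_trap_traces(cfg2, conditions["WT"])
        assert not np.array_equal(t1[0].position[: min(t1[0].position.size, t2[0].position.size)],
                                  t2[0].position[: min(t1[0].position.size, t2[0].position.size)])


class TestTrapGenerator:
    def test_noiseless_limit_exact_forces_and_counts(self):
        # no noise and an unreachable escape midpoint: every cargo makes
        # exactly max_attempts failed attempts at F_i = F1 + beta_F (i-1)
        cond = cq.SimCondition(
            "noiseless",
            base_peak_force=2.0,
            force_increment=0.5,
            base_persistence=1.0,
            persistence_increment=0.2,
            force_noise_sd=0.0,
            persistence_noise_sd=0.0,
            escape_midpoint=float("inf"),
        )
        cfg = cq.TrapSimConfig(
            seed=0, n_experiments=1, n_cargos_per_experiment=2, position_noise_sd=0.0
        )
        traces, truth = cq.gen_trap_traces(cfg, cond)
        per_cargo = {}
        for a in truth.attempts:
            per_cargo.setdefault(a.cargo_id, []).append(a)
        for attempts in per_cargo.values():
            assert len(attempts) == cfg.max_attempts
            assert all(a.outcome == "failed" for a in attempts)
            for a in attempts:
                assert a.peak_force == pytest.approx(2.0 + 0.5 * (a.attempt_index - 1), abs=1e-9)
        # noiseless position equals F/k on the stall plateau
        k = cfg.trap_stiffness
        for trace in traces:
            assert trace.position.max() == pytest.approx(
                (2.0 + 0.5 * (cfg.max_attempts - 1)) / k, abs=1e-6
            )

    def test_wt_ground_truth_persistence_increases(self, conditions):
        cfg = cq.TrapSimConfig(seed=2, n_experiments=4, n_cargos_per_experiment=30)
        _, truth = cq.gen_trap_traces(cfg, conditions["WT"])
        means = {}
        for a in truth.attempts:
            if a.outcome == "failed":
                means.setdefault(a.attempt_index, []).append(a.persistence_time)
        sequence = [np.mean(means[i]) for i in sorted(means)]
        assert all(b > a for a, b in zip(sequence, sequence[1:]))

    def test_escape_labels_consistent_with_radius(self, conditions):
        cfg = cq.TrapSimConfig(seed=4, n_experiments=2, n_cargos_per_experiment=20)
        _, truth = cq.gen_trap_traces(cfg, conditions["WT"])
        k, radius = cfg.trap_stiffness, cfg.escape_radius
        outcomes = {a.outcome for a in truth.attempts}
        assert outcomes == {"escaped", "failed"}
        for a in truth.attempts:
            if a.outcome == "escaped":
                assert a.peak_force >= k * radius
            else:
                assert a.peak_force < k * radius

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            cq.TrapSimConfig(trap_stiffness=0.0)
        with pytest.raises(ConfigurationError):
            cq.TrapSimConfig(sampling_rate=-1.0)
        with pytest.raises(ConfigurationError):
            cq.SimCondition("bad", base_peak_force=-1.0)


class TestOrganelleGenerator:
    def test_point_mass_at_zero_renders_disks(self):
        mix = cq.EccentricityMixture(base_range=(0.0, 0.0))
        area = math.pi * 20.0**2
        _, truth = cq.gen_organelle_stack(
            2, 3, mix, seed=1, noise=False, blur_sigma=0.0, area_range=(area, area)
        )
        for e in truth.ellipses:
            assert e.semi_major == pytest.approx(e.semi_minor)
            assert e.eccentricity == 0.0

    def test_ground_truth_eccentricity_formula(self):
        mix = cq.EccentricityMixture(base_range=(0.2, 0.9))
        _, truth = cq.gen_organelle_stack(2, 5, mix, seed=2)
        for e in truth.ellipses:
            analytic = math.sqrt(1.0 - (e.semi_minor / e.semi_major) ** 2)
            assert abs(e.eccentricity - analytic) < 1e-12
            assert e.semi_major >= e.semi_minor > 0

    def test_tail_weight_controls_mass_above_09(self):
        heavy = cq.sample_eccentricities(cq.EccentricityMixture(tail_weight=0.3), 2000, 1)
        none = cq.sample_eccentricities(cq.EccentricityMixture(tail_weight=0.0), 2000, 2)
        diff = (heavy > 0.9).mean() - (none > 0.9).mean()
        assert diff == pytest.approx(0.3, abs=0.04)

    def test_oversized_objects_rejected(self):
        mix = cq.EccentricityMixture()
        with pytest.raises(ConfigurationError, match="fit"):
            cq.gen_organelle_stack(
                1, 1, mix, seed=0, frame_shape=(32, 32), area_range=(3000.0, 3000.0)
            )

    def test_bad_mixture_rejected(self):
        with pytest.raises(ConfigurationError):
            cq.EccentricityMixture(base_range=(0.0, 1.0))
        with pytest.raises(ConfigurationError):
            cq.EccentricityMixture(tail_weight=1.5)


class TestTrackGenerator:
    def test_switch_prob_zero_keeps_one_direction(self):
        _, truth = cq.gen_tracks(5, 60.0, switch_prob=0.0, seed=3)
        for segments in truth.segments:
            directions = {s.direction for s in segments if s.kind == "run"}
            assert len(directions) == 1

    def test_mean_run_length_matches_exponential(self):
        # ground-truth sample mean of Exp(500 nm) runs over a 90-track,
        # 100 s cohort stays within 3 SEM of the configured mean
        _, truth = cq.gen_tracks(90, 100.0, mean_run=500.0, seed=4)
        runs = np.array(
            [s.distance for segs in truth.segments for s in segs if s.kind == "run"]
        )
        sem = runs.std(ddof=1) / math.sqrt(runs.size)
        assert abs(runs.mean() - 500.0) < 3 * sem + 10.0  # +10 nm truncation allowance

    def test_segments_alternate_and_tile(self):
        _, truth = cq.gen_tracks(3, 50.0, seed=5)
        for segments in truth.segments:
            for prev, cur in zip(segments, segments[1:]):
                assert prev.kind != cur.kind
                assert cur.start_time == pytest.approx(prev.start_time + prev.duration)

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigurationError):
            cq.gen_tracks(0, 10.0)
        with pytest.raises(ConfigurationError):
            cq.gen_tracks(1, 10.0, switch_prob=2.0)


class TestCellImageGenerator:
    def test_uniform_cytoplasm_gives_80_percent(self):
        _, _, _, truth = cq.gen_cell_image(20000, 5000, mode="uniform", seed=0)
        assert truth.peripheral_fraction == pytest.approx(80.0, abs=0.1)

    def test_all_intensity_in_band_gives_zero(self):
        image, cell, nucleus, truth = cq.gen_cell_image(
            20000, 5000, peripheral_bias=0.0, seed=1
        )
        assert truth.peripheral_fraction == 0.0
        masks = cq.perinuclear_mask(cell, nucleus)
        assert cq.peripheral_fraction(image, masks) == 0.0

    def test_measured_fraction_matches_placed_truth(self):
        image, cell, nucleus, truth = cq.gen_cell_image(
            20000, 5000, peripheral_bias=0.65, seed=2
        )
        masks = cq.perinuclear_mask(cell, nucleus)
        assert cq.peripheral_fraction(image, masks) == pytest.approx(
            truth.peripheral_fraction, abs=1e-9
        )
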