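"""Generator behaviour: determinism, population statistics, event mechanics."""

import numpy as np
import pandas as pd
import pytest

from pyloric import synth


def _pop(n=30, seed=3, condition="decentralized"):
    return synth.PopulationConfig(n_preparations=n, condition=condition, seed=seed)


class TestSamplePopulation:
    def test_sample_mean_tracks_configured_intact_mean(self):
        preps = synth.sample_population(_pop(n=30, seed=11))
        base = np.array([p.baseline_freq for p in preps])
        se = 0.29 / np.sqrt(30)
        assert abs(base.mean() - 1.2) < 3 * se

    def test_zero_sd_gives_degenerate_distribution(self):
        cfg = synth.PopulationConfig(
            n_preparations=5,
            condition="intact",
            intact_freq_sd_across=0.0,
            seed=0,
        )
        preps = synth.sample_population(cfg)
        assert all(p.baseline_freq == 1.2 for p in preps)

    def test_same_seed_reproduces_parameter_lists(self):
        a = synth.sample_population(_pop(seed=7))
        b = synth.sample_population(_pop(seed=7))
        assert a == b

    def test_truncation_keeps_frequencies_positive(self):
        cfg = synth.PopulationConfig(
            n_preparations=200,
            condition="decentralized",
            decentralized_freq_mean=0.1,
            decentralized_freq_sd_across=0.5,
            seed=1,
        )
        preps = synth.sample_population(cfg)
        assert min(p.post_dec_freq for p in preps) > 0.05

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            synth.PopulationConfig(n_preparations=0).validate()
        with pytest.raises(ValueError):
            synth.PopulationConfig(n_preparations=1, intact_freq_mean=-1.0).validate()


class TestGenerateCycleSeries:
    def test_noiseless_limit_exact_periods(self, noiseless_truth):
        c = noiseless_truth.cycles
        assert len(c) == 100
        assert np.allclose(c["period"], 1.0, atol=0, rtol=0)
        assert np.allclose(np.diff(c["pd_start"]), 1.0)

    def test_determinism_bit_identical(self):
        p = synth.PreparationParams(prep_id="d", baseline_freq=0.8, drift_sd=0.05)
        a = synth.generate_cycle_series(p, 500.0, rng_seed=9)
        b = synth.generate_cycle_series(p, 500.0, rng_seed=9)
        pd.testing.assert_frame_equal(a.cycles, b.cycles)

    def test_decentralization_step_lowers_hourly_mean(self):
        for seed in range(5):
            p = synth.PreparationParams(
                prep_id="s",
                baseline_freq=1.0,
                decentralization_time=3600.0,
                post_dec_freq=0.5,
                cycle_jitter_cv=0.03,
            )
            truth = synth.generate_cycle_series(p, 7200.0, rng_seed=seed)
            c = truth.cycles
            before = c[c.pd_start < 3600.0]["period"]
            after = c[c.pd_start >= 3600.0]["period"]
            assert (1 / after).mean() < (1 / before).mean()

    def test_cycle_starts_strictly_increasing_and_none_in_silence(self):
        p = synth.PreparationParams(
            prep_id="sil",
            baseline_freq=1.0,
            silence_episodes=((100.0, 120.0),),
        )
        truth = synth.generate_cycle_series(p, 400.0, rng_seed=2)
        t = truth.cycles["pd_start"].to_numpy()
        assert np.all(np.diff(t) > 0)
        assert not np.any((t >= 100.0) & (t < 220.0))

    def test_conservation_cycle_count_times_period(self, jittered_truth):
        c = jittered_truth.cycles
        active = c["pd_start"].iloc[-1] + c["period"].iloc[-1]
        assert abs(len(c) * c["period"].mean() - active) < 2 * c["period"].std() * np.sqrt(len(c))

    def test_bout_overlapping_silence_raises(self):
        p = synth.PreparationParams(
            prep_id="conflict",
            baseline_freq=1.0,
            cycle_jitter_cv=0.0,
            bout_schedule=((95, 10, 1.5),),
            silence_episodes=((100.0, 60.0),),
        )
        with pytest.raises(synth.GenerationError, match="overlaps silence"):
            synth.generate_cycle_series(p, 300.0, rng_seed=0)

    def test_bad_phase_targets_rejected(self):
        with pytest.raises(ValueError, match="phase targets"):
            synth.PreparationParams(
                prep_id="bad", baseline_freq=1.0, phase_targets=(0.5, 0.4, 0.8)
            ).validate()


class TestRenderSpikeTimes:
    def test_uniform_placement_endpoints_exact(self):
        p = synth.PreparationParams(
            prep_id="u", baseline_freq=1.0, cycle_jitter_cv=0.0, phase_targets=(0.3, 0.45, 0.75)
        )
        truth = synth.generate_cycle_series(p, 2.0, rng_seed=0)
        pd_tr, _ = synth.render_spike_times(truth, spikes_per_burst=4)
        # first burst spans [0, 0.3]
        assert np.allclose(pd_tr.times[:4], [0.0, 0.1, 0.2, 0.3])

    def test_round_trip_recovers_burst_boundaries(self, jittered_truth):
        from pyloric import bursts

        pd_tr, lp_tr = synth.render_spike_times(jittered_truth, spikes_per_burst=5)
        seg = bursts.segment_bursts_adaptive(pd_tr.times)
        c = jittered_truth.cycles
        assert len(seg) == len(c)
        assert np.allclose(seg["start"], c["pd_start"], atol=1e-9)
        assert np.allclose(seg["end"], c["pd_end"], atol=1e-9)

    def test_empty_truth_gives_empty_trains(self):
        p = synth.PreparationParams(prep_id="e", baseline_freq=1.0)
        truth = synth.generate_cycle_series(p, 0.5, rng_seed=0)
        truth.cycles = truth.cycles.iloc[0:0]
        pd_tr, lp_tr = synth.render_spike_times(truth)
        assert pd_tr.times.size == 0 and lp_tr.times.size == 0

    def test_too_few_spikes_rejected(self, noiseless_truth):
        with pytest.raises(ValueError):
            synth.render_spike_times(noiseless_truth, spikes_per_burst=1)


class TestRenderTrace:
    def test_single_spike_peak_equals_template_peak(self):
        tr = synth.SpikeTrain("p", "LP", np.array([0.05]))
        t, x = synth.render_trace(
            (tr, synth.SpikeTrain("p", "PD", np.empty(0))),
            sampling_rate=10_000.0,
            noise_sd=0.0,
            duration=0.1,
        )
        assert x.max() == pytest.approx(1.0)
        assert abs(t[np.argmax(x)] - 0.05) < 1e-9

    def test_noise_only_trace_sd(self):
        empty = synth.SpikeTrain("p", "PD", np.empty(0))
        _, x = synth.render_trace(
            (empty, synth.SpikeTrain("p", "LP", np.empty(0))),
            sampling_rate=5000.0,
            noise_sd=0.2,
            rng_seed=4,
            duration=10.0,
        )
        assert abs(x.std() - 0.2) / 0.2 < 0.05

    def test_solvable_regime_spike_recovery(self):
        """detect_spikes + assign_units recover >= 99% of spikes with labels."""
        from pyloric import bursts

        p = synth.PreparationParams(prep_id="t", baseline_freq=1.0, cycle_jitter_cv=0.03)
        truth = synth.generate_cycle_series(p, 600.0, rng_seed=5)
        pd_tr, lp_tr = synth.render_spike_times(truth, spikes_per_burst=4)
        t, x = synth.render_trace(
            (pd_tr, lp_tr),
            sampling_rate=10_000.0,
            unit_amplitudes={"PD": 0.4, "LP": 1.0},
            noise_sd=0.03,
            rng_seed=6,
        )
        times, amps = bursts.detect_spikes(x, 10_000.0, threshold=0.2, refractory=0.002)
        labeled, discarded = bursts.assign_units(
            times, amps, {"PD": (0.25, 0.62), "LP": (0.75, 1.4)}
        )
        for tr_true, unit in ((pd_tr, "PD"), (lp_tr, "LP")):
            got = labeled[unit].times
            matched = 0
            for ts in tr_true.times:
                k = np.searchsorted(got, ts)
                near = [got[j] for j in (k - 1, k) if 0 <= j < got.size]
                if near and min(abs(np.array(near) - ts)) < 1.5e-3:
                    matched += 1
            assert matched / tr_true.times.size >= 0.99, unit
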