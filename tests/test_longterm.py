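"""Binned summaries, box statistics, windows, CV measures, saline contrasts."""

import numpy as np
import pandas as pd
import pytest

from pyloric import longterm, stats, synth
from pyloric.longterm import PreparationTimeline
from pyloric.pipeline import analyze_preparation
from oracles import fastest_window_bruteforce


def _cycle_table(times, freqs, lp_silent=False):
    n = len(times)
    return pd.DataFrame(
        {
            "index": np.arange(n),
            "pd_start": np.asarray(times, dtype=float),
            "pd_end": np.asarray(times, dtype=float) + 0.1,
            "lp_start": np.nan,
            "lp_end": np.nan,
            "period": 1.0 / np.asarray(freqs, dtype=float),
            "frequency": np.asarray(freqs, dtype=float),
            "pd_off_phase": 0.3,
            "lp_on_phase": 0.45,
            "lp_off_phase": 0.75,
            "valid": True,
            "lp_silent": lp_silent,
            "extra_lp": 0,
            "invalid_reason": "",
        }
    )


class TestBinSeries:
    def test_constant_hour_ten_bins(self):
        t = np.arange(0, 3600.0, 1.0)
        b = longterm.bin_series(_cycle_table(t, np.ones(t.size)), 0.1, "median")
        assert len(b) == 10
        assert np.allclose(b.values, 1.0)

    def test_median_robust_to_outlier(self):
        tab = _cycle_table([1.0, 2.0, 3.0], [0.4, 0.6, 5.0])
        b = longterm.bin_series(tab, 0.1, "median")
        assert b.values[0] == pytest.approx(0.6)

    def test_empty_bins_absent_not_zero(self):
        tab = _cycle_table([10.0, 3600.0 + 10.0], [1.0, 1.0])
        b = longterm.bin_series(tab, 0.1, "median")
        assert np.isnan(b.values[1:10]).all()

    def test_against_independent_groupby(self, rng):
        t = np.sort(rng.uniform(0, 7200, 500))
        f = rng.uniform(0.2, 2.0, 500)
        b = longterm.bin_series(_cycle_table(t, f), 0.25, "mean")
        # independent re-binning with a dict accumulator
        acc: dict[int, list] = {}
        for ti, fi in zip(t, f):
            acc.setdefault(int(ti / 900.0), []).append(fi)
        for k, vals in acc.items():
            assert b.values[k] == pytest.approx(sum(vals) / len(vals))


class TestBoxStats:
    def test_five_point_hand_computation(self):
        b = longterm.boxstats([1, 2, 3, 4, 5])
        assert (b.median, b.q1, b.q3) == (3.0, 2.0, 4.0)
        assert b.outliers == ()
        assert (b.whisker_low, b.whisker_high) == (1.0, 5.0)

    def test_all_equal_zero_width(self):
        b = longterm.boxstats([2.0, 2.0, 2.0])
        assert b.q1 == b.median == b.q3 == 2.0
        assert b.outliers == ()

    def test_outlier_flagged_by_iqr_rule(self):
        # q1 = 1, q3 = 1, iqr = 0: the 10 sits outside the fences
        b = longterm.boxstats([1, 1, 1, 1, 10])
        assert b.outliers == (10.0,)
        assert b.whisker_high == 1.0

    def test_hourly_layout(self):
        hours = {"a": np.array([1.0, np.nan]), "b": np.array([2.0, 3.0])}
        out = longterm.hourly_boxstats(hours)
        assert out[0].median == pytest.approx(1.5)
        assert out[1].median == pytest.approx(3.0)


class TestDailyAndSnapshots:
    def test_two_constant_days(self):
        t = np.arange(0.0, 2 * 86400.0, 2.0)
        tl = PreparationTimeline(prep_id="p", decentralization_time=0.0)
        dm = longterm.daily_mean(_cycle_table(t, np.full(t.size, 0.5)), tl)
        assert list(dm.day) == [1, 2]
        assert np.allclose(dm.frequency, 0.5)

    def test_step_recovery_simulation(self):
        p = synth.PreparationParams(
            prep_id="step",
            baseline_freq=1.2,
            decentralization_time=1800.0,
            post_dec_freq=0.5,
            cycle_jitter_cv=0.03,
        )
        truth = synth.generate_cycle_series(p, 1800.0 + 2 * 86400.0, rng_seed=8)
        pd_tr, lp_tr = synth.render_spike_times(truth)
        tab = analyze_preparation(pd_tr, lp_tr)
        tl = PreparationTimeline(prep_id="step", decentralization_time=1800.0)
        dm = longterm.daily_mean(tab, tl, n_days=2)
        se = 0.5 * 0.03 / np.sqrt(86400 * 0.5)
        assert np.all(np.abs(dm.frequency - 0.5) < max(3 * se, 0.01))

    def test_missing_day_absent(self):
        t = np.arange(0.0, 86400.0, 2.0)  # day 1 only
        tl = PreparationTimeline(prep_id="p", decentralization_time=0.0)
        dm = longterm.daily_mean(_cycle_table(t, np.ones(t.size)), tl, n_days=3)
        assert list(dm.day) == [1]

    def test_snapshot_constant_and_empty(self, caplog):
        tab = _cycle_table(np.arange(0, 600.0, 1.0), np.full(600, 0.7))
        assert longterm.snapshot_mean(tab, 300.0, 60.0) == pytest.approx(0.7)
        with caplog.at_level("INFO"):
            assert longterm.snapshot_mean(tab, 5000.0, 60.0) is None
        assert "no valid cycles" in caplog.text

    def test_snapshot_step_fixture_exact(self):
        t = np.arange(0, 1200.0, 1.0)
        f = np.where(t < 600, 1.0, 0.5)
        tab = _cycle_table(t, f)
        assert longterm.snapshot_mean(tab, 900.0, 100.0) == pytest.approx(0.5)


class TestFastestWindow:
    def test_constant_series_tie_breaks_to_start(self):
        t = np.arange(0.0, 20 * 3600.0, 2.0)
        tl = PreparationTimeline(prep_id="p", decentralization_time=0.0)
        res = longterm.fastest_window(
            _cycle_table(t, np.ones(t.size)), tl, window_h=5.0, horizon_h=20.0
        )
        assert res["start_s"] == 0.0

    def test_plateau_window_found(self):
        t = np.arange(0.0, 30 * 3600.0, 2.0)
        f = np.where((t > 10 * 3600.0) & (t < 16 * 3600.0), 0.9, 0.4)
        tl = PreparationTimeline(prep_id="p", decentralization_time=0.0)
        res = longterm.fastest_window(_cycle_table(t, f), tl, window_h=5.0, horizon_h=30.0)
        assert 10 * 3600.0 <= res["start_s"] <= 11 * 3600.0
        assert res["mean_frequency"] > 0.85

    def test_matches_bruteforce_on_random_fixture(self, rng):
        for _ in range(25):
            t = np.sort(rng.uniform(0, 12 * 3600.0, 800))
            f = rng.uniform(0.2, 1.5, 800)
            tl = PreparationTimeline(prep_id="p", decentralization_time=0.0)
            got = longterm.fastest_window(
                _cycle_table(t, f), tl, window_h=2.0, horizon_h=12.0
            )
            exp = fastest_window_bruteforce(t, f, 0.0, window_h=2.0, horizon_h=12.0)
            assert (got is None) == (exp is None)
            if got is not None:
                assert got["start_s"] == pytest.approx(exp[0])
                assert got["mean_frequency"] == pytest.approx(exp[1])


class TestVariability:
    def test_within_prep_cv_hand_values(self):
        assert longterm.within_prep_cv(np.full(50, 0.8)) == pytest.approx(0.0, abs=1e-12)
        assert longterm.within_prep_cv([0.9, 1.1]) == pytest.approx(
            np.std([0.9, 1.1], ddof=1) / 1.0
        )

    def test_jitter_monotone_in_cv(self):
        cvs = []
        for jitter in (0.02, 0.05, 0.10):
            p = synth.PreparationParams(
                prep_id="j", baseline_freq=1.0, cycle_jitter_cv=jitter
            )
            truth = synth.generate_cycle_series(p, 600.0, rng_seed=13)
            cvs.append(longterm.within_prep_cv(1.0 / truth.cycles.period.to_numpy()))
        assert cvs == sorted(cvs)

    def test_across_prep_cv_hand_value(self):
        assert longterm.across_prep_cv([0.4, 0.6]) == pytest.approx(
            np.std([0.4, 0.6], ddof=1) / 0.5
        )
        assert longterm.across_prep_cv([0.7, 0.7, 0.7]) == pytest.approx(0.0, abs=1e-12)


class TestSilence:
    def test_empty_train_entirely_silent(self):
        out = longterm.detect_silence(np.empty(0), (0.0, 600.0))
        assert out == [(0.0, 600.0)]

    def test_continuous_rhythm_no_silence(self):
        t = np.arange(0.0, 600.0, 1.0)
        assert longterm.detect_silence(t, (0.0, 600.0)) == []

    def test_recovers_injected_silence_episode(self):
        p = synth.PreparationParams(
            prep_id="sil",
            baseline_freq=1.0,
            silence_episodes=((1200.0, 1800.0),),
        )
        truth = synth.generate_cycle_series(p, 4000.0, rng_seed=4)
        out = longterm.detect_silence(
            truth.cycles["pd_start"].to_numpy(), (0.0, 4000.0), window=60.0
        )
        assert len(out) == 1
        s, e = out[0]
        assert abs(s - 1200.0) <= 60.0 and abs(e - 3000.0) <= 60.0

    def test_agrees_with_cycle_table(self):
        p = synth.PreparationParams(
            prep_id="sil2", baseline_freq=0.8, silence_episodes=((500.0, 400.0),)
        )
        truth = synth.generate_cycle_series(p, 2000.0, rng_seed=5)
        t = truth.cycles["pd_start"].to_numpy()
        for s, e in longterm.detect_silence(t, (0.0, 2000.0)):
            # no PD burst onset strictly inside a reported silent interval
            assert not np.any((t > s) & (t < e - 60.0))


class TestSalineEffect:
    def test_no_change_pre_equals_post(self):
        t = np.arange(0.0, 4 * 3600.0, 2.0)
        tl = PreparationTimeline(
            prep_id="p", saline_exchange_times=(2 * 3600.0,), decentralization_time=0.0
        )
        df = longterm.saline_effect(_cycle_table(t, np.full(t.size, 0.5)), tl)
        assert len(df) == 1
        assert df.iloc[0].pre_mean == pytest.approx(df.iloc[0].post_mean)

    def test_boost_raises_post_mean_every_seed(self):
        for seed in range(5):
            p = synth.PreparationParams(
                prep_id="sal",
                baseline_freq=0.5,
                cycle_jitter_cv=0.03,
                saline_exchange_times=(4 * 3600.0,),
                saline_boost=(1.5, 7200.0),
            )
            truth = synth.generate_cycle_series(p, 6 * 3600.0, rng_seed=seed)
            tab = _cycle_table(
                truth.cycles["pd_start"].to_numpy(),
                1.0 / truth.cycles["period"].to_numpy(),
            )
            tl = PreparationTimeline(
                prep_id="sal", decentralization_time=0.0, saline_exchange_times=(4 * 3600.0,)
            )
            df = longterm.saline_effect(tab, tl)
            assert df.iloc[0].post_mean > df.iloc[0].pre_mean

    def test_paired_t_power_across_population(self):
        """A 1.5x decaying boost is detected by the paired t at n = 10."""
        rejections = 0
        for seed in range(20):
            pre, post = [], []
            rng = np.random.default_rng(seed)
            for i in range(10):
                p = synth.PreparationParams(
                    prep_id=f"s{i}",
                    baseline_freq=max(0.1, rng.normal(0.52, 0.30)),
                    cycle_jitter_cv=0.03,
                    saline_exchange_times=(2 * 3600.0,),
                )
                truth = synth.generate_cycle_series(
                    p, 4 * 3600.0, rng_seed=seed * 1000 + i
                )
                tab = _cycle_table(
                    truth.cycles["pd_start"].to_numpy(),
                    1.0 / truth.cycles["period"].to_numpy(),
                )
                tl = PreparationTimeline(
                    prep_id=p.prep_id,
                    decentralization_time=0.0,
                    saline_exchange_times=(2 * 3600.0,),
                )
                df = longterm.saline_effect(tab, tl)
                pre.append(df.iloc[0].pre_mean)
                post.append(df.iloc[0].post_mean)
            if stats.paired_t(pre, post).p < 0.05:
                rejections += 1
        assert rejections >= 19

    def test_close_exchanges_truncated_nonoverlapping(self, caplog):
        t = np.arange(0.0, 8 * 3600.0, 2.0)
        tl = PreparationTimeline(
            prep_id="p",
            decentralization_time=0.0,
            saline_exchange_times=(3 * 3600.0, 4.5 * 3600.0),
        )
        with caplog.at_level("INFO"):
            df = longterm.saline_effect(_cycle_table(t, np.ones(t.size)), tl)
        assert len(df) == 2
        assert "truncated" in caplog.text
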