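"""Synthetic multi-day pyloric recordings with known ground truth.

The pyloric rhythm of the crustacean stomatogastric ganglion is a triphasic
motor pattern in which the PD/AB pacemaker kernel bursts first and the LP
follower bursts at a characteristic phase of each cycle.  Removing the
descending modulatory input ("decentralization") roughly halves the cycle
frequency and makes the rhythm far more variable.  This module generates
cycle-resolved ground truth for such recordings — a per-cycle table of PD and
LP burst times — and renders it down to spike times and, optionally, an
extracellular-nerve-like voltage trace, so that every downstream analysis
stage can be tested against a known answer.

The generative model, per preparation:

* a baseline cycle frequency drawn from a truncated normal across the
  population (intact: 1.2 +- 0.29 Hz; decentralized: 0.52 +- 0.30 Hz), with
  a step to the post-decentralization frequency at the decentralization time;
* slow drift as an Ornstein-Uhlenbeck (mean-reverting) process added to the
  baseline, plus i.i.d. multiplicative per-cycle jitter — two time scales of
  variability, matching the long- and short-time-scale wander seen in
  long-duration recordings;
* transient frequency "bouts": scheduled runs of >= 3 cycles whose target
  frequency is multiplied by a factor >= 1.4, the detection threshold of the
  trailing-mean bout rule;
* silence episodes during which no cycles are emitted;
* saline-exchange transients: an additive frequency boost that decays
  exponentially (default time constant 2 h) from each exchange time.

Phases are applied per cycle: PD burst ends at ``pd_off * period`` after its
start, LP runs from ``lp_on * period`` to ``lp_off * period``.  A
constant-duration mode (burst lengths fixed in seconds rather than in phase)
is available to emulate a pacemaker that cannot stretch its burst at
arbitrarily slow frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PopulationConfig",
    "PreparationParams",
    "GroundTruth",
    "SpikeTrain",
    "GenerationError",
    "sample_population",
    "generate_cycle_series",
    "render_spike_times",
    "render_trace",
    "spike_template",
]

#: lowest sustained frequency ever emitted or sampled, Hz
MIN_FREQ_HZ = 0.05


class GenerationError(ValueError):
    """Raised when a preparation's event schedule is internally inconsistent."""


@dataclass(frozen=True)
class PopulationConfig:
    """Across-preparation frequency distribution for one simulated cohort."""

    n_preparations: int
    condition: str = "decentralized"  # {"intact", "decentralized"}
    intact_freq_mean: float = 1.2
    intact_freq_sd_across: float = 0.29
    decentralized_freq_mean: float = 0.52
    decentralized_freq_sd_across: float = 0.30
    seed: int = 0

    def validate(self) -> None:
        if self.n_preparations < 1:
            raise ValueError("n_preparations must be >= 1")
        if self.condition not in ("intact", "decentralized"):
            raise ValueError(f"unknown condition {self.condition!r}")
        for name in (
            "intact_freq_mean",
            "intact_freq_sd_across",
            "decentralized_freq_mean",
            "decentralized_freq_sd_across",
        ):
            v = getattr(self, name)
            if name.endswith("mean") and v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
            if name.endswith("across") and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")


@dataclass(frozen=True)
class PreparationParams:
    """Generative parameters of a single preparation.

    ``drift_rate`` (1/s) and ``drift_sd`` (Hz, stationary SD) parameterise the
    mean-reverting slow-drift process; ``cycle_jitter_cv`` is the coefficient
    of variation of the i.i.d. multiplicative period jitter.  ``bout_schedule``
    entries are ``(start_cycle_index, n_cycles, amplitude_factor)``;
    ``silence_episodes`` are ``(start_s, duration_s)``.  ``saline_boost`` is
    ``(factor, decay_s)``: each exchange adds ``baseline * (factor - 1)`` Hz,
    decaying exponentially.
    """

    prep_id: str
    baseline_freq: float
    decentralization_time: float | None = None
    post_dec_freq: float | None = None
    drift_rate: float = 1.0 / 3600.0
    drift_sd: float = 0.0
    cycle_jitter_cv: float = 0.03
    phase_targets: tuple[float, float, float] = (0.3, 0.45, 0.75)
    bout_schedule: tuple[tuple[int, int, float], ...] = ()
    silence_episodes: tuple[tuple[float, float], ...] = ()
    saline_exchange_times: tuple[float, ...] = ()
    saline_boost: tuple[float, float] = (1.5, 7200.0)
    # constant-duration mode: burst boundaries fixed in seconds, not phase
    fixed_pd_duration_s: float | None = None
    fixed_lp_on_s: float | None = None
    fixed_lp_off_s: float | None = None

    def validate(self) -> None:
        if self.baseline_freq <= 0:
            raise ValueError("baseline_freq must be > 0")
        pd_off, lp_on, lp_off = self.phase_targets
        if not (0.0 < pd_off < lp_on < lp_off < 1.0):
            raise ValueError(
                f"phase targets must satisfy 0 < pd_off < lp_on < lp_off < 1, got {self.phase_targets}"
            )
        if self.cycle_jitter_cv < 0:
            raise ValueError("cycle_jitter_cv must be >= 0")
        for start, n, factor in self.bout_schedule:
            if n < 3:
                raise ValueError(f"bout at cycle {start}: n_cycles must be >= 3")
            if factor < 1.4:
                raise ValueError(
                    f"bout at cycle {start}: amplitude factor {factor} < 1.4 "
                    "cannot satisfy the detection rule"
                )
        if self.decentralization_time is not None and self.post_dec_freq is None:
            raise ValueError("post_dec_freq required when decentralization_time is set")
        factor, decay = self.saline_boost
        if factor <= 1 or decay <= 0:
            raise ValueError("saline_boost must be (factor > 1, decay_s > 0)")


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times of one unit (PD or LP) of one preparation."""

    prep_id: str
    unit: str
    times: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0):
            raise ValueError("spike times must be strictly increasing and non-negative")


@dataclass
class GroundTruth:
    """Cycle-resolved truth for one preparation.

    ``cycles`` has one row per emitted pyloric cycle with columns
    ``pd_start, pd_end, lp_start, lp_end, period, target_freq``; ``period`` is
    the interval to the next PD burst onset.  ``bout_cycles`` lists the cycle
    indices whose target frequency carried a bout amplitude factor.
    """

    params: PreparationParams
    duration: float
    cycles: pd.DataFrame
    bout_cycles: np.ndarray
    silence_episodes: tuple[tuple[float, float], ...]


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lower: float) -> float:
    """One draw from N(mean, sd) truncated to > lower, by rejection."""
    if sd == 0.0:
        if mean <= lower:
            raise ValueError(f"degenerate mean {mean} below truncation bound {lower}")
        return mean
    for _ in range(10_000):
        x = mean + sd * rng.standard_normal()
        if x > lower:
            return x
    raise RuntimeError("truncated-normal rejection sampling failed to converge")


def sample_population(
    config: PopulationConfig,
    rng_seed: int | None = None,
    decentralization_time: float = 3600.0,
    **overrides,
) -> list[PreparationParams]:
    """Draw per-preparation parameters for one cohort.

    Baseline frequencies come from the intact across-preparation distribution;
    for a decentralized cohort each preparation additionally receives a
    post-decentralization frequency from the decentralized distribution and a
    decentralization time (default 1 h of baseline, the standard protocol).
    Keyword ``overrides`` are forwarded to every ``PreparationParams``.
    Deterministic for a fixed seed.
    """
    config.validate()
    seed = config.seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)
    preps: list[PreparationParams] = []
    for i in range(config.n_preparations):
        base = _truncnorm(
            rng, config.intact_freq_mean, config.intact_freq_sd_across, MIN_FREQ_HZ
        )
        if config.condition == "decentralized":
            post = _truncnorm(
                rng,
                config.decentralized_freq_mean,
                config.decentralized_freq_sd_across,
                MIN_FREQ_HZ,
            )
            p = PreparationParams(
                prep_id=f"{config.condition}-{i:03d}",
                baseline_freq=base,
                decentralization_time=decentralization_time,
                post_dec_freq=post,
                **overrides,
            )
        else:
            p = PreparationParams(
                prep_id=f"{config.condition}-{i:03d}", baseline_freq=base, **overrides
            )
        p.validate()
        preps.append(p)
    return preps


def generate_cycle_series(
    params: PreparationParams, duration: float, rng_seed: int = 0
) -> GroundTruth:
    """Emit the cycle table for one preparation over ``duration`` seconds.

    Each cycle's target frequency is ``(baseline-or-post + OU drift + saline
    boost) * bout factor``, floored at 0.05 Hz; the realized period is
    ``1/target * (1 + jitter)`` with zero-mean Gaussian jitter of CV
    ``cycle_jitter_cv``.  No cycles are emitted inside silence episodes; a
    scheduled bout that collides with a silence episode raises
    :class:`GenerationError`.
    """
    params.validate()
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(rng_seed)

    silences = sorted(
        (float(s), float(s) + float(d)) for s, d in params.silence_episodes
    )
    bouts = sorted((int(s), int(s) + int(n), float(f)) for s, n, f in params.bout_schedule)
    exchanges = sorted(float(t) for t in params.saline_exchange_times)
    boost_factor, boost_decay = params.saline_boost
    dec_t = params.decentralization_time
    pd_off, lp_on, lp_off = params.phase_targets
    fixed_pd = params.fixed_pd_duration_s
    fixed_lp_on = params.fixed_lp_on_s
    fixed_lp_off = params.fixed_lp_off_s
    cv = params.cycle_jitter_cv
    theta = params.drift_rate
    drift_sd = params.drift_sd
    base_pre = params.baseline_freq
    base_post = params.post_dec_freq if params.post_dec_freq is not None else base_pre

    # pre-drawn normals, refilled in chunks: keeps the per-cycle loop cheap
    CHUNK = 8192
    jit_buf = rng.standard_normal(CHUNK)
    ou_buf = rng.standard_normal(CHUNK)
    buf_i = 0

    exp = math.exp
    pd_starts: list[float] = []
    pd_ends: list[float] = []
    lp_starts: list[float] = []
    lp_ends: list[float] = []
    periods: list[float] = []
    tfreqs: list[float] = []
    bout_idx: list[int] = []

    t = 0.0
    idx = 0
    ou = 0.0
    si = 0  # pointer into silences
    bi = 0  # pointer into bouts
    n_exch = len(exchanges)
    while t < duration:
        # silence handling: skip to the episode end, breaking the cycle chain
        while si < len(silences) and t >= silences[si][1]:
            si += 1
        if si < len(silences) and silences[si][0] <= t:
            if bi < len(bouts) and bouts[bi][0] <= idx < bouts[bi][1]:
                raise GenerationError(
                    f"bout scheduled at cycles [{bouts[bi][0]}, {bouts[bi][1]}) "
                    f"overlaps silence episode {silences[si]}"
                )
            t = silences[si][1]
            si += 1
            ou = 0.0  # drift state does not persist across silence
            continue

        base = base_pre if (dec_t is None or t < dec_t) else base_post
        boost = 0.0
        for k in range(n_exch):
            te = exchanges[k]
            if te <= t:
                boost += base * (boost_factor - 1.0) * exp(-(t - te) / boost_decay)
        while bi < len(bouts) and idx >= bouts[bi][1]:
            bi += 1
        if bi < len(bouts) and bouts[bi][0] <= idx < bouts[bi][1]:
            bf = bouts[bi][2]
            bout_idx.append(idx)
        else:
            bf = 1.0
        f = (base + ou + boost) * bf
        if f < MIN_FREQ_HZ:
            f = MIN_FREQ_HZ

        if buf_i >= CHUNK:
            jit_buf = rng.standard_normal(CHUNK)
            ou_buf = rng.standard_normal(CHUNK)
            buf_i = 0
        jfac = 1.0 + cv * jit_buf[buf_i]
        if jfac < 0.1:
            jfac = 0.1
        period = jfac / f

        # truncate a cycle interrupted by an upcoming silence episode
        if si < len(silences) and t + period > silences[si][0]:
            if bf != 1.0:
                raise GenerationError(
                    f"bout scheduled at cycle {idx} overlaps silence episode {silences[si]}"
                )
            t = silences[si][0]
            buf_i += 1
            continue

        pd_starts.append(t)
        periods.append(period)
        tfreqs.append(f)
        if fixed_pd is not None:
            pd_ends.append(t + min(fixed_pd, 0.95 * period))
        else:
            pd_ends.append(t + pd_off * period)
        if fixed_lp_on is not None and fixed_lp_off is not None:
            lp_starts.append(t + min(fixed_lp_on, 0.96 * period))
            lp_ends.append(t + min(fixed_lp_off, 0.99 * period))
        else:
            lp_starts.append(t + lp_on * period)
            lp_ends.append(t + lp_off * period)

        a = exp(-theta * period)
        ou = a * ou + drift_sd * math.sqrt(max(0.0, 1.0 - a * a)) * ou_buf[buf_i]
        buf_i += 1
        t += period
        idx += 1

    cycles = pd.DataFrame(
        {
            "pd_start": np.asarray(pd_starts),
            "pd_end": np.asarray(pd_ends),
            "lp_start": np.asarray(lp_starts),
            "lp_end": np.asarray(lp_ends),
            "period": np.asarray(periods),
            "target_freq": np.asarray(tfreqs),
        }
    )
    return GroundTruth(
        params=params,
        duration=duration,
        cycles=cycles,
        bout_cycles=np.asarray(bout_idx, dtype=int),
        silence_episodes=tuple((s, e - s) for s, e in silences),
    )


def render_spike_times(
    truth: GroundTruth,
    spikes_per_burst: int = 5,
    rng_seed: int = 0,
    refractory: float = 0.001,
) -> tuple[SpikeTrain, SpikeTrain]:
    """Turn the cycle table into (PD, LP) spike trains.

    Spikes are spread uniformly within each burst, endpoints included, so the
    first/last spike of a burst reproduce the burst boundaries exactly.
    """
    if spikes_per_burst < 2:
        raise ValueError("spikes_per_burst must be >= 2")
    c = truth.cycles
    if len(c) == 0:
        empty = np.empty(0)
        return (
            SpikeTrain(truth.params.prep_id, "PD", empty),
            SpikeTrain(truth.params.prep_id, "LP", empty),
        )
    min_dur = (spikes_per_burst - 1) * refractory
    frac = np.linspace(0.0, 1.0, spikes_per_burst)

    def _render(starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        dur = ends - starts
        if np.any(dur < min_dur):
            raise ValueError(
                f"burst shorter than ({spikes_per_burst} - 1) x refractory {refractory} s"
            )
        return (starts[:, None] + dur[:, None] * frac[None, :]).ravel()

    pd_sp = _render(c["pd_start"].to_numpy(), c["pd_end"].to_numpy())
    lp_sp = _render(c["lp_start"].to_numpy(), c["lp_end"].to_numpy())
    return (
        SpikeTrain(truth.params.prep_id, "PD", pd_sp),
        SpikeTrain(truth.params.prep_id, "LP", lp_sp),
    )


def spike_template(sampling_rate: float) -> np.ndarray:
    """Biphasic extracellular spike template, positive peak normalised to 1.

    A 1.5 ms positive lobe followed by a shallower negative afterswing, the
    classic shape of an extracellular nerve-recording unit.  The positive
    peak sits at the centre sample so rendered spikes peak at the spike time.
    """
    half = int(round(1.5e-3 * sampling_rate))
    n = 2 * half + 1
    t = (np.arange(n) - half) / sampling_rate
    sigma = 0.35e-3
    pos = np.exp(-0.5 * (t / sigma) ** 2)
    neg = 0.45 * np.exp(-0.5 * ((t - 0.9e-3) / (1.6 * sigma)) ** 2)
    tmpl = pos - neg
    return tmpl / tmpl.max()


def render_trace(
    trains: tuple[SpikeTrain, SpikeTrain],
    sampling_rate: float = 10_000.0,
    unit_amplitudes: dict[str, float] | None = None,
    noise_sd: float = 0.05,
    rng_seed: int = 0,
    duration: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render spike trains into a voltage-like sampled trace.

    Returns ``(times_s, trace)``.  Each spike adds the biphasic template
    scaled by its unit's amplitude; overlapping spikes sum.  White Gaussian
    noise of SD ``noise_sd`` is added.  Deterministic per seed.
    """
    if sampling_rate < 1000:
        raise ValueError("sampling rate must be >= 1 kHz")
    if unit_amplitudes is None:
        unit_amplitudes = {"PD": 0.4, "LP": 1.0}
    rng = np.random.default_rng(rng_seed)
    tmpl = spike_template(sampling_rate)
    half = len(tmpl) // 2
    if duration is None:
        last = max((tr.times[-1] if tr.times.size else 0.0) for tr in trains)
        duration = last + 0.05
    n = int(math.ceil(duration * sampling_rate)) + 1
    trace = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    for tr in trains:
        amp = unit_amplitudes[tr.unit]
        centers = np.round(tr.times * sampling_rate).astype(int)
        for ctr in centers:
            lo = max(0, ctr - half)
            hi = min(n, ctr + half + 1)
            trace[lo:hi] += amp * tmpl[(lo - ctr + half) : (hi - ctr + half)]
    times = np.arange(n) / sampling_rate
    return times, trace


def step_preparation(
    prep: PreparationParams, post_freq_scale: float
) -> PreparationParams:
    """Convenience: copy a preparation with post-dec frequency scaled from baseline."""
    return replace(prep, post_dec_freq=prep.baseline_freq * post_freq_scale)
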