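# Methods

## The system and the question

The pyloric circuit of the crustacean stomatogastric ganglion (STG) produces
a continuous triphasic motor pattern: the electrically coupled PD/AB
pacemaker kernel bursts first, the LP follower bursts at a characteristic
latency, and PY neurons fill the third phase. Severing or blocking the
single input nerve that carries descending neuromodulation
("decentralization") roughly halves the cycle frequency within half an hour
and disrupts the phase constancy that is a hallmark of the intact rhythm.
Whether the network later *recovers* intact-like activity is a long-standing
question; answering it requires quantifying days-long recordings: per-cycle
frequency and phase tables, transient frequency "bouts", binned long-term
summaries, and population statistics.

This package implements that quantification pipeline and a synthetic-data
generator with cycle-level ground truth, so that every stage is testable
without access to any original recordings.

## Cycle and phase conventions

* A cycle runs from one PD burst onset to the next (onset-referenced
  period); frequency is its reciprocal.
* Phases are latencies from the PD burst start divided by the period:
  PD off-phase (the pacemaker duty cycle), LP on-phase, LP off-phase, all
  dimensionless in [0, 1) for a well-formed cycle.
* The LP burst of a cycle is the first LP burst starting in the half-open
  interval between the two PD onsets; extra LP bursts in the same cycle are
  counted but ignored; cycles without one are kept and flagged `lp_silent`,
  and LP-phase aggregates exclude them.
* A period longer than 5 times the trailing median period (rolling median of
  the preceding up-to-11 periods) breaks the cycle chain: the row is kept but
  marked invalid with reason `gap`, so no "cycle" spans a pause or silence.
  The factor 5 and the window are configurable; using the raw rather than
  the previously-valid periods in the rolling median is deliberate — an
  11-wide median is robust to the isolated gap values the distinction would
  affect, and it vectorises.
* `filter_cycles` additionally invalidates cycles outside a frequency range
  (default 0.02–3.0 Hz, generously bracketing the observed range) and cycles
  whose LP burst overruns the next PD onset (`lp_off_phase >= 1`).

## Burst segmentation

The original acquisition scripts are unpublished, so the segmentation rule
is this package's explicit convention: a burst is a maximal run of spikes
with every inter-spike interval at most `max_isi`; runs with fewer than
`min_spikes` (default 2 — a one-spike "burst" has zero duration and breaks
the phase definitions) are dropped; burst start/end are the first/last spike.

Two threshold policies are provided:

* `segment_bursts(times, max_isi)` — fixed threshold, the primitive that the
  brute-force oracle tests check exactly.
* `segment_bursts_adaptive(times)` — the pipeline default. The threshold at
  each gap is 3 times the centred rolling median (window 25) of nearby
  inter-spike intervals. Because most ISIs are within-burst, the rolling
  median tracks the local within-burst interval, which is proportional to
  the local cycle period; the rule therefore survives the several-fold
  frequency step at decentralization, where any single global threshold
  shatters the slow regime's bursts or merges the fast regime's.

The factor 3 sits between the within-burst ISI and the inter-burst gap over
the realistic range: with a pacemaker duty cycle near 0.3 and *s* spikes per
burst the within-burst ISI is `0.3/(s-1)` periods while the gap is ~0.7
periods. This also bounds which bouts are resolvable: during a bout of
amplitude `a` the gap shrinks to `0.7/a` periods, so bursts remain separable
while `3 x 0.3/(s-1) < 0.7/a` — e.g. up to `a ~ 3` at 5 spikes per burst but
only `a ~ 1.5` at 3. Synthetic rendering therefore defaults to 5 spikes per
burst.

A trace front end (`detect_spikes`, rectified local maxima with a refractory
window; `assign_units`, disjoint amplitude windows) is provided for
synthetic extracellular-like traces whose units separate by amplitude; it is
not a spike sorter and is out of scope for real multi-unit data.

## Bout detection

A bout is a transient frequency elevation: at candidate cycle *i* the
background is the trailing mean of the previous 10 cycle frequencies, and
the rule fires if the next 3 frequencies (starting at *i*) are all at least
1.4 times the background. The threshold is inclusive (>= 40% increase) by
default with a strict (>) switch, since both readings of the published rule
are defensible. Consecutive firing indices merge into one bout event (a new
event needs at least one non-firing index between firings); the merge rule
is this package's choice, as the original analysis does not define bout
extent, and unmerged firing indices remain available via `firing_indices`.
`time_to_first_bout` is measured from the decentralization time; daily bout
counts use 24 h bins from recording start.

The detector is vectorised (prefix sums); its correctness is established by
exact agreement with a quadratic-time pure-Python re-evaluation on tens of
thousands of random series, and by exact count recovery of bouts injected by
the generator. The injection-recovery experiment uses period jitter CV 0.01:
the margin between the weakest injected bout (factor 1.5) and the detection
threshold (1.4) is ~7%, so jitter must be well below that for *exact* count
equality to be the correct expectation — at CV 0.03 a few percent of
3-cycle bouts would legitimately fall under the threshold. The rule itself
is validated separately on arbitrary series.

## Long-term summaries

* Single-preparation time courses: median frequency in 0.1 h (6 min) bins;
  empty bins are absent, never zero.
* Population time courses: per-hour box statistics across preparations.
  Quartiles use linear interpolation (the numpy default, type-7 hinge);
  whiskers extend to the most extreme datum within 1.5 interquartile ranges
  of the nearest quartile, and everything beyond is an outlier. The original
  software's quartile convention is unknown; this one is documented.
* Daily means: 24 h bins counted from the decentralization time, or for
  intact preparations from the matched post-baseline time (recording start
  + 1 h, the standard baseline duration). Days without valid cycles are
  absent and excluded from repeated-measures tables.
* Snapshot mean: mean valid-cycle frequency in a window around a time point,
  default half-width 5 min; used for the "30 min post-decentralization"
  state, whose exact original window is unstated.
* Fastest window: the 5 h stretch with the highest mean valid-cycle
  frequency, sliding in 0.1 h steps over the first 120 h after
  decentralization; ties break to the earliest start. Windows in which fewer
  than half the 0.1 h sub-bins contain a valid cycle are ineligible, which
  prevents a near-empty stretch from winning on a handful of fast cycles.
  Verified against exhaustive candidate evaluation.
* Variability: within-preparation CV is sample SD / mean of per-cycle
  frequency within a day bin; across-preparation CV is SD / mean of
  per-preparation daily means (ddof = 1 throughout). The source analysis
  names these measures without formulas; these are the obvious definitions.
* Silence: a 60 s tile with fewer than 3 PD bursts is silent; maximal unions
  of silent tiles are reported. Criterion and tile width are configurable —
  the original silence criterion is unstated.
* Saline exchanges: mean valid-cycle frequency in the hour before versus the
  hour after each exchange. Exchanges closer than 2 h split the shared
  stretch at the midpoint so windows never overlap; exchanges with under
  30 min of data on a side are skipped (logged).

## Comparison statistics

Implemented from the classical formulas, with scipy supplying only the
t/F/chi-square tail probabilities; all two-sided, significance convention
0.05, no multiple-testing correction (matching the source analysis):

* Pearson correlation with `p` from `t = R sqrt((n-2)/(1-R^2))`.
* Paired t; unpaired t with pooled variance by default (the stated use case
  is groups of similar size and variance) and Welch optional.
* Mood's median test: grand median of the pooled sample, 2x2 table of
  (> median) vs (<= median) per group, Pearson chi-square with 1 df and no
  continuity correction. Ties at the grand median count as <= median
  (documented; the source is silent).
* Two-way mixed (split-plot) ANOVA: condition between subjects, time within.
  Classical univariate decomposition with two error strata — subjects within
  groups for the between effect; time x subjects within groups for the time
  and interaction effects. Because every subject contributes every time
  level, cell counts are proportional to group sizes, so the
  observation-weighted decomposition is exactly orthogonal and handles
  unequal groups (19 vs 9 in the motivating design) without ambiguity.
  No sphericity correction by default (the source reports uncorrected
  tests); Greenhouse–Geisser is available as an option. Correctness: exact
  SS agreement with an explicit-loop oracle on balanced designs, F and p
  agreement with pingouin on unbalanced ones, and a simulated null at the
  19-vs-9 design whose type-I error sits inside the binomial 99% CI of 0.05.
  This is the classical fixed-effects split-plot, not a likelihood-based
  mixed model.

## The synthetic generator

Per preparation, the target frequency at cycle *n* is

    f_n = (base(t) + OU(t) + saline(t)) * bout_n,      f_n >= 0.05 Hz

where `base` steps from the baseline to the post-decentralization frequency
at the decentralization time; `OU` is a mean-reverting (Ornstein–Uhlenbeck)
drift with rate 1/3600 s^-1 and configurable stationary SD (default 0 —
drift is opt-in; population studies here use 0.05 Hz); `saline` adds
`base x (factor - 1)` decaying exponentially (default factor 1.5, time
constant 2 h — the observed transients last "several hours", exact kinetics
unknown) after each exchange; and `bout_n` multiplies scheduled cycles by an
amplitude factor >= 1.4. The realized period is `(1 + jitter)/f_n` with
i.i.d. Gaussian jitter of CV 0.03 by default (the short-term jitter of
intact preparations is not reported; 0.03 is a free parameter chosen as
realistic for a stable motor pattern). Two noise time scales — slow OU drift
plus per-cycle jitter — mirror the long- and short-time-scale variation of
real long-term recordings. No cycles are emitted inside silence episodes,
the drift state resets across them, and a bout scheduled across a silence
episode is a configuration error.

Population sampling draws baselines from a truncated normal (rejection below
0.05 Hz): intact 1.2 +- 0.29 Hz; post-decentralization 0.52 +- 0.30 Hz
across preparations.

Phases are applied per cycle (PD off 0.3, LP on 0.45, LP off 0.75 by
default), so computed phases recover the targets essentially exactly; a
constant-duration mode fixes burst boundaries in seconds instead, which
makes phase = duration x frequency and reproduces the positive
phase–frequency correlation of decentralized rhythms whose pacemaker cannot
stretch its burst at arbitrarily long periods. Spikes are spread uniformly
within bursts, endpoints included, so segmentation recovers burst boundaries
to machine precision; the optional trace renderer sums a biphasic template
(1.5 ms positive lobe, shallower afterswing) at spike times with white
noise.

What the generator does *not* emulate: PY neurons and the gastric mill,
conductance-based dynamics, gradual post-decentralization slow-down (the
step is instantaneous), bout ramping, electrode drift, or non-stationary
animal populations. Passing tests therefore demonstrate correctness of the
quantification rules on data with the assumed statistical structure, not
robustness to every artifact of real recordings.

## Problem sizes and numerical choices

Simulation studies use sizes chosen to make their statistical checks sharp
while remaining quick on one CPU: acute cohorts of n = 30 preparations with
45 min recordings (decentralization at 10 min; snapshots 5 min half-width);
200 seeded cohorts for the paired-t power study; long-term cohorts of 19
decentralized + 9 intact preparations over 6 days for the split-plot ANOVA
(mirroring the motivating design's group sizes); 2000 replicates for null
calibrations; and 2,000–10,000 random instances for oracle-equivalence
studies. Oracle comparisons use exact equality of indices and spike times
(float ties at detection thresholds have measure zero for continuous random
inputs); recovery tolerances are 3 SE for population means, 0.01 absolute
for phases, and 1% relative for frequency. Tie-breaks are deterministic
(earliest window start, first LP burst), and all randomness flows through
`numpy.random.default_rng` seeds, so every result in `results/` is exactly
reproducible.

## Known limitations

* Burst segmentation assumes a mostly-regular bursting train; tonic spiking
  or very sparse bursts defeat the adaptive threshold (the fixed-threshold
  primitive remains available).
* The adaptive rule can merge one or two bursts exactly at an abrupt
  several-fold frequency step; analyses here never read cycles within
  minutes of the step.
* The split-plot ANOVA excludes subjects missing any day bin rather than
  imputing; with heavy missingness a likelihood-based mixed model would be
  preferable and is out of scope.
* Published population tables from the motivating dataset derive from
  ~130 wild-caught-animal recordings that are not deposited; nothing here
  attempts to reproduce those numbers, only the methods that produced them.
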