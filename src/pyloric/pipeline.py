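"""End-to-end path from spike trains to the filtered cycle table."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import bursts as _bursts
from . import cycles as _cycles
from .synth import SpikeTrain

__all__ = ["analyze_preparation"]


def analyze_preparation(
    pd_train: SpikeTrain,
    lp_train: SpikeTrain,
    max_isi: float | None = None,
    min_spikes: int = 2,
    min_freq: float = 0.02,
    max_freq: float = 3.0,
) -> pd.DataFrame:
    """Segment both trains, build the cycle table, and set validity flags.

    ``max_isi=None`` (the default) selects the locally adaptive rule
    (:func:`pyloric.bursts.segment_bursts_adaptive`), which tracks the
    within-burst inter-spike interval as the cycle period changes — necessary
    for recordings that step to a several-fold slower rhythm at
    decentralization.  Passing a number segments both trains with that fixed
    threshold instead.
    """
    if max_isi is None:
        pd_b = _bursts.segment_bursts_adaptive(pd_train.times, min_spikes=min_spikes)
        lp_b = _bursts.segment_bursts_adaptive(lp_train.times, min_spikes=min_spikes)
    else:
        pd_b = _bursts.segment_bursts(pd_train.times, max_isi=max_isi, min_spikes=min_spikes)
        lp_b = _bursts.segment_bursts(lp_train.times, max_isi=max_isi, min_spikes=min_spikes)
    table = _cycles.build_cycles(pd_b, lp_b)
    return _cycles.filter_cycles(table, min_freq=min_freq, max_freq=max_freq)
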