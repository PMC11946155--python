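"""Behavioural summary measures for the equiprobable Go/No-Go task.

Six within-participant measures: omission errors (Go, no press before the
next stimulus), slow RT errors (press after 500 ms), fast RT errors (press
before 100 ms), mean and SD of valid-window RTs (100-500 ms), and No-Go
commission errors (any press before the next stimulus).  Error measures are
percentages of the relevant trial count; RT moments use valid-window
responses only, so slow presses count as slow errors rather than entering
the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = ["BehaviourSummary", "summarize_behaviour"]


@dataclass
class BehaviourSummary:
    omission_pct: float
    slow_rt_pct: float
    fast_rt_pct: float
    mean_rt_ms: float
    rt_sd_ms: float
    commission_pct: float

    def as_dict(self) -> dict:
        return asdict(self)


def summarize_behaviour(events: pd.DataFrame,
                        rt_window_ms: tuple[float, float] = (100.0, 500.0),
                        soa_ms: float | None = None) -> BehaviourSummary:
    """Compute the six behavioural measures from one event table.

    ``events`` needs ``code`` and ``rt_ms`` columns (NaN = no press).  A
    press is attributed to its own trial; with a fixed stimulus onset
    asynchrony every recorded press precedes the next stimulus, so "no press
    before the next stimulus" reduces to "no press".
    """
    is_go = (events["code"] == "go").to_numpy()
    rt = events["rt_ms"].to_numpy(float)
    n_go = int(is_go.sum())
    n_nogo = int((~is_go).sum())
    if n_go == 0 or n_nogo == 0:
        raise ValueError("behaviour measures undefined without both trial types")
    lo, hi = rt_window_ms

    go_rt = rt[is_go]
    omission = np.isnan(go_rt)
    slow = ~omission & (go_rt > hi)
    fast = ~omission & (go_rt < lo)
    valid = ~omission & (go_rt >= lo) & (go_rt <= hi)
    valid_rt = go_rt[valid]
    mean_rt = float(np.mean(valid_rt)) if valid_rt.size else float("nan")
    sd_rt = float(np.std(valid_rt, ddof=0)) if valid_rt.size else float("nan")

    commission = ~np.isnan(rt[~is_go])
    return BehaviourSummary(
        omission_pct=100.0 * omission.mean(),
        slow_rt_pct=100.0 * slow.mean(),
        fast_rt_pct=100.0 * fast.mean(),
        mean_rt_ms=mean_rt,
        rt_sd_ms=sd_rt,
        commission_pct=100.0 * commission.mean(),
    )
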