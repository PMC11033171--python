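"""Visually-selective-channel filter.

A channel is visually selective if its trial-averaged voltage (ERP)
deviates from the pre-target baseline mean by more than ``k_sd`` baseline
SDs for one contiguous run of at least 50 ms inside the 50-350 ms
post-target search window.  Channels failing the criterion in both the
actor and observer role are excluded from downstream spectral analyses.

The criterion is two-sided (|v - mean|, the "+/- 2SD" threshold) and the
SD is computed on the trial-averaged ERP over the baseline window
(default 300 ms before target onset; the [-0.2, 0] variant is a
parameter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .session import Session, ValidationError, BoundsError, realign, select_trials
from .spectral import EpochSet

__all__ = [
    "SelectivityResult",
    "compute_erp",
    "baseline_stats",
    "visual_selectivity",
    "selectivity_table",
    "selective_either",
]


@dataclass
class SelectivityResult:
    channel_id: str
    selective: bool
    onset_s: float | None
    erp: np.ndarray
    baseline_mean: float
    baseline_sd: float


def compute_erp(epochs: EpochSet, channel: int) -> np.ndarray:
    """Point-wise trial mean of one channel's aligned voltage."""
    if epochs.data.shape[0] < 1:
        raise ValidationError("need at least one trial to average")
    return np.asarray(epochs.data[:, channel, :], dtype=float).mean(axis=0)


def baseline_stats(trace: np.ndarray, times: np.ndarray,
                   baseline_window: tuple = (-0.3, 0.0)) -> tuple:
    """Arithmetic mean and sample SD of the trace over the baseline window."""
    trace = np.asarray(trace, dtype=float)
    times = np.asarray(times, dtype=float)
    a, b = baseline_window
    dt = float(np.median(np.diff(times))) if times.size > 1 else 0.0
    if a < times[0] - 1e-9 or b > times[-1] + dt + 1e-9:
        raise BoundsError(f"baseline window {baseline_window} outside the trace span")
    sel = (times >= a - 1e-9) & (times < b - 1e-9)
    if sel.sum() < 2:
        raise ValidationError("baseline window must contain at least 2 samples")
    v = trace[sel]
    return float(v.mean()), float(v.std(ddof=1))


def visual_selectivity(trace: np.ndarray, times: np.ndarray, stats: tuple,
                       k_sd: float = 2.0, min_run_s: float = 0.05,
                       search_window: tuple = (0.05, 0.35),
                       channel_id: str = "") -> SelectivityResult:
    """Apply the +/- k*SD-for-50-ms criterion to an ERP trace.

    Selective iff a contiguous run of at least ``min_run_s`` inside the
    search window has |v(t) - baseline mean| > k_sd * baseline SD; the
    onset is the start of the earliest such run.  A degenerate SD of 0
    makes any deviation from the mean count as exceeding.
    """
    trace = np.asarray(trace, dtype=float)
    times = np.asarray(times, dtype=float)
    mean, sd = stats
    if sd < 0:
        raise ValidationError("baseline SD must be non-negative")
    a, b = search_window
    if min_run_s > b - a:
        raise ValidationError(
            f"min_run_s={min_run_s} longer than the search window {search_window}")
    dt = float(np.median(np.diff(times)))
    n_run = max(1, int(round(min_run_s / dt)))
    sel = (times >= a - 1e-9) & (times <= b + 1e-9)
    dev = np.abs(trace[sel] - mean)
    exceed = dev > (k_sd * sd if sd > 0 else 0.0)
    t_sel = times[sel]
    run = 0
    for i, e in enumerate(exceed):
        run = run + 1 if e else 0
        if run >= n_run:
            onset = float(t_sel[i - run + 1])
            return SelectivityResult(channel_id, True, onset, trace, mean, sd)
    return SelectivityResult(channel_id, False, None, trace, mean, sd)


def selectivity_table(session: Session, roles: tuple = ("actor", "observer"),
                      baseline_window: tuple = (-0.3, 0.0), k_sd: float = 2.0,
                      min_run_s: float = 0.05,
                      search_window: tuple = (0.05, 0.35)) -> pd.DataFrame:
    """Per-channel, per-role selectivity results for a session.

    Actor trials are restricted to correct ones; observer trials are all
    included (bad-agent trials are errors by design).  Returns a tidy
    DataFrame with columns channel_id, role, selective, onset_s,
    baseline_mean, baseline_sd.
    """
    rows = []
    for role in roles:
        crit = {"role": role}
        if role == "actor":
            crit["outcome"] = "correct"
        idx = select_trials(session, crit)
        if not idx:
            raise ValidationError(f"no trials for role {role!r}")
        epochs = realign(session, idx, "target_onset", session.epoch_window)
        for c, ch_id in enumerate(session.channel_ids):
            erp = compute_erp(epochs, c)
            stats = baseline_stats(erp, epochs.times, baseline_window)
            res = visual_selectivity(erp, epochs.times, stats, k_sd=k_sd,
                                     min_run_s=min_run_s,
                                     search_window=search_window,
                                     channel_id=ch_id)
            rows.append({"channel_id": ch_id, "role": role,
                         "selective": res.selective, "onset_s": res.onset_s,
                         "baseline_mean": res.baseline_mean,
                         "baseline_sd": res.baseline_sd})
    return pd.DataFrame(rows)


def selective_either(table: pd.DataFrame) -> pd.Series:
    """Per-channel flag: selective in at least one role (kept downstream)."""
    return table.groupby("channel_id", sort=False)["selective"].any()
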