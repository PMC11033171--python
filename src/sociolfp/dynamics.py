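"""Band time-course analyses: extremum latencies, movement-locked windows,
latency comparisons across conditions, beta-gamma response patterns and
their correlations, and the movement-locked alpha contrast."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .session import ValidationError, BoundsError
from .stats import kruskal_wallis

__all__ = [
    "ExtremumResult",
    "extremum_latency",
    "movement_window",
    "latency_comparison",
    "response_pattern",
    "pattern_correlation",
    "alpha_movement_contrast",
]


@dataclass
class ExtremumResult:
    t_star: float
    v_star: float
    window: tuple
    mode: str


def extremum_latency(times: np.ndarray, tc: np.ndarray, window: tuple,
                     mode: str = "max") -> ExtremumResult:
    """Global extremum of a band time course inside a window.

    Ties are broken by the earliest time (argmin/argmax take the first hit).
    """
    times = np.asarray(times, dtype=float)
    tc = np.asarray(tc, dtype=float)
    a, b = window
    sel = (times >= a - 1e-9) & (times <= b + 1e-9)
    if sel.sum() < 3:
        raise ValidationError(
            f"window {window} contains fewer than 3 time samples")
    t_w, v_w = times[sel], tc[sel]
    i = int(np.argmax(v_w)) if mode == "max" else int(np.argmin(v_w))
    if mode not in ("max", "min"):
        raise ValidationError(f"mode must be 'max' or 'min', got {mode!r}")
    return ExtremumResult(t_star=float(t_w[i]), v_star=float(v_w[i]),
                          window=(float(a), float(b)), mode=mode)


def movement_window(trials) -> tuple:
    """Movement-locked analysis window (-median RT, median move-to-touch)."""
    trials = list(trials)
    if not trials:
        raise ValidationError("no trials given")
    rts = np.array([tr.rt_s for tr in trials], dtype=float)
    touch = np.array([tr.t_touch - tr.t_move for tr in trials], dtype=float)
    if np.isnan(rts).any() or np.isnan(touch).any():
        raise ValidationError("missing event times")
    return (-float(np.median(rts)), float(np.median(touch)))


def latency_comparison(latencies_by_condition: dict, unit: str = "channel") -> dict:
    """Kruskal-Wallis comparison of extremum latencies across conditions.

    Returns H, df, p, the unit of observation, and (for two conditions)
    the direction: sign of median(first) - median(second), so a negative
    direction means the first condition peaks earlier.
    """
    conds = list(latencies_by_condition)
    if len(conds) < 2:
        raise ValidationError("need at least 2 conditions")
    samples = [np.asarray(latencies_by_condition[c], dtype=float) for c in conds]
    if any(s.size < 2 for s in samples):
        raise ValidationError("every condition needs at least 2 latency samples")
    h, df, p = kruskal_wallis(samples)
    direction = 0
    if len(conds) == 2:
        direction = int(np.sign(np.median(samples[0]) - np.median(samples[1])))
    return {"H": h, "df": df, "p": p, "conditions": conds,
            "direction": direction, "unit": unit}


def response_pattern(beta_tc: np.ndarray, gamma_tc: np.ndarray) -> np.ndarray:
    """The overall response pattern: point-wise gamma minus beta (dB)."""
    beta_tc = np.asarray(beta_tc, dtype=float)
    gamma_tc = np.asarray(gamma_tc, dtype=float)
    if beta_tc.shape != gamma_tc.shape:
        raise ValidationError("beta and gamma time courses must share a time base")
    if beta_tc.size < 3:
        raise ValidationError("need at least 3 time points")
    return gamma_tc - beta_tc


def pattern_correlation(p1: np.ndarray, p2: np.ndarray) -> float:
    """Pearson correlation of two response patterns over their common support."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape or p1.size < 3:
        raise ValidationError("patterns must share a time base of >= 3 points")
    if np.std(p1) == 0 or np.std(p2) == 0:
        raise ValidationError("correlation undefined for a zero-variance pattern")
    r, _ = sstats.pearsonr(p1, p2)
    return float(r)


def alpha_movement_contrast(alpha_per_trial: np.ndarray, times: np.ndarray,
                            t_move: np.ndarray, pre: tuple = (-0.3, 0.0),
                            post: tuple = (0.0, 0.3)) -> dict:
    """Pre- vs post-movement per-trial alpha power, Kruskal-Wallis compared.

    ``alpha_per_trial`` is trials x times (dB, target-onset time base);
    windows are taken around each trial's movement onset.  Direction is the
    sign of median(post) - median(pre): negative = movement-locked alpha
    desynchronization.
    """
    alpha_per_trial = np.asarray(alpha_per_trial, dtype=float)
    times = np.asarray(times, dtype=float)
    t_move = np.asarray(t_move, dtype=float)
    if alpha_per_trial.shape[0] != t_move.size:
        raise ValidationError("one movement time per trial required")
    pre_vals, post_vals = [], []
    for i, tm in enumerate(t_move):
        for (a, b), acc in ((pre, pre_vals), (post, post_vals)):
            sel = (times >= tm + a - 1e-9) & (times < tm + b - 1e-9)
            if not sel.any():
                raise BoundsError(
                    f"window ({a}, {b}) around movement at {tm:.3f}s has no "
                    "spectrogram bins inside the epoch")
            acc.append(alpha_per_trial[i, sel].mean())
    h, df, p = kruskal_wallis([pre_vals, post_vals])
    direction = int(np.sign(np.median(post_vals) - np.median(pre_vals)))
    return {"direction": direction, "H": h, "df": df, "p": p,
            "median_pre_db": float(np.median(pre_vals)),
            "median_post_db": float(np.median(post_vals))}
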