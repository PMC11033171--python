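"""Full-session orchestration: behavior summary, selectivity filtering,
baseline-relative spectrograms, condition contrasts with permutation/FDR
statistics, band dynamics, and decoding.

The comparison structure mirrors the study design: GA1-vs-GA2 (control,
expected null), Good-vs-Bad per social role at target / movement /
feedback alignments, actor-vs-observer band dynamics, and previous-target
decoding from pre-target beta power.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from .session import Session, ValidationError, read_session, realign, select_trials
from .selectivity import selectivity_table, selective_either
from .spectral import (MTParams, TFGrid, BANDS, mt_spectrogram, baseline_power,
                       relative_spectrogram, band_timecourse)
from .stats import DiffMap, perm_diff_map, apply_fdr, kruskal_wallis
from .dynamics import (extremum_latency, latency_comparison, response_pattern,
                       pattern_correlation, alpha_movement_contrast,
                       movement_window)
from .decoding import (DecodingConfig, build_feature_matrix, run_decoding,
                       permutation_significance)
from .simulate import SynthConfig, generate_session

__all__ = [
    "AnalysisConfig",
    "ReportBundle",
    "behavior_summary",
    "relative_grids",
    "run_full_analysis",
]

log = logging.getLogger("sociolfp")


def default_contrasts() -> list:
    """(name, group A spec, group B spec, alignment, window) tuples."""
    return [
        ("ga1_vs_ga2_observer", {"agent_id": "GA1"}, {"agent_id": "GA2"},
         "target_onset", (-0.4, 1.2)),
        ("good_vs_bad_observer_target",
         {"role": "observer", "agent_type": "good"},
         {"role": "observer", "agent_type": "bad"}, "target_onset", (-0.4, 1.2)),
        ("good_vs_bad_observer_movement",
         {"role": "observer", "agent_type": "good"},
         {"role": "observer", "agent_type": "bad"}, "movement_onset", (-0.5, 1.0)),
        ("good_vs_bad_observer_feedback",
         {"role": "observer", "agent_type": "good"},
         {"role": "observer", "agent_type": "bad"}, "feedback_onset", (-0.5, 1.0)),
        ("good_vs_bad_actor_target",
         {"role": "actor", "context_agent_type": "good", "outcome": "correct"},
         {"role": "actor", "context_agent_type": "bad", "outcome": "correct"},
         "target_onset", (-0.4, 1.2)),
    ]


@dataclass
class AnalysisConfig:
    """Everything :func:`run_full_analysis` needs, reproducible from seed."""

    session_paths: list = field(default_factory=list)
    synth: SynthConfig | None = None
    mt: MTParams = field(default_factory=MTParams)
    selectivity_params: dict = field(default_factory=dict)
    contrasts: list = field(default_factory=default_contrasts)
    n_perm: int = 5000
    alpha: float = 0.01
    fdr_method: str = "as_printed"
    decoding: DecodingConfig | None = field(default_factory=DecodingConfig)
    min_trials_per_interaction: int = 50
    seed: int = 0

    def config_hash(self) -> str:
        def enc(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if hasattr(o, "__dataclass_fields__"):
                return asdict(o)
            return repr(o)
        payload = json.dumps(asdict(self), default=enc, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """All artifacts of one full analysis, traceable to config + seed."""

    behavior: pd.DataFrame
    behavior_tests: dict
    selectivity: pd.DataFrame
    channels_kept: list
    diffmaps: dict                  # contrast name -> DiffMap
    band_timecourses: dict          # (role, interaction) -> {band: time series}
    timecourse_times: np.ndarray | None
    latency_stats: dict
    pattern_correlations: pd.DataFrame | None
    alpha_contrasts: dict
    decoding: object | None
    provenance: dict


def behavior_summary(session: Session | pd.DataFrame) -> tuple:
    """Accuracy and RT summaries per (role, agent), with KW comparisons.

    Returns ``(summary_df, tests)`` where tests hold GA1-vs-GA2 RT,
    good-vs-bad observer RT, and the monkey's actor RT split by the
    interaction context.
    """
    df = session.trials_dataframe() if isinstance(session, Session) else session
    rows = []
    for (role, agent), g in df.groupby(["role", "agent_id"]):
        rows.append({
            "role": role, "agent_id": agent, "n_trials": len(g),
            "accuracy": float((g.outcome == "correct").mean()),
            "rt_mean_s": float(g.rt_s.mean()),
            "rt_sd_s": float(g.rt_s.std(ddof=1)) if len(g) > 1 else 0.0,
        })
    summary = pd.DataFrame(rows)
    tests = {}

    def _kw(name, a, b, la, lb):
        if len(a) > 1 and len(b) > 1:
            h, dfree, p = kruskal_wallis([a, b])
            tests[name] = {"H": h, "df": dfree, "p": p, "groups": (la, lb),
                           "medians_s": (float(np.median(a)), float(np.median(b)))}

    ga1 = df[df.agent_id == "GA1"].rt_s.to_numpy()
    ga2 = df[df.agent_id == "GA2"].rt_s.to_numpy()
    _kw("rt_ga1_vs_ga2", ga1, ga2, "GA1", "GA2")
    ga = df[(df.role == "observer") & (df.agent_type == "good")].rt_s.to_numpy()
    ba = df[(df.role == "observer") & (df.agent_type == "bad")].rt_s.to_numpy()
    _kw("rt_good_vs_bad_agent", ga, ba, "GA", "BA")
    mg = df[(df.role == "actor") & (df.context_agent_type == "good")].rt_s.to_numpy()
    mb = df[(df.role == "actor") & (df.context_agent_type == "bad")].rt_s.to_numpy()
    _kw("rt_monkey_by_partner_type", mg, mb, "good context", "bad context")
    return summary, tests


def relative_grids(session: Session, trial_idx, channels, alignment: str,
                   window: tuple, mt: MTParams | None = None,
                   baseline_trials=None) -> dict:
    """Per-channel baseline-relative (dB) TFGrids for a trial set.

    The baseline is the mean pre-target (300 ms) power, whatever the
    alignment of the analyzed window.  ``baseline_trials`` defaults to the
    analyzed trials; when two groups are contrasted, pass their union so
    both share one baseline (a per-group baseline would turn baseline
    sampling noise into a group-common offset that a trial permutation
    cannot exchange away).
    """
    mt = mt or MTParams()
    trial_idx = list(trial_idx)
    base_idx = trial_idx if baseline_trials is None else list(baseline_trials)
    base_epochs = realign(session, base_idx, "target_onset",
                          (-mt.window_s - 0.05, 0.05))
    epochs = realign(session, trial_idx, alignment, window)
    out = {}
    for c in channels:
        base_tf = mt_spectrogram(base_epochs, c, mt)
        b = baseline_power(base_tf, baseline_window=(-mt.window_s, 0.0))
        tf = mt_spectrogram(epochs, c, mt)
        out[session.channel_ids[c]] = relative_spectrogram(tf, b)
    return out


def _band_mean_timecourses(grids: dict, bands=("alpha", "beta", "gamma")) -> dict:
    """Channel-averaged mean band time courses from per-channel rel grids."""
    out = {}
    for b in bands:
        tcs = [band_timecourse(tf, b, reduce="mean") for tf in grids.values()]
        out[b] = np.mean(tcs, axis=0)
    return out


def run_full_analysis(config: AnalysisConfig) -> ReportBundle:
    """Run the full pipeline on one session (loaded or synthesized)."""
    if config.synth is not None:
        session, _ = generate_session(config.synth)
    elif config.session_paths:
        session = read_session(config.session_paths[0])
    else:
        raise ValidationError("config needs session_paths or a synth config")
    log.info(json.dumps({"stage": "load", "session": session.session_id,
                         "n_trials": session.n_trials,
                         "n_channels": session.n_channels}))

    behavior, behavior_tests = behavior_summary(session)

    sel = selectivity_table(session, **config.selectivity_params)
    keep_flags = selective_either(sel)
    channels = [i for i, ch in enumerate(session.channel_ids) if keep_flags[ch]]
    if not channels:
        raise ValidationError("no channel passed the selectivity filter")
    log.info(json.dumps({"stage": "selectivity",
                         "kept": len(channels),
                         "total": session.n_channels}))

    rng_seq = np.random.SeedSequence([config.seed, 3])
    seeds = rng_seq.generate_state(len(config.contrasts) + 1)

    diffmaps = {}
    for k, (name, spec_a, spec_b, alignment, window) in enumerate(config.contrasts):
        idx_a = select_trials(session, spec_a)
        idx_b = select_trials(session, spec_b)
        if len(idx_a) < 2 or len(idx_b) < 2:
            log.info(json.dumps({"stage": "contrast", "name": name,
                                 "skipped": "too few trials"}))
            continue
        pooled = idx_a + idx_b
        ga = relative_grids(session, idx_a, channels, alignment, window,
                            config.mt, baseline_trials=pooled)
        gb = relative_grids(session, idx_b, channels, alignment, window,
                            config.mt, baseline_trials=pooled)
        any_tf = next(iter(ga.values()))
        # trials are the exchangeable unit: average maps across channels
        A = np.mean([tf.power for tf in ga.values()], axis=0)
        B = np.mean([tf.power for tf in gb.values()], axis=0)
        dm = perm_diff_map(A, B, n_perm=config.n_perm, seed=int(seeds[k]),
                           groups=(name + ":A", name + ":B"),
                           times=any_tf.times, freqs=any_tf.freqs)
        apply_fdr(dm, alpha=config.alpha, method=config.fdr_method)
        diffmaps[name] = dm
        log.info(json.dumps({"stage": "contrast", "name": name,
                             "sig_bins": int(dm.mask.sum())}))

    # band dynamics per (role, interaction)
    conditions = {
        ("actor", "good"): {"role": "actor", "context_agent_type": "good",
                            "outcome": "correct"},
        ("actor", "bad"): {"role": "actor", "context_agent_type": "bad",
                           "outcome": "correct"},
        ("observer", "good"): {"role": "observer", "agent_type": "good"},
        ("observer", "bad"): {"role": "observer", "agent_type": "bad"},
    }
    tc_by_cond, grids_by_cond, trials_by_cond = {}, {}, {}
    tc_times = None
    dyn_window = (-0.4, 2.2)
    for cond, spec in conditions.items():
        idx = select_trials(session, spec)
        if len(idx) < 2:
            continue
        grids = relative_grids(session, idx, channels, "target_onset",
                               dyn_window, config.mt)
        grids_by_cond[cond] = grids
        trials_by_cond[cond] = idx
        tc_by_cond[cond] = _band_mean_timecourses(grids)
        tc_times = next(iter(grids.values())).times

    latency_stats = {}
    for interaction in ("good", "bad"):
        for band, mode in (("beta", "min"), ("gamma", "max")):
            lats = {}
            for role in ("actor", "observer"):
                cond = (role, interaction)
                if cond not in grids_by_cond:
                    continue
                mw = movement_window([session.trials[i]
                                      for i in trials_by_cond[cond]])
                med_move = float(np.median([session.trials[i].t_move
                                            for i in trials_by_cond[cond]]))
                win = (0.0, max(0.6, med_move + mw[1]))
                per_ch = []
                for tf in grids_by_cond[cond].values():
                    tc = band_timecourse(tf, band, reduce="mean")
                    per_ch.append(extremum_latency(tf.times, tc, win, mode).t_star)
                lats[role] = np.asarray(per_ch)
            if len(lats) == 2:
                latency_stats[(interaction, band)] = latency_comparison(
                    lats, unit="channel")

    pattern_corr = None
    if len(tc_by_cond) >= 2:
        pats = {c: response_pattern(tc["beta"], tc["gamma"])
                for c, tc in tc_by_cond.items()}
        names = list(pats)
        r = pd.DataFrame(index=[str(n) for n in names],
                         columns=[str(n) for n in names], dtype=float)
        for a in names:
            for b in names:
                r.loc[str(a), str(b)] = pattern_correlation(pats[a], pats[b])
        pattern_corr = r

    alpha_contrasts = {}
    for cond, grids in grids_by_cond.items():
        idx = trials_by_cond[cond]
        t_move = np.array([session.trials[i].t_move for i in idx])
        per_trial = np.mean([band_timecourse(tf, "alpha", reduce="per-trial")
                             for tf in grids.values()], axis=0)
        try:
            alpha_contrasts[cond] = alpha_movement_contrast(
                per_trial, tc_times, t_move)
        except Exception as e:  # a movement window may exceed the epoch
            alpha_contrasts[cond] = {"error": str(e)}

    decoding_result = None
    if config.decoding is not None:
        idx = select_trials(session, {})
        grids = relative_grids(session, idx, channels, "target_onset",
                               (-0.45, 0.35), config.mt)
        labels = np.array([session.trials[i].prev_correct_target for i in idx])
        feats = np.stack([build_feature_matrix(grids, tb, config.decoding.band).T
                          for tb in config.decoding.time_bins])
        try:
            decoding_result = permutation_significance(feats, labels,
                                                       config.decoding)
        except ValidationError as e:
            decoding_result = {"error": str(e)}
        log.info(json.dumps({"stage": "decoding", "done": True}))

    provenance = {"config_hash": config.config_hash(), "seed": config.seed,
                  "version": __version__, "session_id": session.session_id}
    return ReportBundle(behavior=behavior, behavior_tests=behavior_tests,
                        selectivity=sel, channels_kept=channels,
                        diffmaps=diffmaps, band_timecourses=tc_by_cond,
                        timecourse_times=tc_times, latency_stats=latency_stats,
                        pattern_correlations=pattern_corr,
                        alpha_contrasts=alpha_contrasts,
                        decoding=decoding_result, provenance=provenance)
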