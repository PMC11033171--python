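import numpy as np
import pytest

import sociolfp as sl


def make_trial(i, agent="SELF", outcome=None, prev=(-1, -1), chosen=None,
               t_go=1.0, t_move=1.3, t_touch=1.7, t_feedback=2.1,
               delay=1.0, context=""):
    meta = {"SELF": ("monkey", "actor", "self"),
            "GA1": ("human", "observer", "good"),
            "GA2": ("human", "observer", "good"),
            "BA": ("human", "observer", "bad")}
    performer, role, agent_type = meta[agent]
    if outcome is None:
        outcome = "error" if agent == "BA" else "correct"
    if chosen is None:
        chosen = prev if outcome == "error" else (-prev[0], -prev[1])
    return sl.TrialInfo(trial_id=i, performer=performer, role=role,
                        agent_id=agent, agent_type=agent_type, outcome=outcome,
                        delay_s=delay, prev_correct_target=prev,
                        chosen_target=chosen, t_go=t_go, t_move=t_move,
                        t_touch=t_touch, t_feedback=t_feedback,
                        context_agent_type=context)


def make_session(agents, fs=250.0, epoch=(-0.4, 2.4), n_channels=2, lfp=None,
                 seed=0, **trial_kw):
    trials = [make_trial(i, a, **trial_kw) for i, a in enumerate(agents)]
    n = int(round((epoch[1] - epoch[0]) * fs))
    if lfp is None:
        rng = np.random.default_rng(seed)
        lfp = rng.standard_normal((len(trials), n_channels, n)).astype(np.float32)
    return sl.Session(session_id="hand", monkey_id="P", fs=fs,
                      channel_ids=[f"c{k}" for k in range(n_channels)],
                      epoch_window=epoch, lfp=lfp, trials=trials)


@pytest.fixture(scope="session")
def planted_session():
    """Medium synthetic session with the default planted repertoire and
    beta target tuning; shared across dynamics/selectivity tests."""
    cfg = sl.SynthConfig(
        n_trials={"SELF": 40, "GA1": 20, "GA2": 20, "BA": 40},
        n_channels=4, tuning_gain_db=sl.default_tuning(4, 2.0), seed=1234)
    return sl.generate_session(cfg)


@pytest.fixture(scope="session")
def planted_grids(planted_session):
    """Target-aligned per-trial relative grids per condition for the
    planted session (channel dict per condition)."""
    session, _ = planted_session
    out = {}
    for cond, spec in {
        ("actor", "self"): {"role": "actor"},
        ("observer", "good"): {"role": "observer", "agent_type": "good"},
        ("observer", "bad"): {"role": "observer", "agent_type": "bad"},
    }.items():
        idx = sl.select_trials(session, spec)
        out[cond] = (idx, sl.relative_grids(session, idx,
                                            range(session.n_channels),
                                            "target_onset", (-0.4, 2.2)))
    return out
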