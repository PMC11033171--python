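"""Session container, trial metadata, trial selection and event re-alignment.

A :class:`Session` holds trial-epoched multi-channel LFP as a
``trials x channels x samples`` array together with an ordered list of
:class:`TrialInfo` records.  All epochs are stored aligned to target onset
(time 0); movement- and feedback-aligned views are re-derived by slicing
with per-trial event times (:func:`realign`).

On disk a session is an HDF5 file (``/lfp``, ``/time`` plus scalar
attributes) with a sibling ``<name>.trials.csv`` holding one row per trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "TrialInfo",
    "Session",
    "EpochSet",
    "ValidationError",
    "FormatError",
    "BoundsError",
    "write_session",
    "read_session",
    "select_trials",
    "session_included",
    "realign",
]

PERFORMERS = ("monkey", "human")
ROLES = ("actor", "observer")
AGENT_IDS = ("SELF", "GA1", "GA2", "BA")
AGENT_TYPES = ("self", "good", "bad")
OUTCOMES = ("correct", "error")
ALIGNMENT_EVENTS = ("target_onset", "movement_onset", "feedback_onset")

#: the four target positions, sign-coded (x, y)
TARGET_POSITIONS = ((-1, -1), (-1, 1), (1, -1), (1, 1))


class ValidationError(ValueError):
    """Invalid argument or inconsistent metadata."""


class FormatError(ValueError):
    """Malformed on-disk session container."""


class BoundsError(ValueError):
    """A requested window falls outside the stored epoch."""


@dataclass
class TrialInfo:
    """Metadata of one trial; all times in seconds relative to target onset.

    ``rt_s`` is the response time ``t_touch - t_go`` (reaction + movement).
    ``context_agent_type`` is the interaction type ('good'/'bad') the trial
    is embedded in; for observer trials it equals ``agent_type``.
    """

    trial_id: int
    performer: str
    role: str
    agent_id: str
    agent_type: str
    outcome: str
    delay_s: float
    prev_correct_target: tuple
    chosen_target: tuple
    t_go: float
    t_move: float
    t_touch: float
    t_feedback: float
    rt_s: float = field(default=None)  # type: ignore[assignment]
    is_correction: bool = False
    context_agent_type: str = ""

    def __post_init__(self):
        if self.performer not in PERFORMERS:
            raise ValidationError(f"unknown performer {self.performer!r}")
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r}")
        if self.agent_id not in AGENT_IDS:
            raise ValidationError(f"unknown agent_id {self.agent_id!r}")
        if self.agent_type not in AGENT_TYPES:
            raise ValidationError(f"unknown agent_type {self.agent_type!r}")
        if self.outcome not in OUTCOMES:
            raise ValidationError(f"unknown outcome {self.outcome!r}")
        # actor iff the monkey performs (monkey's perspective)
        if (self.performer == "monkey") != (self.role == "actor"):
            raise ValidationError("role must be 'actor' iff performer is 'monkey'")
        if self.agent_id in ("GA1", "GA2") and (
            self.agent_type != "good" or self.outcome != "correct"
        ):
            raise ValidationError("good agents perform always correct trials")
        if self.agent_id == "BA" and (
            self.agent_type != "bad" or self.outcome != "error"
        ):
            raise ValidationError("the bad agent performs always incorrect trials")
        if self.agent_id == "SELF" and self.agent_type != "self":
            raise ValidationError("agent_id SELF requires agent_type 'self'")
        self.prev_correct_target = tuple(int(v) for v in self.prev_correct_target)
        self.chosen_target = tuple(int(v) for v in self.chosen_target)
        for tgt in (self.prev_correct_target, self.chosen_target):
            if tgt not in TARGET_POSITIONS:
                raise ValidationError(f"target {tgt} not one of the four positions")
        if self.outcome == "correct" and self.chosen_target == self.prev_correct_target:
            raise ValidationError(
                "nonmatch rule: a correct choice differs from the previous correct target"
            )
        if not (0.0 <= self.t_go < self.t_move < self.t_touch < self.t_feedback):
            raise ValidationError(
                f"event times must satisfy 0 <= go < move < touch < feedback, got "
                f"({self.t_go}, {self.t_move}, {self.t_touch}, {self.t_feedback})"
            )
        if self.rt_s is None:
            self.rt_s = self.t_touch - self.t_go
        if not self.context_agent_type:
            self.context_agent_type = (
                self.agent_type if self.agent_type in ("good", "bad") else "good"
            )
        if self.context_agent_type not in ("good", "bad"):
            raise ValidationError("context_agent_type must be 'good' or 'bad'")

    def event_time(self, event: str) -> float:
        if event == "target_onset":
            return 0.0
        if event == "movement_onset":
            return self.t_move
        if event == "feedback_onset":
            return self.t_feedback
        raise ValidationError(f"unknown alignment event {event!r}")


@dataclass
class Session:
    """Trial-epoched multi-channel LFP plus per-trial metadata."""

    session_id: str
    monkey_id: str
    fs: float
    channel_ids: list
    epoch_window: tuple
    lfp: np.ndarray  # trials x channels x samples, microvolts
    trials: list

    def __post_init__(self):
        if self.fs <= 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        self.lfp = np.asarray(self.lfp, dtype=np.float32)
        if self.lfp.ndim != 3:
            raise ValidationError("lfp must be trials x channels x samples")
        t0, t1 = self.epoch_window
        n_expected = int(round((t1 - t0) * self.fs))
        if self.lfp.shape[2] != n_expected:
            raise ValidationError(
                f"lfp has {self.lfp.shape[2]} samples, epoch window implies {n_expected}"
            )
        if np.isnan(self.lfp).any():
            raise ValidationError("lfp contains missing values")
        if self.lfp.shape[0] != len(self.trials):
            raise ValidationError("trials list length must equal the lfp trial axis")
        if self.lfp.shape[1] != len(self.channel_ids):
            raise ValidationError("channel_ids length must equal the channel axis")
        for tr in self.trials:
            for ev in ("t_go", "t_move", "t_touch", "t_feedback"):
                t = getattr(tr, ev)
                if not (t0 <= t <= t1):
                    raise ValidationError(
                        f"trial {tr.trial_id}: {ev}={t} outside epoch {self.epoch_window}"
                    )

    @property
    def n_trials(self) -> int:
        return self.lfp.shape[0]

    @property
    def n_channels(self) -> int:
        return self.lfp.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Sample times (s, target onset = 0); bin k covers [t_k, t_k + 1/fs)."""
        t0 = self.epoch_window[0]
        return t0 + np.arange(self.lfp.shape[2]) / self.fs

    def trials_dataframe(self) -> pd.DataFrame:
        rows = []
        for tr in self.trials:
            d = asdict(tr)
            px, py = d.pop("prev_correct_target")
            cx, cy = d.pop("chosen_target")
            d["prev_target_x"], d["prev_target_y"] = px, py
            d["chosen_x"], d["chosen_y"] = cx, cy
            rows.append(d)
        return pd.DataFrame(rows)


@dataclass
class EpochSet:
    """Per-trial LFP slices re-aligned so time 0 is the alignment event."""

    alignment_event: str
    window: tuple
    data: np.ndarray  # trials x channels x samples
    source_trial_ids: list
    fs: float

    @property
    def times(self) -> np.ndarray:
        return self.window[0] + np.arange(self.data.shape[2]) / self.fs

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


_TRIAL_COLUMNS = [
    "trial_id", "performer", "role", "agent_id", "agent_type", "outcome",
    "delay_s", "prev_target_x", "prev_target_y", "chosen_x", "chosen_y",
    "t_go", "t_move", "t_touch", "t_feedback", "rt_s", "is_correction",
    "context_agent_type",
]


def _csv_path(path) -> Path:
    return Path(path).with_suffix(".trials.csv")


def write_session(session: Session, path) -> None:
    """Write the HDF5 container and the sibling ``.trials.csv`` table."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("lfp", data=session.lfp.astype(np.float32))
        f.create_dataset("time", data=session.times.astype(np.float64))
        f.attrs["fs"] = float(session.fs)
        f.attrs["session_id"] = session.session_id
        f.attrs["monkey_id"] = session.monkey_id
        f.attrs["epoch_t0"] = float(session.epoch_window[0])
        f.attrs["epoch_t1"] = float(session.epoch_window[1])
        f.attrs["channel_ids"] = [str(c) for c in session.channel_ids]
    # %.17g guarantees binary64 decimal round-trip for the event times
    session.trials_dataframe()[_TRIAL_COLUMNS].to_csv(_csv_path(path), index=False,
                                                      float_format="%.17g")


def read_session(path) -> Session:
    """Read a session written by :func:`write_session`.

    Raises :class:`FormatError` naming the missing dataset/column on a
    malformed container.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such session container: {path}")
    with h5py.File(path, "r") as f:
        for ds in ("lfp", "time"):
            if ds not in f:
                raise FormatError(f"container missing dataset '/{ds}'")
        for attr in ("fs", "session_id", "monkey_id", "epoch_t0", "epoch_t1",
                     "channel_ids"):
            if attr not in f.attrs:
                raise FormatError(f"container missing attribute '{attr}'")
        lfp = f["lfp"][()]
        fs = float(f.attrs["fs"])
        session_id = str(f.attrs["session_id"])
        monkey_id = str(f.attrs["monkey_id"])
        epoch = (float(f.attrs["epoch_t0"]), float(f.attrs["epoch_t1"]))
        channel_ids = [str(c) for c in f.attrs["channel_ids"]]
    if fs <= 0:
        raise ValidationError(f"fs must be positive, got {fs}")
    csv = _csv_path(path)
    if not csv.exists():
        raise FormatError(f"container missing the trial table {csv.name}")
    df = pd.read_csv(csv, float_precision="round_trip")
    for col in _TRIAL_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"trial table missing column '{col}'")
    trials = []
    for _, row in df.iterrows():
        trials.append(TrialInfo(
            trial_id=int(row.trial_id),
            performer=str(row.performer),
            role=str(row.role),
            agent_id=str(row.agent_id),
            agent_type=str(row.agent_type),
            outcome=str(row.outcome),
            delay_s=float(row.delay_s),
            prev_correct_target=(int(row.prev_target_x), int(row.prev_target_y)),
            chosen_target=(int(row.chosen_x), int(row.chosen_y)),
            t_go=float(row.t_go),
            t_move=float(row.t_move),
            t_touch=float(row.t_touch),
            t_feedback=float(row.t_feedback),
            rt_s=float(row.rt_s),
            is_correction=bool(row.is_correction),
            context_agent_type=str(row.context_agent_type),
        ))
    return Session(session_id=session_id, monkey_id=monkey_id, fs=fs,
                   channel_ids=channel_ids, epoch_window=epoch, lfp=lfp,
                   trials=trials)


_CRITERIA = ("role", "agent_type", "agent_id", "outcome", "delay_s",
             "performer", "is_correction", "context_agent_type")


def select_trials(session: Session, criteria: dict | None = None, **kwargs) -> list:
    """Indices of trials satisfying all given criteria, in original order.

    Criteria keys: role, agent_type, agent_id, outcome, delay_s, performer,
    is_correction, context_agent_type.  Empty criteria select every trial.
    """
    crit = dict(criteria or {})
    crit.update(kwargs)
    for key in crit:
        if key not in _CRITERIA:
            raise ValidationError(f"unknown selection criterion {key!r}")
    out = []
    for i, tr in enumerate(session.trials):
        ok = True
        for key, want in crit.items():
            have = getattr(tr, key)
            if isinstance(want, float) or isinstance(have, float):
                ok = abs(float(have) - float(want)) < 1e-9
            else:
                ok = have == want
            if not ok:
                break
        if ok:
            out.append(i)
    return out


def session_included(session: Session, min_trials: int = 50) -> dict:
    """Per interaction type, whether the >=min_trials-trial inclusion rule holds.

    The good interaction counts correct good-agent observer trials; the bad
    interaction counts all BA observer trials (errors by task design).
    """
    n_good = len(select_trials(session, {"agent_type": "good", "outcome": "correct"}))
    n_bad = len(select_trials(session, {"agent_type": "bad"}))
    return {"good": n_good >= min_trials, "bad": n_bad >= min_trials}


def realign(session: Session, trial_indices, event: str, window: tuple) -> EpochSet:
    """Slice per-trial epochs so output time 0 maps to the trial's event time."""
    if event not in ALIGNMENT_EVENTS:
        raise ValidationError(f"unknown alignment event {event!r}")
    a, b = window
    if b <= a:
        raise ValidationError(f"empty window {window}")
    fs = session.fs
    t0 = session.epoch_window[0]
    n_samples = session.lfp.shape[2]
    n_out = int(round((b - a) * fs))
    trial_indices = list(trial_indices)
    starts, bad = [], []
    for i in trial_indices:
        e = session.trials[i].event_time(event)
        k = int(round((e + a - t0) * fs))
        if k < 0 or k + n_out > n_samples:
            bad.append(session.trials[i].trial_id)
        starts.append(k)
    if bad:
        raise BoundsError(
            f"window {window} around {event} exceeds the stored epoch for trials {bad}"
        )
    data = np.empty((len(trial_indices), session.lfp.shape[1], n_out),
                    dtype=session.lfp.dtype)
    for j, (i, k) in enumerate(zip(trial_indices, starts)):
        data[j] = session.lfp[i, :, k:k + n_out]
    return EpochSet(alignment_event=event, window=(float(a), float(b)), data=data,
                    source_trial_ids=[session.trials[i].trial_id for i in trial_indices],
                    fs=fs)
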