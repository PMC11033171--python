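"""Synthetic session generator with planted, recoverable spectral structure.

Each trial is 1/f^beta background noise per channel.  Planted band-power
effects multiply the band-passed component of that background by a
Gaussian-envelope power gain anchored to a task event, so a +3 dB planted
gain is, by construction, a +3 dB expected deviation in the
baseline-relative spectrogram.  Selective channels additionally carry a
damped-sinusoid evoked potential after target onset, and pre-target beta
power is tuned to the previous trial's correct target so the decoder has a
recoverable signal.  Behavior (agent-specific lognormal response times,
always-correct good agents, always-wrong bad agent, nonmatch-consistent
targets) mirrors the task structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .session import (Session, TrialInfo, ValidationError, TARGET_POSITIONS,
                      ALIGNMENT_EVENTS)
from .spectral import MTParams

__all__ = [
    "PlantedEffect",
    "SynthConfig",
    "GroundTruth",
    "pink_noise",
    "band_component",
    "evoked_waveform",
    "sample_rts",
    "generate_session",
    "default_effects",
    "default_tuning",
]


@dataclass(frozen=True)
class PlantedEffect:
    """A band-limited power modulation anchored to a task event.

    ``gain_db`` is the peak power gain (positive = synchronization);
    the envelope is a Gaussian of SD ``width`` centered ``center`` seconds
    after ``anchor``.  ``applies_to`` lists the (role, agent_type) cells
    that receive the effect.
    """

    band: tuple          # (f_lo, f_hi) Hz
    anchor: str          # alignment event
    center: float        # s relative to anchor
    width: float         # s, Gaussian SD of the envelope
    gain_db: float
    applies_to: tuple    # of (role, agent_type)

    def __post_init__(self):
        if self.anchor not in ALIGNMENT_EVENTS:
            raise ValidationError(f"unknown anchor event {self.anchor!r}")
        if not (0 < self.band[0] < self.band[1]):
            raise ValidationError(f"bad band {self.band}")
        if self.width <= 0:
            raise ValidationError("envelope width must be positive")
        object.__setattr__(self, "applies_to",
                           tuple((r, a) for r, a in self.applies_to))


def default_effects() -> list:
    """The default planted repertoire: actor-early / observer-late
    gamma bursts with anti-phase beta dips, opposite alpha modulations
    after movement, and observer-BA low-frequency boosts after the
    partner's movement and after feedback."""
    A = (("actor", "self"),)
    Og = (("observer", "good"),)
    Ob = (("observer", "bad"),)
    O = Og + Ob
    return [
        PlantedEffect((45, 75), "target_onset", 0.25, 0.10, 3.0, A),
        PlantedEffect((20, 30), "target_onset", 0.20, 0.05, -3.0, A),
        PlantedEffect((45, 75), "movement_onset", 0.10, 0.10, 1.5, A),
        PlantedEffect((20, 30), "movement_onset", 0.10, 0.08, -1.5, A),
        PlantedEffect((7, 14), "movement_onset", 0.15, 0.12, -2.0, A),
        PlantedEffect((45, 75), "movement_onset", 0.12, 0.10, 3.0, O),
        PlantedEffect((20, 30), "movement_onset", 0.12, 0.08, -3.0, O),
        PlantedEffect((7, 14), "movement_onset", 0.15, 0.12, 2.0, O),
        PlantedEffect((7, 15), "movement_onset", 0.20, 0.15, 3.0, Ob),
        PlantedEffect((7, 15), "feedback_onset", 0.20, 0.15, 3.0, Ob),
    ]


def default_tuning(n_channels: int, gain_db: float = 2.0) -> np.ndarray:
    """A deterministic channels x 2 beta-tuning matrix covering both axes."""
    pats = np.array([[1, 0], [0, 1], [-1, 0], [0, -1],
                     [1, 1], [-1, 1], [1, -1], [-1, -1]], dtype=float)
    return gain_db * pats[np.arange(n_channels) % len(pats)]


@dataclass
class SynthConfig:
    """Generator settings; defaults define the simulated study conditions."""

    n_trials: dict = field(default_factory=lambda: {
        "SELF": 60, "GA1": 60, "GA2": 60, "BA": 60})
    n_channels: int = 8
    fs: float = 1000.0
    epoch_window: tuple = (-0.8, 3.0)
    pink_exponent: float = 1.0
    noise_sd: float = 20.0            # microvolts
    evoked_amp_sd_units: float = 5.0  # multiples of the baseline ERP SD
    # 4 Hz keeps a half-cycle above the 2SD threshold longer than the
    # 50 ms contiguous-run criterion requires
    evoked_freq: float = 4.0
    evoked_decay: float = 0.35        # s
    evoked_onset: float = 0.08        # s after target onset
    effects: list = field(default_factory=default_effects)
    tuning_gain_db: np.ndarray | None = None  # channels x 2, dB per unit coordinate
    rt_median_s: dict = field(default_factory=lambda: {
        "SELF": 0.50, "GA1": 0.95, "GA2": 0.80, "BA": 1.10})
    rt_sigma: float = 0.12            # lognormal sigma
    delay_s: float = 1.0
    move_frac: float = 0.4            # reaction fraction of RT before movement
    feedback_delay_s: float = 0.5     # touch -> feedback
    selective_channels: np.ndarray | None = None  # default: all channels
    seed: int = 0

    def __post_init__(self):
        for agent, n in self.n_trials.items():
            if n < 0:
                raise ValidationError(f"negative trial count for {agent}")
        for agent, m in self.rt_median_s.items():
            if m <= 0:
                raise ValidationError(f"RT median for {agent} must be positive")
        if self.tuning_gain_db is not None:
            self.tuning_gain_db = np.asarray(self.tuning_gain_db, dtype=float)
            if self.tuning_gain_db.shape != (self.n_channels, 2):
                raise ValidationError("tuning_gain_db must be channels x 2")


def pink_noise(n: int, beta: float, seed=None) -> np.ndarray:
    """Zero-mean, unit-variance noise with expected log-PSD slope -beta."""
    if n < 2:
        raise ValidationError("need at least 2 samples")
    if not (0 <= beta <= 2):
        raise ValidationError("spectral slope beta must lie in [0, 2]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-beta / 2.0)
    x = np.fft.irfft(spec * scale, n)
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_mask(freqs: np.ndarray, lo: float, hi: float, edge: float = 1.0):
    """Brick-wall band mask with raised-cosine edges of width ``edge`` Hz."""
    m = np.zeros_like(freqs)
    core = (freqs >= lo) & (freqs <= hi)
    m[core] = 1.0
    for sel, f0 in (((freqs > lo - edge) & (freqs < lo), lo),
                    ((freqs > hi) & (freqs < hi + edge), hi)):
        m[sel] = 0.5 * (1 + np.cos(np.pi * np.abs(freqs[sel] - f0) / edge))
    return m


def _bandpass(x: np.ndarray, fs: float, lo: float, hi: float) -> np.ndarray:
    """Zero-phase FFT band-pass along the last axis."""
    n = x.shape[-1]
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    return np.fft.irfft(np.fft.rfft(x, axis=-1) * _band_mask(freqs, lo, hi),
                        n, axis=-1)


def band_component(band: tuple, envelope: np.ndarray, fs: float, n: int,
                   seed=None) -> np.ndarray:
    """Band-limited unit-variance Gaussian noise times a point-wise envelope."""
    envelope = np.asarray(envelope, dtype=float)
    if envelope.shape != (n,):
        raise ValidationError("envelope length must equal n")
    lo, hi = band
    if not (0 < lo < hi < fs / 2):
        raise ValidationError(f"band {band} outside (0, Nyquist)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = _bandpass(rng.standard_normal(n), fs, lo, hi)
    sd = x.std()
    if sd > 0:
        x = x / sd
    return x * envelope


def evoked_waveform(amp: float, freq: float, decay: float, onset: float,
                    fs: float, n: int) -> np.ndarray:
    """Deterministic damped sinusoid starting at ``onset`` (series time base)."""
    if decay <= 0:
        raise ValidationError("decay must be positive")
    t = np.arange(n) / fs - onset
    w = amp * np.exp(-t / decay) * np.sin(2 * np.pi * freq * t)
    w[t < 0] = 0.0
    return w


def sample_rts(agent_id: str, n: int, seed=None, median_s: dict | float | None = None,
               sigma: float = 0.12) -> np.ndarray:
    """Lognormal response times whose median converges to the configured one."""
    defaults = SynthConfig.__dataclass_fields__["rt_median_s"].default_factory()
    if median_s is None:
        median_s = defaults
    if isinstance(median_s, dict):
        if agent_id not in median_s:
            raise ValidationError(f"no RT median configured for agent {agent_id!r}")
        median = median_s[agent_id]
    else:
        median = float(median_s)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if sigma == 0:
        return np.full(n, median)
    return np.exp(np.log(median) + sigma * rng.standard_normal(n))


def _tuning_envelope(t: np.ndarray) -> np.ndarray:
    """Pre-target beta tuning gain envelope: full until 0.1 s after target
    onset, cosine roll-off to zero by 0.3 s."""
    env = np.zeros_like(t)
    env[t <= 0.1] = 1.0
    ramp = (t > 0.1) & (t < 0.3)
    env[ramp] = 0.5 * (1 + np.cos(np.pi * (t[ramp] - 0.1) / 0.2))
    return env


@dataclass
class GroundTruth:
    """What was planted: per-channel selectivity, the beta-tuning matrix,
    per-cell median event times, and expected relative-dB differences on
    any analysis grid."""

    selective_channels: np.ndarray
    tuning_weights: np.ndarray
    median_events: dict            # (role, agent_type) -> {'t_move': ..., 't_feedback': ...}
    config: SynthConfig

    def _anchor_time(self, cell: tuple, anchor: str, alignment: str) -> float:
        """Median anchor-event time in the alignment's time coordinates."""
        med = self.median_events[cell]
        ev = {"target_onset": 0.0,
              "movement_onset": med["t_move"],
              "feedback_onset": med["t_feedback"]}
        return ev[anchor] - ev[alignment]

    def expected_cell_db(self, cell: tuple, alignment: str, times: np.ndarray,
                         freqs: np.ndarray, window_s: float = 0.3,
                         half_bandwidth_hz: float = 5.0) -> np.ndarray:
        """Expected relative-dB map of a (role, agent_type) cell on a grid.

        Accounts for the analysis smoothing: the power gain is averaged
        over the 300 ms window in time, and mixed over the taper
        concentration bandwidth (+/- W) in frequency, so bins just outside
        a planted band carry their expected leakage share.
        """
        times = np.asarray(times, dtype=float)
        freqs = np.asarray(freqs, dtype=float)
        out = np.zeros((times.size, freqs.size))
        offs = np.linspace(-window_s / 2, window_s / 2, 31)
        W = half_bandwidth_hz
        for eff in self.config.effects:
            if cell not in eff.applies_to:
                continue
            t_anchor = self._anchor_time(cell, eff.anchor, alignment)
            tt = times[:, None] + offs[None, :] - t_anchor - eff.center
            env = np.exp(-0.5 * (tt / eff.width) ** 2)
            gain_pow = np.mean(10.0 ** (eff.gain_db * env / 10.0), axis=1)
            # fraction of each bin's +/-W concentration band inside the effect
            lo = np.maximum(freqs - W, eff.band[0])
            hi = np.minimum(freqs + W, eff.band[1])
            w = np.clip(hi - lo, 0.0, None) / (2 * W)
            mix = (1.0 - w[None, :]) + w[None, :] * gain_pow[:, None]
            out += 10.0 * np.log10(mix)
        return out

    def expected_diff_db(self, cell_a: tuple, cell_b: tuple, alignment: str,
                         times, freqs, window_s: float = 0.3) -> np.ndarray:
        return (self.expected_cell_db(cell_a, alignment, times, freqs, window_s)
                - self.expected_cell_db(cell_b, alignment, times, freqs, window_s))

    def effect_mask(self, cell_a: tuple, cell_b: tuple, alignment: str,
                    times, freqs, threshold_db: float = 0.5,
                    window_s: float = 0.3) -> np.ndarray:
        """Boolean grid mask where the planted difference exceeds threshold."""
        d = self.expected_diff_db(cell_a, cell_b, alignment, times, freqs, window_s)
        return np.abs(d) >= threshold_db


_AGENT_META = {
    "SELF": ("monkey", "actor", "self"),
    "GA1": ("human", "observer", "good"),
    "GA2": ("human", "observer", "good"),
    "BA": ("human", "observer", "bad"),
}


def _make_trials(config: SynthConfig, rng: np.random.Generator) -> list:
    t0, t1 = config.epoch_window
    contexts = []
    if config.n_trials.get("GA1", 0) + config.n_trials.get("GA2", 0) > 0:
        contexts.append("good")
    if config.n_trials.get("BA", 0) > 0:
        contexts.append("bad")
    if not contexts:
        contexts = ["good"]
    per_agent = []
    for agent, n in config.n_trials.items():
        if agent not in _AGENT_META:
            raise ValidationError(f"unknown agent_id {agent!r}")
        per_agent.append([agent] * n)
    # round-robin interleave to mimic agent alternation
    order = []
    k = 0
    while any(per_agent):
        for lst in per_agent:
            if lst:
                order.append(lst.pop())
        k += 1
    trials = []
    n_resampled = 0
    for i, agent in enumerate(order):
        performer, role, agent_type = _AGENT_META[agent]
        outcome = "error" if agent == "BA" else "correct"
        prev = TARGET_POSITIONS[rng.integers(4)]
        if outcome == "correct":
            others = [p for p in TARGET_POSITIONS if p != prev]
            chosen = others[rng.integers(3)]
        else:
            chosen = prev
        t_go = config.delay_s
        for attempt in range(200):
            rt = float(sample_rts(agent, 1, rng, config.rt_median_s,
                                  config.rt_sigma)[0])
            t_move = t_go + config.move_frac * rt
            t_touch = t_go + rt
            t_feedback = t_touch + config.feedback_delay_s
            if t_feedback <= t1 - 0.02 and t_move > t_go:
                break
            n_resampled += 1
        context = agent_type if agent_type in ("good", "bad") else \
            contexts[i % len(contexts)]
        trials.append(TrialInfo(
            trial_id=i, performer=performer, role=role, agent_id=agent,
            agent_type=agent_type, outcome=outcome, delay_s=config.delay_s,
            prev_correct_target=prev, chosen_target=chosen,
            t_go=t_go, t_move=t_move, t_touch=t_touch, t_feedback=t_feedback,
            context_agent_type=context))
    if n_resampled:
        warnings.warn(f"resampled {n_resampled} response times falling outside "
                      "the epoch", stacklevel=2)
    return trials


def generate_session(config: SynthConfig) -> tuple:
    """Generate a synthetic :class:`Session` and its :class:`GroundTruth`.

    Fully reproducible from ``config.seed``; trial k's signal stream is
    derived from (seed, k) so any trial regenerates in isolation.
    """
    master = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    trials = _make_trials(config, master)
    t0, t1 = config.epoch_window
    fs = config.fs
    n = int(round((t1 - t0) * fs))
    t_abs = t0 + np.arange(n) / fs
    n_ch = config.n_channels
    selective = (np.ones(n_ch, dtype=bool) if config.selective_channels is None
                 else np.asarray(config.selective_channels, dtype=bool))
    tuning = (np.zeros((n_ch, 2)) if config.tuning_gain_db is None
              else config.tuning_gain_db)

    n_by_role = {}
    for tr in trials:
        n_by_role[tr.role] = n_by_role.get(tr.role, 0) + 1

    rfreqs = np.fft.rfftfreq(n, 1.0 / fs)
    tune_env = _tuning_envelope(t_abs)
    lfp = np.empty((len(trials), n_ch, n), dtype=np.float32)
    for i, tr in enumerate(trials):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2, i]))
        white = rng.standard_normal((n_ch, n))
        spec = np.fft.rfft(white, axis=-1)
        scale = np.zeros_like(rfreqs)
        scale[1:] = rfreqs[1:] ** (-config.pink_exponent / 2.0)
        bg = np.fft.irfft(spec * scale, n, axis=-1)
        bg -= bg.mean(axis=-1, keepdims=True)
        bg /= bg.std(axis=-1, keepdims=True)
        x = config.noise_sd * bg
        spec_x = np.fft.rfft(x, axis=-1)
        # planted condition effects: multiplicative gain on the in-band part
        for eff in config.effects:
            if (tr.role, tr.agent_type) not in eff.applies_to:
                continue
            anchor_t = tr.event_time(eff.anchor)
            env = np.exp(-0.5 * ((t_abs - anchor_t - eff.center) / eff.width) ** 2)
            xb = np.fft.irfft(spec_x * _band_mask(rfreqs, *eff.band), n, axis=-1)
            x = x + xb * (10.0 ** (eff.gain_db * env / 20.0) - 1.0)
        # pre-target beta tuning to the previous correct target
        if np.any(tuning):
            gains_db = tuning @ np.asarray(tr.prev_correct_target, dtype=float)
            xb = np.fft.irfft(spec_x * _band_mask(rfreqs, 20.0, 30.0), n, axis=-1)
            amp = 10.0 ** (gains_db[:, None] * tune_env[None, :] / 20.0) - 1.0
            x = x + xb * amp
        # evoked potential on selective channels
        amp_ev = (config.evoked_amp_sd_units * config.noise_sd
                  / np.sqrt(n_by_role[tr.role]))
        if amp_ev > 0 and selective.any():
            w = evoked_waveform(amp_ev, config.evoked_freq, config.evoked_decay,
                                -t0 + config.evoked_onset, fs, n)
            x[selective] += w
        lfp[i] = x.astype(np.float32)

    session = Session(session_id=f"synth-{config.seed}", monkey_id="synthM",
                      fs=fs, channel_ids=[f"ch{c:02d}" for c in range(n_ch)],
                      epoch_window=config.epoch_window, lfp=lfp, trials=trials)

    med_ev = {}
    for cell in {("actor", "self"), ("observer", "good"), ("observer", "bad")}:
        tms = [tr.t_move for tr in trials if (tr.role, tr.agent_type) == cell]
        tfb = [tr.t_feedback for tr in trials if (tr.role, tr.agent_type) == cell]
        if tms:
            med_ev[cell] = {"t_move": float(np.median(tms)),
                            "t_feedback": float(np.median(tfb))}
    gt = GroundTruth(selective_channels=selective, tuning_weights=tuning,
                     median_events=med_ev, config=config)
    return session, gt
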