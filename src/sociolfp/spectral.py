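"""Multitaper time-frequency estimation and baseline-relative normalization.

Spectrograms use 300 ms windows stepped every 10 ms, K = 2 unit-norm DPSS
(Slepian) tapers at half-bandwidth W = 5 Hz (time-half-bandwidth product
NW = 1.5), zero-padded FFTs giving a ~1.5 Hz frequency grid truncated at
100 Hz.  Relative spectrograms are 10*log10 of power over the mean
pre-target baseline power of the same trials, per frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal

from .session import EpochSet, ValidationError, BoundsError

__all__ = [
    "MTParams",
    "TFGrid",
    "BandDef",
    "BANDS",
    "detrend_trial",
    "dpss_tapers",
    "mt_spectrogram",
    "baseline_power",
    "relative_spectrogram",
    "band_timecourse",
]


@dataclass
class MTParams:
    """Multitaper settings; defaults follow the analysis grid used throughout.

    ``half_bandwidth_hz`` (W) is the spectral concentration half-bandwidth;
    with a 0.3 s window this gives NW = 1.5 and 2*NW - 1 = 2 admissible
    tapers.
    """

    window_s: float = 0.3
    step_s: float = 0.01
    half_bandwidth_hz: float = 5.0
    n_tapers: int = 2
    fmax_hz: float = 100.0
    freq_step_hz: float = 1.5
    eigen_weighting: bool = False  # unweighted taper average by default

    @property
    def nw(self) -> float:
        """Time-half-bandwidth product NW = T * W."""
        return self.window_s * self.half_bandwidth_hz

    @property
    def n_tapers_implied(self) -> int:
        """Number of well-concentrated tapers, floor(2*NW) - 1."""
        return int(np.floor(2.0 * self.nw)) - 1

    def validate(self, fs: float) -> None:
        if self.window_s <= 0 or self.step_s <= 0:
            raise ValidationError("window_s and step_s must be positive")
        if self.fmax_hz > fs / 2:
            raise ValidationError(f"fmax {self.fmax_hz} exceeds Nyquist {fs / 2}")
        if self.n_tapers > self.n_tapers_implied:
            warnings.warn(
                f"K={self.n_tapers} exceeds 2*NW-1={self.n_tapers_implied}; "
                "extra tapers are poorly concentrated", stacklevel=2)

    def nfft(self, fs: float) -> int:
        # smallest FFT length whose grid spacing does not exceed freq_step_hz
        return int(np.ceil(fs / self.freq_step_hz))


@dataclass
class TFGrid:
    """trials x times x freqs power array on the analysis grid."""

    times: np.ndarray  # window centers, s
    freqs: np.ndarray  # Hz, constant spacing
    power: np.ndarray  # trials x times x freqs
    channel_id: str = ""
    alignment_event: str = "target_onset"
    window_s: float = 0.3
    units: str = "power"  # 'power' or 'dB'
    trial_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power)
        if self.power.ndim != 3:
            raise ValidationError("power must be trials x times x freqs")
        if self.power.shape[1:] != (self.times.size, self.freqs.size):
            raise ValidationError("power shape inconsistent with times/freqs")


@dataclass(frozen=True)
class BandDef:
    name: str
    lo: float
    hi: float


#: canonical frequency bands (Hz); 'alpha_wide' is the 7-15 Hz variant
BANDS = {
    "alpha": BandDef("alpha", 7.0, 14.0),
    "alpha_wide": BandDef("alpha_wide", 7.0, 15.0),
    "beta": BandDef("beta", 20.0, 30.0),
    "gamma": BandDef("gamma", 45.0, 100.0),
    "low": BandDef("low", 7.0, 20.0),
}


def detrend_trial(x: np.ndarray) -> np.ndarray:
    """Remove the mean value and least-squares linear trend."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 2:
        raise ValidationError("detrend needs at least 2 samples")
    return signal.detrend(x, axis=-1, type="linear")


def dpss_tapers(n_samples: int, nw: float, k: int):
    """K unit-norm, mutually orthogonal Slepian tapers with concentrations.

    Returns ``(tapers, ratios)`` with ``tapers`` of shape ``(k, n_samples)``
    ordered by decreasing in-band energy concentration.
    """
    if k < 1:
        raise ValidationError("need at least one taper")
    if k > n_samples:
        raise ValidationError(f"K={k} exceeds n_samples={n_samples}")
    if k > 2 * nw - 1:
        warnings.warn(f"K={k} exceeds 2*NW-1={2 * nw - 1:.1f}; "
                      "extra tapers are poorly concentrated", stacklevel=2)
    tapers, ratios = signal.windows.dpss(n_samples, nw, Kmax=k, return_ratios=True,
                                         norm=2)
    return np.atleast_2d(tapers), np.atleast_1d(ratios)


def _window_starts(n_samples: int, n_win: int, step: int) -> np.ndarray:
    if n_win > n_samples:
        raise ValidationError(
            f"window of {n_win} samples longer than epoch of {n_samples}")
    return np.arange(0, n_samples - n_win + 1, step)


def mt_spectrogram(epochs: EpochSet, channel: int, params: MTParams | None = None,
                   notch_hz: float | None = None) -> TFGrid:
    """Multitaper spectrogram of one channel over all trials of an epoch set.

    Each window is detrended, multiplied by each DPSS taper, Fourier
    transformed with zero-padding to the ~1.5 Hz grid, and the squared
    moduli are averaged across tapers and scaled to one-sided PSD.
    Time stamps are window centers; the first window starts at epoch start.
    """
    params = params or MTParams()
    fs = epochs.fs
    params.validate(fs)
    x = np.asarray(epochs.data[:, channel, :], dtype=float)
    if notch_hz is not None:
        b, a = signal.iirnotch(notch_hz, Q=30.0, fs=fs)
        x = signal.filtfilt(b, a, x, axis=-1)
    n_win = int(round(params.window_s * fs))
    step = int(round(params.step_s * fs))
    starts = _window_starts(x.shape[-1], n_win, step)
    nfft = params.nfft(fs)
    freqs_all = np.fft.rfftfreq(nfft, 1.0 / fs)
    fsel = freqs_all <= params.fmax_hz + 1e-9
    tapers, ratios = dpss_tapers(n_win, params.nw, params.n_tapers)
    if params.eigen_weighting:
        w = ratios / ratios.sum()
    else:
        w = np.full(params.n_tapers, 1.0 / params.n_tapers)
    times = epochs.times[starts] + params.window_s / 2.0

    n_trials = x.shape[0]
    out = np.empty((n_trials, starts.size, int(fsel.sum())))
    # chunk trials to bound the trials x windows x tapers x freqs workspace
    chunk = max(1, int(2e7 // (starts.size * params.n_tapers * nfft // 2)))
    for lo in range(0, n_trials, chunk):
        xa = x[lo:lo + chunk]
        wins = sliding_window_view(xa, n_win, axis=-1)[:, starts, :]
        wins = signal.detrend(wins, axis=-1, type="linear")
        tap = wins[:, :, None, :] * tapers[None, None, :, :]
        spec = np.fft.rfft(tap, n=nfft, axis=-1)
        psd = (spec.real ** 2 + spec.imag ** 2)
        psd = np.tensordot(psd, w, axes=([2], [0]))
        # one-sided PSD scaling (unit-norm tapers): x2 except DC/Nyquist
        psd *= 2.0 / fs
        psd[..., 0] /= 2.0
        if nfft % 2 == 0:
            psd[..., -1] /= 2.0
        out[lo:lo + chunk] = psd[..., fsel]
    return TFGrid(times=times, freqs=freqs_all[fsel], power=out,
                  channel_id=str(channel), alignment_event=epochs.alignment_event,
                  window_s=params.window_s)


def baseline_power(tf: TFGrid, trial_set=None,
                   baseline_window: tuple = (-0.3, 0.0)) -> np.ndarray:
    """Per-frequency mean power over trials and windows fully inside baseline."""
    if tf.units != "power":
        raise ValidationError("baseline_power expects a raw-power TFGrid")
    half = tf.window_s / 2.0
    a, b = baseline_window
    sel = (tf.times - half >= a - 1e-9) & (tf.times + half <= b + 1e-9)
    if not sel.any():
        raise ValidationError(
            f"no spectrogram window lies fully inside the baseline {baseline_window}")
    p = tf.power if trial_set is None else tf.power[np.asarray(trial_set)]
    return p[:, sel, :].mean(axis=(0, 1))


def relative_spectrogram(tf: TFGrid, baseline: np.ndarray,
                         reduce: str = "per-trial") -> TFGrid:
    """10*log10(P/B) per bin; negative values mean below-baseline power.

    ``reduce='per-trial'`` converts each trial's power (the input to
    per-bin permutation tests and decoding features); ``reduce='mean'``
    first averages power across trials and returns a single-"trial"
    condition-average relative map (the unbiased display/time-course
    convention: the log of a mean, not the mean of logs).
    """
    baseline = np.asarray(baseline, dtype=float)
    if baseline.shape != (tf.freqs.size,):
        raise ValidationError("baseline must be a per-frequency vector")
    bad = np.where(baseline <= 0)[0]
    if bad.size:
        raise ValidationError(
            f"baseline power is not positive at {tf.freqs[bad][:5]} Hz")
    if reduce == "mean":
        p = tf.power.mean(axis=0, keepdims=True)
    elif reduce == "per-trial":
        p = tf.power
    else:
        raise ValidationError(f"unknown reduce mode {reduce!r}")
    db = 10.0 * np.log10(p / baseline[None, None, :])
    return replace(tf, power=db, units="dB")


def band_timecourse(rel: TFGrid, band: BandDef | str, reduce: str = "mean"):
    """Unweighted mean relative power over grid frequencies inside the band.

    ``reduce='mean'`` averages over trials (returns a time series);
    ``reduce='per-trial'`` returns a trials x times array.
    """
    if isinstance(band, str):
        band = BANDS[band]
    sel = (rel.freqs >= band.lo - 1e-9) & (rel.freqs <= band.hi + 1e-9)
    if not sel.any():
        raise ValidationError(
            f"band {band.name} [{band.lo}, {band.hi}] Hz does not intersect the grid")
    tc = rel.power[:, :, sel].mean(axis=2)
    if reduce == "per-trial":
        return tc
    if reduce == "mean":
        return tc.mean(axis=0)
    raise ValidationError(f"unknown reduce mode {reduce!r}")
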