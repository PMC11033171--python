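"""RegOLE decoding of the previous trial's correct target from beta power.

The decoder is a regularized optimal linear estimator: two independent
ridge regressions map the channel-wise beta feature vector to the
sign-coded x and y coordinates of the previous correct target, minimizing
||W R + b - C||^2 + lambda ||W||^2 in closed form (features and targets
centered, the intercept absorbing the means).

Accuracy is estimated by balanced resampling runs: each run draws 8 trials
per target location (32 in total); every leave-one-trial-out fold removes
one random trial from each of the other three locations so training is
always 28 trials, 7 per location.  Joint accuracy (both axes correct,
chance 1/4) is reported alongside per-axis accuracies.  Significance is
the upper tail of a label-permutation null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .session import ValidationError
from .spectral import TFGrid, BandDef, BANDS, band_timecourse

__all__ = [
    "RegOLEDecoder",
    "DecoderModel",
    "DecodingConfig",
    "DecodingResult",
    "regole_fit",
    "regole_classify",
    "build_feature_matrix",
    "run_decoding",
    "permutation_significance",
]


class RegOLEDecoder(BaseEstimator):
    """Ridge-penalized linear sign decoder, one regression per target axis.

    Parameters
    ----------
    lam : float
        Tikhonov regularization weight (lambda >= 0).

    Attributes (after fit)
    ----------------------
    W_ : ndarray, (n_axes, n_features)
    b_ : ndarray, (n_axes,)
    """

    def __init__(self, lam: float = 1.0):
        self.lam = lam

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if X.ndim != 2 or X.shape[0] != Y.shape[0]:
            raise ValidationError("X must be n_trials x n_features matching y")
        if X.shape[0] < 2:
            raise ValidationError("need at least 2 training trials")
        if self.lam < 0:
            raise ValidationError("lam must be non-negative")
        xm = X.mean(axis=0)
        ym = Y.mean(axis=0)
        Xc = X - xm
        Yc = Y - ym
        G = Xc.T @ Xc + self.lam * np.eye(X.shape[1])
        if self.lam == 0 and np.linalg.matrix_rank(Xc) < X.shape[1]:
            raise ValidationError(
                "degenerate features make the unregularized problem singular; "
                "set lam > 0")
        Wt = np.linalg.solve(G, Xc.T @ Yc)  # n_features x n_axes
        self.W_ = Wt.T
        self.b_ = ym - self.W_ @ xm
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.W_.shape[1]:
            raise ValidationError(
                f"expected {self.W_.shape[1]} features, got {X.shape[1]}")
        return X @ self.W_.T + self.b_

    def predict(self, X):
        """Sign of each axis's linear output; sign(0) maps to +1."""
        d = self.decision_function(X)
        return np.where(d >= 0, 1, -1)


@dataclass
class DecoderModel:
    """Functional view of a fitted RegOLE: C = W r + b per axis."""

    W: np.ndarray   # n_axes x n_channels
    b: np.ndarray   # n_axes
    lam: float


def regole_fit(R: np.ndarray, C: np.ndarray, lam: float = 1.0) -> DecoderModel:
    """Fit RegOLE from a channels x trials feature matrix R and 2 x trials
    sign-coded targets C."""
    R = np.asarray(R, dtype=float)
    C = np.asarray(C, dtype=float)
    est = RegOLEDecoder(lam=lam).fit(R.T, C.T)
    return DecoderModel(W=est.W_, b=est.b_, lam=lam)


def regole_classify(model: DecoderModel, r: np.ndarray) -> tuple:
    """Classify one feature vector into (x, y) in {-1, +1}^2."""
    r = np.asarray(r, dtype=float).ravel()
    if r.size != model.W.shape[1]:
        raise ValidationError(
            f"expected {model.W.shape[1]} features, got {r.size}")
    d = model.W @ r + model.b
    out = np.where(d >= 0, 1, -1)
    return int(out[0]), int(out[1])


def build_feature_matrix(rel_grids: dict, time_bin: float,
                         band: BandDef | str = "beta") -> np.ndarray:
    """channels x trials band-mean relative power at one analysis time bin.

    ``rel_grids`` maps channel id to that channel's per-trial relative
    (dB) :class:`TFGrid`; all grids must share the trial set and time base.
    """
    if isinstance(band, str):
        band = BANDS[band]
    rows = []
    n_trials = None
    for ch, tf in rel_grids.items():
        if not isinstance(tf, TFGrid):
            raise ValidationError(f"channel {ch}: expected a TFGrid")
        j = int(np.argmin(np.abs(tf.times - time_bin)))
        if abs(tf.times[j] - time_bin) > 0.5 * np.median(np.diff(tf.times)) + 1e-9:
            raise ValidationError(
                f"time bin {time_bin} s is not on the analysis grid")
        tc = band_timecourse(tf, band, reduce="per-trial")
        if n_trials is None:
            n_trials = tc.shape[0]
        elif tc.shape[0] != n_trials:
            raise ValidationError("channels disagree on the trial set")
        rows.append(tc[:, j])
    if not rows:
        raise ValidationError("no channels given")
    return np.vstack(rows)


@dataclass
class DecodingConfig:
    """Resampling and significance settings for the decoding analysis."""

    per_location: int = 8
    n_runs: int = 1000
    n_perm: int = 1000
    n_runs_null: int = 100
    tail: float = 0.001
    lam: float = 1.0
    standardize: bool = True
    time_bins: tuple = (-0.20, -0.15, -0.10, -0.05, 0.0, 0.05)
    band: str = "beta"
    seed: int = 0

    def __post_init__(self):
        if self.per_location < 2:
            raise ValidationError("per_location must be at least 2")
        if not (0 < self.tail < 0.5):
            raise ValidationError("tail must lie in (0, 0.5)")


@dataclass
class DecodingResult:
    time_bins: np.ndarray
    accuracy: np.ndarray            # joint (both axes), mean over runs
    acc_x: np.ndarray
    acc_y: np.ndarray
    null_quantile: np.ndarray | None = None
    significant: np.ndarray | None = None
    null_accuracies: np.ndarray | None = None  # n_perm x n_bins
    train_fold_sizes: list = field(default_factory=list)


def _loc_index(labels: np.ndarray) -> np.ndarray:
    return ((labels[:, 0] > 0).astype(int) * 2 + (labels[:, 1] > 0).astype(int))


def _decode_bin(X: np.ndarray, labels: np.ndarray, cfg: DecodingConfig,
                rng: np.random.Generator, n_runs: int,
                fold_sizes: list | None = None) -> tuple:
    """Mean joint/x/y accuracy over balanced leave-one-trial-out runs."""
    locs = _loc_index(labels)
    by_loc = [np.where(locs == l)[0] for l in range(4)]
    for l, idx in enumerate(by_loc):
        if idx.size < cfg.per_location:
            raise ValidationError(
                f"location {l} has {idx.size} trials, need {cfg.per_location}")
    acc = np.zeros(3)
    n_total = 4 * cfg.per_location
    for _ in range(n_runs):
        drawn = [rng.choice(idx, cfg.per_location, replace=False)
                 for idx in by_loc]
        pool = np.concatenate(drawn)
        pool_locs = np.repeat(np.arange(4), cfg.per_location)
        hits = np.zeros(3)
        for t in range(n_total):
            test = pool[t]
            keep = np.ones(n_total, dtype=bool)
            keep[t] = False
            # rebalance: drop one random trial from each other location
            for l in range(4):
                if l == pool_locs[t]:
                    continue
                cand = np.where(keep & (pool_locs == l))[0]
                keep[rng.choice(cand)] = False
            tr = pool[keep]
            if fold_sizes is not None:
                fold_sizes.append((tr.size, tuple(np.bincount(pool_locs[keep],
                                                              minlength=4))))
            Xtr, Xte = X[tr], X[test][None, :]
            if cfg.standardize:
                mu = Xtr.mean(axis=0)
                sd = Xtr.std(axis=0)
                sd[sd == 0] = 1.0
                Xtr = (Xtr - mu) / sd
                Xte = (Xte - mu) / sd
            est = RegOLEDecoder(lam=cfg.lam).fit(Xtr, labels[tr])
            pred = est.predict(Xte)[0]
            ok = pred == labels[test]
            hits += (ok.all(), ok[0], ok[1])
        acc += hits / n_total
    return acc / n_runs


def run_decoding(features, labels, config: DecodingConfig | None = None,
                 rng=None, n_runs: int | None = None,
                 record_folds: bool = False) -> DecodingResult:
    """Balanced leave-one-trial-out decoding accuracy per time bin.

    ``features`` is a n_bins x n_trials x n_channels array (or a dict
    time_bin -> n_trials x n_channels); ``labels`` is n_trials x 2 in
    {-1, +1}.
    """
    config = config or DecodingConfig()
    if isinstance(features, dict):
        bins = np.array(sorted(features), dtype=float)
        feats = np.stack([np.asarray(features[b], dtype=float) for b in bins])
    else:
        feats = np.asarray(features, dtype=float)
        if feats.ndim == 2:
            feats = feats[None, :, :]
        bins = np.asarray(config.time_bins[:feats.shape[0]], dtype=float)
        if bins.size != feats.shape[0]:
            bins = np.arange(feats.shape[0], dtype=float)
    labels = np.asarray(labels)
    if labels.shape != (feats.shape[1], 2):
        raise ValidationError("labels must be n_trials x 2")
    if not np.all(np.isin(labels, (-1, 1))):
        raise ValidationError("labels must be sign-coded in {-1, +1}")
    rng = rng if isinstance(rng, np.random.Generator) else \
        np.random.default_rng(config.seed if rng is None else rng)
    n_runs = n_runs or config.n_runs
    fold_sizes: list = [] if record_folds else None  # type: ignore[assignment]
    accs = np.array([_decode_bin(feats[k], labels, config, rng, n_runs,
                                 fold_sizes)
                     for k in range(feats.shape[0])])
    return DecodingResult(time_bins=bins, accuracy=accs[:, 0],
                          acc_x=accs[:, 1], acc_y=accs[:, 2],
                          train_fold_sizes=fold_sizes or [])


def permutation_significance(features, labels, config: DecodingConfig | None = None
                             ) -> DecodingResult:
    """Label-permutation null for the decoding accuracy per time bin.

    The real accuracy uses ``n_runs`` runs; each of ``n_perm`` label
    permutations (shuffled across trials, preserving counts) is scored by
    the same procedure at ``n_runs_null`` runs.  A bin is significant iff
    the real accuracy reaches the (1 - tail) empirical null quantile.
    """
    import warnings
    config = config or DecodingConfig()
    if config.n_perm < 20:
        warnings.warn("fewer than 20 permutations: the null tail quantile is "
                      "unstable", stacklevel=2)
    labels = np.asarray(labels)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    real = run_decoding(features, labels, config, rng=rng)
    null = np.empty((config.n_perm, real.time_bins.size))
    for p in range(config.n_perm):
        perm = rng.permutation(labels.shape[0])
        res = run_decoding(features, labels[perm], config, rng=rng,
                           n_runs=config.n_runs_null)
        null[p] = res.accuracy
    q = np.quantile(null, 1.0 - config.tail, axis=0)
    real.null_accuracies = null
    real.null_quantile = q
    real.significant = real.accuracy >= q
    return real
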