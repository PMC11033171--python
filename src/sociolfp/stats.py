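"""Permutation statistics for time-frequency maps, FDR step-up, Kruskal-Wallis.

Per-bin differences between two trial groups are tested by relabeling
permutations of the pooled trials (default: one relabeling per permutation
shared across all bins, preserving the spatial correlation of the null).
Multiple comparisons are corrected by the FDR step-up rule: order the
p-values ascending and reject all bins with p <= p(k) for the largest k
with p(k) <= alpha*k/m (Benjamini-Hochberg form; ``method='by'`` divides
alpha by the harmonic sum, the Benjamini-Yekutieli variant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .session import ValidationError

__all__ = [
    "DiffMap",
    "perm_diff_test",
    "perm_diff_map",
    "fdr_step_up",
    "apply_fdr",
    "significance_map",
    "kruskal_wallis",
]


@dataclass
class DiffMap:
    """Signed time-frequency difference map with per-bin permutation p-values."""

    diff: np.ndarray          # times x freqs, mean(A) - mean(B)
    pmap: np.ndarray          # times x freqs
    mask: np.ndarray | None   # boolean, after FDR
    alpha: float
    n_perm: int
    groups: tuple = ("A", "B")
    times: np.ndarray | None = None
    freqs: np.ndarray | None = None
    fdr_method: str = "as_printed"


def _perm_null_diffs(pooled: np.ndarray, na: int, n_perm: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Null mean differences for relabelings shared across trailing axes."""
    n = pooled.shape[0]
    nb = n - na
    total = pooled.sum(axis=0)
    flat = pooled.reshape(n, -1)
    m = flat.shape[1]
    out = np.empty((n_perm, m))
    chunk = max(1, int(2e7 // max(1, na * m)))
    for lo in range(0, n_perm, chunk):
        k = min(chunk, n_perm - lo)
        idx = np.argsort(rng.random((k, n)), axis=1)[:, :na]
        sum_a = flat[idx].sum(axis=1)
        out[lo:lo + k] = sum_a / na - (total.ravel()[None, :] - sum_a) / nb
    return out


def perm_diff_test(a, b, n_perm: int = 5000, seed=None) -> tuple:
    """Two-sided permutation test of the difference in means.

    Returns ``(diff, p)`` with ``p = (1 + #{|d*| >= |diff|}) / (n_perm + 1)``.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 values")
    rng = np.random.default_rng(seed)
    diff = a.mean() - b.mean()
    null = _perm_null_diffs(np.concatenate([a, b])[:, None], a.size, n_perm, rng)
    count = int((np.abs(null[:, 0]) >= abs(diff) - 1e-12).sum())
    return float(diff), (1 + count) / (n_perm + 1)


def perm_diff_map(A: np.ndarray, B: np.ndarray, n_perm: int = 5000, seed=None,
                  shared_relabeling: bool = True,
                  groups: tuple = ("A", "B"), times=None, freqs=None) -> DiffMap:
    """Per-bin permutation test between two trials x times x freqs arrays.

    By default one relabeling is drawn per permutation and applied to every
    bin; ``shared_relabeling=False`` shuffles each bin independently (with
    per-bin derived seeds).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape[1:] != B.shape[1:]:
        raise ValidationError(f"grid mismatch: {A.shape[1:]} vs {B.shape[1:]}")
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValidationError("each group needs at least 2 trials")
    shape = A.shape[1:]
    na = A.shape[0]
    nb = B.shape[0]
    diff = A.mean(axis=0) - B.mean(axis=0)
    pooled = np.concatenate([A, B], axis=0)
    if shared_relabeling:
        rng = np.random.default_rng(seed)
        null = _perm_null_diffs(pooled, na, n_perm, rng)
        count = (np.abs(null) >= np.abs(diff).ravel()[None, :] - 1e-12).sum(axis=0)
    else:
        flat = pooled.reshape(na + nb, -1)
        count = np.empty(flat.shape[1], dtype=int)
        ss = np.random.SeedSequence(seed)
        child = ss.spawn(flat.shape[1])
        for j in range(flat.shape[1]):
            rng_j = np.random.default_rng(child[j])
            null_j = _perm_null_diffs(flat[:, j:j + 1], na, n_perm, rng_j)
            count[j] = (np.abs(null_j[:, 0]) >= abs(diff.ravel()[j]) - 1e-12).sum()
    pmap = ((1 + count) / (n_perm + 1)).reshape(shape)
    return DiffMap(diff=diff, pmap=pmap, mask=None, alpha=np.nan, n_perm=n_perm,
                   groups=groups,
                   times=None if times is None else np.asarray(times),
                   freqs=None if freqs is None else np.asarray(freqs))


def fdr_step_up(p, alpha: float = 0.01, method: str = "as_printed") -> np.ndarray:
    """Boolean rejection mask of the FDR step-up rule, preserving input shape."""
    p = np.asarray(p, dtype=float)
    if p.size < 1:
        raise ValidationError("need at least one p-value")
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if method == "by":
        alpha = alpha / np.sum(1.0 / np.arange(1, p.size + 1))
    elif method != "as_printed":
        raise ValidationError(f"unknown FDR method {method!r}")
    flat = p.ravel()
    m = flat.size
    order = np.sort(flat)
    ks = np.nonzero(order <= alpha * np.arange(1, m + 1) / m)[0]
    if ks.size == 0:
        return np.zeros_like(p, dtype=bool)
    return p <= order[ks[-1]]


def apply_fdr(dm: DiffMap, alpha: float = 0.01, method: str = "as_printed") -> DiffMap:
    """Attach the FDR rejection mask to a difference map (in place)."""
    dm.mask = fdr_step_up(dm.pmap, alpha=alpha, method=method)
    dm.alpha = alpha
    dm.fdr_method = method
    return dm


def significance_map(dm: DiffMap) -> np.ndarray:
    """Signed difference where the FDR mask rejects, zero elsewhere."""
    if dm.mask is None:
        raise ValidationError("apply_fdr before requesting the significance map")
    return np.where(dm.mask, dm.diff, 0.0)


def kruskal_wallis(groups) -> tuple:
    """Kruskal-Wallis H (midrank ties, tie-corrected), df, chi-square p."""
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    if any(g.size < 1 for g in groups):
        raise ValidationError("every group needs at least one observation")
    n_total = sum(g.size for g in groups)
    if n_total < 3:
        raise ValidationError("need at least 3 observations in total")
    df = len(groups) - 1
    allv = np.concatenate(groups)
    if np.all(allv == allv[0]):
        return 0.0, df, 1.0
    h, p = sstats.kruskal(*groups)
    return float(h), df, float(p)
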