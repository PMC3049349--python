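"""Familywise control of significance across time.

Point-by-point randomization tests inflate false positives across the
many time points of an ERP epoch.  Two overall statistics, both derived
from the very randomization runs that produced the point-wise p-values
(no fresh randomization), control this:

* the *count test*: is the observed number of significant time points
  larger than expected when the null holds everywhere?
* the *duration threshold*: how long must a continuous stretch of
  significant time points be before stretches that long become unlikely
  (probability ``alpha``) under the null?  Analogous to cluster-size
  statistics in neuroimaging.

Both need, for every randomization run, p-values computed *as if that
run were the observed data*: the pseudo-P matrix ranks each run's
statistic against all remaining runs, per time point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "pseudo_p_matrix",
    "count_significance_test",
    "duration_threshold",
    "apply_duration_mask",
    "max_run_lengths",
    "GlobalInference",
    "infer_global",
    "global_table",
]


def pseudo_p_matrix(null_s: np.ndarray) -> np.ndarray:
    """Per-run, per-time-point p-values of the null statistics.

    ``p'(r, t) = (1 + #{r' != r : s(r', t) >= s(r, t)}) / n_runs`` — the
    run's statistic ranked against the remaining runs, with the run
    itself counted once so p' is never zero.  Within each time point the
    multiset of p' values depends only on ties, not on run order.
    """
    null_s = np.asarray(null_s, dtype=float)
    if null_s.ndim != 2 or null_s.shape[0] < 2:
        raise ValueError("null_s must be (n_runs >= 2, n_time)")
    n_runs = null_s.shape[0]
    r_min = rankdata(null_s, method="min", axis=0)  # 1 + #{strictly smaller}
    return (n_runs - r_min + 1) / n_runs


def count_significance_test(p_obs: np.ndarray, pseudo_p: np.ndarray,
                            alpha: float) -> float:
    """Global p for the observed count of significant time points.

    The observed count ``k = #{t : p_obs(t) < alpha}`` is compared
    against the null counts ``k_r`` obtained from the pseudo-P rows;
    ``p = (1 + #{r : k_r >= k}) / (1 + n_runs)``.
    """
    p_obs = np.asarray(p_obs, dtype=float)
    pseudo_p = np.asarray(pseudo_p, dtype=float)
    if p_obs.shape[0] != pseudo_p.shape[1]:
        raise ValueError("p_obs and pseudo_p must share the time axis")
    k = int(np.count_nonzero(p_obs < alpha))
    k_r = np.count_nonzero(pseudo_p < alpha, axis=1)
    return float((1 + np.count_nonzero(k_r >= k)) / (1 + pseudo_p.shape[0]))


def max_run_lengths(significant: np.ndarray) -> np.ndarray:
    """Longest run of consecutive True per row of a 2-D boolean array."""
    sig = np.asarray(significant, dtype=bool)
    if sig.ndim == 1:
        sig = sig[None, :]
    n_rows, n_t = sig.shape
    # flatten with a separating False between rows, then scan run lengths
    padded = np.zeros((n_rows, n_t + 1), dtype=bool)
    padded[:, :n_t] = sig
    flat = padded.ravel()
    d = np.diff(flat.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if flat[0]:
        starts = np.r_[0, starts]
    lengths = ends - starts
    out = np.zeros(n_rows, dtype=int)
    if lengths.size:
        rows = starts // (n_t + 1)
        np.maximum.at(out, rows, lengths)
    return out


def duration_threshold(pseudo_p: np.ndarray, alpha: float) -> int:
    """Minimal duration (in samples) of a globally significant stretch.

    For every randomization run the longest stretch of consecutive
    pseudo-P values below ``alpha`` is computed.  The threshold is the
    shortest null-attained duration that is reached or exceeded by at
    most an ``alpha`` share of the runs — the empirical ``(1 - alpha)``
    quantile of the per-run maxima, with ties resolved so that the
    exceedance probability of the threshold stays at or below ``alpha``
    (a plain positional quantile can sit inside a heavy tie and be
    exceeded far more often than ``alpha``).  Never less than one
    sample.  Observed periods at least this long are unlikely under the
    null at level ``alpha``, which gives the duration mask familywise
    control over time.
    """
    pseudo_p = np.asarray(pseudo_p, dtype=float)
    if pseudo_p.ndim != 2 or pseudo_p.shape[0] < 2:
        raise ValueError("pseudo_p must be (n_runs >= 2, n_time)")
    maxima = max_run_lengths(pseudo_p < alpha)
    n_runs = maxima.size
    # smallest duration d with #{maxlen >= d} <= alpha * n_runs ...
    sorted_max = np.sort(maxima)
    n_exceed = n_runs - np.searchsorted(sorted_max, np.arange(
        sorted_max[-1] + 2), side="left")
    d0 = int(np.argmax(n_exceed <= alpha * n_runs))
    # ... rounded up to the next duration the null actually attained
    attained = sorted_max[np.searchsorted(sorted_max, d0, side="left"):]
    thr = int(attained[0]) if attained.size else d0
    return max(thr, 1)


def apply_duration_mask(p_obs: np.ndarray, threshold: int,
                        alpha: float) -> list:
    """Maximal intervals of sub-alpha p-values at least ``threshold`` long.

    Returns half-open sample intervals ``(start, stop)``.  Boundary
    samples with p exactly equal to alpha count as non-significant.
    """
    p_obs = np.asarray(p_obs, dtype=float)
    sig = p_obs < alpha
    padded = np.r_[False, sig, False].astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return [(int(a), int(b)) for a, b in zip(starts, stops)
            if b - a >= threshold]


@dataclass
class GlobalInference:
    """Overall statistics of one effect across the analysis window."""

    effect_id: str
    count_p: float
    duration_threshold_samples: int
    duration_threshold_ms: float
    clusters: list            # half-open (start, stop) sample intervals
    alpha: float

    def to_dict(self) -> dict:
        return {"effect_id": self.effect_id, "count_p": self.count_p,
                "duration_threshold_samples": self.duration_threshold_samples,
                "duration_threshold_ms": self.duration_threshold_ms,
                "clusters": [list(c) for c in self.clusters],
                "alpha": self.alpha}

    @classmethod
    def from_dict(cls, d: dict) -> "GlobalInference":
        return cls(d["effect_id"], d["count_p"],
                   d["duration_threshold_samples"], d["duration_threshold_ms"],
                   [tuple(c) for c in d["clusters"]], d["alpha"])


def infer_global(result, alpha: float | None = None) -> dict:
    """Count test, duration threshold and surviving clusters per effect.

    ``result`` is a :class:`~topostats.randomization.RandomizationResult`;
    the overall statistics re-use its randomization runs.  Returns a dict
    keyed by effect id.
    """
    alpha = result.options.alpha if alpha is None else alpha
    times = np.asarray(result.times_ms, dtype=float)
    dt_ms = float(times[1] - times[0]) if times.size > 1 else 0.0
    out = {}
    for eff in result.effects:
        pseudo = pseudo_p_matrix(result.null[eff.id])
        count_p = count_significance_test(result.p[eff.id], pseudo, alpha)
        thr = duration_threshold(pseudo, alpha)
        clusters = apply_duration_mask(result.p[eff.id], thr, alpha)
        out[eff.id] = GlobalInference(
            eff.id, count_p, thr, thr * dt_ms, clusters, alpha)
    return out


def global_table(inference: dict, result=None):
    """Tabular export of per-effect global statistics."""
    import pandas as pd
    times = None if result is None else np.asarray(result.times_ms)
    rows = []
    for eid, gi in inference.items():
        spans = "; ".join(
            (f"{times[a]:g}..{times[b - 1]:g} ms" if times is not None
             else f"{a}..{b - 1}") for a, b in gi.clusters) or "-"
        rows.append((eid, gi.count_p, gi.duration_threshold_samples,
                     gi.duration_threshold_ms, len(gi.clusters), spans))
    return pd.DataFrame(rows, columns=[
        "effect", "count_test_p", "duration_threshold_samples",
        "duration_threshold_ms", "n_clusters", "clusters"])
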