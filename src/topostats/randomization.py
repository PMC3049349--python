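"""The randomization engine: TANOVA and TANCOVA.

For every testable effect of a design the engine computes the observed
global effect strength ``s(t)`` at every time point of the analysis
window, builds the null distribution of ``s`` by repeatedly shuffling
the condition and/or group labels (one shuffle per randomization run,
re-used across all time points so that the null preserves the temporal
structure the overall count/duration statistics rely on), and converts
the observed values into time point-wise p-values.

The statistic is the generalized GFP of the effect's (centered) marginal
mean maps; for covariate effects it is the GFP of the covariance map of
the data with the permuted predictor.  Data can be analyzed raw, after
scaling every individual map to unit GFP (L2 normalization — the
recommended way to isolate topographic from amplitude effects), or with
the legacy "dissimilarity" normalization applied at the level of the
condition/group grand means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .data_io import ErpDataset, apply_average_reference
from .designs import (BetweenDesign, EffectSpec, WithinDesign,
                      draw_relabelings, effect_structure, enumerate_effects,
                      enumerate_relabelings)

__all__ = [
    "RandomizationOptions",
    "RandomizationResult",
    "pointwise_p",
    "run_tanova",
    "run_tancova",
    "averaged_window_tanova",
    "exact_pointwise_p",
    "result_table",
]

_NORMALIZATIONS = ("none", "l2", "dissimilarity")


@dataclass(frozen=True)
class RandomizationOptions:
    """Parameters of one randomization analysis.

    ``n_runs`` randomization runs estimate the null; 1000 runs give an
    accurate estimate of significance at the 5% level, 5000 at the 1%
    level.  ``alpha`` is the significance threshold used for display and
    for the count/duration statistics.  ``window`` restricts the
    analysis to a half-open sample interval ``(start, stop)``; ``None``
    analyzes all time points.  ``seed`` makes every run bit-reproducible;
    each effect receives its own deterministic substream, so a single
    effect can be recomputed independently with identical results.
    """

    n_runs: int = 1000
    alpha: float = 0.05
    normalization: str = "l2"
    seed: int = 0
    window: tuple | None = None

    def __post_init__(self):
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.normalization not in _NORMALIZATIONS:
            raise ValueError(
                f"normalization must be one of {_NORMALIZATIONS}")

    def to_dict(self) -> dict:
        return {"n_runs": self.n_runs, "alpha": self.alpha,
                "normalization": self.normalization, "seed": self.seed,
                "window": None if self.window is None else list(self.window)}

    @classmethod
    def from_dict(cls, d: dict) -> "RandomizationOptions":
        w = d.get("window")
        return cls(d["n_runs"], d["alpha"], d["normalization"], d["seed"],
                   None if w is None else tuple(w))


@dataclass
class RandomizationResult:
    """Observed strengths, null matrices and p-values, one set per effect."""

    effects: list
    observed: dict          # effect id -> (T,) observed s
    null: dict              # effect id -> (n_runs, T) null s
    p: dict                 # effect id -> (T,) p-values in (0, 1]
    times_ms: np.ndarray
    options: RandomizationOptions
    statistic: str = "tanova"

    def effect_ids(self) -> list:
        return [e.id for e in self.effects]

    def to_dict(self) -> dict:
        return {
            "effects": [{"id": e.id, "name": e.name,
                         "within_factors": list(e.within_factors),
                         "between": e.between} for e in self.effects],
            "observed": dict(self.observed), "null": dict(self.null),
            "p": dict(self.p), "times_ms": np.asarray(self.times_ms),
            "options": self.options.to_dict(), "statistic": self.statistic,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RandomizationResult":
        effects = [EffectSpec(e["id"], e["name"],
                              tuple(e["within_factors"]), e["between"])
                   for e in d["effects"]]
        return cls(effects, dict(d["observed"]), dict(d["null"]),
                   dict(d["p"]), np.asarray(d["times_ms"]),
                   RandomizationOptions.from_dict(d["options"]),
                   d.get("statistic", "tanova"))


def pointwise_p(observed: float, null) -> float:
    """Randomization p-value of one observed statistic.

    ``p = (1 + #{null >= observed}) / (1 + n_runs)``: the fraction of
    null values at least as large as the observed one, with the observed
    data counted as one realization of its own null so that p is never
    exactly zero.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    return float((1 + np.count_nonzero(null >= observed)) / (1 + null.size))


# ---------------------------------------------------------------------------
# Core computation
# ---------------------------------------------------------------------------

def _select_data(dataset: ErpDataset, within, between,
                 normalization: str, window) -> tuple[np.ndarray, np.ndarray]:
    """Used-subject / included-condition / window view, referenced and
    (for l2) map-wise normalized.  Returns (X, times_ms)."""
    if not dataset.average_referenced:
        dataset = apply_average_reference(dataset)
    subs = (between.used if between is not None
            else np.arange(dataset.n_subjects))
    conds = (within.included if within is not None
             else np.arange(dataset.n_conditions))
    lo, hi = (0, dataset.n_time) if window is None else window
    if not (0 <= lo < hi <= dataset.n_time):
        raise ValueError(f"analysis window {window} outside data range")
    X = dataset.data[np.ix_(subs, conds)][:, :, lo:hi, :].copy()
    if normalization == "l2":
        g = np.sqrt(np.mean(
            (X - X.mean(axis=3, keepdims=True)) ** 2, axis=3))
        if np.any(g <= 0):
            s, c, t = np.unravel_index(int(np.argmin(g)), g.shape)
            raise ValueError(
                "cannot L2-normalize a flat map: subject "
                f"{dataset.subject_labels[subs[s]]!r}, condition "
                f"{dataset.condition_labels[conds[c]]!r}, sample {lo + t}")
        X /= g[..., None]
    return X, dataset.times_ms[lo:hi]


def _effect_geometry(struct, within, n_conditions: int):
    """Within-cell index per included condition and cell multiplicity."""
    if within is None:
        cell_w = np.zeros(n_conditions, dtype=int)
    else:
        cell_w = struct.cell_of_cond
    e_w = struct.n_cells_w
    m_w = cell_w.size // e_w
    return cell_w, e_w, m_w


def _strength_batch(X: np.ndarray, struct, within,
                    cond_source: np.ndarray | None,
                    subject_source: np.ndarray | None,
                    n_batch: int, normalization: str) -> np.ndarray:
    """Effect strength s for a batch of relabelings; shape (n_batch, T)."""
    S, C, T, J = X.shape
    effect = struct.effect
    cell_w, e_w, m_w = _effect_geometry(struct, within, C)
    n_groups = max(struct.n_groups, 1)
    E = e_w * (struct.n_groups if effect.between == "group" else 1)

    r_idx = np.arange(n_batch)[:, None, None]
    s_idx = np.arange(S)[None, :, None]
    if cond_source is None or not effect.within_factors:
        c_src = np.broadcast_to(np.arange(C), (n_batch, S, C))
    else:
        c_src = cond_source

    if effect.between == "group":
        gcodes = struct.group_codes
        counts = np.bincount(gcodes, minlength=struct.n_groups)
        g_rs = gcodes[subject_source]                        # (R, S)
        e_full = g_rs[:, :, None] * e_w + cell_w[None, None, :]
        w = 1.0 / (counts[g_rs][:, :, None] * m_w)
        w = np.broadcast_to(w, (n_batch, S, C))
    elif effect.between == "covariate":
        b = struct.covariate - struct.covariate.mean()
        b_rs = b[subject_source]                             # (R, S)
        e_full = np.broadcast_to(cell_w, (n_batch, S, C))
        w = np.broadcast_to(b_rs[:, :, None] / m_w, (n_batch, S, C))
    else:
        e_full = np.broadcast_to(cell_w, (n_batch, S, C))
        w = np.full((n_batch, S, C), 1.0 / (S * m_w))

    flat = (((r_idx * E + e_full) * S + s_idx) * C + c_src).ravel()
    W = np.bincount(flat, weights=np.broadcast_to(
        w, (n_batch, S, C)).ravel(), minlength=n_batch * E * S * C)
    W = W.reshape(n_batch * E, S * C)

    cm = (W @ X.reshape(S * C, T * J)).reshape(n_batch, E, T, J)

    if normalization == "dissimilarity" and effect.between != "covariate":
        g = np.sqrt(np.mean(
            (cm - cm.mean(axis=3, keepdims=True)) ** 2, axis=3))
        g[g <= 0] = 1.0
        cm = cm / g[..., None]

    cm = np.matmul(struct.centering, cm.reshape(n_batch, E, T * J))
    cm = cm.reshape(n_batch, E, T, J)
    if effect.between == "covariate":
        cm = cm - cm.mean(axis=3, keepdims=True)
    return np.sqrt(np.einsum("retj,retj->rt", cm, cm) / J)


def _observed_cell_maps(dataset, within, between, struct, t: int):
    """Centered (interactions) or raw (main effects) cell means at one t.

    Returns an (n_cells, n_sensors) array; used by
    :func:`topostats.designs.cell_means`.
    """
    effect = struct.effect
    X, _ = _select_data(dataset, within, between, "none", (t, t + 1))
    S, C, T, J = X.shape
    cell_w, e_w, m_w = _effect_geometry(struct, within, C)
    E = e_w * (struct.n_groups if effect.between == "group" else 1)
    cm = np.zeros((E, J))
    if effect.between == "group":
        gcodes = struct.group_codes
        counts = np.bincount(gcodes, minlength=struct.n_groups)
        if np.any(counts == 0):
            raise ValueError("a group cell is empty (all subjects excluded)")
        for s in range(S):
            for c in range(C):
                e = gcodes[s] * e_w + cell_w[c]
                cm[e] += X[s, c, 0] / (counts[gcodes[s]] * m_w)
    elif effect.between == "covariate":
        b = struct.covariate - struct.covariate.mean()
        for s in range(S):
            for c in range(C):
                cm[cell_w[c]] += b[s] * X[s, c, 0] / m_w
    else:
        for s in range(S):
            for c in range(C):
                cm[cell_w[c]] += X[s, c, 0] / (S * m_w)
    if effect.is_interaction:
        cm = struct.centering @ cm
    return cm


def _run_effect(X, within, between, effect, options, rng) -> dict:
    """Observed s(t), null matrix and p(t) for one effect."""
    struct = effect_structure(within, between, effect)
    S, C, T, J = X.shape

    identity = np.broadcast_to(np.arange(C), (1, S, C))
    subj_id = (np.arange(len(between.used))[None, :]
               if effect.between is not None else None)
    observed = _strength_batch(X, struct, within, identity, subj_id, 1,
                               options.normalization)[0]

    n_runs = options.n_runs
    null = np.empty((n_runs, T))
    # keep the scatter/matmul working set bounded
    chunk = max(1, int(2.5e7 / (max(struct.n_cells, 1) * T * J)))
    done = 0
    while done < n_runs:
        n = min(chunk, n_runs - done)
        cond_src, subj_src = draw_relabelings(
            within, between, effect, S, rng, n)
        null[done:done + n] = _strength_batch(
            X, struct, within, cond_src, subj_src, n, options.normalization)
        done += n

    count_ge = np.count_nonzero(null >= observed[None, :], axis=0)
    p = (1.0 + count_ge) / (1.0 + n_runs)
    return {"observed": observed, "null": null, "p": p}


def _run(dataset, within, between, options, statistic: str):
    if within is None and between is None:
        raise ValueError("need a within and/or between design")
    if options.n_runs < 1000 and options.alpha <= 0.05:
        warnings.warn(
            f"{options.n_runs} randomization runs may be too few for an "
            f"accurate significance estimate at the {options.alpha:g} level "
            "(1000 runs are recommended at the 5% level)", stacklevel=3)
    X, times = _select_data(dataset, within, between,
                            options.normalization, options.window)
    effects = enumerate_effects(within, between)
    seeds = np.random.SeedSequence(options.seed).spawn(len(effects))
    observed, null, p = {}, {}, {}
    for effect, seed in zip(effects, seeds):
        out = _run_effect(X, within, between, effect, options,
                          np.random.default_rng(seed))
        observed[effect.id] = out["observed"]
        null[effect.id] = out["null"]
        p[effect.id] = out["p"]
    return RandomizationResult(effects, observed, null, p, times, options,
                               statistic)


def run_tanova(dataset: ErpDataset, within: WithinDesign | None,
               between: BetweenDesign | None = None,
               options: RandomizationOptions | None = None
               ) -> RandomizationResult:
    """Time point-wise TANOVA over all effects of the design.

    For each effect and time point the observed effect strength is
    compared against ``n_runs`` label shufflings; the same shuffle is
    applied across all time points of a run.  If a continuous between
    design is supplied, the covariate terms are computed as TANCOVAs.
    """
    options = options or RandomizationOptions()
    stat = ("tancova" if between is not None and between.mode == "continuous"
            else "tanova")
    return _run(dataset, within, between, options, stat)


def run_tancova(dataset: ErpDataset, within: WithinDesign | None,
                covariate: BetweenDesign,
                options: RandomizationOptions | None = None
                ) -> RandomizationResult:
    """TANCOVA: the between term is a continuous per-subject predictor.

    The statistic of the covariate effects is the GFP of the covariance
    map of the (per-effect centered) maps with the mean-centered
    predictor; the null permutes the predictor values across subjects.
    """
    if covariate is None or covariate.mode != "continuous":
        raise ValueError("run_tancova requires a continuous between design")
    options = options or RandomizationOptions()
    return _run(dataset, within, covariate, options, "tancova")


def averaged_window_tanova(dataset: ErpDataset, within, between,
                           options: RandomizationOptions | None,
                           window: tuple) -> RandomizationResult:
    """TANOVA on maps averaged across a time window (one p per effect).

    Every subject/condition's maps are averaged across the half-open
    sample window first; the identical statistic pipeline (including
    normalization) then runs on the single averaged map.  With the same
    seed, a one-sample window reproduces the point-wise result at that
    sample exactly.
    """
    options = options or RandomizationOptions()
    lo, hi = window
    if not (0 <= lo < hi <= dataset.n_time):
        raise ValueError(f"window {window} is empty or outside the data")
    avg = dataset.data[:, :, lo:hi, :].mean(axis=2, keepdims=True)
    mid_ms = float(np.mean(dataset.times_ms[lo:hi]))
    ds = replace(dataset, data=avg, onset_latency=mid_ms, sampling_rate=1.0)
    result = _run(ds, within, between, replace(options, window=None),
                  "tanova-averaged")
    result.options = replace(options, window=(lo, hi))  # echo the window
    return result


def exact_pointwise_p(dataset: ErpDataset, within, between,
                      effect: EffectSpec, t: int,
                      normalization: str = "none",
                      limit: int = 2_000_000) -> float:
    """Exact randomization p by exhaustive enumeration of the null orbit.

    Every possible relabeling (including the identity) is evaluated;
    ``p = #{relabelings with s >= s_observed} / #relabelings``.  Only
    feasible for small designs; the reference oracle for the Monte-Carlo
    engine.
    """
    struct = effect_structure(within, between, effect)
    X, _ = _select_data(dataset, within, between, normalization, (t, t + 1))
    S, C, T, J = X.shape
    identity = np.broadcast_to(np.arange(C), (1, S, C))
    subj_id = (np.arange(len(between.used))[None, :]
               if effect.between is not None else None)
    s_obs = _strength_batch(X, struct, within, identity, subj_id, 1,
                            normalization)[0, 0]
    count_ge = 0
    total = 0
    batch_c, batch_s = [], []
    for rel in enumerate_relabelings(within, between, effect, S, limit=limit):
        batch_c.append(rel.cond_source)
        batch_s.append(rel.subject_source)
        if len(batch_c) == 4096:
            count_ge += _exact_batch(X, struct, within, batch_c, batch_s,
                                     normalization, s_obs)
            total += len(batch_c)
            batch_c, batch_s = [], []
    if batch_c:
        count_ge += _exact_batch(X, struct, within, batch_c, batch_s,
                                 normalization, s_obs)
        total += len(batch_c)
    return count_ge / total


def _exact_batch(X, struct, within, batch_c, batch_s, normalization, s_obs):
    cond = np.stack(batch_c)
    subj = None if batch_s[0] is None else np.stack(batch_s)
    s = _strength_batch(X, struct, within, cond, subj, len(batch_c),
                        normalization)[:, 0]
    # tolerate roundoff when permuted statistics tie the observed one
    return int(np.count_nonzero(s >= s_obs - 1e-12))


def result_table(result: RandomizationResult):
    """Long-format table (effect, time_ms, observed s, p) for export."""
    import pandas as pd
    rows = []
    for eff in result.effects:
        for k, t_ms in enumerate(result.times_ms):
            rows.append((eff.id, eff.name, float(t_ms),
                         float(result.observed[eff.id][k]),
                         float(result.p[eff.id][k])))
    return pd.DataFrame(rows, columns=["effect", "effect_name", "time_ms",
                                       "observed_s", "p"])
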