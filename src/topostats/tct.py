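"""Topographic consistency test (TCT).

Before comparing conditions it is worth asking whether, within each
group and condition, the subjects share a common map topography at all:
an effect can only be interpreted where there is evidence for a
consistent pattern of active sources across subjects.

The test statistic at each time point is the GFP of the across-subject
mean map: if subjects share a topography their maps add up coherently
and the mean keeps a high GFP; if topographies are unrelated they cancel
and the mean's GFP shrinks toward the noise floor.  The null is built by
shuffling, independently within every subject, the values of the map
across sensors (one sensor permutation per subject per run, re-used
across time so the null keeps the temporal structure needed for the
duration statistics), which preserves each subject's value distribution
while destroying any shared spatial pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import ErpDataset, apply_average_reference
from .global_inference import (apply_duration_mask, duration_threshold,
                               pseudo_p_matrix)
from .randomization import RandomizationOptions

__all__ = ["TctResult", "topographic_consistency_test", "tct_table"]


@dataclass
class TctResult:
    """Per condition (and group): consistency p(t), mean-map GFP(t), and
    the periods that survive the duration criterion."""

    keys: list               # (group_label, condition_label) tuples
    p: dict                  # key -> (T,) p-values
    gfp_mean: dict           # key -> (T,) GFP of the across-subject mean map
    consistent_intervals: dict  # key -> list of half-open (start, stop)
    times_ms: np.ndarray
    options: RandomizationOptions

    def to_dict(self) -> dict:
        keys = ["␟".join(k) for k in self.keys]
        return {"keys": keys,
                "p": {k: v for k, v in zip(keys, self.p.values())},
                "gfp_mean": {k: v for k, v in
                             zip(keys, self.gfp_mean.values())},
                "consistent_intervals": {
                    k: [list(c) for c in v]
                    for k, v in zip(keys, self.consistent_intervals.values())},
                "times_ms": np.asarray(self.times_ms),
                "options": self.options.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "TctResult":
        keys = [tuple(k.split("␟")) for k in d["keys"]]
        remap = dict(zip(d["keys"], keys))
        return cls(keys,
                   {remap[k]: v for k, v in d["p"].items()},
                   {remap[k]: v for k, v in d["gfp_mean"].items()},
                   {remap[k]: [tuple(c) for c in v]
                    for k, v in d["consistent_intervals"].items()},
                   np.asarray(d["times_ms"]),
                   RandomizationOptions.from_dict(d["options"]))


def topographic_consistency_test(dataset: ErpDataset,
                                 options: RandomizationOptions | None = None,
                                 between=None) -> TctResult:
    """Test every group/condition for a consistent topography over time.

    When a categorical between design is given, each group is tested
    separately; excluded subjects are left out.  L2 normalization (the
    default options) equalizes subjects' map amplitudes so the test is
    driven purely by topographic agreement.  The statistic is invariant
    to re-referencing and to applying one common sensor permutation to
    all subjects.
    """
    options = options or RandomizationOptions()
    if not dataset.average_referenced:
        dataset = apply_average_reference(dataset)
    lo, hi = ((0, dataset.n_time) if options.window is None
              else options.window)
    times = dataset.times_ms[lo:hi]

    if between is not None and between.mode == "categorical":
        codes = between.group_codes()
        used = between.used
        labels = sorted({int(round(between.value_array[u])) for u in used})
        groups = [(f"{between.name}={lab}",
                   used[codes == gi]) for gi, lab in enumerate(labels)]
    elif between is not None:
        groups = [("all", between.used)]
    else:
        groups = [("all", np.arange(dataset.n_subjects))]

    seeds = np.random.SeedSequence(options.seed).spawn(
        len(groups) * dataset.n_conditions)
    keys, p, gfp_mean, intervals = [], {}, {}, {}
    si = 0
    for gname, subj_idx in groups:
        if len(subj_idx) < 2:
            raise ValueError(
                f"TCT needs >= 2 subjects per tested cell ({gname})")
        for ci, cname in enumerate(dataset.condition_labels):
            X = dataset.data[subj_idx, ci, lo:hi, :]  # (S, T, J)
            key = (gname, cname)
            rng = np.random.default_rng(seeds[si]); si += 1
            res = _tct_one(X, options, rng)
            keys.append(key)
            p[key], gfp_mean[key] = res["p"], res["gfp"]
            intervals[key] = res["intervals"]
    return TctResult(keys, p, gfp_mean, intervals, times, options)


def _tct_one(X: np.ndarray, options: RandomizationOptions,
             rng: np.random.Generator) -> dict:
    S, T, J = X.shape

    def stat(maps):  # (..., S, T, J) -> (..., T)
        mean = maps.mean(axis=-3)
        mean = mean - mean.mean(axis=-1, keepdims=True)
        return np.sqrt(np.mean(mean ** 2, axis=-1))

    gfp_raw = stat(X)  # GFP trace of the raw mean map, in data units
    if options.normalization == "l2":
        g = np.sqrt(np.mean((X - X.mean(axis=2, keepdims=True)) ** 2, axis=2))
        if np.any(g <= 0):
            # flat maps carry no topography; leave them at zero amplitude
            g = np.where(g <= 0, 1.0, g)
        X = X / g[..., None]

    observed = stat(X)

    n_runs = options.n_runs
    null = np.empty((n_runs, T))
    chunk = max(1, int(2.5e7 / (S * T * J)))
    done = 0
    while done < n_runs:
        n = min(chunk, n_runs - done)
        perms = np.argsort(rng.random((n, S, J)), axis=-1)  # (n, S, J)
        shuffled = np.take_along_axis(
            X[None, :, :, :], perms[:, :, None, :], axis=3)
        null[done:done + n] = stat(shuffled)
        done += n

    count_ge = np.count_nonzero(null >= observed[None, :], axis=0)
    p = (1.0 + count_ge) / (1.0 + n_runs)
    pseudo = pseudo_p_matrix(null) if n_runs >= 2 else None
    if pseudo is not None:
        thr = duration_threshold(pseudo, options.alpha)
        intervals = apply_duration_mask(p, thr, options.alpha)
    else:
        intervals = apply_duration_mask(p, 1, options.alpha)
    return {"p": p, "gfp": gfp_raw, "intervals": intervals}


def tct_table(result: TctResult):
    """Long-format export: group, condition, time, GFP of mean map, p."""
    import pandas as pd
    rows = []
    for key in result.keys:
        for k, t_ms in enumerate(result.times_ms):
            rows.append((key[0], key[1], float(t_ms),
                         float(result.gfp_mean[key][k]),
                         float(result.p[key][k])))
    return pd.DataFrame(rows, columns=["group", "condition", "time_ms",
                                       "gfp_mean_map", "p"])
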