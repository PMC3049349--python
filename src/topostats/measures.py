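"""Scalar measures of scalp field strength and difference.

A *scalp map* is the vector of simultaneous measurements across all
sensors at one moment in time.  All statistics in this package reduce
maps, or sets of maps, to a single non-negative strength value:

* :func:`gfp` — global field power, the spatial RMS of one map about its
  mean across sensors; the canonical reference-independent measure of
  field strength.
* :func:`effect_strength` — the generalized GFP of the differences among
  a set of condition/group mean maps; the test statistic of the TANOVA.
* :func:`covariance_map` / :func:`tancova_strength` — the per-sensor
  covariance of a set of maps with a continuous predictor, and its GFP;
  the test statistic of the TANCOVA.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "gfp",
    "normalize_map",
    "effect_strength",
    "covariance_map",
    "tancova_strength",
]


def _as_map(values) -> np.ndarray:
    m = np.asarray(values, dtype=float)
    if m.ndim != 1:
        raise ValueError(f"a scalp map must be 1-D, got shape {m.shape}")
    if m.size < 2:
        raise ValueError("a scalp map needs at least 2 sensors")
    if not np.all(np.isfinite(m)):
        raise ValueError("scalp map contains non-finite values")
    return m


def gfp(values) -> float:
    """Global field power of one scalp map.

    GFP is the root-mean-square deviation of the sensor values about
    their spatial mean, ``sqrt(sum_j (v_j - vbar)^2 / n)`` — the
    (population) standard deviation across sensors.  It is invariant to
    adding a constant to every sensor, i.e. independent of the recording
    reference, and scales with |k| when the map is scaled by k.
    """
    m = _as_map(values)
    return float(np.sqrt(np.mean((m - m.mean()) ** 2)))


def normalize_map(values, mode: str = "l2") -> np.ndarray:
    """Scale one scalp map to unit spatial variance (unit GFP).

    ``mode="l2"`` divides the map by its GFP so that amplitude
    (quantitative) information is removed and only the topography
    (the qualitative pattern) remains.  ``mode="none"`` returns the map
    unchanged.  The map is *not* re-centered: the spatial mean is left
    alone, so average-referenced maps stay average-referenced.
    """
    m = _as_map(values)
    if mode == "none":
        return m
    if mode != "l2":
        raise ValueError(f"unknown normalization mode: {mode!r}")
    g = gfp(m)
    if g <= 0.0:
        raise ValueError("cannot L2-normalize a flat (zero-GFP) map")
    return m / g


def effect_strength(cell_means) -> float:
    """Generalized global field power of differences among mean maps.

    Given the mean maps ``v_i`` of the *c* cells of an effect (conditions,
    groups, or their centered interaction residuals), the statistic is

        s = sqrt( sum_i sum_j (v_ij - vgrand_j)^2 / n )

    where ``vgrand_j`` is the unweighted mean of the cell means at sensor
    *j* and *n* the number of sensors.  ``s`` is zero iff all cell means
    are identical, invariant to the order of the cells and to adding a
    common map to every cell.  For two cells it reduces (up to a constant
    factor) to the GFP of the difference map.
    """
    cells = np.asarray(cell_means, dtype=float)
    if cells.ndim != 2:
        raise ValueError("cell_means must be a (n_cells, n_sensors) array "
                         "or list of equal-length maps")
    if cells.shape[0] < 2:
        raise ValueError("need at least 2 cell means")
    if not np.all(np.isfinite(cells)):
        raise ValueError("cell means contain non-finite values")
    grand = cells.mean(axis=0)
    return float(np.sqrt(np.sum((cells - grand) ** 2) / cells.shape[1]))


def covariance_map(maps, predictor) -> np.ndarray:
    """Per-sensor covariance of a set of maps with a continuous predictor.

    ``beta_j = sum_i v_ij * (b_i - bbar)``.  The predictor is mean-centered
    before the sum so that a constant offset of ``b`` does not leak the
    grand-mean topography into ``beta``; the result estimates the
    topography of the sources whose strength covaries with ``b``.
    """
    v = np.asarray(maps, dtype=float)
    b = np.asarray(predictor, dtype=float)
    if v.ndim != 2:
        raise ValueError("maps must be a (n_observations, n_sensors) array")
    if b.shape != (v.shape[0],):
        raise ValueError(
            f"predictor length {b.shape} does not match {v.shape[0]} maps")
    bc = b - b.mean()
    return bc @ v


def tancova_strength(beta) -> float:
    """Strength of a covariance map: its global field power."""
    return gfp(beta)
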