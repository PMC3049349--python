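"""Visualization: MDS of mean maps and effect result panels.

With more than two mean maps, pairwise difference maps become hard to
survey.  A spatial PCA of the mean maps — the classical-MDS solution for
covariance similarities — projects every map onto the first two
eigenvectors of the between-map covariance matrix: points that plot
close together are similar topographies, and the two eigenvector maps
show which spatial patterns the axes stand for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MdsProjection", "mds_project", "render_effect_view"]


@dataclass(frozen=True)
class MdsProjection:
    """2-D embedding of a set of mean maps.

    ``coordinates[i]`` are the inner products of centered map *i* with
    the two orthonormal ``eigenvector_maps``; ``explained`` gives each
    axis' share of the total between-map covariance.
    """

    coordinates: np.ndarray       # (n_maps, 2)
    eigenvector_maps: np.ndarray  # (2, n_sensors)
    explained: np.ndarray         # (2,)


def mds_project(mean_maps) -> MdsProjection:
    """Project mean maps onto the first two spatial eigenvectors.

    The maps are centered across the map set (MDS operates on the
    covariance structure of the differences), the covariance matrix
    between the centered maps is eigendecomposed, and every map is
    projected onto the top-2 eigenvector maps.  Distances in the plane
    are the best rank-2 approximation of the maps' pairwise covariance
    structure.  Eigenvector signs follow a fixed convention — the sensor
    with the largest absolute loading is positive — so plots reproduce
    across runs and platforms.  A rank-1 map set (e.g. two maps) gets a
    second coordinate of zeros; that is not an error.
    """
    M = np.asarray(mean_maps, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValueError("need >= 2 mean maps on a common sensor set")
    Mc = M - M.mean(axis=0, keepdims=True)
    # spatial PCA via SVD: right singular vectors are the eigenvector maps
    U, sv, Vt = np.linalg.svd(Mc, full_matrices=False)
    var = sv ** 2
    total = var.sum()
    comps = np.zeros((2, M.shape[1]))
    coords = np.zeros((M.shape[0], 2))
    explained = np.zeros(2)
    tol = sv[0] * max(M.shape) * np.finfo(float).eps if sv.size else 0.0
    for k in range(min(2, sv.size)):
        if sv[k] <= tol:
            break
        v = Vt[k]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        comps[k] = v
        coords[:, k] = Mc @ v
        explained[k] = var[k] / total if total > 0 else 0.0
    return MdsProjection(coords, comps, explained)


def _interpolate_map(values, positions, grid=67):
    """Inverse-distance interpolation of one map on the 2-D montage."""
    pos = positions[:, :2]
    span = pos.max(axis=0) - pos.min(axis=0)
    lo = pos.min(axis=0) - 0.1 * span
    hi = pos.max(axis=0) + 0.1 * span
    gx, gy = np.meshgrid(np.linspace(lo[0], hi[0], grid),
                         np.linspace(lo[1], hi[1], grid))
    d2 = ((gx[..., None] - pos[:, 0]) ** 2
          + (gy[..., None] - pos[:, 1]) ** 2)
    w = 1.0 / np.maximum(d2, 1e-12) ** 1.5
    img = (w * values).sum(axis=-1) / w.sum(axis=-1)
    # blank out pixels far from every sensor
    near = np.sqrt(d2.min(axis=-1)) < 0.35 * max(span)
    img[~near] = np.nan
    return img, (lo[0], hi[0], lo[1], hi[1])


def render_effect_view(result, effect_id: str, t: int | None = None,
                       dataset=None, within=None, between=None,
                       inference=None, montage=None, cell_labels=None):
    """One-effect results panel: p(t) trace, mean maps, MDS scatter.

    ``result`` is a RandomizationResult; ``t`` selects the displayed time
    sample of the result (default: the most significant one).  Passing
    the dataset and designs adds the effect's mean maps at that latency
    and their MDS scatter.  If global inference is supplied,
    duration-masked periods are highlighted.  Without a montage, maps
    fall back to per-sensor bar plots (with a warning in the axes
    title).  Single-time-point (window-averaged) results are shown as a
    significance bar instead of a trace.

    Returns a matplotlib Figure.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    eff = {e.id: e for e in result.effects}[effect_id]
    p = np.asarray(result.p[effect_id])
    times = np.asarray(result.times_ms)
    alpha = result.options.alpha
    if t is None:
        t = int(np.argmin(p))

    maps = None
    if dataset is not None:
        from dataclasses import replace
        from .designs import cell_means
        ds = dataset
        if result.statistic == "tanova-averaged":
            lo, hi = result.options.window or (0, dataset.n_time)
            ds = replace(dataset,
                         data=dataset.data[:, :, lo:hi, :].mean(
                             axis=2, keepdims=True),
                         onset_latency=float(times[0]), sampling_rate=1.0)
            sample = 0
        else:
            sample = ds.ms_to_sample(float(times[t]))
        maps = np.asarray(cell_means(ds, within, between, eff, sample))
        if montage is None:
            montage = dataset.montage
    fig = plt.figure(figsize=(10, 6))
    gs = fig.add_gridspec(2, 2, width_ratios=[1.4, 1.0])

    ax_p = fig.add_subplot(gs[:, 0])
    if p.size == 1:
        ax_p.bar([0], [p[0]], color="tab:green" if p[0] < alpha else "0.6")
        ax_p.set_xticks([0])
        ax_p.set_xticklabels([f"{times[0]:g} ms (window mean)"])
        ax_p.set_title(f"{eff.name}: p = {p[0]:.4g}")
    else:
        ax_p.plot(times, p, color="0.2", lw=1)
        ax_p.axhline(alpha, color="tab:red", lw=0.8)
        sig = p < alpha
        ax_p.fill_between(times, 0, 1, where=sig, color="0.85", step="mid")
        if inference is not None:
            for a, b in inference[effect_id].clusters:
                ax_p.axvspan(times[a], times[b - 1], color="tab:green",
                             alpha=0.3)
        ax_p.axvline(times[t], color="tab:blue", lw=0.8, ls="--")
        ax_p.set_ylim(0, 1)
        ax_p.set_title(f"{eff.name}: p({times[t]:g} ms) = {p[t]:.4g}")
    ax_p.set_xlabel("time (ms)")
    ax_p.set_ylabel("p")

    if maps is None:
        ax_m = fig.add_subplot(gs[0, 1])
        ax_m.text(0.5, 0.5, "no mean maps stored", ha="center", va="center")
        ax_m.set_axis_off()
        fig.tight_layout()
        return fig

    maps = np.asarray(maps)
    n_cells = maps.shape[0]
    labels = cell_labels or [f"cell {i + 1}" for i in range(n_cells)]
    sub = fig.add_gridspec(2, n_cells, width_ratios=[1] * n_cells,
                           top=0.93, bottom=0.55, left=0.62, right=0.98)
    vmax = np.abs(maps).max() or 1.0
    for i in range(n_cells):
        ax = fig.add_subplot(sub[0, i])
        if montage is not None and montage.positions.shape[1] >= 2:
            img, extent = _interpolate_map(maps[i], montage.positions)
            ax.imshow(img, origin="lower", extent=extent, cmap="RdBu_r",
                      vmin=-vmax, vmax=vmax)
            ax.scatter(montage.positions[:, 0], montage.positions[:, 1],
                       s=2, c="k")
        else:
            ax.bar(range(maps.shape[1]), maps[i], color="0.4")
            ax.set_ylim(-vmax, vmax)
            if i == 0:
                ax.set_title("no montage: sensor bars", fontsize=7)
        ax.set_xticks([]), ax.set_yticks([])
        ax.set_xlabel(labels[i], fontsize=7)

    ax_mds = fig.add_subplot(gs[1, 1])
    proj = mds_project(maps)
    ax_mds.scatter(proj.coordinates[:, 0], proj.coordinates[:, 1],
                   c=range(n_cells), cmap="tab10")
    for i, lab in enumerate(labels):
        ax_mds.annotate(lab, proj.coordinates[i], fontsize=7,
                        xytext=(2, 2), textcoords="offset points")
    ax_mds.axhline(0, color="0.8", lw=0.5)
    ax_mds.axvline(0, color="0.8", lw=0.5)
    ax_mds.set_xlabel(f"eigenvector 1 ({proj.explained[0]:.0%})")
    ax_mds.set_ylabel(f"eigenvector 2 ({proj.explained[1]:.0%})")
    return fig
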