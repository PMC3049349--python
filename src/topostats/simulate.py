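"""Synthetic ERP datasets with known ground truth.

Scalp fields are additive: whatever set of sources is active, the
measured map is the sum of the maps each source would produce alone.
The generator builds on exactly that model — every dataset is a sum of
*sources*, each a fixed unit-GFP topography multiplied by an amplitude
time course and by per-cell, per-group, per-covariate and per-subject
amplitude factors — plus spatially correlated sensor noise.  Because the
generating truth (which cells differ, when, with which topography) is
recorded alongside, every statistical routine in the package can be
validated without external recordings: null datasets calibrate false
positive rates, effect datasets measure power and recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data_io import ErpDataset, SensorMontage, circular_montage, \
    write_ascii_map_series

__all__ = [
    "SourceEffect",
    "GenerativeSpec",
    "generate",
    "write_ascii_directory",
    "gaussian_pulse",
    "boxcar",
    "random_topography",
]


def random_topography(n_sensors: int, rng: np.random.Generator) -> np.ndarray:
    """A random average-referenced, unit-GFP scalp topography."""
    v = rng.standard_normal(n_sensors)
    v -= v.mean()
    g = np.sqrt(np.mean(v ** 2))
    if g == 0:
        raise ValueError("degenerate zero topography")
    return v / g


def gaussian_pulse(n_time: int, center: float, width: float) -> np.ndarray:
    """Gaussian amplitude time course, peak 1 at ``center`` (samples)."""
    t = np.arange(n_time)
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def boxcar(n_time: int, start: int, stop: int) -> np.ndarray:
    """Unit amplitude on the half-open sample window [start, stop)."""
    tc = np.zeros(n_time)
    tc[start:stop] = 1.0
    return tc


@dataclass(frozen=True)
class SourceEffect:
    """One intracranial source as seen on the scalp.

    The source contributes
    ``amplitude * topography[j] * time_course[t] * condition_weight[c]
    * group_weight[g] * (1 + covariate_gain * z_i) * subject_factor_i``
    to subject *i*'s map in condition *c*.  ``condition_weights`` of all
    ones make the source common to every condition (background activity);
    differing weights create condition effects, group weights create
    between-group effects, a nonzero ``covariate_gain`` ties the source
    amplitude linearly to the (standardized) covariate.  ``subject_sd``
    jitters each subject's amplitude around 1 (shared sources stay
    positively weighted for realistic inter-subject variability).
    """

    topography: np.ndarray
    time_course: np.ndarray
    amplitude: float = 1.0
    condition_weights: np.ndarray | None = None
    group_weights: np.ndarray | None = None
    covariate_gain: float = 0.0
    subject_sd: float = 0.0


@dataclass(frozen=True)
class GenerativeSpec:
    """Study conditions for one synthetic dataset.

    Defaults describe the toy scale used throughout the test-bench: 12
    subjects, a 2 x 2 within design (4 conditions), 40 time points, 16
    sensors on a circular montage, unit-variance sensor noise with a
    spatial correlation length of 0.5 (in montage units, radius 1 —
    volume conduction blurs real measurements in space, so white sensor
    noise would be unrealistically easy to average away).
    """

    n_subjects: int = 12
    design_shape: tuple = (2, 2)
    n_time: int = 40
    n_sensors: int = 16
    sampling_rate: float = 250.0
    sources: tuple = ()
    noise_sd: float = 1.0
    noise_corr_length: float = 0.5
    groups: tuple | None = None       # per-subject group codes
    covariate: tuple | None = None    # per-subject covariate values
    seed: int = 0

    @property
    def n_conditions(self) -> int:
        return int(np.prod(self.design_shape))


@dataclass
class GroundTruth:
    """What was injected: per source, the active window, the topography,
    and the cell/group/covariate weighting."""

    sources: list = field(default_factory=list)
    montage: SensorMontage | None = None


def _noise_chol(montage: SensorMontage, corr_length: float) -> np.ndarray:
    """Cholesky factor of a squared-exponential spatial noise covariance."""
    pos = montage.positions
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    if corr_length <= 0:
        return np.eye(pos.shape[0])
    K = np.exp(-0.5 * d2 / corr_length ** 2)
    K[np.diag_indices_from(K)] += 1e-9
    return np.linalg.cholesky(K)


def generate(spec: GenerativeSpec,
             rng: np.random.Generator | None = None
             ) -> tuple[ErpDataset, GroundTruth]:
    """Generate one dataset (and its ground truth) from a spec.

    Deterministic given the spec's seed.  The returned data are
    average-referenced (topographies are generated average-referenced and
    the noise is re-referenced after mixing).
    """
    if spec.n_subjects < 2 or spec.n_time < 1 or spec.n_sensors < 2:
        raise ValueError("degenerate spec: need >= 2 subjects, >= 1 time "
                         "point, >= 2 sensors")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    S, C, T, J = (spec.n_subjects, spec.n_conditions, spec.n_time,
                  spec.n_sensors)
    montage = circular_montage(J)

    groups = None if spec.groups is None else np.asarray(spec.groups, int)
    cov = None if spec.covariate is None else np.asarray(spec.covariate,
                                                         float)
    if groups is not None and groups.size != S:
        raise ValueError("groups must give one code per subject")
    if cov is not None and cov.size != S:
        raise ValueError("covariate must give one value per subject")
    z = None
    if cov is not None:
        sd = cov.std()
        z = (cov - cov.mean()) / (sd if sd > 0 else 1.0)

    data = np.zeros((S, C, T, J))
    truth = GroundTruth(montage=montage)
    for src in spec.sources:
        topo = np.asarray(src.topography, float)
        if topo.shape != (J,):
            raise ValueError("source topography length must match sensors")
        tc = np.asarray(src.time_course, float)
        if tc.shape != (T,):
            raise ValueError("source time course length must match n_time")
        cw = (np.ones(C) if src.condition_weights is None
              else np.asarray(src.condition_weights, float))
        if cw.shape != (C,):
            raise ValueError("condition_weights must have one entry per "
                             "condition")
        subj_amp = 1.0 + src.subject_sd * rng.standard_normal(S)
        if src.group_weights is not None:
            if groups is None:
                raise ValueError("group_weights need spec.groups")
            subj_amp = subj_amp * np.asarray(src.group_weights,
                                             float)[groups]
        if src.covariate_gain != 0.0:
            if z is None:
                raise ValueError("covariate_gain needs spec.covariate")
            subj_amp = subj_amp * (1.0 + src.covariate_gain * z)
        data += (src.amplitude * subj_amp[:, None, None, None]
                 * cw[None, :, None, None] * tc[None, None, :, None]
                 * topo[None, None, None, :])
        active = np.flatnonzero(np.abs(tc) > 1e-3 * np.abs(tc).max()) \
            if np.abs(tc).max() > 0 else np.array([], int)
        truth.sources.append({
            "topography": topo, "time_course": tc,
            "active_window": ((int(active[0]), int(active[-1]) + 1)
                              if active.size else None),
            "condition_weights": cw, "amplitude": src.amplitude,
            "covariate_gain": src.covariate_gain,
        })

    if spec.noise_sd > 0:
        L = _noise_chol(montage, spec.noise_corr_length)
        noise = rng.standard_normal((S, C, T, J)) @ L.T
        # normalize so noise_sd is the marginal per-sensor SD
        noise /= np.sqrt(np.mean(np.diag(L @ L.T)))
        data += spec.noise_sd * noise

    data -= data.mean(axis=3, keepdims=True)
    ds = ErpDataset(data, sampling_rate=spec.sampling_rate,
                    montage=montage, average_referenced=True)
    return ds, truth


def write_ascii_directory(dataset: ErpDataset, directory,
                          name_template: str = "{subject}_{condition}.asc"
                          ) -> list:
    """Write one ASCII file per subject and condition into a directory.

    File names come from ``name_template`` with ``{subject}`` and
    ``{condition}`` placeholders filled from the dataset labels, so the
    directory can be re-imported with a search mask such as
    ``"S*_C1.asc"``.  Returns the written file names.
    """
    from pathlib import Path
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for si, slab in enumerate(dataset.subject_labels):
        for ci, clab in enumerate(dataset.condition_labels):
            name = name_template.format(subject=slab, condition=clab)
            write_ascii_map_series(dataset.data[si, ci], directory / name)
            written.append(name)
    return written


# ---------------------------------------------------------------------------
# Canned study conditions for the test bench
# ---------------------------------------------------------------------------

def null_spec(seed: int = 0, **overrides) -> GenerativeSpec:
    """Pure-noise dataset: every effect's null hypothesis holds."""
    return GenerativeSpec(seed=seed, sources=(), **overrides)


def condition_effect_spec(seed: int = 0, effect_amplitude: float = 1.0,
                          window: tuple = (15, 26),
                          subject_sd: float = 0.2,
                          **overrides) -> GenerativeSpec:
    """A main effect of the first within factor inside a known window.

    One background source is common to all conditions; a second source
    with an independent topography is added with opposite sign for the
    two levels of factor A (constant across factor B), active on the
    half-open sample ``window``.  ``effect_amplitude`` against the unit
    noise SD sets the SNR.
    """
    spec = GenerativeSpec(seed=seed, **overrides)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC0FFEE)))
    T, J = spec.n_time, spec.n_sensors
    la, lb = spec.design_shape
    a_level = np.repeat(np.arange(la), lb)          # condition -> A level
    sign = np.where(a_level == 0, 1.0, -1.0)
    bg = SourceEffect(random_topography(J, rng),
                      gaussian_pulse(T, T * 0.45, T * 0.15),
                      amplitude=2.0, subject_sd=0.3)
    eff = SourceEffect(random_topography(J, rng), boxcar(T, *window),
                       amplitude=effect_amplitude, condition_weights=sign,
                       subject_sd=subject_sd)
    return replace(spec, sources=(bg, eff))


def covariate_effect_spec(seed: int = 0, gain: float = 1.0,
                          effect_amplitude: float = 1.0,
                          window: tuple = (15, 26),
                          **overrides) -> GenerativeSpec:
    """A source whose amplitude is linearly tied to a subject covariate."""
    spec = GenerativeSpec(seed=seed, **overrides)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xBEEF)))
    T, J = spec.n_time, spec.n_sensors
    covariate = tuple(rng.standard_normal(spec.n_subjects))
    src = SourceEffect(random_topography(J, rng), boxcar(T, *window),
                       amplitude=effect_amplitude, covariate_gain=gain)
    return replace(spec, sources=(src,), covariate=covariate)


def consistent_topography_spec(seed: int = 0, amplitude: float = 3.0,
                               **overrides) -> GenerativeSpec:
    """All subjects share one topography (positively weighted), plus noise."""
    spec = GenerativeSpec(seed=seed, **overrides)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xA11)))
    T, J = spec.n_time, spec.n_sensors
    src = SourceEffect(random_topography(J, rng), gaussian_pulse(
        T, T * 0.5, T * 0.2), amplitude=amplitude, subject_sd=0.25)
    return replace(spec, sources=(src,))
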