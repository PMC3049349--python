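"""Factorial designs, testable effects, and label shufflings.

A within-subject design assigns every condition a level on up to two
factors (conditions may be excluded for post-hoc comparisons; with two
factors the included conditions must form a complete crossing).  A
between-subject design either partitions the subjects into groups or
attaches a continuous/rank-scaled covariate value to each subject;
individual subjects can be excluded via a use flag.

From the designs a list of testable effects is enumerated (main effects,
their interactions, and — when a between design exists — the group or
covariate terms).  For every effect this module also provides

* the *marginal cell means* the effect is computed on (interaction cell
  means are multiply-centered so that purely additive data yields zero),
* the *label shuffling* that generates one draw from the effect's null
  distribution: condition and/or group labels are permuted in a way that
  destroys the tested effect under H0 while leaving every non-tested
  structure — and each subject's actual maps — untouched.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import reduce

import numpy as np

__all__ = [
    "WithinDesign",
    "BetweenDesign",
    "EffectSpec",
    "Relabeling",
    "enumerate_effects",
    "cell_means",
    "shuffle_labels",
    "draw_relabelings",
    "enumerate_relabelings",
    "count_relabelings",
    "effect_structure",
]


@dataclass(frozen=True)
class WithinDesign:
    """Assignment of conditions to the levels of up to two within factors.

    ``levels`` has one row per condition and one column per factor; level
    codes are non-negative integers and ``None``/``-1`` marks a condition
    as excluded from the analysis.
    """

    levels: tuple              # (n_conditions, n_factors) after coercion
    factor_names: tuple = ()
    level_labels: tuple = ()   # per factor: tuple of labels, indexed by level

    def __post_init__(self):
        lv = np.asarray(
            [[-1 if v is None else int(v) for v in row] for row in self.levels],
            dtype=int)
        if lv.ndim != 2:
            raise ValueError("levels must be (n_conditions, n_factors)")
        if lv.shape[1] not in (1, 2):
            raise ValueError("at most two within-subject factors are supported")
        names = tuple(self.factor_names) or tuple(
            "AB"[i] for i in range(lv.shape[1]))
        if len(names) != lv.shape[1]:
            raise ValueError("need one name per factor")
        incl = np.all(lv >= 0, axis=1)
        if np.any(np.any(lv >= 0, axis=1) & ~incl):
            raise ValueError(
                "every included condition needs a level on every factor")
        if not incl.any():
            raise ValueError("all conditions are excluded")
        if lv.shape[1] == 2:
            # included conditions must form a complete, balanced crossing
            la = np.unique(lv[incl, 0])
            lb = np.unique(lv[incl, 1])
            counts = {}
            for a, b in lv[incl]:
                counts[(a, b)] = counts.get((a, b), 0) + 1
            cells = set(itertools.product(la, lb))
            if set(counts) != cells or len(set(counts.values())) != 1:
                raise ValueError(
                    "the levels of the two factors must be orthogonal: the "
                    "included conditions must cover every level combination "
                    "equally often (condition exclusion that breaks the "
                    "crossing is rejected)")
        object.__setattr__(self, "levels", tuple(map(tuple, lv)))
        object.__setattr__(self, "factor_names", names)
        object.__setattr__(self, "level_labels", tuple(
            tuple(map(str, labs)) for labs in self.level_labels))

    # -- accessors ------------------------------------------------------
    @property
    def n_factors(self) -> int:
        return len(self.levels[0])

    @property
    def n_conditions(self) -> int:
        return len(self.levels)

    @property
    def level_array(self) -> np.ndarray:
        return np.asarray(self.levels, dtype=int)

    @property
    def included(self) -> np.ndarray:
        """Indices of the conditions that take part in the analysis."""
        return np.flatnonzero(np.all(self.level_array >= 0, axis=1))

    def factor_levels(self, factor: int) -> np.ndarray:
        """Sorted distinct level codes of one factor among included conditions."""
        return np.unique(self.level_array[self.included, factor])

    def to_dict(self) -> dict:
        return {"levels": [list(r) for r in self.levels],
                "factor_names": list(self.factor_names),
                "level_labels": [list(l) for l in self.level_labels]}

    @classmethod
    def from_dict(cls, d: dict) -> "WithinDesign":
        return cls(tuple(map(tuple, d["levels"])),
                   tuple(d["factor_names"]),
                   tuple(map(tuple, d.get("level_labels", ()))))


@dataclass(frozen=True)
class BetweenDesign:
    """Group membership or a continuous covariate, one value per subject.

    ``mode`` is ``"categorical"`` (values are group codes) or
    ``"continuous"`` (values are interval/rank-scaled covariate values for
    a TANCOVA).  ``use`` flags subjects into or out of the analysis.
    """

    mode: str
    values: tuple
    use: tuple = ()
    name: str = "group"

    def __post_init__(self):
        if self.mode not in ("categorical", "continuous"):
            raise ValueError("mode must be 'categorical' or 'continuous'")
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError("need one value per subject (>= 2 subjects)")
        use = np.asarray(self.use if len(self.use) else [True] * vals.size,
                         dtype=bool)
        if use.shape != vals.shape:
            raise ValueError("use flags must match the number of subjects")
        if not use.any():
            raise ValueError("all subjects are excluded")
        used_vals = vals[use]
        if self.mode == "continuous":
            if np.unique(used_vals).size < 2:
                raise ValueError("a covariate needs >= 2 distinct values "
                                 "among the used subjects")
        else:
            if not np.allclose(used_vals, np.round(used_vals)):
                raise ValueError("categorical group codes must be integers")
        object.__setattr__(self, "values", tuple(vals))
        object.__setattr__(self, "use", tuple(bool(u) for u in use))

    @property
    def n_subjects(self) -> int:
        return len(self.values)

    @property
    def used(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.use, dtype=bool))

    @property
    def value_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def group_codes(self) -> np.ndarray:
        """Contiguous group indices (0..G-1) for the used subjects."""
        if self.mode != "categorical":
            raise ValueError("group codes are only defined for categorical mode")
        vals = np.round(self.value_array[self.used]).astype(int)
        _, codes = np.unique(vals, return_inverse=True)
        return codes

    def to_dict(self) -> dict:
        return {"mode": self.mode, "values": list(self.values),
                "use": list(self.use), "name": self.name}

    @classmethod
    def from_dict(cls, d: dict) -> "BetweenDesign":
        return cls(d["mode"], tuple(d["values"]), tuple(d.get("use", ())),
                   d.get("name", "group"))


@dataclass(frozen=True)
class EffectSpec:
    """One testable effect: a main effect or interaction.

    ``within_factors`` lists the within-factor indices the effect
    involves; ``between`` is ``None``, ``"group"`` or ``"covariate"``.
    The ``id`` is a stable short code (``A``, ``B``, ``AxB``, ``G``,
    ``GxA`` ... ``COVxAxB``) and ``name`` a human-readable label built
    from the design's factor names.
    """

    id: str
    name: str
    within_factors: tuple = ()
    between: str | None = None

    @property
    def is_interaction(self) -> bool:
        n_terms = len(self.within_factors) + (self.between is not None)
        return n_terms > 1

    @property
    def is_covariate(self) -> bool:
        return self.between == "covariate"


def enumerate_effects(within: WithinDesign | None,
                      between: BetweenDesign | None = None) -> list[EffectSpec]:
    """All testable effects of a design pair, in a fixed canonical order.

    Within main effects come first, then the within interaction, then the
    between term and its interactions with the within factors.  Two
    within factors alone yield 3 effects; adding a group factor yields 7.
    """
    effects: list[EffectSpec] = []
    wnames = list(within.factor_names) if within is not None else []
    codes = ["A", "B"][: len(wnames)]
    for i, (code, nm) in enumerate(zip(codes, wnames)):
        effects.append(EffectSpec(code, nm, (i,)))
    if len(wnames) == 2:
        effects.append(EffectSpec("AxB", f"{wnames[0]} x {wnames[1]}", (0, 1)))
    if between is not None:
        kind = "group" if between.mode == "categorical" else "covariate"
        bcode = "G" if kind == "group" else "COV"
        bname = between.name
        effects.append(EffectSpec(bcode, bname, (), kind))
        for i, (code, nm) in enumerate(zip(codes, wnames)):
            effects.append(EffectSpec(f"{bcode}x{code}", f"{bname} x {nm}",
                                      (i,), kind))
        if len(wnames) == 2:
            effects.append(EffectSpec(
                f"{bcode}xAxB", f"{bname} x {wnames[0]} x {wnames[1]}",
                (0, 1), kind))
    return effects


# ---------------------------------------------------------------------------
# Effect structure: cells, weights, centering
# ---------------------------------------------------------------------------

def _centering(dim: int) -> np.ndarray:
    return np.eye(dim) - np.full((dim, dim), 1.0 / dim)


@dataclass(frozen=True)
class EffectStructure:
    """Precomputed bookkeeping for one effect on one design pair.

    ``included`` are the dataset condition indices that take part;
    ``cell_of_cond`` maps each included condition to its cell on the
    effect's *within* grid (shape ``grid_w``); ``orbit`` arranges the
    included conditions for level permutations (see
    :func:`draw_relabelings`).  ``centering`` is the projection applied
    along the flattened full cell grid (group axis first): the identity
    minus the mean for every involved axis, so main effects are centered
    by the grand mean and interactions are double- (or triple-) centered.
    """

    effect: EffectSpec
    included: np.ndarray
    cell_of_cond: np.ndarray
    grid_w: tuple
    orbit: np.ndarray | None   # (n_slots, n_levels) condition positions
    n_groups: int
    group_codes: np.ndarray | None
    covariate: np.ndarray | None
    centering: np.ndarray
    centering_w: np.ndarray

    @property
    def n_cells_w(self) -> int:
        return int(np.prod(self.grid_w)) if self.grid_w else 1

    @property
    def n_cells(self) -> int:
        return self.n_cells_w * max(self.n_groups, 1)


def effect_structure(within: WithinDesign | None,
                     between: BetweenDesign | None,
                     effect: EffectSpec) -> EffectStructure:
    if effect.within_factors and within is None:
        raise ValueError(f"effect {effect.id} needs a within design")
    if effect.between is not None and between is None:
        raise ValueError(f"effect {effect.id} needs a between design")

    if within is not None:
        included = within.included
        lv = within.level_array[included]
    else:
        included = None  # caller substitutes all conditions
        lv = None

    # within part of the cell grid
    if effect.within_factors and within is not None:
        axes = []
        idx_per_factor = []
        for f in effect.within_factors:
            levels = within.factor_levels(f)
            axes.append(len(levels))
            idx_per_factor.append(np.searchsorted(levels, lv[:, f]))
        grid_w = tuple(axes)
        cell = np.zeros(lv.shape[0], dtype=int)
        for ax_len, idx in zip(grid_w, idx_per_factor):
            cell = cell * ax_len + idx
    else:
        grid_w = ()
        cell = np.zeros(len(included) if included is not None else 1, dtype=int)

    # orbit table for level permutations of a single within factor:
    # conditions sharing all *other* structure are paired across levels
    orbit = None
    if len(effect.within_factors) == 1 and within is not None:
        f = effect.within_factors[0]
        levels = within.factor_levels(f)
        slots: dict[tuple, dict[int, list[int]]] = {}
        for pos, cidx in enumerate(included):
            key = tuple(v for j, v in enumerate(within.level_array[cidx])
                        if j != f)
            li = int(np.searchsorted(levels, within.level_array[cidx, f]))
            slots.setdefault(key, {}).setdefault(li, []).append(pos)
        rows = []
        for key, per_level in sorted(slots.items()):
            sizes = {len(per_level.get(li, ())) for li in range(len(levels))}
            if len(sizes) != 1:
                raise ValueError(
                    f"factor {within.factor_names[f]!r}: unbalanced levels "
                    f"within stratum {key}; cannot permute level labels")
            for rank in range(sizes.pop()):
                rows.append([per_level[li][rank] for li in range(len(levels))])
        orbit = np.asarray(rows, dtype=int)

    # between part
    n_groups, group_codes, covariate = 0, None, None
    if effect.between == "group":
        group_codes = between.group_codes()
        n_groups = int(group_codes.max()) + 1
        counts = np.bincount(group_codes, minlength=n_groups)
        if np.any(counts < 2):
            raise ValueError("every group needs >= 2 used subjects for a "
                             "between-subject effect")
    elif effect.between == "covariate":
        covariate = between.value_array[between.used]
        if np.unique(covariate).size < 3:
            raise ValueError("a TANCOVA needs >= 3 distinct covariate values")

    cent_w = (reduce(np.kron, (_centering(d) for d in grid_w))
              if grid_w else np.ones((1, 1)))
    if effect.between == "group":
        centering = np.kron(_centering(n_groups), cent_w)
    else:
        centering = cent_w

    return EffectStructure(
        effect=effect, included=included, cell_of_cond=cell, grid_w=grid_w,
        orbit=orbit, n_groups=n_groups, group_codes=group_codes,
        covariate=covariate, centering=centering, centering_w=cent_w)


# ---------------------------------------------------------------------------
# Cell means
# ---------------------------------------------------------------------------

def cell_means(dataset, within: WithinDesign | None,
               between: BetweenDesign | None, effect: EffectSpec,
               t: int) -> list[np.ndarray]:
    """Marginal mean maps of one effect at one time point.

    Main effects return the plain marginal means (averaged over subjects
    of the relevant stratum and over the levels of every non-involved
    factor); interaction effects return the multiply-centered cell means,
    which are identically zero for purely additive data.  One map per
    cell of the effect's grid, group axis varying slowest.
    """
    from .randomization import _observed_cell_maps  # single implementation
    if not 0 <= t < dataset.n_time:
        raise ValueError(f"time index {t} out of range")
    struct = effect_structure(within, between, effect)
    maps = _observed_cell_maps(dataset, within, between, struct, t)
    return [maps[i] for i in range(maps.shape[0])]


# ---------------------------------------------------------------------------
# Shuffling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Relabeling:
    """One permutation of labels, leaving every subject's maps untouched.

    ``cond_source[s, c]`` gives, for subject ``s``, the included-condition
    position whose data now carries label ``c`` (identity when the effect
    permutes no condition labels).  ``subject_source`` permutes the
    between-design values (group codes or covariate) across used
    subjects; ``None`` for pure within effects.
    """

    cond_source: np.ndarray
    subject_source: np.ndarray | None = None


def draw_relabelings(within: WithinDesign | None,
                     between: BetweenDesign | None, effect: EffectSpec,
                     n_subjects: int, rng: np.random.Generator,
                     n: int = 1) -> tuple[np.ndarray, np.ndarray | None]:
    """Draw ``n`` independent relabelings for one effect, vectorized.

    Returns ``(cond_source, subject_source)`` with shapes
    ``(n, n_subjects, n_included_conditions)`` and ``(n, n_subjects_used)``
    (the latter ``None`` when the effect involves no between term).

    Scheme per effect class — each is exchangeable under its null and
    preserves all non-tested structure:

    * within main effect: per subject, one random permutation of that
      factor's level labels, applied consistently across the levels of
      the other factor (2 levels: keep or swap, a coin flip per subject);
    * within interaction: per subject, one random permutation of all
      included condition labels (tested on multiply-centered cell means);
    * between main effect: one global permutation of the group labels
      (or covariate values) across used subjects;
    * mixed interactions: the corresponding within permutation and the
      between permutation applied simultaneously.
    """
    struct = effect_structure(within, between, effect)
    n_incl = (len(struct.included) if struct.included is not None
              else (within.n_conditions if within else 1))

    cond_source = np.broadcast_to(np.arange(n_incl), (n, n_subjects, n_incl))
    if effect.within_factors:
        if len(effect.within_factors) == 1:
            orbit = struct.orbit  # (n_slots, L)
            L = orbit.shape[1]
            perms = np.argsort(rng.random((n, n_subjects, L)), axis=-1)
            cond_source = np.empty((n, n_subjects, n_incl), dtype=int)
            # label at orbit[slot, l] now carries data of orbit[slot, perm[l]]
            src = orbit[:, perms]              # (slots, n, S, L)
            src = np.moveaxis(src, 0, 2)       # (n, S, slots, L)
            dest = orbit.ravel()               # slot-major positions
            cond_source[..., dest] = src.reshape(n, n_subjects, -1)
        else:
            cond_source = np.argsort(
                rng.random((n, n_subjects, n_incl)), axis=-1)

    subject_source = None
    if effect.between is not None:
        n_used = len(between.used)
        subject_source = np.argsort(rng.random((n, n_used)), axis=-1)
    return np.ascontiguousarray(cond_source), subject_source


def shuffle_labels(within: WithinDesign | None,
                   between: BetweenDesign | None, effect: EffectSpec,
                   rng: np.random.Generator,
                   n_subjects: int | None = None) -> Relabeling:
    """Draw a single relabeling for one effect (see :func:`draw_relabelings`)."""
    if n_subjects is None:
        n_subjects = len(between.used) if between is not None else 1
    cond, subj = draw_relabelings(within, between, effect, n_subjects, rng, 1)
    return Relabeling(cond[0], None if subj is None else subj[0])


def enumerate_relabelings(within: WithinDesign | None,
                          between: BetweenDesign | None, effect: EffectSpec,
                          n_subjects: int,
                          limit: int = 2_000_000):
    """Exhaustively enumerate every relabeling of one effect.

    Yields :class:`Relabeling` objects covering the complete null orbit —
    the exact reference distribution for small designs.  Raises if the
    orbit exceeds ``limit``.
    """
    struct = effect_structure(within, between, effect)
    n_incl = (len(struct.included) if struct.included is not None
              else (within.n_conditions if within else 1))
    identity = np.arange(n_incl)

    if effect.within_factors:
        if len(effect.within_factors) == 1:
            orbit = struct.orbit
            L = orbit.shape[1]
            per_subject = []
            for perm in itertools.permutations(range(L)):
                cs = identity.copy()
                src = orbit[:, list(perm)]
                cs[orbit.ravel()] = src.ravel()
                per_subject.append(cs)
        else:
            per_subject = [np.asarray(p, dtype=int)
                           for p in itertools.permutations(range(n_incl))]
        n_within = len(per_subject) ** n_subjects
    else:
        per_subject, n_within = None, 1

    if effect.between is not None:
        n_used = len(between.used)
        subj_perms = [np.asarray(p, dtype=int)
                      for p in itertools.permutations(range(n_used))]
    else:
        subj_perms = [None]

    total = n_within * len(subj_perms)
    if total > limit:
        raise ValueError(
            f"orbit of effect {effect.id} has {total} relabelings "
            f"(> limit {limit}); use Monte-Carlo shuffling instead")

    if per_subject is None:
        for sp in subj_perms:
            yield Relabeling(np.broadcast_to(identity, (n_subjects, n_incl)),
                             sp)
        return
    for combo in itertools.product(per_subject, repeat=n_subjects):
        cond = np.stack(combo)
        for sp in subj_perms:
            yield Relabeling(cond, sp)


def count_relabelings(within, between, effect, n_subjects: int) -> int:
    """Size of the exhaustive null orbit of one effect."""
    struct = effect_structure(within, between, effect)
    n_incl = (len(struct.included) if struct.included is not None else 1)
    n = 1
    if effect.within_factors:
        if len(effect.within_factors) == 1:
            n = math.factorial(struct.orbit.shape[1]) ** n_subjects
        else:
            n = math.factorial(n_incl) ** n_subjects
    if effect.between is not None:
        n *= math.factorial(len(between.used))
    return n
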