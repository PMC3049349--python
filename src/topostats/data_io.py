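"""Reading, writing and containing event-related scalp field data.

The on-disk exchange format is deliberately primitive: one plain ASCII
file per subject and condition holding a time x sensor matrix of
measurements (one row per time point, one column per sensor, whitespace
delimited, no header).  A whole experiment is imported from a directory
of such files via a search mask with condition tags, and lives in memory
as a single 4-D array (subjects x conditions x time x sensors) — the
:class:`ErpDataset`.

A complete analysis (data, designs, options, results) can be saved to and
restored from a single session archive so that results are never
separated from the data and parameters that produced them.
"""

from __future__ import annotations

import fnmatch
import io
import json
import zipfile
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "SensorMontage",
    "ErpDataset",
    "read_ascii_map_series",
    "write_ascii_map_series",
    "import_dataset",
    "apply_average_reference",
    "read_montage",
    "save_session",
    "load_session",
    "Session",
]

SESSION_FORMAT = "topostats-session/1"


class AsciiFormatError(ValueError):
    """Raised when an ASCII map-series file is malformed."""


class ImportError_(ValueError):
    """Raised when a directory import cannot be completed."""


@dataclass(frozen=True)
class SensorMontage:
    """Sensor names and 2-D or 3-D positions.

    Positions are used only for display and spatial interpolation of
    maps and for generating spatially correlated noise — never for the
    statistics themselves, which treat sensors as exchangeable columns.
    """

    names: tuple
    positions: np.ndarray  # (n_sensors, 2 or 3)

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "names", tuple(str(n) for n in self.names))
        if pos.ndim != 2 or pos.shape[1] not in (2, 3):
            raise ValueError("positions must be (n_sensors, 2|3)")
        if len(self.names) != pos.shape[0]:
            raise ValueError("one name per sensor position required")
        if len(set(self.names)) != len(self.names):
            raise ValueError("sensor names must be unique")

    @property
    def n_sensors(self) -> int:
        return self.positions.shape[0]


def circular_montage(n_sensors: int) -> SensorMontage:
    """Evenly spaced sensors on the unit circle (a generic 2-D layout)."""
    ang = 2 * np.pi * np.arange(n_sensors) / n_sensors
    pos = np.column_stack([np.cos(ang), np.sin(ang)])
    names = tuple(f"E{i + 1}" for i in range(n_sensors))
    return SensorMontage(names, pos)


@dataclass(frozen=True)
class ErpDataset:
    """All scalp field data of one experiment.

    ``data`` is indexed (subject, condition, time, sensor).  Missing
    cells are not allowed: every subject must have every condition with
    the identical time x sensor shape, and all values must be finite.

    ``sampling_rate`` is in Hz; ``onset_latency`` gives the latency of
    the first sample in ms relative to the event (0 = stimulus-locked
    first sample).  Units of the measurements (µV for EEG, fT for MEG)
    are carried as metadata only.
    """

    data: np.ndarray
    sampling_rate: float = 1.0
    onset_latency: float = 0.0
    subject_labels: tuple = ()
    condition_labels: tuple = ()
    montage: SensorMontage | None = None
    unit: str = "µV"
    average_referenced: bool = False

    def __post_init__(self):
        arr = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", arr)
        if arr.ndim != 4:
            raise ValueError(
                "data must be 4-D (subject, condition, time, sensor), "
                f"got shape {arr.shape}")
        if min(arr.shape) < 1:
            raise ValueError("all four dimensions must be >= 1")
        if not np.all(np.isfinite(arr)):
            raise ValueError("data contains non-finite values; "
                             "missing data is not allowed")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        subj = self.subject_labels or tuple(
            f"S{i + 1:02d}" for i in range(arr.shape[0]))
        cond = self.condition_labels or tuple(
            f"C{i + 1}" for i in range(arr.shape[1]))
        object.__setattr__(self, "subject_labels", tuple(map(str, subj)))
        object.__setattr__(self, "condition_labels", tuple(map(str, cond)))
        if len(self.subject_labels) != arr.shape[0]:
            raise ValueError("need one subject label per subject")
        if len(self.condition_labels) != arr.shape[1]:
            raise ValueError("need one condition label per condition")
        if self.montage is not None and self.montage.n_sensors != arr.shape[3]:
            raise ValueError("montage size does not match sensor count")

    # -- shape accessors ------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.data.shape[1]

    @property
    def n_time(self) -> int:
        return self.data.shape[2]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[3]

    @property
    def times_ms(self) -> np.ndarray:
        """Latency of every sample in ms relative to the event."""
        return self.onset_latency + np.arange(self.n_time) * 1000.0 / self.sampling_rate

    def ms_to_sample(self, ms: float) -> int:
        """Nearest sample index for a latency in ms (clipped to range)."""
        idx = int(round((ms - self.onset_latency) * self.sampling_rate / 1000.0))
        return int(np.clip(idx, 0, self.n_time - 1))

    def window_to_samples(self, start_ms: float, end_ms: float) -> tuple[int, int]:
        """Half-open sample interval [start, stop) covering [start_ms, end_ms)."""
        lo = int(np.ceil((start_ms - self.onset_latency) * self.sampling_rate / 1000.0 - 1e-9))
        hi = int(np.ceil((end_ms - self.onset_latency) * self.sampling_rate / 1000.0 - 1e-9))
        lo = max(lo, 0)
        hi = min(max(hi, lo + 1), self.n_time)
        if lo >= self.n_time:
            raise ValueError(f"window {start_ms}:{end_ms} ms is outside the data")
        return lo, hi


# ---------------------------------------------------------------------------
# ASCII map series
# ---------------------------------------------------------------------------

def read_ascii_map_series(path) -> np.ndarray:
    """Read one time x sensor matrix from a plain ASCII file.

    The file must contain whitespace-delimited numbers, one row per time
    point and one column per sensor, with no header.  Ragged rows and
    non-numeric tokens raise :class:`AsciiFormatError` naming the
    offending line; an empty file is an error.
    """
    path = Path(path)
    rows: list[list[float]] = []
    n_cols = None
    with open(path, "r", encoding="ascii") as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue  # blank lines are ignored
            try:
                values = [float(tok) for tok in tokens]
            except ValueError as exc:
                raise AsciiFormatError(
                    f"{path.name}, line {lineno}: non-numeric token ({exc})"
                ) from None
            if n_cols is None:
                n_cols = len(values)
            elif len(values) != n_cols:
                raise AsciiFormatError(
                    f"{path.name}, line {lineno}: expected {n_cols} columns, "
                    f"found {len(values)}")
            rows.append(values)
    if not rows:
        raise AsciiFormatError(f"{path.name}: file contains no data")
    return np.array(rows, dtype=float)


def write_ascii_map_series(matrix, path) -> None:
    """Write one time x sensor matrix as whitespace-delimited ASCII."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("matrix must be 2-D (time, sensor)")
    np.savetxt(path, m, fmt="%.15g", delimiter="\t")


def read_montage(path) -> SensorMontage:
    """Read a montage table: one line per sensor, ``name x y [z]``."""
    names, rows = [], []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens or tokens[0].startswith("#"):
                continue
            if len(tokens) not in (3, 4):
                raise AsciiFormatError(
                    f"montage line {lineno}: expected 'name x y [z]'")
            names.append(tokens[0])
            try:
                rows.append([float(t) for t in tokens[1:]])
            except ValueError:
                raise AsciiFormatError(
                    f"montage line {lineno}: non-numeric coordinate") from None
    if not names:
        raise AsciiFormatError("montage file contains no sensors")
    if len({len(r) for r in rows}) != 1:
        raise AsciiFormatError("montage mixes 2-D and 3-D coordinates")
    return SensorMontage(tuple(names), np.array(rows))


# ---------------------------------------------------------------------------
# Directory import
# ---------------------------------------------------------------------------

def _split_mask(search_mask: str, condition_tags) -> tuple[str, str, str]:
    """Locate the single condition tag inside the search mask."""
    hits = [(search_mask.find(tag), tag) for tag in condition_tags
            if search_mask.find(tag) >= 0]
    if not hits:
        raise ImportError_(
            f"none of the condition tags {list(condition_tags)} occurs in "
            f"the search mask {search_mask!r}")
    # longest match wins if tags overlap textually
    hits.sort(key=lambda h: (-len(h[1]), h[0]))
    pos, tag = hits[0]
    if any(search_mask.find(t, pos + len(tag)) >= 0 for t in condition_tags):
        other = [t for t in condition_tags
                 if search_mask.find(t, pos + len(tag)) >= 0]
        raise ImportError_(
            f"search mask {search_mask!r} must contain exactly one condition "
            f"tag; found {tag!r} and {other}")
    return search_mask[:pos], tag, search_mask[pos + len(tag):]


def import_dataset(directory, search_mask: str, condition_tags,
                   sampling_rate: float = 1.0, onset_latency: float = 0.0,
                   montage: SensorMontage | None = None,
                   apply_reference: bool = True, unit: str = "µV",
                   log=None) -> ErpDataset:
    """Import a directory of per-subject/per-condition ASCII files.

    ``search_mask`` is a glob pattern matching exactly the files of *one*
    condition; it must contain exactly one of ``condition_tags``.  The
    matched files define the subjects (sorted lexicographically by file
    name, so the order is identical across runs and platforms); the file
    names of the remaining conditions are constructed by substituting
    each tag for the one found in the mask.  A missing file or
    inconsistent matrix shapes abort the import with a message listing
    the problem.

    By default the average reference is applied to every map on import
    (appropriate for potentials); pass ``apply_reference=False`` for
    data, such as MEG, that should not be re-referenced.
    """
    directory = Path(directory)
    tags = [str(t) for t in condition_tags]
    if len(set(tags)) != len(tags):
        raise ImportError_("condition tags must be unique")
    pre, mask_tag, suf = _split_mask(search_mask, tags)

    matched = sorted(p.name for p in directory.iterdir()
                     if p.is_file() and fnmatch.fnmatch(p.name, search_mask))
    if not matched:
        raise ImportError_(
            f"search mask {search_mask!r} matched no files in {directory}")

    # subject stem = matched file name with the tag removed
    expected: dict[str, list[str]] = {}
    missing = []
    for name in matched:
        pos = _tag_position(name, pre, mask_tag, suf)
        names_per_cond = [name[:pos] + t + name[pos + len(mask_tag):]
                          for t in tags]
        expected[name] = names_per_cond
        missing += [n for n in names_per_cond if not (directory / n).exists()]
    if missing:
        raise ImportError_(
            "expected files are absent: " + ", ".join(sorted(set(missing))))

    blocks, subject_labels = [], []
    shape = None
    for name in matched:
        per_cond = []
        for fname in expected[name]:
            mat = read_ascii_map_series(directory / fname)
            if shape is None:
                shape = mat.shape
            elif mat.shape != shape:
                raise ImportError_(
                    f"{fname}: matrix shape {mat.shape} differs from "
                    f"{shape} of the first file")
            per_cond.append(mat)
        blocks.append(per_cond)
        pos = _tag_position(name, pre, mask_tag, suf)
        stem = name[:pos] + name[pos + len(mask_tag):]
        subject_labels.append(Path(stem).stem.strip("_-. ") or name)

    data = np.array(blocks)  # (subject, condition, time, sensor)
    ds = ErpDataset(data, sampling_rate=sampling_rate,
                    onset_latency=onset_latency,
                    subject_labels=tuple(subject_labels),
                    condition_labels=tuple(tags), montage=montage, unit=unit)
    if apply_reference:
        ds = apply_average_reference(ds)
    if log is not None:
        log(f"imported {ds.n_subjects} subjects x {ds.n_conditions} "
            f"conditions x {ds.n_time} time points x {ds.n_sensors} sensors")
    return ds


def _tag_position(name: str, pre: str, tag: str, suf: str) -> int:
    """Index of the condition tag inside a matched file name."""
    # the prefix part of the mask may contain wildcards; search for the tag
    # at every position consistent with the fixed suffix after it
    candidates = []
    start = 0
    while True:
        pos = name.find(tag, start)
        if pos < 0:
            break
        if fnmatch.fnmatch(name[:pos], pre) and fnmatch.fnmatch(
                name[pos + len(tag):], suf):
            candidates.append(pos)
        start = pos + 1
    if not candidates:
        raise ImportError_(
            f"cannot locate the condition tag {tag!r} inside {name!r}")
    return candidates[0]


def apply_average_reference(dataset: ErpDataset) -> ErpDataset:
    """Re-express every map relative to its mean across sensors.

    After re-referencing every (subject, condition, time) map has zero
    spatial mean.  The operation is idempotent and leaves the GFP of
    every map unchanged.
    """
    if dataset.n_sensors < 2:
        raise ValueError("average reference is undefined for < 2 sensors")
    data = dataset.data - dataset.data.mean(axis=3, keepdims=True)
    return replace(dataset, data=data, average_referenced=True)


# ---------------------------------------------------------------------------
# Session container
# ---------------------------------------------------------------------------

class Session:
    """One self-contained analysis: data, designs, options and results.

    Keeping everything in one archive rules out uncertainty about which
    results were obtained with which data and parameters.
    """

    def __init__(self, dataset, within=None, between=None, options=None,
                 results=None):
        self.dataset = dataset
        self.within = within
        self.between = between
        self.options = dict(options or {})
        self.results = dict(results or {})


def _encode(obj, arrays: dict, prefix: str):
    """Recursively JSON-encode, hoisting ndarrays into ``arrays``."""
    if isinstance(obj, np.ndarray):
        key = f"arr_{len(arrays):05d}"
        arrays[key] = obj
        return {"__array__": key}
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _encode(v, arrays, prefix) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_encode(v, arrays, prefix) for v in obj]
    if obj is None or isinstance(obj, (bool, int, float, str)):
        return obj
    if hasattr(obj, "to_dict"):
        return {"__object__": type(obj).__name__,
                "state": _encode(obj.to_dict(), arrays, prefix)}
    raise TypeError(f"cannot serialize {type(obj).__name__} into a session")


def _decode(obj, arrays: dict, registry: dict):
    if isinstance(obj, dict):
        if "__array__" in obj:
            return arrays[obj["__array__"]]
        if "__object__" in obj:
            cls = registry[obj["__object__"]]
            return cls.from_dict(_decode(obj["state"], arrays, registry))
        return {k: _decode(v, arrays, registry) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_decode(v, arrays, registry) for v in obj]
    return obj


def _registry() -> dict:
    from . import designs, randomization, global_inference, tct
    classes = [designs.WithinDesign, designs.BetweenDesign,
               randomization.RandomizationResult,
               global_inference.GlobalInference, tct.TctResult]
    return {cls.__name__: cls for cls in classes}


def save_session(session: Session, path) -> None:
    """Write a session to a single versioned archive.

    The archive is a zip holding a JSON manifest plus one ``.npy`` entry
    per array; arrays round-trip bit-exactly.
    """
    ds = session.dataset
    arrays: dict[str, np.ndarray] = {}
    manifest = {
        "format": SESSION_FORMAT,
        "dataset": {
            "data": _encode(ds.data, arrays, "d"),
            "sampling_rate": ds.sampling_rate,
            "onset_latency": ds.onset_latency,
            "subject_labels": list(ds.subject_labels),
            "condition_labels": list(ds.condition_labels),
            "unit": ds.unit,
            "average_referenced": ds.average_referenced,
            "montage": None if ds.montage is None else {
                "names": list(ds.montage.names),
                "positions": _encode(ds.montage.positions, arrays, "m"),
            },
        },
        "within": _encode(session.within, arrays, "w"),
        "between": _encode(session.between, arrays, "b"),
        "options": _encode(session.options, arrays, "o"),
        "results": _encode(session.results, arrays, "r"),
    }
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("manifest.json", json.dumps(manifest, indent=1))
        for key, arr in arrays.items():
            buf = io.BytesIO()
            np.save(buf, np.ascontiguousarray(arr), allow_pickle=False)
            zf.writestr(f"arrays/{key}.npy", buf.getvalue())


def load_session(path) -> Session:
    """Load a session archive written by :func:`save_session`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with zipfile.ZipFile(path, "r") as zf:
            manifest = json.loads(zf.read("manifest.json"))
            arrays = {}
            for info in zf.namelist():
                if info.startswith("arrays/") and info.endswith(".npy"):
                    arrays[Path(info).stem] = np.load(
                        io.BytesIO(zf.read(info)), allow_pickle=False)
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError) as exc:
        raise ValueError(f"{path}: not a readable session archive ({exc})")
    fmt = manifest.get("format")
    if fmt != SESSION_FORMAT:
        raise ValueError(
            f"{path}: session format {fmt!r} is not supported "
            f"(expected {SESSION_FORMAT!r})")
    reg = _registry()
    dsm = manifest["dataset"]
    montage = None
    if dsm.get("montage"):
        montage = SensorMontage(
            tuple(dsm["montage"]["names"]),
            _decode(dsm["montage"]["positions"], arrays, reg))
    dataset = ErpDataset(
        _decode(dsm["data"], arrays, reg),
        sampling_rate=dsm["sampling_rate"],
        onset_latency=dsm["onset_latency"],
        subject_labels=tuple(dsm["subject_labels"]),
        condition_labels=tuple(dsm["condition_labels"]),
        montage=montage, unit=dsm["unit"],
        average_referenced=dsm["average_referenced"])
    return Session(
        dataset,
        within=_decode(manifest["within"], arrays, reg),
        between=_decode(manifest["between"], arrays, reg),
        options=_decode(manifest["options"], arrays, reg),
        results=_decode(manifest["results"], arrays, reg),
    )
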