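"""In-memory containers and array primitives shared by writer, reader and
validator.

NSDF distinguishes four categories of recorded data:

* **uniform** — a variable sampled from P sources at Q shared, regularly
  spaced time points; a P x Q matrix plus ``tstart``/``dt`` (or an explicit
  time axis).  Column j corresponds to time ``tstart + j*dt`` (0-based j).
* **nonuniform** — per-source series with explicitly stored sampling times,
  as produced by adaptive-timestep solvers.  When all sources share one time
  array the set is eligible for the regular-2D (NUREGULAR) storage variant.
* **event** — per-source arrays of occurrence times (spikes); lengths differ
  across sources and there is no value axis, only times.
* **static** — non-time-varying tables: morphology coordinates, synaptic
  connectivity, biophysical parameters.

Ragged per-source arrays can be serialized three ways (``ONED``: one 1D
dataset per source, ``VLEN``: a ragged HDF5 dataset, ``NANPADDED``: a regular
matrix padded with trailing NaN); :func:`nan_pad` / :func:`nan_unpad`
implement the padded representation.  NaN is reserved strictly as the padding
sentinel, so payload NaN is rejected on the way in and an interior NaN on the
way out is a format error rather than data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field
from enum import Enum
from typing import Iterator, Sequence

import numpy as np

from .exceptions import FormatError, InvalidArgumentError

__all__ = [
    "Variant", "StaticLayout", "CATEGORIES",
    "UniformBlock", "RaggedSeries", "EventSet", "StaticTable",
    "Column", "ModelNode", "FileMetadata",
    "uniform_time_axis", "make_uid", "split_uid", "nan_pad", "nan_unpad",
]

#: Level-2 category group names under /data and /map.
CATEGORIES = ("static", "uniform", "nonuniform", "event")

NSDF_VERSION = "1.0"


class Variant(str, Enum):
    """Storage variants for ragged (nonuniform/event) data.

    NUREGULAR (shared sampling times stored as one regular 2D matrix) applies
    to nonuniform data only; events never have a shared time axis.
    """

    NUREGULAR = "NUREGULAR"
    ONED = "ONED"
    VLEN = "VLEN"
    NANPADDED = "NANPADDED"


class StaticLayout(str, Enum):
    HOMOGENEOUS_2D = "HOMOGENEOUS_2D"
    COMPOUND = "COMPOUND"


# ---------------------------------------------------------------------------
# array primitives
# ---------------------------------------------------------------------------

def uniform_time_axis(tstart: float, dt: float, n: int) -> np.ndarray:
    """Sampling times of *n* uniformly spaced samples.

    Column j (0-based) of a uniform dataset was sampled at
    ``tstart + j * dt``; equivalently the k-th sample in 1-based counting
    falls at ``tstart + (k - 1) * dt``.
    """
    if not dt > 0:
        raise InvalidArgumentError(f"dt must be positive, got {dt}")
    if n < 0:
        raise InvalidArgumentError(f"n must be >= 0, got {n}")
    return tstart + dt * np.arange(n, dtype=np.float64)


def make_uid(path_components: Sequence[str]) -> str:
    """Join path components into a '/'-rooted unique identifier.

    Tree-structured models use the element path as the uid, so distinct
    component lists map to distinct uids and the components can be recovered
    by splitting on '/'.
    """
    if not path_components:
        raise InvalidArgumentError("path_components must be nonempty")
    for c in path_components:
        if not isinstance(c, str) or c == "":
            raise InvalidArgumentError("path components must be nonempty strings")
        if "/" in c:
            raise InvalidArgumentError(f"path component contains '/': {c!r}")
    return "/" + "/".join(path_components)


def split_uid(uid: str) -> list[str]:
    """Inverse of :func:`make_uid` for uids produced by it."""
    if not uid.startswith("/"):
        raise InvalidArgumentError(f"not a rooted uid: {uid!r}")
    return uid.lstrip("/").split("/")


def nan_pad(rows: Sequence[np.ndarray]) -> np.ndarray:
    """Stack ragged rows into a regular 2D matrix padded with trailing NaN.

    NaN is reserved as the padding sentinel, so rows containing NaN are
    rejected rather than silently round-tripped into ambiguity.
    """
    if len(rows) == 0:
        raise InvalidArgumentError("need at least one row")
    arrs = [np.asarray(r, dtype=np.float64) for r in rows]
    for i, a in enumerate(arrs):
        if a.ndim != 1:
            raise InvalidArgumentError(f"row {i} is not 1-D")
        if np.isnan(a).any():
            raise InvalidArgumentError(
                f"row {i} contains NaN; NaN is reserved as padding")
    width = max((a.size for a in arrs), default=0)
    out = np.full((len(arrs), width), np.nan, dtype=np.float64)
    for i, a in enumerate(arrs):
        out[i, : a.size] = a
    return out


def nan_unpad(matrix: np.ndarray) -> list[np.ndarray]:
    """Strip trailing-NaN padding from each row of a 2D matrix.

    In every row NaNs must form a contiguous suffix; a valid value appearing
    after a NaN is a format error (the row cannot be distinguished from
    corrupted padding).
    """
    m = np.asarray(matrix, dtype=np.float64)
    if m.ndim != 2:
        raise InvalidArgumentError("expected a 2-D matrix")
    rows: list[np.ndarray] = []
    for i in range(m.shape[0]):
        row = m[i]
        mask = np.isnan(row)
        if not mask.any():
            rows.append(row.copy())
            continue
        first = int(np.argmax(mask))
        if not mask[first:].all():
            raise FormatError(f"row {i} has an interior NaN (valid value "
                              "after padding started)")
        rows.append(row[:first].copy())
    return rows


def _as_f8(a, name: str) -> np.ndarray:
    out = np.asarray(a, dtype=np.float64)
    if out.ndim != 1:
        raise InvalidArgumentError(f"{name} must be 1-D")
    return out


def _check_increasing(times: np.ndarray, what: str, strict: bool = True) -> None:
    if times.size > 1:
        d = np.diff(times)
        if strict and not (d > 0).all():
            raise InvalidArgumentError(f"{what} must be strictly increasing")
        if not strict and not (d >= 0).all():
            raise InvalidArgumentError(f"{what} must be nondecreasing")


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class UniformBlock:
    """A variable recorded from P sources at Q shared, regular time points.

    ``values[i, j]`` is the sample from ``sources[i]`` at time
    ``tstart + j*dt``.  An ``explicit_times`` axis may be given instead of
    (or in addition to) ``tstart``/``dt``; when both are present they must
    agree and readers prefer the explicit axis.
    """

    population: str
    variable: str
    sources: list[str]
    values: np.ndarray
    unit: str
    tstart: float = 0.0
    dt: float | None = None
    tunit: str = "s"
    field: str | None = None
    explicit_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise InvalidArgumentError("values must be a 2-D matrix")
        if self.values.shape[0] != len(self.sources):
            raise InvalidArgumentError(
                f"values has {self.values.shape[0]} rows but "
                f"{len(self.sources)} sources")
        if self.field is None:
            self.field = self.variable
        if self.explicit_times is not None:
            self.explicit_times = _as_f8(self.explicit_times, "explicit_times")
            if self.explicit_times.size != self.values.shape[1]:
                raise InvalidArgumentError(
                    "explicit_times length does not match column count")
            _check_increasing(self.explicit_times, "explicit_times")
        elif self.dt is None or not self.dt > 0:
            raise InvalidArgumentError(
                "need dt > 0 when explicit_times is absent")

    @property
    def n_sources(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Sampling times: the explicit axis if present, else computed."""
        if self.explicit_times is not None:
            return self.explicit_times
        return uniform_time_axis(self.tstart, self.dt, self.n_samples)

    def __eq__(self, other) -> bool:
        if not isinstance(other, UniformBlock):
            return NotImplemented
        return (
            self.population == other.population
            and self.variable == other.variable
            and self.sources == other.sources
            and self.unit == other.unit
            and self.tunit == other.tunit
            and self.field == other.field
            and np.array_equal(self.values, other.values)
            and np.array_equal(self.times, other.times)
        )


@dataclass
class RaggedSeries:
    """Per-source value series with explicitly stored sampling times.

    ``entries`` is an ordered list of ``(uid, values, times)`` with
    ``len(values) == len(times)`` for every source.  Alternatively a single
    ``shared_times`` array may serve all sources (entry ``times`` then
    ``None``), which makes the series eligible for NUREGULAR storage.
    """

    population: str
    variable: str
    entries: list[tuple[str, np.ndarray, np.ndarray | None]]
    unit: str
    tunit: str = "s"
    field: str | None = None
    shared_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.field is None:
            self.field = self.variable
        if self.shared_times is not None:
            self.shared_times = _as_f8(self.shared_times, "shared_times")
            _check_increasing(self.shared_times, "shared_times")
        fixed = []
        for uid, values, times in self.entries:
            values = _as_f8(values, f"values of {uid}")
            if times is None:
                if self.shared_times is None:
                    raise InvalidArgumentError(
                        f"entry {uid} has no times and no shared_times set")
                if values.size != self.shared_times.size:
                    raise InvalidArgumentError(
                        f"entry {uid}: values length {values.size} != "
                        f"shared_times length {self.shared_times.size}")
            else:
                times = _as_f8(times, f"times of {uid}")
                if values.size != times.size:
                    raise InvalidArgumentError(
                        f"entry {uid}: values length {values.size} != "
                        f"times length {times.size}")
                _check_increasing(times, f"times of {uid}")
            fixed.append((uid, values, times))
        self.entries = fixed

    @property
    def sources(self) -> list[str]:
        return [uid for uid, _, _ in self.entries]

    def times_for(self, i: int) -> np.ndarray:
        uid, _, times = self.entries[i]
        if times is not None:
            return times
        return self.shared_times

    @property
    def homogeneous_times(self) -> bool:
        """True when all sources sample at one shared set of time points."""
        return self.shared_times is not None and all(
            t is None or np.array_equal(t, self.shared_times)
            for _, _, t in self.entries)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RaggedSeries):
            return NotImplemented
        if (self.population, self.variable, self.unit, self.tunit,
                self.field) != (other.population, other.variable, other.unit,
                                other.tunit, other.field):
            return False
        if len(self.entries) != len(other.entries):
            return False
        for i, ((ua, va, _), (ub, vb, _)) in enumerate(
                zip(self.entries, other.entries)):
            if ua != ub or not np.array_equal(va, vb):
                return False
            if not np.array_equal(self.times_for(i), other.times_for(i)):
                return False
        return True


@dataclass
class EventSet:
    """Per-source arrays of event (e.g. spike) times; lengths may differ."""

    population: str
    variable: str
    entries: list[tuple[str, np.ndarray]]
    unit: str = "s"
    field: str | None = None

    def __post_init__(self) -> None:
        if self.field is None:
            self.field = self.variable
        fixed = []
        for uid, times in self.entries:
            times = _as_f8(times, f"event times of {uid}")
            _check_increasing(times, f"event times of {uid}", strict=False)
            fixed.append((uid, times))
        self.entries = fixed

    @property
    def sources(self) -> list[str]:
        return [uid for uid, _ in self.entries]

    def counts(self) -> dict[str, int]:
        return {uid: times.size for uid, times in self.entries}

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventSet):
            return NotImplemented
        if (self.population, self.variable, self.unit, self.field) != (
                other.population, other.variable, other.unit, other.field):
            return False
        return len(self.entries) == len(other.entries) and all(
            ua == ub and np.array_equal(ta, tb)
            for (ua, ta), (ub, tb) in zip(self.entries, other.entries))


@dataclass
class Column:
    """One column of a static table: label, unit ('' for non-physical
    columns such as indices or identifiers) and one value per source."""

    label: str
    unit: str
    values: np.ndarray | list

    def is_string(self) -> bool:
        a = np.asarray(self.values)
        return a.dtype.kind in ("U", "S", "O")


@dataclass
class StaticTable:
    """Non-time-varying data for a population.

    ``HOMOGENEOUS_2D``: all columns numeric, stored as one 2D matrix with a
    column-label scale; a single shared unit is permitted via ``unit``.
    ``COMPOUND``: a record-style table with named, individually-united
    fields (columns holding identifiers get the empty-string unit).
    """

    population: str
    name: str
    sources: list[str]
    layout: StaticLayout
    columns: list[Column]
    unit: str | None = None  # shared unit, HOMOGENEOUS_2D only

    def __post_init__(self) -> None:
        if not self.columns:
            raise InvalidArgumentError("table needs at least one column")
        n = len(self.sources)
        for col in self.columns:
            if len(col.values) != n:
                raise InvalidArgumentError(
                    f"column {col.label!r} has {len(col.values)} values for "
                    f"{n} sources")
        if self.layout == StaticLayout.HOMOGENEOUS_2D:
            for col in self.columns:
                if col.is_string():
                    raise InvalidArgumentError(
                        "HOMOGENEOUS_2D requires numeric columns; use the "
                        "COMPOUND layout for string fields")

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.columns]

    @property
    def units(self) -> list[str]:
        if self.layout == StaticLayout.HOMOGENEOUS_2D and self.unit is not None:
            return [self.unit] * len(self.columns)
        return [c.unit for c in self.columns]

    def matrix(self) -> np.ndarray:
        """Column-stacked numeric matrix (HOMOGENEOUS_2D layout only)."""
        return np.column_stack(
            [np.asarray(c.values, dtype=np.float64) for c in self.columns])

    def __eq__(self, other) -> bool:
        if not isinstance(other, StaticTable):
            return NotImplemented
        if (self.population, self.name, self.sources, self.layout,
                self.labels, self.units) != (
                other.population, other.name, other.sources, other.layout,
                other.labels, other.units):
            return False
        for ca, cb in zip(self.columns, other.columns):
            if ca.is_string() != cb.is_string():
                return False
            if ca.is_string():
                if list(ca.values) != list(cb.values):
                    return False
            elif not np.array_equal(np.asarray(ca.values, dtype=np.float64),
                                    np.asarray(cb.values, dtype=np.float64)):
                return False
        return True


# ---------------------------------------------------------------------------
# model tree
# ---------------------------------------------------------------------------

@dataclass
class ModelNode:
    """Node of the fallback hierarchical model description.

    The tree is not a runnable model definition; it exists to uniquely
    identify each component whose data are stored.  ``uid`` must be unique
    within one file and is conventionally the '/'-joined tree path.
    ``map_refs`` lists paths of mapping datasets holding data recorded from
    this component, so tools can jump from model to data without scanning.
    """

    name: str
    uid: str | None = None
    ontology: str | None = None
    attributes: dict[str, str] = dc_field(default_factory=dict)
    children: list["ModelNode"] = dc_field(default_factory=list)
    map_refs: list[str] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        if "/" in self.name or self.name == "":
            raise InvalidArgumentError(
                f"node name must be nonempty without '/': {self.name!r}")

    def add_child(self, child: "ModelNode") -> "ModelNode":
        if any(c.name == child.name for c in self.children):
            raise InvalidArgumentError(
                f"duplicate sibling name {child.name!r} under {self.name!r}")
        self.children.append(child)
        return child

    def walk(self) -> Iterator["ModelNode"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def assign_path_uids(self, prefix: Sequence[str] = ("model", "modeltree")) -> None:
        """Set each node's uid to its '/'-joined path below /model/modeltree."""
        self.uid = make_uid([*prefix, self.name])
        for c in self.children:
            c.assign_path_uids((*prefix, self.name))

    def find(self, uid: str) -> "ModelNode | None":
        for node in self.walk():
            if node.uid == uid:
                return node
        return None

    def isomorphic(self, other: "ModelNode") -> bool:
        """Structural equality: names, uids, ontology and child order."""
        if (self.name, self.uid, self.ontology) != (
                other.name, other.uid, other.ontology):
            return False
        if len(self.children) != len(other.children):
            return False
        return all(a.isomorphic(b)
                   for a, b in zip(self.children, other.children))


# ---------------------------------------------------------------------------
# file metadata
# ---------------------------------------------------------------------------

_ISO8601_RE = re.compile(
    r"^\d{4}-\d{2}-\d{2}([T ]\d{2}:\d{2}(:\d{2}(\.\d+)?)?"
    r"(Z|[+-]\d{2}:?\d{2})?)?$")


def is_iso8601(value: str) -> bool:
    """Loose ISO 8601 date-time check (date, optional time, optional zone)."""
    return bool(_ISO8601_RE.match(value))


#: Root attributes every file should carry.
CORE_ROOT_ATTRIBUTES = ("title", "creator", "created", "software", "method",
                        "nsdf_version")
#: Root attributes that are recommended but optional.
OPTIONAL_ROOT_ATTRIBUTES = ("description", "contributor", "license", "rights",
                            "tstart", "tend")


@dataclass
class FileMetadata:
    """Root-group attributes describing the file and its provenance.

    ``created``/``tstart``/``tend`` are ISO 8601 date-time strings;
    ``software`` and ``method`` may be single strings or lists.
    """

    title: str = ""
    description: str | None = None
    creator: str | list[str] = ""
    contributor: str | list[str] | None = None
    created: str | None = None
    license: str | None = None
    rights: str | None = None
    tstart: str | None = None
    tend: str | None = None
    software: str | list[str] = ""
    method: str | list[str] = ""
    nsdf_version: str = NSDF_VERSION

    def __post_init__(self) -> None:
        if self.created is None:
            from datetime import datetime, timezone
            self.created = datetime.now(timezone.utc).strftime(
                "%Y-%m-%dT%H:%M:%SZ")
        if not self.nsdf_version:
            raise InvalidArgumentError("nsdf_version must be nonempty")
        for attr in ("created", "tstart", "tend"):
            v = getattr(self, attr)
            if v is not None and not is_iso8601(v):
                raise InvalidArgumentError(
                    f"{attr} is not an ISO 8601 date-time: {v!r}")

    def to_attrs(self) -> dict[str, object]:
        out: dict[str, object] = {}
        for key in CORE_ROOT_ATTRIBUTES + OPTIONAL_ROOT_ATTRIBUTES:
            v = getattr(self, key)
            if v is None:
                continue
            out[key] = list(v) if isinstance(v, (list, tuple)) else v
        return out
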