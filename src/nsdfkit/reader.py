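"""Reading NSDF files: variant detection, container reconstruction, source
resolution and chunked column access.

The reader is tolerant by design: unknown extra attributes and groups are
ignored (files may carry arbitrary user metadata), and the storage variant of
every variable is detected from the layout rather than trusted from any
writer-side convention.  Source order is always taken from the stored scale
or map table, never re-sorted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import h5py
import numpy as np

from ._h5 import as_str, dim_scales, is_vlen_float, read_str_dataset
from .core import (CATEGORIES, Column, EventSet, ModelNode, RaggedSeries,
                   StaticLayout, StaticTable, UniformBlock, Variant,
                   nan_unpad, uniform_time_axis)
from .exceptions import (BrokenMappingError, FormatError,
                         IncompleteMetadataError, InvalidArgumentError,
                         StructureError)

__all__ = ["FileIndex", "open_index", "detect_variant", "read_uniform",
           "read_events", "read_nonuniform", "read_static",
           "read_column_range", "read_modeltree", "sources_to_data"]


def detect_variant(category: str, node) -> Variant | None:
    """Classify the storage variant of a level-4 node under /data.

    * a group of 1D datasets (with a source/data map table) -> ONED
    * a ragged dataset -> VLEN
    * a 2D matrix: events -> NANPADDED; nonuniform -> NANPADDED when its
      time scale is itself a padded matrix (or values carry NaN suffixes),
      NUREGULAR when a shared 1D time scale is attached.

    Uniform and static data are variant-free; ``None`` is returned for them
    and for unrecognizable layouts.
    """
    if isinstance(node, h5py.Group):
        if category in ("nonuniform", "event"):
            return Variant.ONED
        return None
    if not isinstance(node, h5py.Dataset):
        return None
    if is_vlen_float(node):
        return Variant.VLEN
    if category == "event":
        return Variant.NANPADDED if node.ndim == 2 else None
    if category == "nonuniform" and node.ndim == 2:
        tscale = dim_scales(node, 1).get("time")
        if tscale is not None and tscale.ndim == 1:
            return Variant.NUREGULAR
        if tscale is not None and tscale.ndim == 2:
            return Variant.NANPADDED
        return (Variant.NANPADDED
                if np.isnan(node[...]).any() else Variant.NUREGULAR)
    return None


@dataclass
class FileIndex:
    """Open handle plus an inventory of an NSDF file.

    ``entries[category][population][variable]`` holds the detected
    :class:`Variant` (``None`` for the variant-free uniform/static
    categories); ``model_kinds`` lists which model-description mechanisms
    are present; ``violations`` collects layouts the scan could not
    classify (reported, not raised).
    """

    path: str
    entries: dict[str, dict[str, dict[str, Variant | None]]]
    model_kinds: list[str]
    violations: list[str] = dc_field(default_factory=list)
    _h5: h5py.File | None = None

    @property
    def h5(self) -> h5py.File:
        if self._h5 is None or not self._h5.id.valid:
            self._h5 = h5py.File(self.path, "r")
        return self._h5

    def close(self) -> None:
        if self._h5 is not None and self._h5.id.valid:
            self._h5.close()

    def __enter__(self) -> "FileIndex":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def variables(self, category: str) -> list[tuple[str, str]]:
        return [(pop, var)
                for pop, variables in self.entries.get(category, {}).items()
                for var in variables]

    def variant_of(self, category: str, population: str,
                   variable: str) -> Variant | None:
        return self.entries[category][population][variable]

    # convenience method forms of the module-level readers
    def read_uniform(self, population, variable):
        return read_uniform(self, population, variable)

    def read_events(self, population, variable):
        return read_events(self, population, variable)

    def read_nonuniform(self, population, variable):
        return read_nonuniform(self, population, variable)

    def read_static(self, population, name):
        return read_static(self, population, name)


def open_index(path) -> FileIndex:
    """Open a file and enumerate its populations, variables and variants."""
    f = h5py.File(path, "r")
    if "data" not in f:
        f.close()
        raise StructureError(f"{path}: missing /data — not an NSDF file")
    entries: dict[str, dict[str, dict[str, Variant | None]]] = {}
    violations: list[str] = []
    for category in CATEGORIES:
        cat_grp = f["data"].get(category)
        if cat_grp is None:
            continue
        entries[category] = {}
        for pop_name, pop in cat_grp.items():
            if not isinstance(pop, h5py.Group):
                violations.append(f"/data/{category}/{pop_name}: "
                                  "expected a population group")
                continue
            entries[category][pop_name] = {}
            for var_name, node in pop.items():
                variant = detect_variant(category, node)
                if (variant is None
                        and category in ("nonuniform", "event")):
                    violations.append(
                        f"{node.name}: unrecognizable {category} layout")
                entries[category][pop_name][var_name] = variant
    model_kinds = []
    model = f.get("model")
    if model is not None:
        for kind in ("modeltree", "filecontents", "filerefs", "links"):
            node = model.get(kind)
            if node is not None and len(node) > 0:
                model_kinds.append(kind)
    ix = FileIndex(path=str(path), entries=entries, model_kinds=model_kinds,
                   violations=violations)
    ix._h5 = f
    return ix


def _get_variable(ix: FileIndex, category: str, population: str,
                  variable: str):
    try:
        node = ix.h5[f"data/{category}/{population}/{variable}"]
    except KeyError:
        raise InvalidArgumentError(
            f"no {category} variable {population}/{variable}") from None
    return node


def _sources_of(node) -> list[str]:
    scales = dim_scales(node, 0)
    if "source" not in scales:
        raise BrokenMappingError(
            f"{node.name}: no 'source' dimension scale attached")
    return read_str_dataset(scales["source"])


# ---------------------------------------------------------------------------
# uniform
# ---------------------------------------------------------------------------

def _uniform_times(ds) -> tuple[np.ndarray, str]:
    """Time axis of a uniform dataset.

    The explicit ``time`` scale takes precedence over ``tstart``/``dt``
    attributes; when both exist and disagree beyond 1e-9 relative tolerance
    a warning is emitted (the scale still wins).
    """
    scales = dim_scales(ds, 1)
    tscale = scales.get("time")
    has_attrs = "tstart" in ds.attrs and "dt" in ds.attrs
    if tscale is not None:
        times = tscale[...].astype(np.float64)
        tunit = as_str(tscale.attrs.get("unit", "s"))
        if has_attrs:
            computed = uniform_time_axis(float(ds.attrs["tstart"]),
                                         float(ds.attrs["dt"]), times.size)
            scale_ref = np.maximum(np.abs(times), 1e-300)
            if np.any(np.abs(computed - times) / scale_ref > 1e-9):
                warnings.warn(
                    f"{ds.name}: tstart/dt attributes disagree with the "
                    "explicit time scale; using the scale", stacklevel=2)
        return times, tunit
    if has_attrs:
        times = uniform_time_axis(float(ds.attrs["tstart"]),
                                  float(ds.attrs["dt"]), ds.shape[1])
        return times, as_str(ds.attrs.get("tunit", "s"))
    raise IncompleteMetadataError(
        f"{ds.name}: neither tstart/dt attributes nor a time scale present")


def read_uniform(ix: FileIndex, population: str,
                 variable: str) -> UniformBlock:
    """Reconstruct a uniform block: values, sources and the time axis."""
    ds = _get_variable(ix, "uniform", population, variable)
    sources = _sources_of(ds)
    times, tunit = _uniform_times(ds)
    has_scale = "time" in dim_scales(ds, 1)
    return UniformBlock(
        population=population, variable=variable, sources=sources,
        values=ds[...], unit=as_str(ds.attrs.get("unit", "")),
        tstart=float(times[0]) if times.size else 0.0,
        dt=(float(ds.attrs["dt"]) if "dt" in ds.attrs and not has_scale
            else None),
        tunit=tunit, field=as_str(ds.attrs.get("field", variable)),
        explicit_times=times if (has_scale or times.size == 0) else None)


def read_column_range(ix: FileIndex, population: str, variable: str,
                      j0: int, j1: int) -> UniformBlock:
    """Read columns [j0, j1) of a uniform dataset with the matching,
    correctly offset time axis.  Concatenating consecutive ranges
    reproduces the full read."""
    ds = _get_variable(ix, "uniform", population, variable)
    q = ds.shape[1]
    if not (0 <= j0 <= j1 <= q):
        raise InvalidArgumentError(
            f"column range [{j0}, {j1}) out of bounds for Q={q}")
    sources = _sources_of(ds)
    times, tunit = _uniform_times(ds)
    return UniformBlock(
        population=population, variable=variable, sources=sources,
        values=ds[:, j0:j1], unit=as_str(ds.attrs.get("unit", "")),
        tunit=tunit, field=as_str(ds.attrs.get("field", variable)),
        explicit_times=times[j0:j1])


# ---------------------------------------------------------------------------
# ragged categories
# ---------------------------------------------------------------------------

def _oned_members(ix: FileIndex, grp) -> list[tuple[str, h5py.Dataset]]:
    """(uid, dataset) pairs of an ONED variable group, in map-table order."""
    tbl_path = grp.attrs.get("source")
    if tbl_path is None:
        raise BrokenMappingError(
            f"{grp.name}: ONED group lacks the 'source' map-table attribute")
    try:
        tbl = ix.h5[as_str(tbl_path)]
    except KeyError:
        raise BrokenMappingError(
            f"{grp.name}: map table {as_str(tbl_path)!r} missing") from None
    out = []
    for row in tbl[...]:
        uid, dpath = as_str(row["source"]), as_str(row["data"])
        try:
            ds = ix.h5[dpath]
        except KeyError:
            raise BrokenMappingError(
                f"{grp.name}: map row for {uid!r} points to missing dataset "
                f"{dpath!r}") from None
        out.append((uid, ds))
    return out


def read_events(ix: FileIndex, population: str, variable: str) -> EventSet:
    """Variant-independent event read-back.

    Sources come back in stored order: scale order for VLEN/NANPADDED,
    map-table order for ONED.  NaN padding is stripped.
    """
    node = _get_variable(ix, "event", population, variable)
    variant = detect_variant("event", node)
    if variant == Variant.ONED:
        entries = [(uid, ds[...]) for uid, ds in _oned_members(ix, node)]
        unit = (as_str(node[next(iter(node))].attrs.get("unit", "s"))
                if len(node) else "s")
        field = (as_str(node[next(iter(node))].attrs.get("field", variable))
                 if len(node) else variable)
        return EventSet(population=population, variable=variable,
                        entries=entries, unit=unit, field=field)
    sources = _sources_of(node)
    if variant == Variant.VLEN:
        rows = [node[i].astype(np.float64) for i in range(node.shape[0])]
    elif variant == Variant.NANPADDED:
        rows = nan_unpad(node[...])
    else:
        raise FormatError(f"{node.name}: unrecognizable event layout")
    return EventSet(population=population, variable=variable,
                    entries=list(zip(sources, rows)),
                    unit=as_str(node.attrs.get("unit", "s")),
                    field=as_str(node.attrs.get("field", variable)))


def read_nonuniform(ix: FileIndex, population: str,
                    variable: str) -> RaggedSeries:
    """Variant-independent nonuniform read-back with per-source times."""
    node = _get_variable(ix, "nonuniform", population, variable)
    variant = detect_variant("nonuniform", node)
    common = dict(population=population, variable=variable)
    if variant == Variant.ONED:
        entries = []
        unit = tunit = None
        field = variable
        for uid, ds in _oned_members(ix, node):
            tscale = dim_scales(ds, 0).get("time")
            if tscale is None:
                raise BrokenMappingError(
                    f"{ds.name}: no time scale on ONED nonuniform dataset")
            entries.append((uid, ds[...], tscale[...].astype(np.float64)))
            unit = as_str(ds.attrs.get("unit", ""))
            tunit = as_str(tscale.attrs.get("unit", "s"))
            field = as_str(ds.attrs.get("field", variable))
        return RaggedSeries(entries=entries, unit=unit or "",
                            tunit=tunit or "s", field=field, **common)
    sources = _sources_of(node)
    unit = as_str(node.attrs.get("unit", ""))
    field = as_str(node.attrs.get("field", variable))
    if variant == Variant.NUREGULAR:
        tscale = dim_scales(node, 1).get("time")
        if tscale is None:
            raise BrokenMappingError(
                f"{node.name}: NUREGULAR dataset lacks a shared time scale")
        shared = tscale[...].astype(np.float64)
        values = node[...]
        return RaggedSeries(
            entries=[(uid, values[i], None) for i, uid in enumerate(sources)],
            shared_times=shared, unit=unit,
            tunit=as_str(tscale.attrs.get("unit", "s")), field=field,
            **common)
    if variant == Variant.VLEN:
        tscale = dim_scales(node, 0).get("time")
        if tscale is None:
            raise BrokenMappingError(
                f"{node.name}: VLEN nonuniform dataset lacks a time scale")
        entries = [(uid, node[i].astype(np.float64),
                    tscale[i].astype(np.float64))
                   for i, uid in enumerate(sources)]
        for uid, v, t in entries:
            if v.size != t.size:
                raise FormatError(
                    f"{node.name}: row for {uid!r} has {v.size} values but "
                    f"{t.size} times")
        return RaggedSeries(entries=entries, unit=unit,
                            tunit=as_str(tscale.attrs.get("unit", "s")),
                            field=field, **common)
    if variant == Variant.NANPADDED:
        tscale = dim_scales(node, 1).get("time")
        if tscale is None:
            raise BrokenMappingError(
                f"{node.name}: NANPADDED nonuniform dataset lacks a time "
                "scale")
        values_mat, times_mat = node[...], tscale[...]
        if not np.array_equal(np.isnan(values_mat), np.isnan(times_mat)):
            raise FormatError(
                f"{node.name}: NaN masks of values and times are not "
                "congruent")
        value_rows = nan_unpad(values_mat)
        time_rows = nan_unpad(times_mat)
        return RaggedSeries(
            entries=[(uid, value_rows[i], time_rows[i])
                     for i, uid in enumerate(sources)],
            unit=unit, tunit=as_str(tscale.attrs.get("unit", "s")),
            field=field, **common)
    raise FormatError(f"{node.name}: unrecognizable nonuniform layout")


# ---------------------------------------------------------------------------
# static
# ---------------------------------------------------------------------------

def read_static(ix: FileIndex, population: str, name: str) -> StaticTable:
    """Reconstruct a static table, recovering layout, labels and units."""
    ds = _get_variable(ix, "static", population, name)
    sources = _sources_of(ds)
    unit_attr = ds.attrs.get("unit", "")
    if ds.dtype.names:  # COMPOUND
        units = [as_str(u) for u in np.atleast_1d(unit_attr)]
        if len(units) == 1 and len(ds.dtype.names) > 1:
            units = units * len(ds.dtype.names)
        columns = []
        for label, unit in zip(ds.dtype.names, units):
            col = ds[label]
            if ds.dtype[label].kind == "O":
                values = [as_str(v) for v in col]
            else:
                values = np.asarray(col, dtype=np.float64)
            columns.append(Column(label=label, unit=unit, values=values))
        return StaticTable(population=population, name=name, sources=sources,
                           layout=StaticLayout.COMPOUND, columns=columns)
    matrix = ds[...]
    label_scale = dim_scales(ds, 1).get("field")
    labels = (read_str_dataset(label_scale) if label_scale is not None
              else [f"c{i}" for i in range(matrix.shape[1])])
    units = [as_str(u) for u in np.atleast_1d(unit_attr)]
    shared = units[0] if len(units) == 1 else None
    if len(units) == 1:
        units = units * matrix.shape[1]
    columns = [Column(label=lbl, unit=unit, values=matrix[:, i])
               for i, (lbl, unit) in enumerate(zip(labels, units))]
    return StaticTable(population=population, name=name, sources=sources,
                       layout=StaticLayout.HOMOGENEOUS_2D, columns=columns,
                       unit=shared)


# ---------------------------------------------------------------------------
# model tree
# ---------------------------------------------------------------------------

def read_modeltree(ix: FileIndex) -> ModelNode | None:
    """Reconstruct the fallback model tree, or None when absent.

    The returned root is a container node named ``"modeltree"`` whose
    children are the stored top-level components; uids, ontology terms,
    extra attributes and ``map`` references are recovered.
    """
    mt = ix.h5.get("model/modeltree")
    if mt is None:
        return None

    def build(grp: h5py.Group, node: ModelNode) -> None:
        for name, child in grp.items():
            if not isinstance(child, h5py.Group):
                continue
            attrs = {k: as_str(v) for k, v in child.attrs.items()
                     if k not in ("uid", "ontology", "map")}
            cn = ModelNode(
                name=name,
                uid=(as_str(child.attrs["uid"])
                     if "uid" in child.attrs else None),
                ontology=(as_str(child.attrs["ontology"])
                          if "ontology" in child.attrs else None),
                attributes=attrs,
                map_refs=[as_str(p)
                          for p in np.atleast_1d(child.attrs.get("map", []))])
            node.children.append(cn)
            build(child, cn)

    root = ModelNode("modeltree")
    build(mt, root)
    return root


# ---------------------------------------------------------------------------
# source resolution
# ---------------------------------------------------------------------------

def _datasets_using_map(ix: FileIndex, map_path: str) -> set[str]:
    """Data datasets associated with a mapping dataset (scale or table)."""
    f = ix.h5
    try:
        mds = f[map_path]
    except KeyError:
        return set()
    out: set[str] = set()
    if mds.dtype.names and "data" in mds.dtype.names:  # ONED map table
        for row in mds[...]:
            out.add(as_str(row["data"]))
        return out
    # dimension scale: follow HDF5 back-references to the attached datasets
    for ref, _dim in mds.attrs.get("REFERENCE_LIST", []):
        try:
            out.add(f[ref].name)
        except (KeyError, ValueError):
            continue
    return out


def _scan_data_for_uid(ix: FileIndex, uid: str) -> set[str]:
    """Exhaustive /data scan: datasets whose source scale, source attribute
    or map table contains *uid*."""
    found: set[str] = set()

    def visit(name, node):
        if not isinstance(node, h5py.Dataset):
            return
        if "source" in node.attrs and as_str(node.attrs["source"]) == uid:
            found.add(node.name)
            return
        scales = dim_scales(node, 0)
        if "source" in scales and uid in read_str_dataset(scales["source"]):
            found.add(node.name)

    ix.h5["data"].visititems(visit)
    return found


def _modeltree_map_lookup(ix: FileIndex, uid: str) -> set[str] | None:
    """Resolve via modeltree ``map`` attributes; None when unavailable."""
    f = ix.h5
    mt = f.get("model/modeltree")
    if mt is None:
        return None
    hit: list[str] | None = None

    def visit(name, node):
        nonlocal hit
        if isinstance(node, h5py.Group) and \
                as_str(node.attrs.get("uid", "")) == uid:
            hit = [as_str(p) for p in np.atleast_1d(node.attrs.get("map", []))]

    mt.visititems(visit)
    if hit is None:
        return None
    out: set[str] = set()
    for map_path in hit:
        for dpath in _datasets_using_map(ix, map_path):
            node = f.get(dpath)
            if node is None:
                continue
            if "source" in node.attrs:  # ONED member: keep only this uid's
                if as_str(node.attrs["source"]) == uid:
                    out.add(dpath)
            else:
                out.add(dpath)
    return out


def sources_to_data(ix: FileIndex, uid: str,
                    use_model_map: bool | None = None) -> list[str]:
    """All dataset paths under /data recording the source *uid*.

    Uses the modeltree ``map`` attributes when present (avoiding an
    exhaustive scan), otherwise walks /data checking source scales and
    ``source`` attributes.  Unknown uids yield an empty list.
    ``use_model_map`` forces one strategy for cross-checking.
    """
    if use_model_map is True:
        return sorted(_modeltree_map_lookup(ix, uid) or set())
    if use_model_map is False:
        return sorted(_scan_data_for_uid(ix, uid))
    via_map = _modeltree_map_lookup(ix, uid)
    if via_map is not None:
        return sorted(via_map)
    return sorted(_scan_data_for_uid(ix, uid))
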