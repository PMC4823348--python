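"""Writing NSDF files.

An NSDF file is an HDF5 file with three groups at the root:

* ``/data`` — the recorded values, organized as
  ``/data/<category>/<population>/<variable>`` with category one of
  ``static``, ``uniform``, ``nonuniform``, ``event``;
* ``/map`` — the mappings from data rows to their sources: per-population
  ``source`` dimension scales, source->dataset tables for the ONED variant,
  and sampling-time scales under ``/map/time``;
* ``/model`` — optional model description: a fallback ``modeltree`` of
  groups with ``uid`` attributes, embedded file contents, external file
  references, or HDF5 external links.

:class:`NSDFWriter` lays out this structure, attaches dimension scales,
writes the mandatory ``unit``/``field`` attributes, supports all ragged
storage variants (ONED / VLEN / NANPADDED, plus NUREGULAR for nonuniform
series with a shared time axis) and allows streaming appends to uniform and
ragged datasets.  All numeric payloads are stored as double precision.
Within one file each category keeps a single consistent variant; the writer
refuses mixtures.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import h5py
import numpy as np

from ._h5 import (STR_DTYPE, as_str, is_vlen_float, read_str_dataset,
                  sanitize_component, uid_hash)
from .core import (CATEGORIES, EventSet, FileMetadata, ModelNode,
                   RaggedSeries, StaticLayout, StaticTable, UniformBlock,
                   Variant, nan_pad, uniform_time_axis)
from .exceptions import (ConflictError, InvalidArgumentError, ShapeError,
                         StructureError, VariantError)
from .units import UnitError, validate_unit

__all__ = ["NSDFWriter", "create_file", "SourceDimScale"]


def _chunks2d(p: int, q: int) -> tuple[int, int]:
    return (max(1, min(p, 64)), max(1, min(q if q > 0 else 1, 1024)))


@dataclass
class SourceDimScale:
    """Handle to a stored ``source`` dimension scale under /map/<category>."""

    category: str
    population: str
    uids: list[str]
    path: str

    def __len__(self) -> int:
        return len(self.uids)


def _check_unit(unit: str, allow_empty: bool = False) -> str:
    """Units are mandatory; an unknown grammar only warns at write time."""
    if unit is None:
        raise InvalidArgumentError("unit attribute is mandatory")
    try:
        return validate_unit(unit, allow_empty=allow_empty)
    except UnitError as exc:
        warnings.warn(f"unit {unit!r} is outside the supported grammar: {exc}",
                      stacklevel=3)
        return unit


class NSDFWriter:
    """Create or extend an NSDF file.

    Parameters
    ----------
    path:
        Target file.  ``mode="w"`` creates (overwriting any existing file of
        the same name), ``mode="a"`` opens an existing NSDF file for
        appending.
    metadata:
        Root attributes; defaults are filled in for a new file.
    compression:
        ``None`` or ``"gzip"``.  Ragged (VLEN) datasets are always written
        uncompressed because HDF5 cannot compress variable-length data.
    libver:
        h5py file-format bound for new files; the default ``"latest"``
        yields compact chunk indexes (pass ``"earliest"`` for files readable
        by pre-1.10 HDF5 libraries).
    """

    def __init__(self, path, metadata: FileMetadata | None = None,
                 mode: str = "w", compression: str | None = None,
                 compression_level: int = 6, libver: str = "latest"):
        if mode not in ("w", "a"):
            raise InvalidArgumentError(f"mode must be 'w' or 'a', got {mode!r}")
        if compression not in (None, "none", "gzip"):
            raise InvalidArgumentError(
                f"compression must be None or 'gzip', got {compression!r}")
        self.compression = None if compression == "none" else compression
        self.compression_level = int(compression_level)
        if mode == "a":
            if not os.path.exists(path):
                raise StructureError(f"cannot append: {path} does not exist")
            self._h5 = h5py.File(path, "r+")
            for grp in ("/data", "/map", "/model"):
                if grp not in self._h5:
                    self._h5.close()
                    raise StructureError(
                        f"{path} is not an NSDF file: missing {grp}")
        else:
            # The modern file format keeps per-dataset index overhead small,
            # which matters because every dataset is chunked for streaming
            # appends; it requires HDF5 >= 1.10 to read.
            self._h5 = h5py.File(path, "w", libver=libver)
            self._h5.create_group("data")
            m = self._h5.create_group("map")
            m.create_group("time")
            self._h5.create_group("model")
            meta = metadata or FileMetadata()
            for key, value in meta.to_attrs().items():
                self._h5.attrs[key] = value
        self._variant_by_category: dict[str, Variant] = {}
        if mode == "a":
            self._detect_existing_variants()

    # -- plumbing ---------------------------------------------------------

    def _detect_existing_variants(self) -> None:
        from .reader import detect_variant  # local import: no cycle at module load
        for category in ("nonuniform", "event"):
            grp = self._h5["data"].get(category)
            if grp is None:
                continue
            for pop in grp.values():
                for node in pop.values():
                    variant = detect_variant(category, node)
                    if variant is not None:
                        self._variant_by_category.setdefault(category, variant)

    def _claim_variant(self, category: str, variant: Variant) -> None:
        # NUREGULAR coexists with nothing ragged to clash with, but the file
        # stays cleanest with one variant per category throughout.
        prior = self._variant_by_category.get(category)
        if prior is not None and prior != variant:
            raise ConflictError(
                f"category {category!r} already uses variant {prior.value}; "
                f"cannot mix in {variant.value}")
        self._variant_by_category[category] = variant

    def _filters(self, vlen: bool = False) -> dict:
        # byte-shuffle before gzip: double-precision payloads share exponent
        # bytes, which compress well once grouped by byte position
        if self.compression == "gzip" and not vlen:
            return {"compression": "gzip",
                    "compression_opts": self.compression_level,
                    "shuffle": True}
        return {}

    def _data_group(self, category: str, population: str) -> h5py.Group:
        return self._h5.require_group(f"data/{category}/{population}")

    def _map_group(self, category: str) -> h5py.Group:
        return self._h5.require_group(f"map/{category}")

    @property
    def filename(self) -> str:
        return self._h5.filename

    def close(self) -> None:
        self._h5.close()

    def __enter__(self) -> "NSDFWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- source dimension scales ------------------------------------------

    def add_source_dim_scale(self, category: str, population: str,
                             uids: list[str]) -> SourceDimScale:
        """Store the population's source uids as a ``source`` dimension scale.

        The scale lives at ``/map/<category>/<population>`` and is shared by
        every variable of the population.  Calling again with identical uids
        returns the existing scale; different uids for the same population
        are a conflict.
        """
        if category not in CATEGORIES:
            raise InvalidArgumentError(f"unknown category {category!r}")
        if not uids:
            raise InvalidArgumentError("uids must be nonempty")
        if len(set(uids)) != len(uids):
            raise InvalidArgumentError("uids must be unique within a scale")
        grp = self._map_group(category)
        path = f"/map/{category}/{population}"
        if population in grp:
            existing = read_str_dataset(grp[population])
            if existing != list(uids):
                raise ConflictError(
                    f"population {population!r} already has a source scale "
                    "with different uids")
            return SourceDimScale(category, population, existing, path)
        ds = grp.create_dataset(population,
                                data=np.array(uids, dtype=STR_DTYPE))
        ds.make_scale("source")
        return SourceDimScale(category, population, list(uids), path)

    def _attach_source(self, dset: h5py.Dataset, scale: SourceDimScale,
                       dim: int = 0) -> None:
        dset.dims[dim].attach_scale(self._h5[scale.path])
        dset.dims[dim].label = "source"

    def _auto_scale(self, category: str, population: str,
                    sources: list[str],
                    scale: SourceDimScale | None) -> SourceDimScale:
        if scale is None:
            return self.add_source_dim_scale(category, population, sources)
        if scale.category != category:
            raise InvalidArgumentError(
                f"scale belongs to category {scale.category!r}, "
                f"need {category!r}")
        if len(scale) != len(sources):
            raise ShapeError(
                f"scale has {len(scale)} sources, data has {len(sources)}")
        return scale

    # -- time scales --------------------------------------------------------

    def _time_scale_name(self, category: str, population: str,
                         variable: str, uid: str | None = None) -> str:
        # Deterministic names keep files reproducible; the layout leaves
        # naming under /map/time free.
        name = f"{category}_{population}_{variable}"
        if uid is not None:
            name += f"_{uid_hash(uid)}"
        return name

    def _create_time_scale(self, name: str, data, unit: str,
                           vlen: bool = False,
                           appendable: bool = False) -> h5py.Dataset:
        grp = self._h5.require_group("map/time")
        if name in grp:
            raise ConflictError(f"time scale {name!r} already exists")
        if vlen:
            vt = h5py.vlen_dtype(np.float64)
            ds = grp.create_dataset(name, shape=(len(data),), dtype=vt,
                                    maxshape=(None,),
                                    chunks=(max(1, min(len(data), 64)),))
            for i, row in enumerate(data):
                ds[i] = np.asarray(row, dtype=np.float64)
        else:
            arr = np.asarray(data, dtype=np.float64)
            kwargs = dict(self._filters())
            if appendable:
                kwargs["maxshape"] = tuple(None for _ in arr.shape)
                kwargs["chunks"] = (_chunks2d(*arr.shape) if arr.ndim == 2
                                    else (max(1, min(max(arr.size, 1), 1024)),))
            ds = grp.create_dataset(name, data=arr, **kwargs)
        ds.make_scale("time")
        ds.attrs["unit"] = unit
        return ds

    # -- uniform ------------------------------------------------------------

    def add_uniform(self, scale: SourceDimScale, block: UniformBlock,
                    time_mode: str = "attrs") -> str:
        """Write a uniformly sampled block as a P x Q dataset.

        ``time_mode="attrs"`` stores timing as ``tstart``/``dt``/``tunit``
        attributes; ``time_mode="explicit_ds"`` stores the full time axis
        under ``/map/time`` and attaches it to the column dimension.  When a
        block carries both ``dt`` and an explicit axis they must agree to
        within 1e-12 relative tolerance — the writer refuses to produce
        inconsistent pairs.
        """
        if time_mode not in ("attrs", "explicit_ds"):
            raise InvalidArgumentError(f"unknown time_mode {time_mode!r}")
        scale = self._auto_scale("uniform", block.population, block.sources,
                                 scale)
        if scale.uids != block.sources:
            raise InvalidArgumentError(
                "block sources do not match the dimension scale")
        unit = _check_unit(block.unit)
        if block.explicit_times is not None and block.dt is not None:
            computed = uniform_time_axis(block.tstart, block.dt,
                                         block.n_samples)
            if not np.allclose(computed, block.explicit_times, rtol=1e-12,
                               atol=0.0):
                raise InvalidArgumentError(
                    "explicit_times disagrees with tstart/dt beyond 1e-12 "
                    "relative tolerance")
        grp = self._data_group("uniform", block.population)
        if block.variable in grp:
            raise ConflictError(
                f"variable {block.variable!r} already exists in population "
                f"{block.population!r}")
        p, q = block.values.shape
        ds = grp.create_dataset(block.variable, data=block.values,
                                maxshape=(p, None), chunks=_chunks2d(p, q),
                                **self._filters())
        ds.attrs["unit"] = unit
        ds.attrs["field"] = block.field
        self._attach_source(ds, scale)
        if time_mode == "attrs":
            if block.dt is None:
                raise InvalidArgumentError(
                    "attrs time mode requires tstart/dt on the block")
            ds.attrs["tstart"] = float(block.tstart)
            ds.attrs["dt"] = float(block.dt)
            ds.attrs["tunit"] = block.tunit
        else:
            tscale = self._create_time_scale(
                self._time_scale_name("uniform", block.population,
                                      block.variable),
                block.times, block.tunit, appendable=True)
            ds.dims[1].attach_scale(tscale)
            ds.dims[1].label = "time"
        return ds.name

    def append_uniform(self, dataset_path: str, new_columns,
                       times=None) -> int:
        """Append K new sample columns to an existing uniform dataset.

        With attribute-based timing nothing besides the matrix changes (the
        axis is defined by ``tstart``/``dt`` regardless of length).  With an
        explicit time scale the matching new times must be supplied.
        Returns the new total column count.
        """
        ds = self._h5[dataset_path]
        new = np.asarray(new_columns, dtype=np.float64)
        if new.ndim != 2:
            raise ShapeError("new_columns must be 2-D")
        p, q = ds.shape
        if new.shape[0] != p:
            raise ShapeError(
                f"dataset has {p} rows, new columns have {new.shape[0]}")
        k = new.shape[1]
        time_scales = dict(ds.dims[1].items()) if ds.ndim == 2 else {}
        if k == 0:
            return q
        if "time" in time_scales:
            if times is None:
                raise InvalidArgumentError(
                    "dataset has an explicit time scale; appending requires "
                    "the matching new times")
            times = np.asarray(times, dtype=np.float64)
            if times.size != k:
                raise ShapeError("times length must equal new column count")
            tscale = time_scales["time"]
            tscale.resize((q + k,))
            tscale[q:] = times
        ds.resize((p, q + k))
        ds[:, q:] = new
        return q + k

    # -- ragged helpers -----------------------------------------------------

    def _write_oned_group(self, category: str, population: str,
                          variable: str, entries, unit: str, field: str,
                          times_info=None) -> str:
        """ONED layout: one appendable 1D dataset per source (level 5), a
        two-field source/data map table under /map/<category>, and the
        table's path stored in the variable group's ``source`` attribute."""
        grp = self._data_group(category, population)
        if variable in grp:
            raise ConflictError(f"{variable!r} already exists")
        vgrp = grp.create_group(variable)
        used: set[str] = set()
        paths: list[str] = []
        for i, (uid, values) in enumerate(entries):
            name = sanitize_component(uid)
            if name in used:
                name = f"{name}_{uid_hash(uid)}"
            used.add(name)
            arr = np.asarray(values, dtype=np.float64)
            ds = vgrp.create_dataset(
                name, data=arr, maxshape=(None,),
                chunks=(max(1, min(max(arr.size, 1), 1024)),),
                **self._filters())
            ds.attrs["unit"] = unit
            ds.attrs["field"] = field
            ds.attrs["source"] = uid
            if times_info is not None:
                times, tunit = times_info[i]
                tscale = self._create_time_scale(
                    self._time_scale_name(category, population, variable,
                                          uid=uid),
                    times, tunit, appendable=True)
                ds.dims[0].attach_scale(tscale)
                ds.dims[0].label = "time"
            paths.append(ds.name)
        # fixed-length strings sized to the longest entry keep the table
        # inline in the file instead of spilling to a global heap
        uids = [uid for uid, _ in entries]
        dtype = np.dtype([
            ("source", h5py.string_dtype(
                length=max(len(u.encode()) for u in uids))),
            ("data", h5py.string_dtype(
                length=max(len(p.encode()) for p in paths))),
        ])
        table = np.empty(len(entries), dtype=dtype)
        table["source"] = uids
        table["data"] = paths
        tbl = self._map_group(category).create_dataset(
            f"{population}_{variable}", data=table)
        vgrp.attrs["source"] = tbl.name
        return vgrp.name

    def _write_vlen(self, category: str, population: str, variable: str,
                    rows, scale: SourceDimScale, unit: str,
                    field: str) -> h5py.Dataset:
        grp = self._data_group(category, population)
        if variable in grp:
            raise ConflictError(f"{variable!r} already exists")
        vt = h5py.vlen_dtype(np.float64)
        # HDF5 cannot compress variable-length payloads, so no filters here.
        ds = grp.create_dataset(variable, shape=(len(rows),), dtype=vt,
                                maxshape=(None,),
                                chunks=(max(1, min(len(rows), 64)),))
        for i, row in enumerate(rows):
            ds[i] = np.asarray(row, dtype=np.float64)
        ds.attrs["unit"] = unit
        ds.attrs["field"] = field
        self._attach_source(ds, scale)
        return ds

    def _write_nanpadded(self, category: str, population: str, variable: str,
                         rows, scale: SourceDimScale, unit: str,
                         field: str) -> h5py.Dataset:
        grp = self._data_group(category, population)
        if variable in grp:
            raise ConflictError(f"{variable!r} already exists")
        padded = nan_pad(rows)
        p, q = padded.shape
        ds = grp.create_dataset(variable, data=padded, maxshape=(p, None),
                                chunks=_chunks2d(p, q), **self._filters())
        ds.attrs["unit"] = unit
        ds.attrs["field"] = field
        self._attach_source(ds, scale)
        return ds

    # -- events -------------------------------------------------------------

    def add_events(self, data: EventSet, variant: Variant | str,
                   scale: SourceDimScale | None = None) -> str:
        """Write an event set in the requested variant.

        Events have no shared time axis, so NUREGULAR is not applicable and
        is rejected.  For VLEN and NANPADDED a ``source`` dimension scale is
        attached (created from the entry order when *scale* is omitted); the
        ONED layout uses its source/data map table instead.
        """
        variant = Variant(variant)
        if variant == Variant.NUREGULAR:
            raise VariantError("NUREGULAR is not applicable to event data")
        self._claim_variant("event", variant)
        unit = _check_unit(data.unit)
        if variant == Variant.ONED:
            return self._write_oned_group(
                "event", data.population, data.variable,
                [(uid, times) for uid, times in data.entries], unit,
                data.field)
        scale = self._auto_scale("event", data.population, data.sources,
                                 scale)
        if scale.uids != data.sources:
            raise InvalidArgumentError(
                "event sources do not match the dimension scale")
        rows = [times for _, times in data.entries]
        if variant == Variant.VLEN:
            return self._write_vlen("event", data.population, data.variable,
                                    rows, scale, unit, data.field).name
        return self._write_nanpadded("event", data.population, data.variable,
                                     rows, scale, unit, data.field).name

    def append_events(self, node_path: str, new: EventSet) -> None:
        """Append new events per source to an existing event variable.

        ONED appends to each per-source 1D dataset; VLEN rewrites each grown
        row; NANPADDED locates the end of valid data in each row (the cost
        inherent to that variant), widening the matrix as needed.
        """
        node = self._h5[node_path]
        incoming = dict(new.entries)
        if isinstance(node, h5py.Group):  # ONED
            tbl = self._h5[as_str(node.attrs["source"])][...]
            for src, dpath in zip(tbl["source"], tbl["data"]):
                uid = as_str(src)
                if uid not in incoming:
                    continue
                extra = incoming[uid]
                ds = self._h5[as_str(dpath)]
                n = ds.shape[0]
                ds.resize((n + extra.size,))
                ds[n:] = extra
            return
        sources = read_str_dataset(dict(node.dims[0].items())["source"])
        if is_vlen_float(node):  # VLEN
            for i, uid in enumerate(sources):
                if uid in incoming:
                    node[i] = np.concatenate([node[i], incoming[uid]])
            return
        # NANPADDED: find per-row fill level, then extend
        mat = node[...]
        rows = []
        for i, uid in enumerate(sources):
            valid = mat[i][~np.isnan(mat[i])]
            rows.append(np.concatenate([valid, incoming.get(uid, [])]))
        padded = nan_pad(rows) if rows else mat
        node.resize(padded.shape)
        node[...] = padded

    # -- nonuniform -----------------------------------------------------------

    def add_nonuniform(self, data: RaggedSeries, variant: Variant | str,
                       scale: SourceDimScale | None = None) -> str:
        """Write a nonuniformly sampled series in the requested variant.

        NUREGULAR requires a shared time axis and produces a regular 2D
        matrix with a 1D ``time`` scale; the ragged variants additionally
        store per-source sampling times under ``/map/time`` (themselves
        ragged or NaN-padded for VLEN/NANPADDED, congruent with the values).
        """
        variant = Variant(variant)
        self._claim_variant("nonuniform", variant)
        unit = _check_unit(data.unit)
        pop, var = data.population, data.variable
        if variant == Variant.NUREGULAR:
            if not data.homogeneous_times:
                raise VariantError(
                    "NUREGULAR requires shared sampling times for all sources")
            scale = self._auto_scale("nonuniform", pop, data.sources, scale)
            grp = self._data_group("nonuniform", pop)
            if var in grp:
                raise ConflictError(f"{var!r} already exists")
            matrix = np.vstack([values for _, values, _ in data.entries])
            ds = grp.create_dataset(var, data=matrix,
                                    chunks=_chunks2d(*matrix.shape),
                                    maxshape=(matrix.shape[0], None),
                                    **self._filters())
            ds.attrs["unit"] = unit
            ds.attrs["field"] = data.field
            self._attach_source(ds, scale)
            tscale = self._create_time_scale(
                self._time_scale_name("nonuniform", pop, var),
                data.shared_times, data.tunit, appendable=True)
            ds.dims[1].attach_scale(tscale)
            ds.dims[1].label = "time"
            return ds.name
        times_rows = [data.times_for(i) for i in range(len(data.entries))]
        if variant == Variant.ONED:
            return self._write_oned_group(
                "nonuniform", pop, var,
                [(uid, values) for uid, values, _ in data.entries], unit,
                data.field,
                times_info=[(t, data.tunit) for t in times_rows])
        scale = self._auto_scale("nonuniform", pop, data.sources, scale)
        if variant == Variant.VLEN:
            ds = self._write_vlen("nonuniform", pop, var,
                                  [v for _, v, _ in data.entries], scale,
                                  unit, data.field)
            tscale = self._create_time_scale(
                self._time_scale_name("nonuniform", pop, var), times_rows,
                data.tunit, vlen=True)
            ds.dims[0].attach_scale(tscale)
            return ds.name
        # NANPADDED: values and times matrices are padded congruently, since
        # len(values) == len(times) per source.
        ds = self._write_nanpadded("nonuniform", pop, var,
                                   [v for _, v, _ in data.entries], scale,
                                   unit, data.field)
        tscale = self._create_time_scale(
            self._time_scale_name("nonuniform", pop, var),
            nan_pad(times_rows), data.tunit, appendable=True)
        ds.dims[1].attach_scale(tscale)
        ds.dims[1].label = "time"
        return ds.name

    # -- static ---------------------------------------------------------------

    def add_static(self, table: StaticTable,
                   scale: SourceDimScale | None = None) -> str:
        """Write a static table.

        HOMOGENEOUS_2D becomes a plain 2D dataset with a ``source`` scale on
        rows and a ``field`` label scale on columns; COMPOUND becomes a
        record dataset with named fields and a per-field ``unit`` string
        array (empty strings for non-physical columns such as indices).
        """
        scale = self._auto_scale("static", table.population, table.sources,
                                 scale)
        if scale.uids != table.sources:
            raise InvalidArgumentError(
                "table sources do not match the dimension scale")
        grp = self._data_group("static", table.population)
        if table.name in grp:
            raise ConflictError(f"{table.name!r} already exists")
        units = [(_check_unit(u, allow_empty=True)) for u in table.units]
        if table.layout == StaticLayout.HOMOGENEOUS_2D:
            matrix = table.matrix()
            ds = grp.create_dataset(table.name, data=matrix,
                                    chunks=_chunks2d(*matrix.shape),
                                    **self._filters())
            if len(set(units)) == 1:
                ds.attrs["unit"] = units[0]
            else:
                ds.attrs["unit"] = np.array(units, dtype=STR_DTYPE)
            labels = self._map_group("static").create_dataset(
                f"{table.population}_{table.name}_labels",
                data=np.array(table.labels, dtype=STR_DTYPE))
            labels.make_scale("field")
            ds.dims[1].attach_scale(labels)
            ds.dims[1].label = "field"
        else:
            fields = []
            for col in table.columns:
                fields.append((col.label,
                               STR_DTYPE if col.is_string() else np.float64))
            rec = np.empty(len(table.sources), dtype=np.dtype(fields))
            for col in table.columns:
                rec[col.label] = (np.asarray(col.values, dtype=object)
                                  if col.is_string()
                                  else np.asarray(col.values,
                                                  dtype=np.float64))
            ds = grp.create_dataset(table.name, data=rec)
            ds.attrs["unit"] = np.array(units, dtype=STR_DTYPE)
        ds.attrs["field"] = table.name
        self._attach_source(ds, scale)
        return ds.name

    # -- model description ------------------------------------------------------

    def add_modeltree(self, root: ModelNode, link_maps: bool = True) -> str:
        """Store the fallback model tree under /model/modeltree.

        A node named ``"modeltree"`` is treated as the tree container (its
        children become the top-level component groups); any other root is
        written as a single top-level component.  When *link_maps* is true,
        every node whose uid appears in a mapping dataset gets a ``map``
        attribute holding the paths of those mapping tables, enabling
        model->data traversal without an exhaustive /data scan.
        """
        tops = root.children if root.name == "modeltree" else [root]
        uids = [n.uid for top in tops for n in top.walk() if n.uid is not None]
        if len(set(uids)) != len(uids):
            raise InvalidArgumentError("uids must be unique in the model tree")
        model = self._h5.require_group("model")
        if "modeltree" not in model:
            # track_order preserves the caller's child ordering on read-back
            model.create_group("modeltree", track_order=True)
        mt = model["modeltree"]

        def write_node(parent: h5py.Group, node: ModelNode) -> None:
            if node.name in parent:
                raise InvalidArgumentError(
                    f"duplicate sibling name {node.name!r} in "
                    f"{parent.name}")
            g = parent.create_group(node.name, track_order=True)
            if node.uid is not None:
                g.attrs["uid"] = node.uid
            if node.ontology is not None:
                g.attrs["ontology"] = node.ontology
            for k, v in node.attributes.items():
                g.attrs[k] = v
            refs = list(node.map_refs)
            if link_maps and node.uid is not None:
                refs.extend(r for r in self._mapping_datasets_for(node.uid)
                            if r not in refs)
            if refs:
                g.attrs["map"] = np.array(refs, dtype=STR_DTYPE)
            for child in node.children:
                write_node(g, child)

        for top in tops:
            write_node(mt, top)
        return mt.name

    def _mapping_datasets_for(self, uid: str) -> list[str]:
        """Paths of mapping datasets (source scales / map tables) that
        contain *uid*."""
        out: list[str] = []
        mp = self._h5["map"]
        for category in CATEGORIES:
            grp = mp.get(category)
            if grp is None:
                continue
            for ds in grp.values():
                if not isinstance(ds, h5py.Dataset):
                    continue
                if ds.dtype.names and "source" in ds.dtype.names:
                    members = [as_str(s) for s in ds["source"]]
                elif ds.dtype.kind == "O" and ds.ndim == 1:
                    members = read_str_dataset(ds)
                else:
                    continue
                if uid in members:
                    out.append(ds.name)
        return out

    def add_filecontents(self, files: list[tuple[str, str]]) -> str:
        """Embed model-description files as string datasets.

        ``files`` is a list of ``(relative_path, text)``; the directory
        structure is replicated as groups under /model/filecontents.
        Absolute paths are rejected for portability.
        """
        root = self._h5.require_group("model/filecontents")
        for relpath, text in files:
            relpath = relpath.replace("\\", "/")
            if relpath.startswith("/") or relpath == "" or ".." in relpath.split("/"):
                raise InvalidArgumentError(
                    f"filecontents paths must be relative: {relpath!r}")
            *dirs, fname = relpath.split("/")
            grp = root
            for d in dirs:
                grp = grp.require_group(d)
            grp.create_dataset(fname, data=text, dtype=STR_DTYPE)
        return root.name

    def add_filerefs(self, paths: list[str], name: str = "files") -> str:
        """Store references (paths/URLs) to external model files."""
        grp = self._h5.require_group("model/filerefs")
        ds = grp.create_dataset(name, data=np.array(paths, dtype=STR_DTYPE))
        return ds.name

    def add_links(self, links: list[tuple[str, str, str]]) -> str:
        """Store HDF5 external links ``(name, target_file, target_path)``
        under /model/links."""
        grp = self._h5.require_group("model/links")
        for name, target_file, target_path in links:
            grp[name] = h5py.ExternalLink(target_file, target_path)
        return grp.name


def create_file(path, metadata: FileMetadata | None = None,
                **options) -> NSDFWriter:
    """Create a fresh NSDF file (overwriting) and return its writer."""
    return NSDFWriter(path, metadata=metadata, mode="w", **options)
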