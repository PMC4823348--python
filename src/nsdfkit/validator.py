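"""Conformance checking of NSDF files.

:func:`validate_file` runs a fixed rule set over a file and returns a
machine-readable report.  Rule ids are stable strings:

========  ==================================================================
R1        level-1 groups /data, /map (and /model) present
R2        level-2 names under /data are a subset of the four categories
R3        ``unit`` attribute present (and inside the unit grammar) on every
          dataset under /data that represents a physical quantity
R4        every dataset has a resolvable source mapping (``source`` scale,
          ``source`` attribute, or ONED map table)
R5        uniform datasets carry timing: tstart/dt attributes or a time scale
R6        NaN-padded matrices have NaN only as a contiguous row suffix
R7        ONED map tables are bidirectionally consistent with the per-source
          datasets' ``source`` attributes
R8        one storage variant per category within a file
R9        core root metadata attributes present
R10       created/tstart/tend root attributes parse as ISO 8601
R11       modeltree uids are unique
R12       VLEN/NANPADDED nonuniform values and times are congruent
========  ==================================================================

Tolerant mode (the default) mirrors the format's "recommended" language:
unit-grammar problems and absent optional metadata stay warnings.  Strict
mode promotes them to errors.  Validation is read-only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import h5py
import numpy as np

from ._h5 import as_str, dim_scales
from .core import (CATEGORIES, CORE_ROOT_ATTRIBUTES, Variant, is_iso8601)
from .reader import detect_variant
from .units import is_valid_unit

__all__ = ["Finding", "ValidationReport", "validate_file",
           "resolve_model_precedence", "RULE_IDS"]

RULE_IDS = tuple(f"R{i}" for i in range(1, 13))

#: Model-description mechanisms in decreasing precedence.
MODEL_PRECEDENCE = ("modeltree", "filecontents", "filerefs", "links")


@dataclass
class Finding:
    severity: str  # "error" | "warning" | "info"
    rule: str
    path: str
    message: str

    def as_dict(self) -> dict:
        return {"severity": self.severity, "rule": self.rule,
                "path": self.path, "message": self.message}


@dataclass
class ValidationReport:
    path: str
    strictness: str
    findings: list[Finding] = dc_field(default_factory=list)

    @property
    def conforms(self) -> bool:
        return not any(f.severity == "error" for f in self.findings)

    def rules_triggered(self, severity: str = "error") -> set[str]:
        return {f.rule for f in self.findings if f.severity == severity}

    def summary(self) -> dict[str, int]:
        out = {"error": 0, "warning": 0, "info": 0}
        for f in self.findings:
            out[f.severity] += 1
        return out

    def to_json(self, indent: int = 2) -> str:
        return json.dumps({
            "path": self.path,
            "strictness": self.strictness,
            "conforms": self.conforms,
            "summary": self.summary(),
            "findings": [f.as_dict() for f in self.findings],
        }, indent=indent)

    def __str__(self) -> str:
        lines = [f"{self.path}: "
                 f"{'CONFORMS' if self.conforms else 'DOES NOT CONFORM'} "
                 f"({self.strictness} mode)"]
        for f in self.findings:
            lines.append(f"  [{f.severity:7s}] {f.rule} {f.path}: {f.message}")
        return "\n".join(lines)


class _Checker:
    def __init__(self, f: h5py.File, strict: bool):
        self.f = f
        self.strict = strict
        self.findings: list[Finding] = []

    def add(self, severity: str, rule: str, path: str, message: str,
            promote: bool = False) -> None:
        if promote and self.strict and severity == "warning":
            severity = "error"
        self.findings.append(Finding(severity, rule, path, message))

    # R1 / R2 ---------------------------------------------------------------
    def check_structure(self) -> None:
        for grp in ("data", "map"):
            if grp not in self.f:
                self.add("error", "R1", f"/{grp}", "mandatory level-1 group "
                         "missing")
        if "model" not in self.f:
            self.add("warning", "R1", "/model",
                     "level-1 group /model missing", promote=True)
        data = self.f.get("data")
        if data is not None:
            for name in data:
                if name not in CATEGORIES:
                    self.add("error", "R2", f"/data/{name}",
                             "unknown data category (expected one of "
                             f"{', '.join(CATEGORIES)})")

    # R9 / R10 --------------------------------------------------------------
    def check_root_attrs(self) -> None:
        attrs = self.f.attrs
        for key in CORE_ROOT_ATTRIBUTES:
            if key not in attrs:
                self.add("error", "R9", "/",
                         f"core root attribute {key!r} missing")
        if "nsdf_version" in attrs and as_str(attrs["nsdf_version"]) == "":
            self.add("error", "R9", "/", "nsdf_version is empty")
        for key in ("created", "tstart", "tend"):
            if key in attrs:
                value = as_str(attrs[key])
                if not is_iso8601(value):
                    self.add("error", "R10", "/",
                             f"root attribute {key!r} is not ISO 8601: "
                             f"{value!r}")

    # R3 --------------------------------------------------------------------
    def check_unit(self, node: h5py.Dataset) -> None:
        if "unit" not in node.attrs:
            self.add("error", "R3", node.name, "unit attribute missing")
            return
        unit = node.attrs["unit"]
        units = [as_str(u) for u in np.atleast_1d(unit)]
        n_fields = len(node.dtype.names) if node.dtype.names else None
        if n_fields is not None and len(units) not in (1, n_fields):
            self.add("error", "R3", node.name,
                     f"unit array has {len(units)} entries for {n_fields} "
                     "fields")
        allow_empty = n_fields is not None or len(units) > 1
        for u in units:
            if not is_valid_unit(u, allow_empty=allow_empty):
                self.add("warning", "R3", node.name,
                         f"unit {u!r} outside the supported grammar",
                         promote=True)

    # R6 --------------------------------------------------------------------
    def check_nan_suffix(self, node: h5py.Dataset, rule: str = "R6") -> None:
        mat = node[...]
        for i in range(mat.shape[0]):
            mask = np.isnan(mat[i])
            if mask.any():
                first = int(np.argmax(mask))
                if not mask[first:].all():
                    self.add("error", rule, node.name,
                             f"row {i}: NaN is not a contiguous suffix")

    # R7 --------------------------------------------------------------------
    def check_oned(self, grp: h5py.Group) -> None:
        tbl_path = grp.attrs.get("source")
        if tbl_path is None:
            self.add("error", "R4", grp.name,
                     "ONED group lacks the 'source' map-table attribute")
            return
        tbl = self.f.get(as_str(tbl_path))
        if tbl is None:
            self.add("error", "R7", grp.name,
                     f"map table {as_str(tbl_path)!r} does not exist")
            return
        mapped_paths = set()
        for row in tbl[...]:
            uid, dpath = as_str(row["source"]), as_str(row["data"])
            mapped_paths.add(dpath)
            ds = self.f.get(dpath)
            if ds is None:
                self.add("error", "R7", tbl.name,
                         f"map row for {uid!r} points to missing dataset "
                         f"{dpath!r}")
                continue
            stored = as_str(ds.attrs.get("source", ""))
            if stored != uid:
                self.add("error", "R7", ds.name,
                         f"dataset source attribute {stored!r} does not "
                         f"match map entry {uid!r}")
        for name, ds in grp.items():
            if isinstance(ds, h5py.Dataset) and ds.name not in mapped_paths:
                self.add("error", "R7", ds.name,
                         "per-source dataset absent from the map table")

    # R4 / R5 / R12 and category walk ----------------------------------------
    def check_data(self) -> None:
        data = self.f.get("data")
        if data is None:
            return
        for category in CATEGORIES:
            cat = data.get(category)
            if cat is None:
                continue
            variants_seen: dict[str, Variant] = {}
            for pop_name, pop in cat.items():
                if not isinstance(pop, h5py.Group):
                    continue
                for var_name, node in pop.items():
                    variant = detect_variant(category, node)
                    if variant is not None:
                        variants_seen[node.name] = variant
                    self.check_variable(category, node, variant)
            distinct = set(variants_seen.values()) - {Variant.NUREGULAR}
            if len(distinct) > 1:
                self.add("error", "R8", f"/data/{category}",
                         "mixed storage variants within one category: "
                         + ", ".join(sorted(v.value for v in distinct)))

    def check_variable(self, category: str, node,
                       variant: Variant | None) -> None:
        if isinstance(node, h5py.Group):
            if variant == Variant.ONED:
                self.check_oned(node)
                for child in node.values():
                    if isinstance(child, h5py.Dataset):
                        self.check_unit(child)
                        if category == "nonuniform" and \
                                "time" not in dim_scales(child, 0):
                            self.add("error", "R12", child.name,
                                     "ONED nonuniform dataset lacks a time "
                                     "scale")
            else:
                self.add("warning", "R4", node.name,
                         "unrecognizable group layout under /data",
                         promote=True)
            return
        if not isinstance(node, h5py.Dataset):
            return
        self.check_unit(node)
        # R4: source mapping
        scales0 = dim_scales(node, 0)
        if "source" not in scales0:
            self.add("error", "R4", node.name,
                     "no 'source' dimension scale attached to the row "
                     "dimension")
        elif node.shape[0] != scales0["source"].shape[0]:
            self.add("error", "R4", node.name,
                     "row count differs from the source scale length")
        if category == "uniform":
            has_attrs = "tstart" in node.attrs and "dt" in node.attrs
            has_scale = "time" in dim_scales(node, 1)
            if not has_attrs and not has_scale:
                self.add("error", "R5", node.name,
                         "uniform dataset has neither tstart/dt attributes "
                         "nor a time scale")
        if category == "event" and variant == Variant.NANPADDED:
            self.check_nan_suffix(node)
        if category == "nonuniform":
            self.check_nonuniform_times(node, variant)

    def check_nonuniform_times(self, node: h5py.Dataset,
                               variant: Variant | None) -> None:
        if variant == Variant.VLEN:
            tscale = dim_scales(node, 0).get("time")
            if tscale is None:
                self.add("error", "R12", node.name,
                         "VLEN nonuniform dataset lacks a time scale")
                return
            for i in range(node.shape[0]):
                if node[i].size != tscale[i].size:
                    self.add("error", "R12", node.name,
                             f"row {i}: {node[i].size} values vs "
                             f"{tscale[i].size} times")
        elif variant == Variant.NANPADDED:
            self.check_nan_suffix(node)
            tscale = dim_scales(node, 1).get("time")
            if tscale is None:
                self.add("error", "R12", node.name,
                         "NANPADDED nonuniform dataset lacks a time scale")
                return
            self.check_nan_suffix(tscale, rule="R12")
            if tscale.shape != node.shape or not np.array_equal(
                    np.isnan(node[...]), np.isnan(tscale[...])):
                self.add("error", "R12", node.name,
                         "NaN masks of values and times are not congruent")
        elif variant == Variant.NUREGULAR:
            tscale = dim_scales(node, 1).get("time")
            if tscale is None:
                self.add("error", "R5", node.name,
                         "NUREGULAR dataset lacks a shared time scale")
            elif tscale.shape[0] != node.shape[1]:
                self.add("error", "R12", node.name,
                         "shared time scale length differs from column "
                         "count")

    # R11 ---------------------------------------------------------------------
    def check_modeltree(self) -> None:
        mt = self.f.get("model/modeltree")
        if mt is None:
            return
        seen: dict[str, str] = {}

        def visit(name, node):
            if not isinstance(node, h5py.Group):
                return
            uid = node.attrs.get("uid")
            if uid is None:
                return
            uid = as_str(uid)
            if uid in seen:
                self.add("error", "R11", node.name,
                         f"duplicate uid {uid!r} (also at {seen[uid]})")
            else:
                seen[uid] = node.name

        mt.visititems(visit)


def validate_file(path, strictness: str = "tolerant") -> ValidationReport:
    """Run the full rule set against *path* and return the report.

    ``strictness="strict"`` promotes unit-grammar warnings and soft
    structural warnings to errors.  The file is opened read-only and is not
    modified.
    """
    if strictness not in ("strict", "tolerant"):
        raise ValueError(f"strictness must be strict|tolerant, "
                         f"got {strictness!r}")
    report = ValidationReport(path=str(path), strictness=strictness)
    try:
        f = h5py.File(path, "r")
    except Exception as exc:  # unreadable file: single fatal finding
        report.findings.append(Finding("error", "R1", str(path),
                                       f"cannot open file: {exc}"))
        return report
    with f:
        checker = _Checker(f, strict=(strictness == "strict"))
        checker.check_structure()
        checker.check_root_attrs()
        checker.check_data()
        checker.check_modeltree()
        report.findings = checker.findings
    return report


def resolve_model_precedence(path) -> tuple[list[str], str | None]:
    """Which model-description kinds a file offers, and the one a reader
    should use.

    The precedence order is modeltree > filecontents > filerefs > links.
    Absence of all kinds is legal (the model description is recommended, not
    required); ``selected`` is then ``None``.
    """
    with h5py.File(path, "r") as f:
        model = f.get("model")
        present = []
        if model is not None:
            for kind in MODEL_PRECEDENCE:
                node = model.get(kind)
                if node is not None and len(node) > 0:
                    present.append(kind)
    # report in precedence order regardless of storage order
    ordered = [k for k in MODEL_PRECEDENCE if k in present]
    return ordered, ordered[0] if ordered else None
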