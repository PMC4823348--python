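"""Deterministic fixture generators.

Every generator is a pure function of its seed and parameters, so the other
modules can be exercised without any external downloads:

* :func:`gen_fig2` — the canonical two-neuron scenario: neuronA and neuronB,
  each with dend/soma/axon compartments, connected by two synapses; membrane
  potential and transmembrane current from neuronA's soma and axon at a
  constant timestep; transmembrane current from neuronB's dend and soma at
  shared nonuniform times; spike trains with exactly 11 events for neuronA
  and 13 for neuronB.
* :func:`gen_hh` — a single-compartment Hodgkin-Huxley-style recording: one
  compartment with Na and K channel children, membrane potential, a 2-row
  channel-current matrix (IChannel) and total membrane current.
* :func:`gen_benchmark` — the storage/benchmark corpus: at full scale 100
  uniform datasets of 100 sources x 10000 samples, and ragged (nonuniform +
  event) rows whose lengths are drawn uniformly between 5000 and 10000; a
  ``scale_factor`` shrinks all counts proportionally.
* :func:`corrupt` — targeted single-rule mutations of written files, used to
  show each validator rule fires on exactly the defect it describes.

Values are pseudo-random and carry no biophysical realism: these fixtures
test the format, not the physiology.  Event and sampling times are drawn in
[0, 10] s, the scale of a typical tens-of-seconds network run.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field as dc_field

import h5py
import numpy as np

from ._h5 import as_str
from .core import (Column, EventSet, FileMetadata, ModelNode, RaggedSeries,
                   StaticLayout, StaticTable, UniformBlock, Variant,
                   make_uid)
from .exceptions import InvalidArgumentError
from .writer import NSDFWriter

__all__ = ["FixtureBundle", "gen_fig2", "gen_hh", "gen_benchmark",
           "write_bundle", "corrupt", "build_rule_corpus"]

_DURATION_S = 10.0  # recording duration emulated by the fixtures


@dataclass
class FixtureBundle:
    """A self-checking collection of containers plus an expected-counts
    manifest (the manifest is asserted against the actual container sizes
    on construction)."""

    model_root: ModelNode | None
    static_tables: list[StaticTable] = dc_field(default_factory=list)
    uniform_blocks: list[UniformBlock] = dc_field(default_factory=list)
    ragged_series: list[RaggedSeries] = dc_field(default_factory=list)
    event_sets: list[EventSet] = dc_field(default_factory=list)
    manifest: dict[str, int] = dc_field(default_factory=dict)

    def check_manifest(self) -> None:
        actual = self.actual_counts()
        for key, expected in self.manifest.items():
            if key in actual and actual[key] != expected:
                raise AssertionError(
                    f"manifest mismatch for {key}: expected {expected}, "
                    f"got {actual[key]}")

    def actual_counts(self) -> dict[str, int]:
        out: dict[str, int] = {
            "static_tables": len(self.static_tables),
            "uniform_blocks": len(self.uniform_blocks),
            "ragged_series": len(self.ragged_series),
            "event_sets": len(self.event_sets),
        }
        for table in self.static_tables:
            out[f"rows:{table.name}"] = len(table.sources)
        for es in self.event_sets:
            for uid, times in es.entries:
                out[f"events:{uid}"] = times.size
        for rs in self.ragged_series:
            for i, (uid, values, _) in enumerate(rs.entries):
                out[f"samples:{rs.variable}:{uid}"] = values.size
        return out


def _sorted_times(rng: np.random.Generator, n: int,
                  duration: float = _DURATION_S) -> np.ndarray:
    # distinct sorted draws so time axes are strictly increasing
    times = np.sort(rng.uniform(0.0, duration, size=n))
    while np.any(np.diff(times) <= 0):  # pragma: no cover - measure-zero
        times = np.sort(rng.uniform(0.0, duration, size=n))
    return times


def default_metadata(title: str) -> FileMetadata:
    return FileMetadata(
        title=title, creator="nsdfkit fixtures",
        created="2015-01-01T00:00:00Z",
        software=["nsdfkit"], method=["synthetic"],
        description="programmatically generated fixture data")


# ---------------------------------------------------------------------------
# two-neuron worked example
# ---------------------------------------------------------------------------

def gen_fig2(seed: int = 0, n_uniform: int = 200,
             m_nonuniform: int = 47) -> FixtureBundle:
    """Two neurons, three compartments each, two synapses, 11 + 13 spikes.

    neuronA runs at a constant timestep: Vm and Im from its soma and axon
    become uniform blocks (dt = 0.1 ms).  neuronB runs under a variable
    timestep: Im from its dend and soma is sampled at ``m_nonuniform``
    shared, irregular time points (the count is a free parameter of the
    scenario; 47 by default).  neuronA spikes 11 times, neuronB 13.
    """
    rng = np.random.default_rng(seed)
    root = ModelNode("modeltree")
    neurons: dict[str, ModelNode] = {}
    for neuron in ("neuronA", "neuronB"):
        node = root.add_child(ModelNode(neuron))
        for comp in ("dend", "soma", "axon"):
            node.add_child(ModelNode(comp))
        neurons[neuron] = node
    root.assign_path_uids(prefix=("model",))

    uid = lambda *parts: make_uid(["model", "modeltree", *parts])

    dt = 1e-4  # s, neuronA's fixed integration step
    srcA = [uid("neuronA", "soma"), uid("neuronA", "axon")]
    vm = UniformBlock(
        population="neuronA", variable="Vm", sources=srcA,
        values=rng.normal(-65.0, 5.0, size=(2, n_uniform)), unit="mV",
        tstart=0.0, dt=dt, tunit="s")
    im_uniform = UniformBlock(
        population="neuronA", variable="Im", sources=srcA,
        values=rng.normal(0.0, 0.5, size=(2, n_uniform)), unit="nA",
        tstart=0.0, dt=dt, tunit="s")

    srcB = [uid("neuronB", "dend"), uid("neuronB", "soma")]
    shared_times = _sorted_times(rng, m_nonuniform)
    im_nonuniform = RaggedSeries(
        population="neuronB", variable="Im",
        entries=[(s, rng.normal(0.0, 0.5, size=m_nonuniform), None)
                 for s in srcB],
        shared_times=shared_times, unit="nA", tunit="s")

    spikes = EventSet(
        population="neurons", variable="spike",
        entries=[(uid("neuronA"), _sorted_times(rng, 11)),
                 (uid("neuronB"), _sorted_times(rng, 13))],
        unit="s")

    synapses = StaticTable(
        population="synapses", name="synapse",
        sources=["syn_0", "syn_1"], layout=StaticLayout.COMPOUND,
        columns=[
            Column("pre", "", [uid("neuronA", "axon"), uid("neuronB", "axon")]),
            Column("post", "", [uid("neuronB", "dend"), uid("neuronA", "dend")]),
            Column("weight", "nS", rng.uniform(0.1, 2.0, size=2)),
        ])

    bundle = FixtureBundle(
        model_root=root, static_tables=[synapses],
        uniform_blocks=[vm, im_uniform], ragged_series=[im_nonuniform],
        event_sets=[spikes],
        manifest={
            "rows:synapse": 2,
            f"events:{uid('neuronA')}": 11,
            f"events:{uid('neuronB')}": 13,
            f"samples:Im:{srcB[0]}": m_nonuniform,
            "uniform_blocks": 2,
        })
    bundle.check_manifest()
    return bundle


# ---------------------------------------------------------------------------
# single-compartment recording
# ---------------------------------------------------------------------------

def gen_hh(seed: int = 0, n_samples: int = 500) -> FixtureBundle:
    """Single-compartment recording with Na/K channel currents.

    One compartment carries a membrane-potential series; its Na and K
    channel children contribute the two rows of the IChannel matrix, and the
    total membrane current Im is stored alongside.
    """
    rng = np.random.default_rng(seed)
    root = ModelNode("modeltree")
    comp = root.add_child(ModelNode("compartment"))
    comp.add_child(ModelNode("Na"))
    comp.add_child(ModelNode("K"))
    root.assign_path_uids(prefix=("model",))

    comp_uid = make_uid(["model", "modeltree", "compartment"])
    na_uid = make_uid(["model", "modeltree", "compartment", "Na"])
    k_uid = make_uid(["model", "modeltree", "compartment", "K"])

    dt = 1e-5  # s
    vm = UniformBlock(
        population="compartment", variable="Vm", sources=[comp_uid],
        values=rng.normal(-65.0, 10.0, size=(1, n_samples)), unit="mV",
        tstart=0.0, dt=dt)
    ichannel = UniformBlock(
        population="channels", variable="IChannel",
        sources=[na_uid, k_uid],
        values=rng.normal(0.0, 1.0, size=(2, n_samples)), unit="nA",
        tstart=0.0, dt=dt)
    im = UniformBlock(
        population="compartment", variable="Im", sources=[comp_uid],
        values=rng.normal(0.0, 1.0, size=(1, n_samples)), unit="nA",
        tstart=0.0, dt=dt)
    bundle = FixtureBundle(
        model_root=root, uniform_blocks=[vm, ichannel, im],
        manifest={"uniform_blocks": 3})
    bundle.check_manifest()
    return bundle


# ---------------------------------------------------------------------------
# benchmark corpus
# ---------------------------------------------------------------------------

def gen_benchmark(seed: int = 0, scale_factor: float = 1.0) -> FixtureBundle:
    """Random benchmark corpus with the study's shapes.

    At scale 1: 100 uniform datasets of 100 sources x 10000 samples, and the
    same number of nonuniform and event variables whose per-source lengths
    are drawn uniformly between 5000 and 10000.  ``scale_factor`` in (0, 1]
    shrinks dataset count, source count and lengths proportionally (floored,
    minimum 1).  A fixed seed keeps the data identical across runs.
    """
    if not (0 < scale_factor <= 1):
        raise InvalidArgumentError(
            f"scale_factor must be in (0, 1], got {scale_factor}")
    rng = np.random.default_rng(seed)
    n_datasets = max(1, int(100 * scale_factor))
    n_sources = max(1, int(100 * scale_factor))
    n_cols = max(1, int(10000 * scale_factor))
    lo = max(1, int(5000 * scale_factor))
    hi = max(lo, int(10000 * scale_factor))

    uniform_blocks = []
    ragged = []
    events = []
    width = len(str(max(n_datasets - 1, 1)))
    for d in range(n_datasets):
        tag = f"{d:0{width}d}"
        pop = f"bench{tag}"
        sources = [f"/{pop}/src{i}" for i in range(n_sources)]
        uniform_blocks.append(UniformBlock(
            population=pop, variable=f"u{tag}", sources=sources,
            values=rng.random(size=(n_sources, n_cols)), unit="mV",
            tstart=0.0, dt=1e-4))
        lengths = rng.integers(lo, hi + 1, size=n_sources)
        ragged.append(RaggedSeries(
            population=pop, variable=f"nu{tag}",
            entries=[(s, rng.random(size=int(n)),
                      _sorted_times(rng, int(n)))
                     for s, n in zip(sources, lengths)],
            unit="mV", tunit="s"))
        lengths = rng.integers(lo, hi + 1, size=n_sources)
        events.append(EventSet(
            population=pop, variable=f"ev{tag}",
            entries=[(s, _sorted_times(rng, int(n)))
                     for s, n in zip(sources, lengths)],
            unit="s"))
    return FixtureBundle(
        model_root=None, uniform_blocks=uniform_blocks,
        ragged_series=ragged, event_sets=events,
        manifest={"uniform_blocks": n_datasets,
                  "ragged_series": n_datasets,
                  "event_sets": n_datasets})


# ---------------------------------------------------------------------------
# materialization
# ---------------------------------------------------------------------------

def write_bundle(bundle: FixtureBundle, path, *,
                 event_variant: Variant | str = Variant.VLEN,
                 nonuniform_variant: Variant | str = Variant.NUREGULAR,
                 uniform_time_mode: str = "attrs",
                 compression: str | None = None,
                 metadata: FileMetadata | None = None,
                 include_model: bool = True) -> str:
    """Write every container of *bundle* to a fresh NSDF file at *path*."""
    meta = metadata or default_metadata("fixture bundle")
    with NSDFWriter(path, metadata=meta, compression=compression) as w:
        for table in bundle.static_tables:
            w.add_static(table)
        for block in bundle.uniform_blocks:
            scale = w.add_source_dim_scale("uniform", block.population,
                                           block.sources)
            w.add_uniform(scale, block, time_mode=uniform_time_mode)
        for series in bundle.ragged_series:
            w.add_nonuniform(series, nonuniform_variant)
        for es in bundle.event_sets:
            w.add_events(es, event_variant)
        if include_model and bundle.model_root is not None:
            w.add_modeltree(bundle.model_root)
    return str(path)


# ---------------------------------------------------------------------------
# targeted corruption for validator tests
# ---------------------------------------------------------------------------

def _first_dataset(f: h5py.File, category: str) -> h5py.Dataset:
    grp = f[f"data/{category}"]
    for pop in grp.values():
        for node in pop.values():
            if isinstance(node, h5py.Dataset):
                return node
    raise InvalidArgumentError(f"no {category} dataset in file")


def corrupt(fixture_file, rule_id: str, out_path, seed: int = 0) -> str:
    """Copy *fixture_file* and apply the minimal mutation triggering
    *rule_id*.

    The input must contain the structures the rule concerns (e.g. R7 needs
    an ONED variable, R6 a NaN-padded one); :func:`build_rule_corpus`
    assembles suitable base files for every rule.
    """
    shutil.copyfile(fixture_file, out_path)
    with h5py.File(out_path, "r+") as f:
        if rule_id == "R1":
            del f["model"]
        elif rule_id == "R2":
            f["data"].create_group("bogus")
        elif rule_id == "R3":
            ds = _first_dataset(f, "uniform")
            del ds.attrs["unit"]
        elif rule_id == "R4":
            ds = _first_dataset(f, "uniform")
            scale = dict(ds.dims[0].items())["source"]
            ds.dims[0].detach_scale(scale)
        elif rule_id == "R5":
            ds = _first_dataset(f, "uniform")
            if "dt" not in ds.attrs:
                raise InvalidArgumentError(
                    "R5 needs an attribute-timed uniform dataset")
            del ds.attrs["tstart"]
            del ds.attrs["dt"]
        elif rule_id == "R6":
            ds = _first_dataset(f, "event")
            mat = ds[...]
            row = np.argmax([np.isnan(r).any() for r in mat])
            if not np.isnan(mat[row]).any():
                raise InvalidArgumentError(
                    "R6 needs a NANPADDED event dataset with padding")
            mat[row, 0] = np.nan  # valid values now follow a NaN
            ds[...] = mat
        elif rule_id == "R7":
            grp = None
            for pop in f["data/event"].values():
                for node in pop.values():
                    if isinstance(node, h5py.Group):
                        grp = node
            if grp is None:
                raise InvalidArgumentError("R7 needs an ONED event variable")
            tbl = f[as_str(grp.attrs["source"])]
            rows = tbl[...]
            rows[0]["data"] = b"/missing"
            tbl[...] = rows
        elif rule_id == "R8":
            pop = next(iter(f["data/event"].values()))
            ragged = None
            for node in pop.values():
                if isinstance(node, h5py.Dataset) and node.ndim == 1 \
                        and h5py.check_vlen_dtype(node.dtype):
                    ragged = node
            if ragged is None:
                raise InvalidArgumentError("R8 needs a VLEN event variable")
            alien = pop.create_dataset("alien",
                                       data=np.full((2, 3), np.nan))
            alien.attrs["unit"] = "s"
            alien.attrs["field"] = "alien"
            scale = dict(ragged.dims[0].items())["source"]
            alien.dims[0].attach_scale(scale)
        elif rule_id == "R9":
            del f.attrs["nsdf_version"]
        elif rule_id == "R10":
            f.attrs["created"] = "yesterday, more or less"
        elif rule_id == "R11":
            groups = []

            def visit(name, node):
                if isinstance(node, h5py.Group) and "uid" in node.attrs:
                    groups.append(node)

            f["model/modeltree"].visititems(visit)
            if len(groups) < 2:
                raise InvalidArgumentError(
                    "R11 needs a modeltree with at least two nodes")
            groups[1].attrs["uid"] = groups[0].attrs["uid"]
        elif rule_id == "R12":
            grp = f["data/nonuniform"]
            target = None
            for pop in grp.values():
                for node in pop.values():
                    if isinstance(node, h5py.Dataset) and node.ndim == 2:
                        tscale = dict(node.dims[1].items()).get("time")
                        if tscale is not None and tscale.ndim == 2:
                            target = tscale
            if target is None:
                raise InvalidArgumentError(
                    "R12 needs a NANPADDED nonuniform variable")
            mat = target[...]
            valid = np.flatnonzero(~np.isnan(mat[0]))
            if valid.size == 0:
                raise InvalidArgumentError("R12 needs a nonempty time row")
            mat[0, valid[-1]] = np.nan  # one fewer time point than values
            target[...] = mat
        else:
            raise InvalidArgumentError(f"unknown rule id {rule_id!r}")
    return str(out_path)


def build_rule_corpus(workdir, seed: int = 0) -> dict[str, str]:
    """Write one conforming base file per rule plus its corrupted twin.

    Returns ``{rule_id: corrupted_path}``.  Base files are chosen so each
    rule's mutation is applicable: R6/R8 use NaN-padded/ragged events, R7
    the ONED layout, R12 NaN-padded nonuniform data.
    """
    import os

    bundle = gen_fig2(seed)
    bases = {}
    for name, ev, nu in (
            ("base_vlen", Variant.VLEN, Variant.NUREGULAR),
            ("base_oned", Variant.ONED, Variant.ONED),
            ("base_padded", Variant.NANPADDED, Variant.NANPADDED)):
        path = os.path.join(workdir, f"{name}.h5")
        write_bundle(bundle, path, event_variant=ev, nonuniform_variant=nu)
        bases[name] = path

    base_for_rule = {
        "R1": "base_vlen", "R2": "base_vlen", "R3": "base_vlen",
        "R4": "base_vlen", "R5": "base_vlen", "R6": "base_padded",
        "R7": "base_oned", "R8": "base_vlen", "R9": "base_vlen",
        "R10": "base_vlen", "R11": "base_vlen", "R12": "base_padded",
    }
    out = {}
    for rule, base in base_for_rule.items():
        out[rule] = corrupt(bases[base], rule,
                            os.path.join(workdir, f"corrupt_{rule}.h5"),
                            seed=seed)
    return out
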