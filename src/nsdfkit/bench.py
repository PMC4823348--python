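"""Benchmark harness for the storage-variant trade-off study.

For each requested cell (category x variant x compression x write mode) the
harness writes the seeded benchmark corpus to a fresh file, measuring wall
time on a monotonic clock, records the on-disk size, and times a full
read-back.  Repetitions give a mean and standard deviation per metric.

Incremental writing mimics streaming simulators: uniform data is appended in
column batches, event data in per-source row batches.  Nonuniform data is
benchmarked one-shot only.  Absolute timings depend on hardware and are
reported, not asserted; the structural size relations (ragged VLEN files are
identical with and without compression; NaN-padded matrices are larger than
per-source 1D datasets uncompressed but compress well) are stable and are
what the acceptance suite checks.
"""

from __future__ import annotations

import json
import os
import statistics
import tempfile
import time
from dataclasses import dataclass, field as dc_field

import numpy as np

from .core import EventSet, UniformBlock, Variant
from .exceptions import InvalidArgumentError
from .fixtures import FixtureBundle, default_metadata, gen_benchmark
from .reader import open_index
from .writer import NSDFWriter

__all__ = ["BenchConfig", "BenchResult", "run_bench"]


@dataclass
class BenchConfig:
    scale_factor: float = 0.02
    reps: int = 2
    seed: int = 0
    variants: tuple = (Variant.ONED, Variant.VLEN, Variant.NANPADDED)
    compression: tuple = (False, True)
    categories: tuple = ("uniform", "nonuniform", "event")
    modes: tuple = ("oneshot", "incremental")
    incremental_batches: int = 10
    compression_level: int = 6

    def __post_init__(self) -> None:
        self.variants = tuple(Variant(v) for v in self.variants)
        for v in self.variants:
            if v == Variant.NUREGULAR:
                raise InvalidArgumentError(
                    "NUREGULAR is not part of the ragged-variant benchmark")


@dataclass
class BenchResult:
    config: dict
    rows: list[dict] = dc_field(default_factory=list)

    def cell(self, category: str, variant: str | None, compression: bool,
             mode: str, metric: str) -> dict | None:
        for row in self.rows:
            if (row["category"], row["variant"], row["compression"],
                    row["mode"], row["metric"]) == (
                    category, variant, compression, mode, metric):
                return row
        return None

    def size(self, category: str, variant: str | None,
             compression: bool) -> int:
        row = self.cell(category, variant, compression, "oneshot",
                        "size_bytes")
        if row is None:
            raise KeyError((category, variant, compression))
        return int(row["mean"])

    def to_json(self, indent: int = 2) -> str:
        return json.dumps({"config": self.config, "rows": self.rows},
                          indent=indent)

    def to_tsv(self) -> str:
        cols = ("category", "variant", "compression", "mode", "metric",
                "mean", "sd", "repetitions")
        lines = ["\t".join(cols)]
        for row in self.rows:
            lines.append("\t".join(str(row[c]) for c in cols))
        return "\n".join(lines)


def _write_uniform(writer: NSDFWriter, blocks: list[UniformBlock],
                   incremental: bool, batches: int) -> None:
    for block in blocks:
        scale = writer.add_source_dim_scale("uniform", block.population,
                                            block.sources)
        if not incremental:
            writer.add_uniform(scale, block)
            continue
        q = block.n_samples
        cuts = np.linspace(0, q, batches + 1).astype(int)
        head = UniformBlock(
            population=block.population, variable=block.variable,
            sources=block.sources, values=block.values[:, :cuts[1]],
            unit=block.unit, tstart=block.tstart, dt=block.dt,
            tunit=block.tunit)
        path = writer.add_uniform(scale, head)
        for a, b in zip(cuts[1:], cuts[2:]):
            writer.append_uniform(path, block.values[:, a:b])


def _write_events(writer: NSDFWriter, event_sets: list[EventSet],
                  variant: Variant, incremental: bool, batches: int) -> None:
    for es in event_sets:
        if not incremental:
            writer.add_events(es, variant)
            continue
        splits = [np.linspace(0, times.size, batches + 1).astype(int)
                  for _, times in es.entries]
        first = EventSet(
            population=es.population, variable=es.variable,
            entries=[(uid, times[:cut[1]])
                     for (uid, times), cut in zip(es.entries, splits)],
            unit=es.unit, field=es.field)
        path = writer.add_events(first, variant)
        for k in range(1, batches):
            chunk = EventSet(
                population=es.population, variable=es.variable,
                entries=[(uid, times[cut[k]:cut[k + 1]])
                         for (uid, times), cut in zip(es.entries, splits)],
                unit=es.unit, field=es.field)
            writer.append_events(path, chunk)


def _write_file(path: str, bundle: FixtureBundle, category: str,
                variant: Variant | None, compressed: bool, mode: str,
                config: BenchConfig) -> float:
    t0 = time.monotonic()
    with NSDFWriter(path, metadata=default_metadata("benchmark"),
                    compression="gzip" if compressed else None,
                    compression_level=config.compression_level) as w:
        if category == "uniform":
            _write_uniform(w, bundle.uniform_blocks,
                           mode == "incremental",
                           config.incremental_batches)
        elif category == "event":
            _write_events(w, bundle.event_sets, variant,
                          mode == "incremental",
                          config.incremental_batches)
        elif category == "nonuniform":
            for series in bundle.ragged_series:
                w.add_nonuniform(series, variant)
        else:
            raise InvalidArgumentError(f"unknown category {category!r}")
    return time.monotonic() - t0


def _read_file(path: str, category: str) -> float:
    t0 = time.monotonic()
    with open_index(path) as ix:
        for pop, var in ix.variables(category):
            if category == "uniform":
                ix.read_uniform(pop, var)
            elif category == "event":
                ix.read_events(pop, var)
            else:
                ix.read_nonuniform(pop, var)
    return time.monotonic() - t0


def run_bench(config: BenchConfig | None = None,
              workdir: str | None = None) -> BenchResult:
    """Measure write time, file size and read time for every requested cell.

    Returns a :class:`BenchResult` whose rows carry mean and standard
    deviation over ``config.reps`` repetitions (identical data each run, by
    fixed seed).
    """
    config = config or BenchConfig()
    bundle = gen_benchmark(config.seed, config.scale_factor)
    result = BenchResult(config={
        "scale_factor": config.scale_factor, "reps": config.reps,
        "seed": config.seed,
        "variants": [v.value for v in config.variants],
        "compression": list(config.compression),
        "categories": list(config.categories),
        "modes": list(config.modes),
        "codec": "gzip", "level": config.compression_level,
    })
    own_tmp = None
    if workdir is None:
        own_tmp = tempfile.TemporaryDirectory(prefix="nsdf_bench_")
        workdir = own_tmp.name
    try:
        for category in config.categories:
            variants = ((None,) if category == "uniform"
                        else config.variants)
            for variant in variants:
                modes = config.modes
                if category == "nonuniform":
                    modes = tuple(m for m in modes if m == "oneshot")
                for compressed in config.compression:
                    for mode in modes:
                        metrics = {"write_s": [], "read_s": [],
                                   "size_bytes": []}
                        for rep in range(config.reps):
                            vtag = variant.value if variant else "uniform"
                            path = os.path.join(
                                workdir,
                                f"{category}_{vtag}_{int(compressed)}_"
                                f"{mode}.h5")
                            metrics["write_s"].append(_write_file(
                                path, bundle, category, variant, compressed,
                                mode, config))
                            metrics["size_bytes"].append(
                                float(os.path.getsize(path)))
                            metrics["read_s"].append(
                                _read_file(path, category))
                        for metric, values in metrics.items():
                            result.rows.append({
                                "category": category,
                                "variant": variant.value if variant else None,
                                "compression": compressed,
                                "mode": mode,
                                "metric": metric,
                                "values": values,
                                "repetitions": len(values),
                                "mean": statistics.fmean(values),
                                "sd": (statistics.stdev(values)
                                       if len(values) >= 2 else 0.0),
                            })
    finally:
        if own_tmp is not None:
            own_tmp.cleanup()
    return result
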