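import numpy as np
import pytest

from nsdfkit import (Column, EventSet, RaggedSeries, StaticLayout,
                     StaticTable, UniformBlock)
from nsdfkit.fixtures import default_metadata, gen_fig2


@pytest.fixture
def fig2_bundle():
    return gen_fig2(seed=0)


@pytest.fixture
def metadata():
    return default_metadata("test file")


def random_uniform_block(rng: np.random.Generator, population="pop",
                         variable="v") -> UniformBlock:
    p = int(rng.integers(1, 5))
    q = int(rng.integers(1, 30))
    return UniformBlock(
        population=population, variable=variable,
        sources=[f"/{population}/s{i}" for i in range(p)],
        values=rng.normal(size=(p, q)), unit="mV",
        tstart=float(rng.uniform(0, 1)), dt=float(rng.uniform(1e-4, 1e-2)))


def random_event_set(rng: np.random.Generator, population="pop",
                     variable="spike", allow_empty=True) -> EventSet:
    p = int(rng.integers(1, 5))
    entries = []
    for i in range(p):
        n = int(rng.integers(0 if allow_empty else 1, 20))
        entries.append((f"/{population}/s{i}",
                        np.sort(rng.uniform(0, 10, size=n))))
    return EventSet(population=population, variable=variable,
                    entries=entries, unit="s")


def random_ragged_series(rng: np.random.Generator, population="pop",
                         variable="x", shared=False) -> RaggedSeries:
    p = int(rng.integers(1, 5))
    if shared:
        m = int(rng.integers(1, 25))
        times = np.sort(rng.uniform(0, 10, size=m))
        while np.any(np.diff(times) <= 0):
            times = np.sort(rng.uniform(0, 10, size=m))
        entries = [(f"/{population}/s{i}", rng.normal(size=m), None)
                   for i in range(p)]
        return RaggedSeries(population=population, variable=variable,
                            entries=entries, shared_times=times, unit="nA")
    entries = []
    for i in range(p):
        n = int(rng.integers(1, 25))
        t = np.sort(rng.uniform(0, 10, size=n))
        while np.any(np.diff(t) <= 0):
            t = np.sort(rng.uniform(0, 10, size=n))
        entries.append((f"/{population}/s{i}", rng.normal(size=n), t))
    return RaggedSeries(population=population, variable=variable,
                        entries=entries, unit="nA")


def random_static_table(rng: np.random.Generator, population="pop",
                        name="tab", compound=False) -> StaticTable:
    p = int(rng.integers(1, 6))
    sources = [f"{name}_{i}" for i in range(p)]
    if compound:
        columns = [
            Column("idx", "", np.arange(p, dtype=float)),
            Column("who", "", [f"/m/c{i}" for i in range(p)]),
            Column("weight", "nS", rng.uniform(0.1, 1.0, size=p)),
        ]
        return StaticTable(population=population, name=name, sources=sources,
                           layout=StaticLayout.COMPOUND, columns=columns)
    c = int(rng.integers(1, 5))
    columns = [Column(f"c{j}", "um", rng.normal(size=p)) for j in range(c)]
    return StaticTable(population=population, name=name, sources=sources,
                       layout=StaticLayout.HOMOGENEOUS_2D, columns=columns,
                       unit="um")
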