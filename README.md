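# nsdfkit

A self-contained Python implementation of **NSDF** (Neuroscience Simulation
Data Format): typed in-memory containers, an HDF5 writer supporting every
storage variant, a variant-detecting reader, a conformance validator,
deterministic example generators, and a benchmark harness for the variant
trade-off study.

## The problem

Neural simulators produce heterogeneous output — membrane potentials sampled
at a fixed timestep from thousands of compartments, currents recorded at the
irregular steps of an adaptive solver, spike times whose count differs per
cell, and static tables such as connectivity or morphology.  Custom per-lab
file layouts make this data hard to share and force every analysis or
visualization tool to re-learn each simulator's conventions.  NSDF addresses
this with a self-documenting HDF5 layout that separates three concerns:

```
/data   /{static,uniform,nonuniform,event}/<population>/<variable>
/map    source and sampling-time mappings (HDF5 dimension scales, map tables)
/model  optional model description (modeltree | filecontents | filerefs | links)
```

Every dataset row is tied to the unique identifier (uid) of the model
component it was recorded from, so tools can traverse from model to data and
back without simulator-specific knowledge.

## The core model

**Uniform data.** A variable recorded from sources n₁…n_P at Q shared,
regular time points is a P×Q matrix V with V[i,j] the sample from nᵢ at

&nbsp;&nbsp;&nbsp;&nbsp;t_j = t_start + j·dt&nbsp;&nbsp;(0-based j),

stored with `tstart`/`dt`/`tunit` attributes or an explicit time scale (the
scale wins if both are present).

**Ragged data** (nonuniform series and event times) can be serialized three
ways, each with different trade-offs:

| variant   | layout                                                     |
|-----------|------------------------------------------------------------|
| ONED      | one appendable 1D dataset per source + a source/data map table |
| VLEN      | a single ragged (variable-row-length) dataset              |
| NANPADDED | a regular 2D matrix padded with trailing NaN               |

Nonuniform series whose sources share one sampling-time axis may instead use
a plain matrix (NUREGULAR).  Within one file each category keeps a single
consistent variant.  Every physical dataset carries a mandatory `unit`
attribute written in a UDUNITS-style SI grammar (`mV`, `mS/cm^2`, …).

## Worked example

Generate the canonical two-neuron scenario — two three-compartment neurons
joined by two synapses, uniform Vm/Im from neuronA, nonuniform Im from
neuronB, and spike trains with 11 and 13 events — then inspect and validate
it:

```text
$ nsdf example fig2 -o fig2.h5 --variant VLEN --seed 0
wrote fig2 example to fig2.h5 (events: VLEN, nonuniform: VLEN)

$ nsdf inspect fig2.h5
fig2.h5
  @created = 2015-01-01T00:00:00Z
  @creator = nsdfkit fixtures
  ...
  /data/event
    neurons
      spike [VLEN]
  /data/nonuniform
    neuronB
      Im [VLEN]
  /data/static
    synapses
      synapse
  /data/uniform
    neuronA
      Im
      Vm
  model descriptions: modeltree (reader should use: modeltree)

$ nsdf validate fig2.h5
fig2.h5: CONFORMS (tolerant mode)
```

The same from Python:

```python
from nsdfkit import open_index

with open_index("fig2.h5") as ix:
    spikes = ix.read_events("neurons", "spike")
    print(spikes.counts())
    vm = ix.read_uniform("neuronA", "Vm")
    print(vm.values.shape, vm.times[:3])
```

prints

```text
{'/model/modeltree/neuronA': 11, '/model/modeltree/neuronB': 13}
(2, 200) [0.     0.0001 0.0002]
```

— the spike counts the scenario defines, and the uniform time axis
reconstructed from the stored `tstart`/`dt` attributes.

`nsdf bench --scale 0.02 --reps 2` runs the variant trade-off measurement
(write time one-shot vs incremental, on-disk size with and without gzip,
read time) on a seeded random corpus and prints a TSV table.

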