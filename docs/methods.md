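# Methods

## Scope and layout

nsdfkit implements the NSDF file layout as a library plus a thin CLI.  A
file holds `/data`, `/map` and `/model` at the root; data live at
`/data/<category>/<population>/<variable>` with categories `static`,
`uniform`, `nonuniform` and `event`.  Mappings are realized with HDF5
dimension scales: a `source` scale (the uids of the population's components)
on the row dimension, and `time` scales under `/map/time` where sampling
times are explicit.  The ONED variant, whose per-source datasets cannot
carry a row scale, instead uses a two-field `source`/`data` map table under
`/map/<category>` whose path is stored in the variable group's `source`
attribute; each per-source dataset additionally records its own uid in a
`source` attribute, giving bidirectional resolution.

Out of scope by design: simulator integrations, visualization, experimental
session/trial structure, image/spatial data types, ontology resolution
against live services, and wrapping external raw binary files (external HDF5
links are supported via `/model/links`).

## Timing model

Uniform data carry either `tstart`/`dt`/`tunit` attributes or an explicit
time scale on the column dimension.  The axis is `t_j = tstart + j*dt` with
0-based column index j (equivalently the k-th sample in 1-based counting is
at `tstart + (k-1)*dt`).  When both representations are present the explicit
scale takes precedence; the writer refuses to produce a pair that disagrees
beyond 1e-12 relative tolerance, and the reader warns (but obeys the scale)
when a foreign file disagrees beyond 1e-9 relative.  Appending columns under
attribute timing touches nothing but the matrix, which is why that
representation is the streaming-friendly default.

## Ragged storage variants

Nonuniform and event data are ragged across sources.  Three serializations
are supported — ONED (one appendable 1D dataset per source), VLEN (a ragged
HDF5 dataset), NANPADDED (a regular matrix with trailing-NaN padding) — plus
NUREGULAR for nonuniform series with one shared time axis.  NaN is reserved
strictly as the padding sentinel: payload NaN is rejected on write, and a
valid value after a NaN on read is a format error naming the row.  For
nonuniform VLEN/NANPADDED data the time store mirrors the value store
(ragged or padded), and the NaN masks of values and times must be congruent.
NUREGULAR never applies to events, which have no value/time pairing to share.
One variant per category is enforced on write; the reader detects the variant
of each variable from its layout and reads whatever it finds, while the
validator flags mixtures.

## Units

Physical datasets must carry a `unit` attribute.  The grammar is a closed
UDUNITS-style subset: SI prefixes × base symbols
{m, s, A, V, S, F, ohm, mol, M, Hz, C, K, cd, kg, g, L} combined with `*`,
`/` and integer powers; "ohm" is written in full and `u` stands for micro so
units stay ASCII.  Exponents may be written `cm^2` or `cm2`; normalization
always inserts the caret.  Compound tables carry one unit per field, the
empty string marking non-physical columns (indices, identifiers).  An
unknown unit warns at write time and in tolerant validation; strict
validation makes it an error.  No conversion or dimensional analysis is
attempted.

## uids and the model tree

Tree-structured models use the '/'-joined element path as the uid (injective
and invertible by splitting); models supplied as external files pass their
own locators through opaquely.  The fallback model tree is stored as groups
under `/model/modeltree` with `uid` and optional `ontology` attributes,
created with HDF5 order tracking so the caller's child ordering survives a
round trip.  Nodes whose uid appears in any mapping dataset receive a `map`
attribute listing those datasets' paths; `sources_to_data` uses these to
avoid an exhaustive `/data` scan and falls back to scanning (source scales
and `source` attributes) when no tree is present — both routes return the
same sets on files this writer produces.  When several model descriptions
coexist, readers should prefer modeltree, then filecontents, then filerefs,
then links.

## File-format engineering

All numeric payloads are double precision, including variable-length rows.
Every dataset under `/data` is chunked (required for streaming appends) with
default chunks of `(min(P, 64), min(Q, 1024))`; new files are written with
`libver="latest"` so chunked datasets use compact modern indexes rather than
v1 B-trees — with dozens of small per-source datasets the index overhead
would otherwise dominate the file size.  Compression is gzip level 6
preceded by the byte-shuffle filter, the standard pipeline for floating
point data (doubles share exponent bytes that compress well once grouped by
byte position).  VLEN datasets are stored uncompressed because HDF5 cannot
compress variable-length payloads — hence a VLEN file has exactly the same
size with compression nominally on or off.  ONED map tables use fixed-length
strings sized to their longest entry so the table stays inline instead of
spilling to a global heap.  Map-table `data` entries are string paths rather
than object references (better third-party support); the API offers no
rename operation, closing the stale-path risk that choice carries.

## Validation

`validate_file` runs twelve rules (R1–R12, stable ids; see the module
docstring) covering group structure, category names, mandatory units, source
mappings, uniform timing, NaN-padding discipline, ONED map-table
consistency, variant homogeneity, root metadata, ISO 8601 timestamps,
modeltree uid uniqueness and nonuniform value/time congruence.  Tolerant
mode (default) keeps recommended-practice findings at warning level; strict
mode promotes them.  Validation is read-only and idempotent; reports
serialize to JSON and the CLI exits 0 exactly when the file conforms.  The
fixtures module can corrupt a conforming file so that exactly one chosen
rule fires, which is how rule exactness is tested.

## Fixtures and what they do (not) show

The generators are pure functions of their seed.  `gen_fig2` encodes the
two-neuron scenario (two synapses; uniform Vm/Im from neuronA's soma and
axon at dt = 0.1 ms over 200 samples; nonuniform Im from neuronB's dend and
soma at M = 47 shared irregular points — M is a free parameter of the
scenario; spike trains of 11 and 13 events in [0, 10] s).  `gen_hh` is a
single-compartment recording with a 2-row channel-current matrix.
`gen_benchmark` reproduces the trade-off corpus: at scale 1, 100 uniform
datasets of 100×10000 doubles and ragged rows of 5000–10000 entries; a
scale factor shrinks counts and lengths proportionally (floored, minimum 1).
Values are pseudo-random with no biophysical content: passing tests
demonstrate that the container/serialization layer is lossless, ordered and
self-describing, not that any simulation is correct.  Real simulator output
differs in magnitude structure (compressibility) and in scale; size and
timing observations at small scale factors weight per-object overhead more
heavily than full-size files would.

## Benchmark protocol

`run_bench` measures, per (category × variant × compression × write mode)
cell: wall write time on a monotonic clock, on-disk size, and full read-back
time, repeated `reps` times (mean ± sd) on identical seeded data.
Incremental writing appends uniform data in column batches and event data in
per-source batches — for NANPADDED this includes the per-row search for the
end of valid data that is inherent to that variant; nonuniform data is
benchmarked one-shot.  Absolute timings are hardware-dependent and only
reported.  The stable, asserted observations are structural: VLEN size is
identical with and without compression; uncompressed NaN padding costs more
space than per-source 1D datasets; compressed padded and 1D layouts come in
at or below VLEN.  These are checked on the event corpus at scale 0.05,
where they hold with margin; for nonuniform data the ONED variant also
stores per-source time datasets whose fixed overhead dominates at such small
scales, so its size orderings only emerge at larger scale factors.

## Numerical and degenerate-input choices

Time axes are computed as `tstart + dt*arange(n)`; successive differences
match dt to within 2 ulp (two rounding steps per element).  Zero-event
sources are legal in every variant (empty row, empty dataset, or all-NaN
row) and read back as empty arrays, not missing sources.  Appending zero
columns is a no-op.  Source order is authoritative from the stored scale or
map table and is never re-sorted.  Event times must be nondecreasing (ties
allowed: simultaneous events are real); sampling-time axes must be strictly
increasing.
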