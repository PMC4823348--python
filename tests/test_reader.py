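"""Reader: indexing, variant detection, precedence and source resolution."""

import warnings

import h5py
import numpy as np
import pytest

from nsdfkit import (BrokenMappingError, EventSet, IncompleteMetadataError,
                     InvalidArgumentError, NSDFWriter, StructureError,
                     UniformBlock, Variant, open_index, read_column_range,
                     sources_to_data)
from nsdfkit.fixtures import write_bundle

from conftest import random_event_set


@pytest.fixture
def fig2_file(tmp_path, fig2_bundle):
    path = tmp_path / "fig2.h5"
    write_bundle(fig2_bundle, path, event_variant="VLEN",
                 nonuniform_variant="NUREGULAR")
    return path


class TestIndex:
    def test_fig2_inventory(self, fig2_file):
        with open_index(fig2_file) as ix:
            assert sorted(v for _, v in ix.variables("uniform")) == \
                ["Im", "Vm"]
            assert ix.variables("nonuniform") == [("neuronB", "Im")]
            assert ix.variables("event") == [("neurons", "spike")]
            assert ix.variables("static") == [("synapses", "synapse")]
            assert ix.model_kinds == ["modeltree"]

    def test_empty_conforming_file(self, tmp_path, metadata):
        path = tmp_path / "empty.h5"
        NSDFWriter(path, metadata=metadata).close()
        with open_index(path) as ix:
            for category in ("static", "uniform", "nonuniform", "event"):
                assert ix.variables(category) == []

    def test_missing_data_group_is_not_nsdf(self, tmp_path):
        path = tmp_path / "no.h5"
        with h5py.File(path, "w") as f:
            f.create_group("whatever")
        with pytest.raises(StructureError):
            open_index(path)

    @pytest.mark.parametrize("variant", ["ONED", "VLEN", "NANPADDED"])
    def test_detection_matches_written_variant(self, tmp_path, metadata,
                                               variant):
        rng = np.random.default_rng(7)
        es = random_event_set(rng)
        path = tmp_path / f"{variant}.h5"
        with NSDFWriter(path, metadata=metadata) as w:
            w.add_events(es, variant)
        with open_index(path) as ix:
            assert ix.variant_of("event", es.population,
                                 es.variable) == Variant(variant)

    def test_nuregular_detected(self, fig2_file):
        with open_index(fig2_file) as ix:
            assert ix.variant_of("nonuniform", "neuronB",
                                 "Im") == Variant.NUREGULAR


class TestUniformRead:
    def test_attrs_mode_times_computed(self, tmp_path, metadata):
        path = tmp_path / "f.h5"
        block = UniformBlock("p", "v", ["/a"], np.zeros((1, 5)), unit="mV",
                             tstart=0.0, dt=0.1)
        with NSDFWriter(path, metadata=metadata) as w:
            w.add_uniform(None, block)
        with open_index(path) as ix:
            back = ix.read_uniform("p", "v")
        np.testing.assert_allclose(back.times, [0, 0.1, 0.2, 0.3, 0.4])

    def test_explicit_scale_overrides_stale_attrs(self, tmp_path, metadata):
        path = tmp_path / "f.h5"
        block = UniformBlock("p", "v", ["/a"], np.zeros((1, 4)), unit="mV",
                             tstart=0.0, dt=0.1)
        with NSDFWriter(path, metadata=metadata) as w:
            dspath = w.add_uniform(None, block, time_mode="explicit_ds")
        with h5py.File(path, "r+") as f:  # simulate stale attributes
            f[dspath].attrs["tstart"] = 5.0
            f[dspath].attrs["dt"] = 9.0
        with open_index(path) as ix:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                back = ix.read_uniform("p", "v")
            assert any("disagree" in str(w.message) for w in caught)
        np.testing.assert_allclose(back.times, block.times)

    def test_missing_timing_metadata(self, tmp_path, metadata):
        path = tmp_path / "f.h5"
        block = UniformBlock("p", "v", ["/a"], np.zeros((1, 4)), unit="mV",
                             dt=0.1)
        with NSDFWriter(path, metadata=metadata) as w:
            dspath = w.add_uniform(None, block)
        with h5py.File(path, "r+") as f:
            del f[dspath].attrs["tstart"]
            del f[dspath].attrs["dt"]
        with open_index(path) as ix:
            with pytest.raises(IncompleteMetadataError):
                ix.read_uniform("p", "v")


class TestColumnRange:
    @pytest.fixture
    def uniform_file(self, tmp_path, metadata):
        rng = np.random.default_rng(11)
        block = UniformBlock("p", "v", ["/a", "/b"],
                             rng.normal(size=(2, 40)), unit="mV",
                             tstart=1.0, dt=0.25)
        path = tmp_path / "f.h5"
        with NSDFWriter(path, metadata=metadata) as w:
            w.add_uniform(None, block)
        return path, block

    def test_full_range_equals_read_uniform(self, uniform_file):
        path, block = uniform_file
        with open_index(path) as ix:
            full = ix.read_uniform("p", "v")
            ranged = read_column_range(ix, "p", "v", 0, block.n_samples)
        np.testing.assert_array_equal(full.values, ranged.values)
        np.testing.assert_array_equal(full.times, ranged.times)

    def test_halves_concatenate_to_full(self, uniform_file):
        path, block = uniform_file
        with open_index(path) as ix:
            a = read_column_range(ix, "p", "v", 0, 20)
            b = read_column_range(ix, "p", "v", 20, 40)
            full = ix.read_uniform("p", "v")
        np.testing.assert_array_equal(np.hstack([a.values, b.values]),
                                      full.values)
        np.testing.assert_array_equal(np.concatenate([a.times, b.times]),
                                      full.times)

    def test_zero_width_range(self, uniform_file):
        path, _ = uniform_file
        with open_index(path) as ix:
            z = read_column_range(ix, "p", "v", 7, 7)
        assert z.values.shape == (2, 0) and z.times.size == 0

    def test_out_of_bounds(self, uniform_file):
        path, _ = uniform_file
        with open_index(path) as ix:
            with pytest.raises(InvalidArgumentError):
                read_column_range(ix, "p", "v", 0, 41)
            with pytest.raises(InvalidArgumentError):
                read_column_range(ix, "p", "v", 30, 20)


class TestBrokenMappings:
    def test_oned_map_row_to_missing_dataset(self, tmp_path, metadata):
        path = tmp_path / "f.h5"
        es = EventSet("p", "spike", [("/m/a", [0.1]), ("/m/b", [0.2])])
        with NSDFWriter(path, metadata=metadata) as w:
            gpath = w.add_events(es, "ONED")
        with h5py.File(path, "r+") as f:
            tbl = f[f[gpath].attrs["source"]]
            rows = tbl[...]
            rows[0]["data"] = b"/missing"
            tbl[...] = rows
        with open_index(path) as ix:
            with pytest.raises(BrokenMappingError):
                ix.read_events("p", "spike")


class TestSourcesToData:
    def test_fig2_soma_resolution(self, fig2_file):
        soma = "/model/modeltree/neuronA/soma"
        with open_index(fig2_file) as ix:
            paths = sources_to_data(ix, soma)
        assert paths == ["/data/uniform/neuronA/Im",
                         "/data/uniform/neuronA/Vm"]

    def test_unknown_uid_empty(self, fig2_file):
        with open_index(fig2_file) as ix:
            assert sources_to_data(ix, "/no/such/thing") == []

    def test_map_attribute_and_scan_agree(self, tmp_path, fig2_bundle):
        # across variants, the modeltree map attributes must resolve to the
        # same dataset sets as an exhaustive /data scan
        for variant in ("ONED", "VLEN", "NANPADDED"):
            path = tmp_path / f"{variant}.h5"
            write_bundle(fig2_bundle, path, event_variant=variant,
                         nonuniform_variant=variant)
            with open_index(path) as ix:
                for node in fig2_bundle.model_root.walk():
                    if node.uid is None or node.name == "modeltree":
                        continue
                    via_map = sources_to_data(ix, node.uid,
                                              use_model_map=True)
                    via_scan = sources_to_data(ix, node.uid,
                                               use_model_map=False)
                    assert via_map == via_scan, (variant, node.uid)


class TestForeignFiles:
    def test_extra_attributes_and_groups_ignored(self, tmp_path, metadata,
                                                 fig2_bundle):
        path = tmp_path / "f.h5"
        write_bundle(fig2_bundle, path)
        with h5py.File(path, "r+") as f:
            f.attrs["x-custom"] = "anything"
            f.create_group("user_extension")
            f["data/uniform/neuronA/Vm"].attrs["note"] = "hand-checked"
        with open_index(path) as ix:
            block = ix.read_uniform("neuronA", "Vm")
        assert block.values.shape == (2, 200)
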