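"""Writer layout, attributes, variants, appends and model description."""

import h5py
import numpy as np
import pytest

from nsdfkit import (Column, ConflictError, EventSet, InvalidArgumentError,
                     NSDFWriter, RaggedSeries, ShapeError, StaticLayout,
                     StaticTable, StructureError, UniformBlock, Variant,
                     VariantError, open_index)
from nsdfkit.core import ModelNode

from conftest import random_uniform_block


@pytest.fixture
def writer(tmp_path, metadata):
    with NSDFWriter(tmp_path / "w.h5", metadata=metadata) as w:
        yield w


class TestCreateFile:
    def test_layout_and_root_attributes(self, tmp_path, metadata):
        path = tmp_path / "f.h5"
        NSDFWriter(path, metadata=metadata).close()
        with h5py.File(path) as f:
            assert {"data", "map", "model"} <= set(f.keys())
            assert "time" in f["map"]
            assert {"title", "creator", "created", "software", "method",
                    "nsdf_version"} <= set(f.attrs)

    def test_overwrite_replaces_content(self, tmp_path, metadata):
        path = tmp_path / "f.h5"
        with NSDFWriter(path, metadata=metadata) as w:
            w.add_filerefs(["/somewhere"])
        NSDFWriter(path, metadata=metadata).close()
        with h5py.File(path) as f:
            assert len(f["model"]) == 0

    def test_append_mode_requires_nsdf_layout(self, tmp_path):
        path = tmp_path / "plain.h5"
        with h5py.File(path, "w") as f:
            f.create_dataset("x", data=[1.0])
        with pytest.raises(StructureError):
            NSDFWriter(path, mode="a")

    def test_append_mode_keeps_existing_data(self, tmp_path, metadata):
        path = tmp_path / "f.h5"
        rng = np.random.default_rng(0)
        block = random_uniform_block(rng)
        with NSDFWriter(path, metadata=metadata) as w:
            scale = w.add_source_dim_scale("uniform", block.population,
                                           block.sources)
            w.add_uniform(scale, block)
        with NSDFWriter(path, mode="a") as w:
            w.add_filerefs(["/extra"])
        with open_index(path) as ix:
            assert ix.read_uniform(block.population, block.variable) == block


class TestSourceDimScale:
    def test_scale_stored_and_idempotent(self, writer):
        uids = ["/model/modeltree/neuronA/soma",
                "/model/modeltree/neuronA/axon"]
        s1 = writer.add_source_dim_scale("uniform", "neuronA", uids)
        s2 = writer.add_source_dim_scale("uniform", "neuronA", uids)
        assert s1.path == s2.path == "/map/uniform/neuronA"
        assert len(s1) == 2

    def test_conflicting_uids_rejected(self, writer):
        writer.add_source_dim_scale("uniform", "pop", ["/a"])
        with pytest.raises(ConflictError):
            writer.add_source_dim_scale("uniform", "pop", ["/b"])

    @pytest.mark.parametrize("uids", [[], ["/a", "/a"]])
    def test_invalid_uids(self, writer, uids):
        with pytest.raises(InvalidArgumentError):
            writer.add_source_dim_scale("uniform", "pop", uids)

    def test_two_variables_share_one_scale(self, tmp_path, metadata):
        path = tmp_path / "f.h5"
        rng = np.random.default_rng(1)
        with NSDFWriter(path, metadata=metadata) as w:
            a = random_uniform_block(rng, variable="Vm")
            b = UniformBlock("pop", "Im", a.sources,
                             rng.normal(size=a.values.shape), unit="nA",
                             dt=a.dt, tstart=a.tstart)
            scale = w.add_source_dim_scale("uniform", "pop", a.sources)
            w.add_uniform(scale, a)
            w.add_uniform(scale, b)
        with h5py.File(path) as f:
            sa = dict(f["data/uniform/pop/Vm"].dims[0].items())["source"]
            sb = dict(f["data/uniform/pop/Im"].dims[0].items())["source"]
            assert sa.name == sb.name


class TestUniform:
    def test_attrs_mode_attributes(self, tmp_path, metadata):
        path = tmp_path / "f.h5"
        block = UniformBlock("pop", "Vm", ["/a", "/b"],
                             np.arange(10.0).reshape(2, 5), unit="mV",
                             tstart=0.5, dt=0.1)
        with NSDFWriter(path, metadata=metadata) as w:
            dspath = w.add_uniform(None, block)
        with h5py.File(path) as f:
            ds = f[dspath]
            assert ds.attrs["tstart"] == 0.5 and ds.attrs["dt"] == 0.1
            assert ds.attrs["unit"] == "mV" and ds.attrs["field"] == "Vm"

    def test_one_by_one_block_roundtrips(self, tmp_path, metadata):
        path = tmp_path / "f.h5"
        block = UniformBlock("p", "v", ["/a"], [[42.0]], unit="mV", dt=1.0)
        with NSDFWriter(path, metadata=metadata) as w:
            w.add_uniform(None, block)
        with open_index(path) as ix:
            assert ix.read_uniform("p", "v") == block

    def test_attrs_and_explicit_modes_read_identically(self, tmp_path,
                                                       metadata):
        rng = np.random.default_rng(2)
        block = random_uniform_block(rng)
        blocks = {}
        for mode in ("attrs", "explicit_ds"):
            path = tmp_path / f"{mode}.h5"
            with NSDFWriter(path, metadata=metadata) as w:
                w.add_uniform(None, block, time_mode=mode)
            with open_index(path) as ix:
                blocks[mode] = ix.read_uniform(block.population,
                                               block.variable)
        a, b = blocks["attrs"], blocks["explicit_ds"]
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(a.times, b.times)

    def test_inconsistent_explicit_times_refused(self, writer):
        block = UniformBlock("p", "v", ["/a"], np.zeros((1, 3)), unit="mV",
                             tstart=0.0, dt=0.1,
                             explicit_times=[0.0, 0.2, 0.4])
        with pytest.raises(InvalidArgumentError):
            writer.add_uniform(None, block, time_mode="explicit_ds")

    def test_scale_length_mismatch(self, writer):
        scale = writer.add_source_dim_scale("uniform", "p", ["/a", "/b"])
        block = UniformBlock("p", "v", ["/a"], np.zeros((1, 3)), unit="mV",
                             dt=0.1)
        with pytest.raises((ShapeError, InvalidArgumentError)):
            writer.add_uniform(scale, block)


class TestAppendUniform:
    def test_many_small_appends_equal_one_shot(self, tmp_path, metadata):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(4, 100))
        sources = [f"/s{i}" for i in range(4)]
        full = UniformBlock("p", "v", sources, values, unit="mV", dt=0.1)
        one, inc = tmp_path / "one.h5", tmp_path / "inc.h5"
        with NSDFWriter(one, metadata=metadata) as w:
            w.add_uniform(None, full)
        with NSDFWriter(inc, metadata=metadata) as w:
            head = UniformBlock("p", "v", sources, values[:, :1], unit="mV",
                                dt=0.1)
            dspath = w.add_uniform(None, head)
            for j in range(1, 100):
                w.append_uniform(dspath, values[:, j:j + 1])
        with open_index(one) as ia, open_index(inc) as ib:
            a, b = ia.read_uniform("p", "v"), ib.read_uniform("p", "v")
        assert a.values.tobytes() == b.values.tobytes()
        assert a == b

    def test_append_zero_columns_is_noop(self, tmp_path, metadata):
        path = tmp_path / "f.h5"
        block = UniformBlock("p", "v", ["/a"], np.zeros((1, 7)), unit="mV",
                             dt=0.1)
        with NSDFWriter(path, metadata=metadata) as w:
            dspath = w.add_uniform(None, block)
            assert w.append_uniform(dspath, np.zeros((1, 0))) == 7

    def test_append_row_mismatch(self, tmp_path, metadata):
        with NSDFWriter(tmp_path / "f.h5", metadata=metadata) as w:
            dspath = w.add_uniform(None, UniformBlock(
                "p", "v", ["/a"], np.zeros((1, 3)), unit="mV", dt=0.1))
            with pytest.raises(ShapeError):
                w.append_uniform(dspath, np.zeros((2, 1)))

    def test_append_explicit_mode_requires_times(self, tmp_path, metadata):
        with NSDFWriter(tmp_path / "f.h5", metadata=metadata) as w:
            dspath = w.add_uniform(
                None, UniformBlock("p", "v", ["/a"], np.zeros((1, 3)),
                                   unit="mV", dt=0.1),
                time_mode="explicit_ds")
            with pytest.raises(InvalidArgumentError):
                w.append_uniform(dspath, np.zeros((1, 2)))
            w.append_uniform(dspath, np.zeros((1, 2)), times=[0.3, 0.4])


class TestEvents:
    def test_nuregular_rejected_for_events(self, writer):
        es = EventSet("p", "spike", [("/a", [0.1])])
        with pytest.raises(VariantError):
            writer.add_events(es, Variant.NUREGULAR)

    @pytest.mark.parametrize("variant", ["ONED", "VLEN", "NANPADDED"])
    def test_zero_event_source_is_legal(self, tmp_path, metadata, variant):
        path = tmp_path / f"{variant}.h5"
        es = EventSet("p", "spike",
                      [("/a", np.array([])), ("/b", [0.5, 0.7])])
        with NSDFWriter(path, metadata=metadata) as w:
            w.add_events(es, variant)
        with open_index(path) as ix:
            back = ix.read_events("p", "spike")
        assert back.entries[0][1].size == 0
        assert back.sources == ["/a", "/b"]

    def test_variant_mixture_within_category_refused(self, writer):
        writer.add_events(EventSet("p", "a", [("/x", [0.1])]), "VLEN")
        with pytest.raises(ConflictError):
            writer.add_events(EventSet("p", "b", [("/x", [0.1])]),
                              "NANPADDED")

    def test_oned_layout_has_map_table_and_source_attrs(self, tmp_path,
                                                        metadata):
        path = tmp_path / "f.h5"
        es = EventSet("p", "spike", [("/m/a", [0.1, 0.2]), ("/m/b", [0.3])])
        with NSDFWriter(path, metadata=metadata) as w:
            gpath = w.add_events(es, "ONED")
        with h5py.File(path) as f:
            grp = f[gpath]
            tbl = f[grp.attrs["source"]]
            assert tbl.dtype.names == ("source", "data")
            for row in tbl[...]:
                ds = f[row["data"].decode()]
                assert ds.attrs["source"].encode() == row["source"] or \
                    ds.attrs["source"] == row["source"].decode()


class TestNonuniform:
    def test_nuregular_requires_shared_times(self, writer):
        series = RaggedSeries("p", "v", [("/a", [1.0], [0.1]),
                                         ("/b", [2.0, 3.0], [0.1, 0.2])],
                              unit="nA")
        with pytest.raises(VariantError):
            writer.add_nonuniform(series, "NUREGULAR")

    def test_nanpadded_times_congruent_with_values(self, tmp_path, metadata):
        path = tmp_path / "f.h5"
        series = RaggedSeries("p", "v",
                              [("/a", [1.0, 2.0, 3.0], [0.1, 0.2, 0.3]),
                               ("/b", [4.0], [0.05])], unit="nA")
        with NSDFWriter(path, metadata=metadata) as w:
            dspath = w.add_nonuniform(series, "NANPADDED")
        with h5py.File(path) as f:
            ds = f[dspath]
            tscale = dict(ds.dims[1].items())["time"]
            assert np.array_equal(np.isnan(ds[...]), np.isnan(tscale[...]))

    def test_single_source_oned(self, tmp_path, metadata):
        path = tmp_path / "f.h5"
        series = RaggedSeries("p", "v", [("/only", [1.0, 2.0], [0.1, 0.4])],
                              unit="nA")
        with NSDFWriter(path, metadata=metadata) as w:
            w.add_nonuniform(series, "ONED")
        with open_index(path) as ix:
            back = ix.read_nonuniform("p", "v")
        assert back == series


class TestStatic:
    def test_compound_synapse_table(self, tmp_path, metadata, fig2_bundle):
        path = tmp_path / "f.h5"
        table = fig2_bundle.static_tables[0]
        with NSDFWriter(path, metadata=metadata) as w:
            dspath = w.add_static(table)
        with h5py.File(path) as f:
            ds = f[dspath]
            assert ds.dtype.names == ("pre", "post", "weight")
            units = [u.decode() if isinstance(u, bytes) else u
                     for u in ds.attrs["unit"]]
            assert units == ["", "", "nS"]

    def test_homogeneous_morphology_layout(self, tmp_path, metadata):
        path = tmp_path / "f.h5"
        labels = ["x0", "y0", "z0", "x1", "y1", "z1"]
        rng = np.random.default_rng(4)
        table = StaticTable(
            "cell", "morphology", [f"/c{i}" for i in range(3)],
            StaticLayout.HOMOGENEOUS_2D,
            [Column(lbl, "um", rng.normal(size=3)) for lbl in labels],
            unit="um")
        with NSDFWriter(path, metadata=metadata) as w:
            w.add_static(table)
        with open_index(path) as ix:
            back = ix.read_static("cell", "morphology")
        assert back.labels == labels
        assert back == table

    def test_unit_count_must_match_fields(self):
        with pytest.raises(InvalidArgumentError):
            StaticTable("p", "t", ["/a"], StaticLayout.COMPOUND,
                        [Column("f", "mV", [[1.0], [2.0]])])


class TestModelDescription:
    def test_modeltree_roundtrip_isomorphic(self, tmp_path, metadata,
                                            fig2_bundle):
        from nsdfkit.reader import read_modeltree
        path = tmp_path / "f.h5"
        with NSDFWriter(path, metadata=metadata) as w:
            w.add_modeltree(fig2_bundle.model_root)
        with open_index(path) as ix:
            back = read_modeltree(ix)
        orig = fig2_bundle.model_root
        assert [c.name for c in back.children] == \
            [c.name for c in orig.children]
        for a, b in zip(orig.children, back.children):
            assert a.isomorphic(b)

    def test_duplicate_uid_rejected(self, writer):
        root = ModelNode("modeltree")
        root.add_child(ModelNode("a", uid="/same"))
        root.add_child(ModelNode("b", uid="/same"))
        with pytest.raises(InvalidArgumentError):
            writer.add_modeltree(root)

    def test_recorded_node_gets_map_attribute(self, tmp_path, metadata):
        path = tmp_path / "f.h5"
        root = ModelNode("modeltree")
        root.add_child(ModelNode("compartment"))
        root.assign_path_uids(prefix=("model",))
        uid = root.children[0].uid
        block = UniformBlock("cells", "Vm", [uid], [[1.0, 2.0]], unit="mV",
                             dt=0.1)
        with NSDFWriter(path, metadata=metadata) as w:
            w.add_uniform(None, block)
            w.add_modeltree(root)
        with h5py.File(path) as f:
            maps = f["model/modeltree/compartment"].attrs["map"]
            assert [m.decode() if isinstance(m, bytes) else m
                    for m in maps] == ["/map/uniform/cells"]

    def test_filecontents_mirror_directories(self, tmp_path, metadata):
        path = tmp_path / "f.h5"
        with NSDFWriter(path, metadata=metadata) as w:
            w.add_filecontents([("network.xml", "<net/>"),
                                ("a/b/c.txt", "hello")])
            with pytest.raises(InvalidArgumentError):
                w.add_filecontents([("/abs/path.txt", "nope")])
        with h5py.File(path) as f:
            assert f["model/filecontents/network.xml"].asstr()[()] == "<net/>"
            assert f["model/filecontents/a/b/c.txt"].asstr()[()] == "hello"

    def test_filerefs_roundtrip(self, tmp_path, metadata):
        path = tmp_path / "f.h5"
        refs = ["/models/x.xml", "/models/y.xml", "http://z"]
        with NSDFWriter(path, metadata=metadata) as w:
            w.add_filerefs(refs)
        with h5py.File(path) as f:
            assert list(f["model/filerefs/files"].asstr()[...]) == refs

    def test_external_links_stored(self, tmp_path, metadata):
        target = tmp_path / "other.h5"
        with h5py.File(target, "w") as f:
            f.create_group("model/modeltree")
        path = tmp_path / "f.h5"
        with NSDFWriter(path, metadata=metadata) as w:
            w.add_links([("other", str(target), "/model/modeltree")])
        with h5py.File(path) as f:
            link = f.get("model/links/other", getlink=True)
            assert isinstance(link, h5py.ExternalLink)


class TestMandatoryUnits:
    def test_every_physical_dataset_has_unit(self, tmp_path, metadata,
                                             fig2_bundle):
        from nsdfkit.fixtures import write_bundle
        path = tmp_path / "f.h5"
        write_bundle(fig2_bundle, path)
        missing = []
        with h5py.File(path) as f:
            def visit(name, node):
                if isinstance(node, h5py.Dataset) and "unit" not in node.attrs:
                    missing.append(name)
            f["data"].visititems(visit)
        assert missing == []
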