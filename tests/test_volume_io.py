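import numpy as np
import pytest
import tifffile
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from niend import (
    SWCMorphology,
    SWCNode,
    Volume3D,
    read_stack,
    read_swc,
    write_stack,
    write_swc,
)


class TestVolume3D:
    def test_rejects_non_3d(self):
        with pytest.raises(ValueError, match="3 axes"):
            Volume3D(np.zeros((4, 4)), dtype_bits=8)

    def test_rejects_out_of_range_values(self):
        with pytest.raises(ValueError, match="8-bit range"):
            Volume3D(np.full((2, 2, 2), 300), dtype_bits=8)

    def test_rejects_nonpositive_voxel_size(self):
        with pytest.raises(ValueError, match="voxel_size"):
            Volume3D(np.zeros((2, 2, 2), np.uint8), dtype_bits=8, voxel_size=(0, 1, 1))

    def test_default_voxel_size_uses_lateral_resolution(self):
        v = Volume3D(np.zeros((2, 2, 2), np.uint16), lateral_res_um=0.3)
        assert v.voxel_size == (1.0, 0.3, 0.3)


class TestTiffRoundTrip:
    @pytest.mark.parametrize("bits,dtype", [(8, np.uint8), (16, np.uint16)])
    def test_round_trip_identity(self, tmp_path, bits, dtype, rng):
        data = rng.integers(0, 2**bits, size=(4, 8, 8)).astype(dtype)
        vol = Volume3D(data, dtype_bits=bits)
        path = tmp_path / "v.tiff"
        write_stack(vol, path)
        back = read_stack(path)
        assert back.dtype_bits == bits
        np.testing.assert_array_equal(back.data, data)

    def test_extreme_values_round_trip(self, tmp_path):
        for fill in (0, 65535):
            vol = Volume3D(np.full((2, 2, 2), fill, np.uint16), dtype_bits=16)
            write_stack(vol, tmp_path / "e.tiff")
            assert np.all(read_stack(tmp_path / "e.tiff").data == fill)

    def test_page_index_maps_to_z(self, tmp_path):
        # unique marker voxel: slice k of the file must come back as data[k]
        data = np.zeros((4, 8, 8), np.uint8)
        data[2, 3, 5] = 7
        write_stack(Volume3D(data, dtype_bits=8), tmp_path / "m.tiff")
        back = read_stack(tmp_path / "m.tiff")
        assert back.data[2, 3, 5] == 7 and back.data.sum() == 7

    def test_float_volume_write_rejected(self, tmp_path):
        vol = Volume3D(np.zeros((2, 2, 2), np.float32), dtype_bits="float")
        with pytest.raises(ValueError, match="convert"):
            write_stack(vol, tmp_path / "f.tiff")

    def test_rgb_tiff_rejected(self, tmp_path):
        tifffile.imwrite(tmp_path / "rgb.tiff", np.zeros((8, 8, 3), np.uint8), photometric="rgb")
        with pytest.raises(ValueError, match="unsupported sample format"):
            read_stack(tmp_path / "rgb.tiff")

    def test_float_tiff_rejected(self, tmp_path):
        tifffile.imwrite(tmp_path / "f32.tiff", np.zeros((2, 8, 8), np.float32))
        with pytest.raises(ValueError, match="unsupported sample format"):
            read_stack(tmp_path / "f32.tiff")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_stack(tmp_path / "nope.tiff")

    @given(
        data=hnp.arrays(
            dtype=np.uint16,
            shape=st.tuples(st.integers(1, 4), st.integers(1, 6), st.integers(1, 6)),
            elements=st.integers(0, 65535),
        )
    )
    def test_round_trip_property(self, data, tmp_path_factory):
        path = tmp_path_factory.mktemp("rt") / "v.tiff"
        write_stack(Volume3D(data, dtype_bits=16), path)
        np.testing.assert_array_equal(read_stack(path).data, data)


TWO_NODE = "1 1 0 0 0 2 -1\n2 3 5 0 0 1 1\n"


class TestSWC:
    def test_two_node_file(self, tmp_path):
        p = tmp_path / "m.swc"
        p.write_text(TWO_NODE)
        m = read_swc(p)
        assert len(m) == 2
        roots = [n for n in m.nodes if n.parent == -1]
        assert len(roots) == 1 and roots[0].radius == 2
        assert m.nodes[1].parent == 1 and m.nodes[1].x == 5

    def test_comments_only_gives_empty(self, tmp_path):
        p = tmp_path / "c.swc"
        p.write_text("# a comment\n\n# another\n")
        assert len(read_swc(p)) == 0

    def test_duplicate_id_reports_line(self, tmp_path):
        p = tmp_path / "d.swc"
        p.write_text("1 1 0 0 0 1 -1\n1 3 1 1 1 1 1\n")
        with pytest.raises(ValueError, match=r":2: duplicate node id 1"):
            read_swc(p)

    def test_missing_parent_rejected(self, tmp_path):
        p = tmp_path / "mp.swc"
        p.write_text("1 1 0 0 0 1 99\n")
        with pytest.raises(ValueError, match="missing parent"):
            read_swc(p)

    def test_round_trip(self, tmp_path, small_phantom):
        _, gold = small_phantom
        p = tmp_path / "g.swc"
        write_swc(gold, p)
        back = read_swc(p)
        assert [n.id for n in back.nodes] == [n.id for n in gold.nodes]
        assert [n.parent for n in back.nodes] == [n.parent for n in gold.nodes]
        np.testing.assert_allclose(back.coordinates(), gold.coordinates(), atol=1e-4)
        np.testing.assert_allclose(
            [n.radius for n in back.nodes], [n.radius for n in gold.nodes], atol=1e-4
        )

    @given(
        coords=st.lists(
            st.tuples(*(st.floats(-100, 100, allow_nan=False) for _ in range(3))),
            min_size=1,
            max_size=20,
        )
    )
    def test_round_trip_property(self, coords, tmp_path_factory):
        nodes = [
            SWCNode(i + 1, 3, *xyz, radius=0.5 + i * 0.25, parent=-1 if i == 0 else i)
            for i, xyz in enumerate(coords)
        ]
        m = SWCMorphology(nodes)
        path = tmp_path_factory.mktemp("swc") / "m.swc"
        write_swc(m, path)
        back = read_swc(path)
        np.testing.assert_allclose(back.coordinates(), m.coordinates(), rtol=1e-5, atol=1e-4)

    def test_morphology_invariants(self):
        with pytest.raises(ValueError, match="duplicate"):
            SWCMorphology([SWCNode(1, 1, 0, 0, 0, 1, -1), SWCNode(1, 3, 1, 1, 1, 1, 1)])
        with pytest.raises(ValueError, match="no root"):
            SWCMorphology([SWCNode(1, 1, 0, 0, 0, 1, 2), SWCNode(2, 3, 1, 1, 1, 1, 1)])
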