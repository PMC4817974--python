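"""Stack I/O, isosurface extraction, projections and line profiles."""

import json

import numpy as np
import pytest
import tifffile
import trimesh

from gutmorph import (
    CellId,
    CellMesh,
    LabelMap,
    LabelStack,
    PrimordiumFrame,
    extract_meshes,
    line_profile,
    orthogonal_projection,
    read_label_stack,
    voxelize,
    write_label_stack,
)
from gutmorph.imaging import ImageStack


@pytest.fixture(scope="module")
def cube_stack():
    frame = PrimordiumFrame(
        0.0, [CellMesh(trimesh.creation.box(extents=(2, 2, 2)), CellId(1, "R"))]
    )
    return voxelize(frame, voxel_xy=0.1, z_step=0.25, n_slices=16)


class TestRoundTrip:
    def test_write_read_lossless(self, cube_stack, tmp_path):
        stack, lmap = cube_stack
        path = write_label_stack(stack, lmap, tmp_path / "cube.tif")
        back, back_map = read_label_stack(path)
        assert np.array_equal(back.data, stack.data)
        assert back.voxel_xy == stack.voxel_xy and back.z_step == stack.z_step
        assert np.allclose(back.origin, stack.origin)
        assert back_map.cells == lmap.cells

    def test_float_pixels_rejected(self, tmp_path):
        path = tmp_path / "float.tif"
        tifffile.imwrite(path, np.zeros((2, 4, 4), dtype=np.float32), photometric="minisblack")
        with pytest.raises(ValueError, match="float"):
            read_label_stack(path)

    def test_missing_sidecar_rejected(self, tmp_path):
        path = tmp_path / "bare.tif"
        tifffile.imwrite(path, np.zeros((2, 4, 4), dtype=np.uint16))
        with pytest.raises(FileNotFoundError, match="sidecar"):
            read_label_stack(path)

    def test_unknown_label_named_in_error(self, cube_stack, tmp_path):
        stack, lmap = cube_stack
        path = write_label_stack(stack, lmap, tmp_path / "cube.tif")
        side = json.loads((tmp_path / "cube.tif.json").read_text())
        side["labels"] = {}
        (tmp_path / "cube.tif.json").write_text(json.dumps(side))
        with pytest.raises(ValueError, match="1"):
            read_label_stack(path)


class TestExtractMeshes:
    def test_cube_volume_recovered(self, cube_stack):
        stack, lmap = cube_stack
        meshes = extract_meshes(stack, lmap)
        assert len(meshes) == 1
        assert meshes[0].volume == pytest.approx(8.0, rel=0.05)
        assert meshes[0].owner == CellId(1, "R")

    def test_disjoint_labels_give_disjoint_meshes(self):
        data = np.zeros((8, 12, 12), dtype=np.uint16)
        data[2:6, 2:5, 2:5] = 1
        data[2:6, 7:10, 7:10] = 2
        stack = LabelStack(data, 0.5, 0.5)
        lmap = LabelMap({1: CellId(1, "R"), 2: CellId(1, "L")})
        meshes = extract_meshes(stack, lmap)
        assert len(meshes) == 2
        b0, b1 = meshes[0].mesh.bounds, meshes[1].mesh.bounds
        assert b0[1][0] < b1[0][0] or b0[1][1] < b1[0][1]

    def test_label_permutation_invariance(self):
        data = np.zeros((6, 10, 10), dtype=np.uint16)
        data[1:5, 1:5, 1:5] = 1
        data[1:5, 6:9, 6:9] = 2
        stack_a = LabelStack(data, 0.4, 0.5)
        map_a = LabelMap({1: CellId(2, "R"), 2: CellId(2, "L")})
        permuted = np.where(data == 1, 2, np.where(data == 2, 1, 0)).astype(np.uint16)
        stack_b = LabelStack(permuted, 0.4, 0.5)
        map_b = LabelMap({2: CellId(2, "R"), 1: CellId(2, "L")})
        by_owner_a = {str(m.owner): m.volume for m in extract_meshes(stack_a, map_a)}
        by_owner_b = {str(m.owner): m.volume for m in extract_meshes(stack_b, map_b)}
        assert by_owner_a == pytest.approx(by_owner_b)

    def test_empty_label_warns_and_skips(self, cube_stack):
        stack, _ = cube_stack
        lmap = LabelMap({1: CellId(1, "R"), 9: CellId(9, "L")})
        with pytest.warns(UserWarning, match="label 9"):
            meshes = extract_meshes(stack, lmap)
        assert len(meshes) == 1

    def test_tube_round_trip_volumes(self, mixed_tube):
        """voxelize -> extract recovers generator volumes within 5%.

        Uses the finer 0.2 um optical step (as in the deconvolved stacks)
        rather than the 0.5 um survey step, whose z-quantization on
        slanted lateral faces is itself a ~5% effect.
        """
        _, _, frame = mixed_tube
        stack, lmap = voxelize(frame, voxel_xy=0.2, z_step=0.2, n_slices=100)
        meshes = extract_meshes(stack, lmap)
        assert len(meshes) == len(frame.cells)
        total_mesh = 0.0
        for cm in meshes:
            truth = frame.meta["volumes"][str(cm.owner)]
            assert cm.volume == pytest.approx(truth, rel=0.05)
            total_mesh += cm.volume
        assert total_mesh <= stack.physical_volume


class TestProjection:
    def test_sphere_projects_to_disc(self):
        sph = trimesh.creation.icosphere(subdivisions=3, radius=2.0)
        frame = PrimordiumFrame(0.0, [CellMesh(sph, CellId(1, "R"))])
        stack, _ = voxelize(frame, voxel_xy=0.1, z_step=0.25, n_slices=20)
        proj = orthogonal_projection(stack, axis="z")
        disc_area = (proj > 0).sum() * 0.1**2
        assert disc_area == pytest.approx(np.pi * 4.0, rel=0.05)

    def test_empty_slab_rejected(self, cube_stack):
        stack, _ = cube_stack
        with pytest.raises(ValueError, match="empty slab"):
            orthogonal_projection(stack, axis="z", slab=(100.0, 101.0))

    def test_mode_projection_majority_label(self):
        data = np.zeros((4, 3, 3), dtype=np.uint16)
        data[0] = 2
        data[1:] = 1
        stack = LabelStack(data, 1.0, 1.0)
        proj = orthogonal_projection(stack, axis="z", method="mode")
        assert (proj == 1).all()

    def test_projection_extents_transpose(self, cube_stack):
        stack, _ = cube_stack
        pz = orthogonal_projection(stack, axis="z")
        py = orthogonal_projection(stack, axis="y")
        px = orthogonal_projection(stack, axis="x")
        nz, ny, nx = stack.shape
        assert pz.shape == (ny, nx)
        assert py.shape == (nz, nx)
        assert px.shape == (nz, ny)


class TestLineProfile:
    @pytest.fixture
    def flat_stack(self):
        return ImageStack(np.full((10, 10, 10), 3.5), 0.5, 0.5)

    def test_background_is_constant(self, flat_stack):
        prof = line_profile(flat_stack, (0.5, 0.5, 0.5), (4.5, 4.5, 4.5), 33)
        assert np.allclose(prof, 3.5)

    def test_reversal_reverses_sequence(self, cube_stack):
        stack, _ = cube_stack
        data = stack.data.astype(float)
        img = ImageStack(data, stack.voxel_xy, stack.z_step, stack.origin)
        lo = stack.origin + 0.3
        hi = stack.origin + np.array([1.8, 1.5, 2.8])
        fwd = line_profile(img, lo, hi, 41)
        rev = line_profile(img, hi, lo, 41)
        assert np.allclose(fwd, rev[::-1])

    def test_endpoints_outside_rejected(self, flat_stack):
        with pytest.raises(ValueError, match="outside"):
            line_profile(flat_stack, (0.5, 0.5, 0.5), (50.0, 0.5, 0.5))
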