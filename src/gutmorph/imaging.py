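"""Label/intensity stack I/O, mesh extraction and display-plane utilities.

Stacks follow the confocal convention: slice-major ZYX arrays, isotropic
xy pixels (``voxel_xy``, um) and a coarser optical step ``z_step`` (um,
0.5 in the reference acquisition of 49 Z-slices).  Label 0 is background.
Physical coordinates are world (x, y, z) um with ``origin`` at the stack
corner; voxel centers sit half a voxel in.  Anisotropy is handled by
scaling mesh vertex coordinates, never by resampling label data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import trimesh
from scipy import ndimage
from skimage import measure

from .geometry import CellId, CellMesh

__all__ = [
    "ImageStack",
    "LabelStack",
    "LabelMap",
    "write_label_stack",
    "read_label_stack",
    "extract_meshes",
    "orthogonal_projection",
    "save_projection_png",
    "line_profile",
]


@dataclass
class ImageStack:
    """A 3D image: ``data`` indexed [z, y, x], voxel sizes in um."""

    data: np.ndarray
    voxel_xy: float
    z_step: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("stack data must be 3D (Z, Y, X)")
        if self.voxel_xy <= 0 or self.z_step <= 0:
            raise ValueError("voxel sizes must be positive")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing_zyx(self) -> tuple[float, float, float]:
        return (self.z_step, self.voxel_xy, self.voxel_xy)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """World (x, y, z) um -> fractional (z, y, x) indices."""
        p = np.atleast_2d(np.asarray(points, dtype=float)) - self.origin
        return np.column_stack(
            [
                p[:, 2] / self.z_step - 0.5,
                p[:, 1] / self.voxel_xy - 0.5,
                p[:, 0] / self.voxel_xy - 0.5,
            ]
        )

    @property
    def physical_volume(self) -> float:
        nz, ny, nx = self.data.shape
        return nz * self.z_step * ny * nx * self.voxel_xy**2


@dataclass
class LabelStack(ImageStack):
    """Integer label stack; label 0 is background."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError(
                f"label stacks must have an integer pixel type, got {self.data.dtype}"
            )

    def labels(self) -> np.ndarray:
        u = np.unique(self.data)
        return u[u != 0]


@dataclass
class LabelMap:
    """Mapping label -> cell identity (and optional display color)."""

    cells: dict[int, CellId]
    colors: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.cells.values())) != len(self.cells):
            raise ValueError("duplicate CellId in label map")

    def label_of(self, cid: CellId) -> int:
        for k, v in self.cells.items():
            if v == cid:
                return k
        raise KeyError(str(cid))

    def to_json_dict(self) -> dict:
        return {
            str(k): {"ring": v.ring, "side": v.side, "color": self.colors.get(k)}
            for k, v in self.cells.items()
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "LabelMap":
        cells = {int(k): CellId(v["ring"], v["side"]) for k, v in d.items()}
        colors = {int(k): v["color"] for k, v in d.items() if v.get("color")}
        return cls(cells, colors)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_label_stack(stack: LabelStack, label_map: LabelMap, path: str | Path) -> Path:
    """Write a multi-page uint16 TIFF (ZYX) plus its JSON sidecar."""
    path = Path(path)
    if stack.data.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("labels exceed uint16 range")
    tifffile.imwrite(path, stack.data.astype(np.uint16))
    sidecar = {
        "axis_order": "ZYX",
        "voxel_xy_um": stack.voxel_xy,
        "z_step_um": stack.z_step,
        "origin_um_xyz": list(map(float, stack.origin)),
        "labels": label_map.to_json_dict(),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_label_stack(path: str | Path) -> tuple[LabelStack, LabelMap]:
    """Read a label stack and its sidecar; validates labels and pixel type."""
    path = Path(path)
    data = tifffile.imread(path)
    if np.issubdtype(data.dtype, np.floating):
        raise ValueError(
            f"{path} has float pixels; label stacks must be integer typed"
        )
    side = _sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(
            f"missing sidecar {side}: write one with write_label_stack, or "
            "provide a JSON mapping each label to its ring index and side"
        )
    meta = json.loads(side.read_text())
    label_map = LabelMap.from_json_dict(meta["labels"])
    stack = LabelStack(
        data=np.asarray(data),
        voxel_xy=float(meta["voxel_xy_um"]),
        z_step=float(meta["z_step_um"]),
        origin=np.asarray(meta.get("origin_um_xyz", (0.0, 0.0, 0.0))),
    )
    unknown = [int(l) for l in stack.labels() if int(l) not in label_map.cells]
    if unknown:
        raise ValueError(f"stack labels missing from sidecar: {unknown}")
    return stack, label_map


def extract_meshes(stack: LabelStack, label_map: LabelMap) -> list[CellMesh]:
    """One closed triangle mesh per label by isosurface extraction.

    Each label's binary mask is padded by one background voxel (so the
    0.5-level surface always closes), marched with anisotropic spacing and
    shifted into world coordinates.  Empty labels are skipped with a
    warning; a non-closed surface is an error.
    """
    present = set(int(l) for l in stack.labels())
    if not present:
        raise ValueError("no non-zero labels in stack")
    out: list[CellMesh] = []
    for label, cid in sorted(label_map.cells.items()):
        if label not in present:
            warnings.warn(f"label {label} ({cid}) has no voxels; skipped")
            continue
        mask = np.pad(stack.data == label, 1)
        verts, faces, _, _ = measure.marching_cubes(
            mask.astype(np.uint8), level=0.5, spacing=stack.spacing_zyx
        )
        # marching_cubes returns (z, y, x); shift for padding, go to world xyz
        verts -= np.array(stack.spacing_zyx)
        world = np.column_stack([verts[:, 2], verts[:, 1], verts[:, 0]])
        world += stack.origin + 0.5 * np.array(
            [stack.voxel_xy, stack.voxel_xy, stack.z_step]
        )
        mesh = trimesh.Trimesh(world, faces, process=True)
        if not mesh.is_watertight:
            trimesh.repair.fill_holes(mesh)
        if not mesh.is_watertight:
            raise ValueError(f"isosurface of label {label} ({cid}) is not closed")
        if mesh.volume < 0:
            mesh.invert()
        out.append(CellMesh(mesh, cid))
    return out


_AXIS_INDEX = {"z": 0, "y": 1, "x": 2}


def orthogonal_projection(
    stack: ImageStack,
    axis: str = "z",
    slab: tuple[float, float] | None = None,
    method: str = "max",
) -> np.ndarray:
    """Project a slab of the stack transverse to ``axis``.

    ``slab`` is a (lo, hi) world-coordinate interval (um) along the chosen
    axis; ``method`` is ``max`` (maximum intensity) or ``mode`` (most
    frequent non-zero label, for label stacks).  Voxel anisotropy is a
    property of the returned plane (z-spacing differs from xy), reported
    by the caller's metadata, not resampled away.
    """
    ai = _AXIS_INDEX[axis]
    n = stack.shape[ai]
    step = stack.z_step if axis == "z" else stack.voxel_xy
    o = stack.origin[2 - ai]  # origin is (x, y, z); data axis 0 is z
    if slab is None:
        i0, i1 = 0, n
    else:
        lo, hi = slab
        i0 = int(np.floor((lo - o) / step))
        i1 = int(np.ceil((hi - o) / step))
        i0, i1 = max(i0, 0), min(i1, n)
    if i1 <= i0:
        raise ValueError(f"empty slab along {axis}: indices [{i0}, {i1})")
    sl = [slice(None)] * 3
    sl[ai] = slice(i0, i1)
    sub = stack.data[tuple(sl)]
    if method == "max":
        return sub.max(axis=ai)
    if method == "mode":
        # most frequent non-zero label per projected pixel
        moved = np.moveaxis(sub, ai, 0).astype(np.int64)
        depth = moved.shape[0]
        flat = moved.reshape(depth, -1)
        nl = int(flat.max()) + 1
        out = np.zeros(flat.shape[1], dtype=stack.data.dtype)
        counts = np.zeros((nl + 1, flat.shape[1]), dtype=np.int32)
        for k in range(depth):
            counts[flat[k], np.arange(flat.shape[1])] += 1
        counts[0] = 0  # background never wins
        best = counts.argmax(axis=0)
        hit = counts[best, np.arange(flat.shape[1])] > 0
        out[hit] = best[hit]
        return out.reshape(moved.shape[1:])
    raise ValueError(f"unknown projection method {method!r}")


def save_projection_png(
    image: np.ndarray, path: str | Path, cmap: str = "gray"
) -> Path:
    """Write a 2D projection to PNG (labels get a categorical colormap)."""
    import matplotlib

    matplotlib.use("Agg")
    from matplotlib import image as mpimg

    img = np.asarray(image)
    if np.issubdtype(img.dtype, np.integer) and cmap == "gray":
        cmap = "tab20"
    path = Path(path)
    mpimg.imsave(path, img, cmap=cmap)
    return path


def line_profile(
    stack: ImageStack,
    p0,
    p1,
    n_samples: int = 100,
) -> np.ndarray:
    """Linearly interpolated intensities along a world-coordinate segment.

    ``p0``/``p1`` are (x, y, z) um and must lie inside the stack.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    idx = stack.world_to_index(np.vstack([p0, p1]))
    hi = np.array(stack.shape, dtype=float) - 0.5
    if np.any(idx < -0.5) or np.any(idx > hi):
        raise ValueError("line endpoints fall outside the stack")
    t = np.linspace(0.0, 1.0, n_samples)
    coords = idx[0][:, None] * (1 - t) + idx[1][:, None] * t
    return ndimage.map_coordinates(
        stack.data.astype(float), coords, order=1, mode="nearest"
    )
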