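"""Cell identity, tube coordinates and basic mesh measures.

The intestinal primordium is modelled as a tube of cells around an
anterior->posterior axis.  All physical quantities are in micrometres (um)
and developmental time is in minutes.

Angular convention
------------------
Circumferential position ``theta`` is measured in degrees from the dorsal
midline, in the range ``(-180, 180]``, and is **positive clockwise as seen
from the anterior end of the tube** (camera anterior of the embryo, looking
posteriorly, dorsal up).  In that view the animal's right side appears on
the screen's left, so right-side (R) cells occupy ``theta in (-180, 0)``
and left-side (L) cells occupy ``(0, 180)``; ``theta = +-180`` is the
ventral midline.  With this convention the wild-type rotation of the
int2-int4 rings is a positive (clockwise) angular motion that carries the
R cells across the dorsal midline, exactly as the rotation and event
detectors in :mod:`gutmorph.rotation` expect.  Mirrored conventions are a
classic source of sign bugs; every angle produced by this package follows
the definition above.

In the default embryo frame the axis runs along +x (anterior at small x),
the dorsal direction is +z and the animal's right side is +y.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import trimesh

__all__ = [
    "SIDES",
    "RING1_SIDES",
    "CellId",
    "CellMesh",
    "TubeAxis",
    "CylCoord",
    "PrimordiumFrame",
    "fit_axis",
    "to_cylindrical",
    "cylindrical_to_point",
    "mesh_volume",
    "mesh_area",
    "mirror_frame",
    "perturb_frame",
]

#: two-cell ring sides and the four int1 daughters after its dorsal-ventral
#: division (1R -> 1RD + 1RV, 1L -> 1LD + 1LV).
SIDES = ("R", "L")
RING1_SIDES = ("RD", "RV", "LD", "LV")


@dataclass(frozen=True, order=True)
class CellId:
    """Identity of one intestinal cell: int ring number and body side.

    Rings are numbered 1 (anterior, the only ring that may hold four
    cells) through 9 (posterior), exactly as in the int-ring nomenclature.
    """

    ring: int
    side: str

    def __post_init__(self) -> None:
        if self.ring < 1:
            raise ValueError(f"ring index must be >= 1, got {self.ring}")
        if self.side in RING1_SIDES:
            if self.ring != 1:
                raise ValueError(
                    f"side {self.side!r} denotes an int1 daughter and is only "
                    f"valid for ring 1, got ring {self.ring}"
                )
        elif self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}")

    @property
    def hand(self) -> str:
        """'R' or 'L' regardless of a ring-1 dorsal/ventral suffix."""
        return self.side[0]

    def __str__(self) -> str:  # e.g. "4R", "1LD"
        return f"{self.ring}{self.side}"

    @classmethod
    def parse(cls, text: str) -> "CellId":
        text = text.strip()
        i = 0
        while i < len(text) and text[i].isdigit():
            i += 1
        if i == 0 or i == len(text):
            raise ValueError(f"cannot parse cell id {text!r}")
        return cls(int(text[:i]), text[i:].upper())


@dataclass
class CellMesh:
    """A closed triangle mesh (um, embryo coordinates) owned by one cell."""

    mesh: trimesh.Trimesh
    owner: CellId

    @property
    def vertices(self) -> np.ndarray:
        return self.mesh.vertices

    @property
    def triangles(self) -> np.ndarray:
        return self.mesh.faces

    @property
    def volume(self) -> float:
        return float(abs(self.mesh.volume))

    @property
    def area(self) -> float:
        return float(self.mesh.area)

    def copy(self) -> "CellMesh":
        return CellMesh(self.mesh.copy(), self.owner)


@dataclass
class TubeAxis:
    """Centerline of the tube plus the reference direction for theta = 0.

    ``centerline`` is an ordered (n, 3) array anterior -> posterior;
    ``dorsal_ref`` is a unit vector defining the dorsal midline and
    ``circumference`` the tube circumference in um (about 47 um for the
    E16-E20 primordium).
    """

    centerline: np.ndarray
    dorsal_ref: np.ndarray
    circumference: float = 47.0

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[0] < 2:
            raise ValueError("centerline needs at least 2 points")
        if self.circumference <= 0:
            raise ValueError("circumference must be positive")
        d = np.asarray(self.dorsal_ref, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("dorsal_ref must be a nonzero vector")
        self.dorsal_ref = d / n

    @property
    def radius(self) -> float:
        return self.circumference / (2.0 * np.pi)

    def segment_frames(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-segment (tangent, dorsal, lateral) orthonormal frames.

        The lateral axis is ``dorsal x tangent`` so that positive theta is
        clockwise viewed from the anterior (see module docstring).
        """
        seg = np.diff(self.centerline, axis=0)
        t = seg / np.linalg.norm(seg, axis=1, keepdims=True)
        d = self.dorsal_ref - (t * (t @ self.dorsal_ref)[:, None])
        norms = np.linalg.norm(d, axis=1)
        if np.any(norms < 1e-9):
            raise ValueError("dorsal_ref is parallel to the tube axis")
        d = d / norms[:, None]
        lat = np.cross(d, t)
        return t, d, lat


@dataclass(frozen=True)
class CylCoord:
    """Tube coordinates: theta (deg from dorsal midline, clockwise-positive
    from the anterior view, range (-180, 180]), z (arclength along the
    centerline, um) and r (radial distance, um)."""

    theta: float
    z: float
    r: float


@dataclass
class PrimordiumFrame:
    """All cell meshes plus the tube axis at one timepoint (minutes)."""

    time: float
    cells: list[CellMesh] = field(default_factory=list)
    axis: TubeAxis | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.time):
            raise ValueError("frame time must be finite")
        ids = [c.owner for c in self.cells]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate CellId in frame")

    def cell(self, cid: CellId | str) -> CellMesh:
        if isinstance(cid, str):
            cid = CellId.parse(cid)
        for c in self.cells:
            if c.owner == cid:
                return c
        raise KeyError(f"no cell {cid} in frame at t={self.time}")

    def ring(self, ring: int) -> list[CellMesh]:
        return [c for c in self.cells if c.owner.ring == ring]

    @property
    def rings(self) -> list[int]:
        return sorted({c.owner.ring for c in self.cells})

    def copy(self) -> "PrimordiumFrame":
        return PrimordiumFrame(
            self.time,
            [c.copy() for c in self.cells],
            dataclasses.replace(self.axis) if self.axis is not None else None,
            dict(self.meta),
        )


# ---------------------------------------------------------------------------
# axis fitting and coordinates

def fit_axis(
    frame: PrimordiumFrame,
    dorsal_hint: Sequence[float] = (0.0, 0.0, 1.0),
    circumference: float | None = None,
    smooth_window: int = 3,
) -> TubeAxis:
    """Fit a smooth centerline through per-ring centroid means.

    Requires at least 4 cells spanning at least 2 rings.  The centerline is
    the sequence of ring centroids (anterior -> posterior) smoothed with a
    moving average; ``dorsal_hint`` fixes the theta = 0 direction after
    projection orthogonal to the local tangent.
    """
    rings = frame.rings
    if len(frame.cells) < 4 or len(rings) < 2:
        raise ValueError(
            f"axis fit needs >= 4 cells spanning >= 2 rings, got "
            f"{len(frame.cells)} cells in {len(rings)} ring(s)"
        )
    cents = []
    for r in rings:
        pts = np.concatenate([c.mesh.vertices for c in frame.ring(r)], axis=0)
        cents.append(pts.mean(axis=0))
    cents = np.asarray(cents)
    if smooth_window > 1 and len(cents) > 2:
        k = min(smooth_window, len(cents))
        kernel = np.ones(k) / k
        sm = np.column_stack(
            [np.convolve(cents[:, i], kernel, mode="valid") for i in range(3)]
        )
        # keep the end points so the axis spans the whole tube
        cents = np.vstack([cents[0], sm, cents[-1]]) if len(sm) else cents
    # drop consecutive duplicates
    keep = np.ones(len(cents), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(cents, axis=0), axis=1) > 1e-9
    cents = cents[keep]
    if len(cents) < 2:
        raise ValueError("degenerate centerline (all ring centroids coincide)")
    hint = np.asarray(dorsal_hint, dtype=float)
    tang = cents[-1] - cents[0]
    tang = tang / np.linalg.norm(tang)
    if np.linalg.norm(hint - tang * (hint @ tang)) < 1e-9:
        raise ValueError("dorsal hint is collinear with the tube axis")
    if circumference is None:
        circumference = frame.axis.circumference if frame.axis is not None else 47.0
    return TubeAxis(cents, hint, circumference)


def _locate_on_axis(points: np.ndarray, axis: TubeAxis):
    """For each point: nearest segment index, arclength, and radial vector."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    c = axis.centerline
    seg = np.diff(c, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    # project on every segment, pick the closest
    ap = pts[:, None, :] - c[None, :-1, :]
    tpar = np.einsum("pse,se->ps", ap, seg) / (seg_len**2)
    tpar = np.clip(tpar, 0.0, 1.0)
    foot = c[None, :-1, :] + tpar[:, :, None] * seg[None, :, :]
    d2 = np.sum((pts[:, None, :] - foot) ** 2, axis=2)
    si = np.argmin(d2, axis=1)
    rows = np.arange(len(pts))
    z = cum[si] + tpar[rows, si] * seg_len[si]
    radial = pts - foot[rows, si]
    return si, z, radial


def to_cylindrical(point: Sequence[float] | np.ndarray, axis: TubeAxis):
    """Convert embryo-frame point(s) to tube coordinates.

    Returns a :class:`CylCoord` for a single point or a structured
    ``(theta, z, r)`` tuple of arrays for an (n, 3) input.  Points on the
    centerline have undefined theta and raise ``ValueError``.
    """
    pts = np.asarray(point, dtype=float)
    single = pts.ndim == 1
    si, z, radial = _locate_on_axis(pts, axis)
    t, d, lat = axis.segment_frames()
    dn = d[si]
    ln = lat[si]
    zc = np.einsum("pe,pe->p", radial, dn)
    yc = np.einsum("pe,pe->p", radial, ln)
    r = np.sqrt(zc**2 + yc**2)
    if np.any(r < 1e-12):
        raise ValueError("theta undefined for point(s) on the centerline")
    # positive theta is clockwise from the anterior view: from dorsal (+d)
    # toward -lateral, where lateral = dorsal x tangent points to the right.
    theta = np.degrees(np.arctan2(-yc, zc))
    theta = np.where(theta <= -180.0, theta + 360.0, theta)
    if single:
        return CylCoord(float(theta[0]), float(z[0]), float(r[0]))
    return theta, z, r


def cylindrical_to_point(coord: CylCoord, axis: TubeAxis) -> np.ndarray:
    """Inverse of :func:`to_cylindrical` (single point)."""
    c = axis.centerline
    seg = np.diff(c, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    si = int(np.clip(np.searchsorted(cum, coord.z, side="right") - 1, 0, len(seg) - 1))
    frac = (coord.z - cum[si]) / seg_len[si]
    base = c[si] + frac * seg[si]
    t, d, lat = axis.segment_frames()
    th = np.radians(coord.theta)
    return base + coord.r * (np.cos(th) * d[si] - np.sin(th) * lat[si])


# ---------------------------------------------------------------------------
# mesh measures

def _require_closed(mesh: trimesh.Trimesh, what: str) -> None:
    if not mesh.is_watertight:
        raise ValueError(f"{what} requires a closed (watertight) mesh")


def mesh_volume(cell: CellMesh | trimesh.Trimesh) -> float:
    """Enclosed volume in um^3 via the divergence theorem (absolute value)."""
    mesh = cell.mesh if isinstance(cell, CellMesh) else cell
    _require_closed(mesh, "mesh_volume")
    return float(abs(mesh.volume))


def mesh_area(cell: CellMesh | trimesh.Trimesh) -> float:
    """Total surface area in um^2 (sum of triangle areas)."""
    mesh = cell.mesh if isinstance(cell, CellMesh) else cell
    return float(mesh.area)


# ---------------------------------------------------------------------------
# frame transforms used by tests and detectors

_MIRROR_SIDE = {"R": "L", "L": "R", "RD": "LD", "LD": "RD", "RV": "LV", "LV": "RV"}


def mirror_frame(frame: PrimordiumFrame) -> PrimordiumFrame:
    """Reflect a frame left-right (sagittal mirror) and relabel sides.

    The reflection flips the y coordinate (right <-> left) and swaps every
    cell's side label so that sides stay literal; every RaL relation in the
    original becomes LaR in the mirror and vice versa.
    """
    out = frame.copy()
    for c in out.cells:
        v = c.mesh.vertices.copy()
        v[:, 1] *= -1.0
        m = trimesh.Trimesh(v, c.mesh.faces[:, ::-1], process=False)
        c.mesh = m
        c.owner = CellId(c.owner.ring, _MIRROR_SIDE[c.owner.side])
    if out.axis is not None:
        cl = out.axis.centerline.copy()
        cl[:, 1] *= -1.0
        dr = out.axis.dorsal_ref.copy()
        dr[1] *= -1.0
        out.axis = TubeAxis(cl, dr, out.axis.circumference)
    return out


def perturb_frame(frame: PrimordiumFrame, amplitude: float, seed: int) -> PrimordiumFrame:
    """Jitter every mesh vertex with isotropic Gaussian noise (um).

    Vertex positions are displaced independently; shared vertices within a
    mesh move coherently so each mesh stays closed.  Used to emulate
    tracing/surface noise when testing measurement robustness.
    """
    if amplitude < 0:
        raise ValueError("jitter amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    out = frame.copy()
    for c in out.cells:
        noise = rng.normal(0.0, amplitude, size=c.mesh.vertices.shape)
        c.mesh = trimesh.Trimesh(c.mesh.vertices + noise, c.mesh.faces, process=False)
    return out
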