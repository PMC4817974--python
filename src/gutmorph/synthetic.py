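"""Synthetic intestinal-primordium generator with known ground truth.

The primordium is idealized as a cylindrical shell of circumference ~47 um
(the measured E16-E20 circumference) tiled by 9 anterior->posterior rings
of cells, two per ring (one R, one L) except the anterior int1 ring which
holds four after its dorsal-ventral division.  Cells are curved prisms:
trapezoids in the unrolled (theta, x) plane extruded radially, so each
ring boundary carries two three-cell junctions, one near the dorsal
midline (theta ~ 0) and one near the ventral midline (theta ~ 180).

Diagonal packing is encoded at those junctions.  Offsetting the R/L
boundary of the posterior ring clockwise past the anterior ring's boundary
at the dorsal junction (and counterclockwise at the ventral junction)
widens the R cell until it touches the anterior L cell: an RaL contact.
The mirrored offsets give LaR, and zero offset leaves all four cells
meeting at a common vertex (Cross).  Sampling the two junctions of every
interface independently reproduces the full set of observed pair
categories (RaL+RaL, RaL+LaR, RaL+C, ...), including the hexagonal
wild-type pattern where an R cell touches two distinct faces of the
anterior L cell.

Morphogenesis is kinematic: scheduled events rigidly rotate rings or
single cells about the tube axis (ring rotation, the pre-rotation shift of
2L, the two int2 intercalation/closure modes), exchange the int5 cells
along the axis, or convert junction configurations over time (the global
LaR -> RaL transition).  No mechanics is simulated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import trimesh

from ._meshdist import fill_volume, subdivide_mesh
from .geometry import CellId, CellMesh, PrimordiumFrame, TubeAxis
from .imaging import ImageStack, LabelMap, LabelStack

__all__ = [
    "PackingSpec",
    "NoiseModel",
    "MorphogenesisSchedule",
    "RingRotation",
    "PreRotationShift",
    "Int2Intercalation",
    "Int5Exchange",
    "JunctionConversion",
    "sample_diagonal_configs",
    "generate_tube",
    "generate_e8_plate",
    "generate_trajectory",
    "trajectory_ground_truth",
    "wt_reference_schedule",
    "wt_reference_trajectory",
    "hatching_configs",
    "voxelize",
    "render_membranes",
]

Call = Literal["RaL", "LaR", "Cross"]
_CALLS = ("RaL", "LaR", "Cross")


# ---------------------------------------------------------------------------
# specifications


@dataclass(frozen=True)
class PackingSpec:
    """Geometry and packing statistics of the generated tube.

    Dimensions are in um.  The paper fixes only the ~47 um circumference;
    ring height and radial thickness are free parameters chosen so that 20
    cells make a plausible E16-E20 shell (see docs/methods.md).  ``p_RaL``
    / ``p_LaR`` / ``p_Cross`` are the per-junction probabilities of each
    diagonal configuration, either scalars or mappings keyed by the
    posterior ring index of the interface.
    """

    n_rings: int = 9
    cells_per_ring: Mapping[int, int] | None = None
    circumference: float = 47.0
    ring_height: float = 2.5
    radial_thickness: float = 3.0
    p_RaL: float | Mapping[int, float] = 0.8
    p_LaR: float | Mapping[int, float] = 0.1
    p_Cross: float | Mapping[int, float] = 0.1
    diagonal_offset_deg: float = 15.0
    seed: int = 0
    # mesh resolution
    max_edge_deg: float = 4.0
    max_edge_ax: float = 1.0
    n_radial: int = 2

    def __post_init__(self) -> None:
        if self.n_rings < 2:
            raise ValueError("n_rings must be >= 2")
        if self.circumference <= 0 or self.ring_height <= 0:
            raise ValueError("circumference and ring_height must be positive")
        if not 0 < self.radial_thickness < self.radius:
            raise ValueError("radial_thickness must be in (0, tube radius)")
        for n in range(2, self.n_rings + 1):
            p = self.probabilities(n)
            if abs(sum(p) - 1.0) > 1e-9 or min(p) < 0:
                raise ValueError(
                    f"p_RaL + p_LaR + p_Cross must be 1 with non-negative "
                    f"terms (interface {n}: {p})"
                )
        for ring, cnt in self.ring_counts.items():
            if cnt > 4:
                raise ValueError(
                    f"infeasible packing: ring {ring} asks for {cnt} cells; "
                    "a ring holds 2 cells (R, L), or 4 for int1 after its "
                    "dorsal-ventral division"
                )
            if cnt == 4 and ring != 1:
                raise ValueError(
                    f"infeasible packing: only ring 1 may hold 4 cells, "
                    f"ring {ring} asks for {cnt}"
                )
            if cnt != 2 and cnt != 4:
                raise ValueError(
                    f"infeasible packing: ring {ring} asks for {cnt} cells"
                )

    @property
    def radius(self) -> float:
        return self.circumference / (2.0 * np.pi)

    @property
    def ring_counts(self) -> dict[int, int]:
        counts = {r: 2 for r in range(1, self.n_rings + 1)}
        if self.cells_per_ring:
            counts.update({int(k): int(v) for k, v in self.cells_per_ring.items()})
        return counts

    @property
    def n_cells(self) -> int:
        return sum(self.ring_counts.values())

    def probabilities(self, interface: int) -> tuple[float, float, float]:
        """(p_RaL, p_LaR, p_Cross) for the interface whose posterior ring
        index is ``interface``."""

        def pick(p):
            return float(p[interface]) if isinstance(p, Mapping) else float(p)

        return pick(self.p_RaL), pick(self.p_LaR), pick(self.p_Cross)


@dataclass(frozen=True)
class NoiseModel:
    """Membrane-render imaging model.

    surface_jitter : um, Gaussian displacement of surface elements
        (emulates tracing/surface noise).
    membrane_intensity : signal per um^2 of membrane per um^3 of voxel;
        two adjoining membranes add, doubling the signal at cell-cell
        interfaces.
    background : additive constant.
    psf_sigma : um, optional isotropic Gaussian blur.
    """

    surface_jitter: float = 0.0
    membrane_intensity: float = 1.0
    background: float = 0.0
    psf_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.surface_jitter, self.membrane_intensity, self.background) < 0:
            raise ValueError("noise amplitudes must be >= 0")
        if self.psf_sigma < 0:
            raise ValueError("psf_sigma must be >= 0")


# ---------------------------------------------------------------------------
# schedule events


def _check_window(t0: float, t1: float) -> None:
    if not (np.isfinite(t0) and np.isfinite(t1) and t0 < t1):
        raise ValueError(f"event needs onset < end, got [{t0}, {t1}]")


@dataclass(frozen=True)
class RingRotation:
    """Rigid rotation of one ring about the tube axis (cw seen from the
    anterior is the wild-type direction for rings 2-4)."""

    ring: int
    t0: float
    t1: float
    angle_deg: float
    direction: Literal["cw", "ccw"] = "cw"

    def __post_init__(self) -> None:
        _check_window(self.t0, self.t1)
        if not np.isfinite(self.angle_deg):
            raise ValueError("rotation angle must be finite")

    @property
    def signed_angle(self) -> float:
        return self.angle_deg if self.direction == "cw" else -self.angle_deg


@dataclass(frozen=True)
class PreRotationShift:
    """Early clockwise shift of the int2 ring that carries 2L across the
    ventral midline (observed from ~289 min, well before ring rotation)."""

    t0: float = 289.0
    t1: float = 305.0
    angle_deg: float = 12.0

    def __post_init__(self) -> None:
        _check_window(self.t0, self.t1)


@dataclass(frozen=True)
class Int2Intercalation:
    """Closure of the int2 ring at the dorsal midline.

    Mode 1: both cells reach the dorsal midline together.  Mode 2: 2L
    stalls ``stall_deg`` short and 2R closes the ring by rotating
    clockwise past the dorsal midline to meet it.  ``gap_deg`` is the
    initial dorsal opening on each side of the midline.
    """

    t0: float = 329.0
    t1: float = 353.0
    mode: int = 1
    gap_deg: float = 25.0
    stall_deg: float = 10.0

    def __post_init__(self) -> None:
        _check_window(self.t0, self.t1)
        if self.mode not in (1, 2):
            raise ValueError("int2 intercalation mode must be 1 or 2")
        if not 0 < self.stall_deg < self.gap_deg:
            raise ValueError("need 0 < stall_deg < gap_deg")


@dataclass(frozen=True)
class Int5Exchange:
    """Anterior-posterior exchange of 5R/5L without angular rotation.

    The shift is a stylized marker of the int5 intercalation (the cells
    realign along the axis without circumferential motion); it is kept
    below the 0.5 um contact threshold so rigid translation does not
    artificially break the transverse contacts with the flanking rings.
    """

    t0: float = 273.0
    t1: float = 297.0
    shift_um: float = 0.3

    def __post_init__(self) -> None:
        _check_window(self.t0, self.t1)


@dataclass(frozen=True)
class JunctionConversion:
    """Continuous change of one junction's diagonal configuration
    (e.g. the global LaR -> RaL conversion after the E8 stage)."""

    interface: int
    junction: Literal["dorsal", "ventral", "both"]
    target: Call
    t0: float = 265.0
    t1: float = 305.0

    def __post_init__(self) -> None:
        _check_window(self.t0, self.t1)
        if self.target not in _CALLS:
            raise ValueError(f"unknown target configuration {self.target!r}")


Event = RingRotation | PreRotationShift | Int2Intercalation | Int5Exchange | JunctionConversion


@dataclass(frozen=True)
class MorphogenesisSchedule:
    """A list of kinematic events; contradictory overlaps are rejected."""

    events: tuple[Event, ...] = ()

    def __post_init__(self) -> None:
        rots: dict[int, list[RingRotation]] = {}
        for e in self.events:
            if isinstance(e, RingRotation):
                rots.setdefault(e.ring, []).append(e)
        for ring, evs in rots.items():
            evs = sorted(evs, key=lambda e: e.t0)
            for a, b in zip(evs, evs[1:]):
                if b.t0 < a.t1:
                    raise ValueError(
                        f"overlapping rotation events for ring {ring}: "
                        f"[{a.t0},{a.t1}] and [{b.t0},{b.t1}]"
                    )
        # all events that rotate the int2 cells must be disjoint in time,
        # and the intercalation closure targets assume any pre-rotation
        # shift has completed first
        ring2 = sorted(
            (
                e
                for e in self.events
                if isinstance(e, (PreRotationShift, Int2Intercalation))
                or (isinstance(e, RingRotation) and e.ring == 2)
            ),
            key=lambda e: e.t0,
        )
        for a, b in zip(ring2, ring2[1:]):
            if b.t0 < a.t1:
                raise ValueError(
                    "contradictory overlapping events for the int2 cells: "
                    f"{a} and {b}"
                )
        for a, b in zip(ring2, ring2[1:]):
            if isinstance(b, PreRotationShift) and isinstance(
                a, (Int2Intercalation, RingRotation)
            ):
                raise ValueError(
                    "the pre-rotation shift must precede int2 closure/rotation"
                )
        convs: dict[tuple[int, str], list[JunctionConversion]] = {}
        for e in self.events:
            if isinstance(e, JunctionConversion):
                juncs = ("dorsal", "ventral") if e.junction == "both" else (e.junction,)
                for j in juncs:
                    convs.setdefault((e.interface, j), []).append(e)
        for key, evs in convs.items():
            evs = sorted(evs, key=lambda e: e.t0)
            for a, b in zip(evs, evs[1:]):
                if b.t0 < a.t1:
                    raise ValueError(f"overlapping conversions at junction {key}")

    def of_type(self, cls) -> list:
        return [e for e in self.events if isinstance(e, cls)]

    @property
    def span(self) -> tuple[float, float]:
        if not self.events:
            return (0.0, 0.0)
        return (min(e.t0 for e in self.events), max(e.t1 for e in self.events))


# ---------------------------------------------------------------------------
# packing configurations


def sample_diagonal_configs(
    spec: PackingSpec, rng: np.random.Generator | None = None
) -> list[dict]:
    """Sample the dorsal and ventral junction configuration of every
    interface; this is the generator's ground truth."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    out = []
    for n in range(2, spec.n_rings + 1):
        p = spec.probabilities(n)
        dorsal, ventral = rng.choice(_CALLS, size=2, p=p)
        out.append({"interface": n, "dorsal": str(dorsal), "ventral": str(ventral)})
    return out


def hatching_configs(spec: PackingSpec) -> list[dict]:
    """The deterministic packing observed at hatching: RaL+RaL in the
    posterior rings, and the invariant equal RaL/LaR pair between int2 and
    the 4-cell int1 ring (2R-1LD is RaL, 2L-1RV is LaR)."""
    out = []
    for n in range(2, spec.n_rings + 1):
        if n == 2:
            out.append({"interface": 2, "dorsal": "RaL", "ventral": "LaR"})
        else:
            out.append({"interface": n, "dorsal": "RaL", "ventral": "RaL"})
    return out


def _junction_offsets(configs: Sequence[dict], s: float) -> dict:
    """Per-interface boundary offsets implied by the junction calls.

    Returns {interface: {'dorsal': (dp_prev, da_next), 'ventral': (vp_prev,
    va_next)}} in degrees, where *prev* is the anterior ring's posterior
    edge and *next* the posterior ring's anterior edge.  A config entry
    may carry an explicit signed ``<junction>_offset_deg`` (mid-conversion
    states interpolate it); otherwise the call name implies +-s or 0.
    """
    sign = {"RaL": 1.0, "LaR": -1.0, "Cross": 0.0}
    out = {}
    for cfg in configs:
        n = cfg["interface"]
        entry = {}
        for junction, base in (("dorsal", 0.0), ("ventral", 180.0)):
            o = cfg.get(f"{junction}_offset_deg")
            if o is None:
                o = sign[cfg[junction]] * s
            if junction == "dorsal":
                entry[junction] = (base - o, base + o)
            else:
                entry[junction] = (base + o, base - o)
        out[n] = entry
    return out


# ---------------------------------------------------------------------------
# prism meshing


@dataclass(frozen=True)
class _Footprint:
    """A cell's footprint in the unrolled (u, x) plane.

    ``u`` is theta in degrees for tube cells (may exceed the principal
    range for cells spanning the ventral midline) or the lateral y
    coordinate in um for plate cells.  Boundaries vary linearly from the
    anterior (``*_a``) to the posterior (``*_p``) edge.
    """

    cell: CellId
    x0: float
    x1: float
    us_a: float
    us_p: float
    ue_a: float
    ue_p: float


def _prism_mesh(
    fp: _Footprint,
    r_in: float,
    r_out: float,
    wrap: bool,
    max_edge_u: float,
    max_edge_x: float,
    n_radial: int,
) -> trimesh.Trimesh:
    """Extrude a footprint radially (tube) or vertically (plate)."""

    def point(x, u, r):
        if wrap:
            th = np.radians(u)
            return np.stack(
                [np.broadcast_to(x, np.shape(th)), -r * np.sin(th), r * np.cos(th)],
                axis=-1,
            )
        return np.stack(
            [
                np.broadcast_to(x, np.shape(u)),
                np.asarray(u, dtype=float),
                np.broadcast_to(r, np.shape(u)),
            ],
            axis=-1,
        )

    nx = max(1, int(np.ceil((fp.x1 - fp.x0) / max_edge_x)))
    width = max(abs(fp.ue_a - fp.us_a), abs(fp.ue_p - fp.us_p))
    nu = max(1, int(np.ceil(width / max_edge_u)))
    xs = np.linspace(fp.x0, fp.x1, nx + 1)
    frac = (xs - fp.x0) / (fp.x1 - fp.x0)
    u0 = fp.us_a + frac * (fp.us_p - fp.us_a)
    u1 = fp.ue_a + frac * (fp.ue_p - fp.ue_a)
    jj = np.linspace(0.0, 1.0, nu + 1)
    U = u0[:, None] + (u1 - u0)[:, None] * jj[None, :]
    X = np.broadcast_to(xs[:, None], U.shape)

    tris: list[np.ndarray] = []

    def quad(a, b, c, d):
        tris.append(np.stack([a, b, c]))
        tris.append(np.stack([a, c, d]))

    top = point(X, U, r_out)
    bot = point(X, U, r_in)
    for i in range(nx):
        for j in range(nu):
            quad(top[i, j], top[i, j + 1], top[i + 1, j + 1], top[i + 1, j])
            quad(bot[i, j], bot[i + 1, j], bot[i + 1, j + 1], bot[i, j + 1])
    rs = np.linspace(r_in, r_out, n_radial + 1)
    # boundary edges of the footprint grid, as (x, u) endpoint pairs
    edges = []
    for i in range(nx):
        edges.append(((xs[i], U[i, 0]), (xs[i + 1], U[i + 1, 0])))
        edges.append(((xs[i], U[i, nu]), (xs[i + 1], U[i + 1, nu])))
    for j in range(nu):
        edges.append(((xs[0], U[0, j]), (xs[0], U[0, j + 1])))
        edges.append(((xs[nx], U[nx, j]), (xs[nx], U[nx, j + 1])))
    for (xa, ua), (xb, ub) in edges:
        for k in range(n_radial):
            quad(
                point(xa, ua, rs[k]),
                point(xb, ub, rs[k]),
                point(xb, ub, rs[k + 1]),
                point(xa, ua, rs[k + 1]),
            )
    soup = np.concatenate(tris, axis=0).reshape(-1, 3)
    faces = np.arange(len(soup)).reshape(-1, 3)
    mesh = trimesh.Trimesh(soup, faces, process=True)
    trimesh.repair.fix_normals(mesh)
    if mesh.volume < 0:
        mesh.invert()
    if not mesh.is_watertight:
        raise RuntimeError(f"generated prism for {fp.cell} is not watertight")
    return mesh


def _analytic_volume(fp: _Footprint, r_in: float, r_out: float, wrap: bool) -> float:
    w_a = fp.ue_a - fp.us_a
    w_p = fp.ue_p - fp.us_p
    base = (fp.x1 - fp.x0) * 0.5 * (w_a + w_p)
    if wrap:
        return np.radians(base) * 0.5 * (r_out**2 - r_in**2)
    return base * (r_out - r_in)


# ---------------------------------------------------------------------------
# tube generation


def _tube_footprints(
    spec: PackingSpec,
    configs: Sequence[dict],
    int2_gap_deg: float = 0.0,
) -> list[_Footprint]:
    s = spec.diagonal_offset_deg
    offs = _junction_offsets(configs, s)
    h = spec.ring_height
    counts = spec.ring_counts
    fps: list[_Footprint] = []
    for ring in range(1, spec.n_rings + 1):
        x0, x1 = (ring - 1) * h, ring * h
        # dorsal boundary d and ventral boundary v at this ring's anterior
        # and posterior edges; free tube ends are unshifted
        da = offs[ring]["dorsal"][1] if ring >= 2 else 0.0
        va = offs[ring]["ventral"][1] if ring >= 2 else 180.0
        dp = offs[ring + 1]["dorsal"][0] if ring + 1 <= spec.n_rings else 0.0
        vp = offs[ring + 1]["ventral"][0] if ring + 1 <= spec.n_rings else 180.0
        gap = int2_gap_deg if ring == 2 else 0.0
        # R occupies (v - 360, d), L occupies (d, v); a dorsal int2 gap
        # retracts both cells' dorsal boundaries symmetrically
        r_fp = _Footprint(None, x0, x1, va - 360.0, vp - 360.0, da - gap, dp - gap)
        l_fp = _Footprint(None, x0, x1, da + gap, dp + gap, va, vp)
        if counts[ring] == 2:
            fps.append(dataclasses.replace(r_fp, cell=CellId(ring, "R")))
            fps.append(dataclasses.replace(l_fp, cell=CellId(ring, "L")))
        else:  # 4-cell int1: split each side at +-90 (dorsal/ventral halves)
            fps.append(
                dataclasses.replace(
                    r_fp, cell=CellId(ring, "RV"), ue_a=-90.0, ue_p=-90.0
                )
            )
            fps.append(
                dataclasses.replace(
                    r_fp, cell=CellId(ring, "RD"), us_a=-90.0, us_p=-90.0
                )
            )
            fps.append(
                dataclasses.replace(l_fp, cell=CellId(ring, "LD"), ue_a=90.0, ue_p=90.0)
            )
            fps.append(
                dataclasses.replace(l_fp, cell=CellId(ring, "LV"), us_a=90.0, us_p=90.0)
            )
    return fps


def _tube_axis(spec: PackingSpec) -> TubeAxis:
    length = spec.n_rings * spec.ring_height
    line = np.column_stack(
        [np.linspace(0.0, length, spec.n_rings + 1), np.zeros(spec.n_rings + 1), np.zeros(spec.n_rings + 1)]
    )
    return TubeAxis(line, (0.0, 0.0, 1.0), spec.circumference)


def generate_tube(
    spec: PackingSpec,
    configs: Sequence[dict] | None = None,
    time: float = 0.0,
) -> PrimordiumFrame:
    """Generate one static primordium frame.

    Junction configurations are sampled from the spec's probabilities
    unless given explicitly.  The frame's ``meta`` carries the ground
    truth: junction configs, per-cell analytic volumes and boundary
    offsets.
    """
    if configs is None:
        configs = sample_diagonal_configs(spec)
    fps = _tube_footprints(spec, configs)
    r_out = spec.radius
    r_in = r_out - spec.radial_thickness
    cells = []
    volumes = {}
    for fp in fps:
        mesh = _prism_mesh(
            fp, r_in, r_out, True, spec.max_edge_deg, spec.max_edge_ax, spec.n_radial
        )
        cells.append(CellMesh(mesh, fp.cell))
        volumes[str(fp.cell)] = _analytic_volume(fp, r_in, r_out, True)
    frame = PrimordiumFrame(time, cells, _tube_axis(spec))
    frame.meta["configs"] = [dict(c) for c in configs]
    frame.meta["volumes"] = volumes
    frame.meta["spec"] = dataclasses.asdict(spec)
    return frame


def generate_e8_plate(
    n_rows: int = 4,
    cell_width: float = 5.0,
    row_height: float = 3.5,
    thickness: float = 3.0,
    junction_offset: float = 1.0,
    p_RaL: float = 0.04,
    p_LaR: float = 0.91,
    p_Cross: float = 0.05,
    seed: int = 0,
    max_edge: float = 1.0,
) -> PrimordiumFrame:
    """Planar E8-stage primordium: ``n_rows`` rows of one R + one L cell.

    The eight E8 cells form a flat plate before the bilayered E16 stage;
    each row interface carries a single R/L junction whose diagonal
    configuration is sampled with an early-stage bias toward LaR (the
    default probabilities follow the early-E8 contact scoring).  R cells
    sit at positive y, L at negative y; RaL means the posterior R cell
    touches the anterior L cell across the row boundary.
    """
    p = (p_RaL, p_LaR, p_Cross)
    if abs(sum(p) - 1.0) > 1e-9 or min(p) < 0:
        raise ValueError("probabilities must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    calls = [str(c) for c in rng.choice(_CALLS, size=n_rows - 1, p=p)]
    o = junction_offset
    fps = []
    for row in range(1, n_rows + 1):
        x0, x1 = (row - 1) * row_height, row * row_height
        # boundary between L (below) and R (above) in y; RaL pushes the
        # posterior ring's boundary down and the anterior's up
        sign = {"RaL": 1.0, "LaR": -1.0, "Cross": 0.0}
        ba = -sign[calls[row - 2]] * o if row >= 2 else 0.0
        bp = sign[calls[row - 1]] * o if row <= n_rows - 1 else 0.0
        fps.append(_Footprint(CellId(row, "R"), x0, x1, ba, bp, cell_width, cell_width))
        fps.append(_Footprint(CellId(row, "L"), x0, x1, -cell_width, -cell_width, ba, bp))
    cells = []
    volumes = {}
    for fp in fps:
        mesh = _prism_mesh(fp, 0.0, thickness, False, max_edge, max_edge, 2)
        cells.append(CellMesh(mesh, fp.cell))
        volumes[str(fp.cell)] = _analytic_volume(fp, 0.0, thickness, False)
    frame = PrimordiumFrame(0.0, cells)
    frame.meta["configs"] = [
        {"interface": i + 2, "junction": calls[i]} for i in range(n_rows - 1)
    ]
    frame.meta["volumes"] = volumes
    return frame


# ---------------------------------------------------------------------------
# trajectories


def _ramp(t: float, t0: float, t1: float) -> float:
    return float(np.clip((t - t0) / (t1 - t0), 0.0, 1.0))


def _configs_at_time(
    base: Sequence[dict], schedule: MorphogenesisSchedule, spec: PackingSpec, t: float
) -> tuple[list[dict], dict]:
    """Junction calls and interpolated offsets at time t."""
    s = spec.diagonal_offset_deg
    sign = {"RaL": 1.0, "LaR": -1.0, "Cross": 0.0}
    state = {
        c["interface"]: {"dorsal": sign[c["dorsal"]] * s, "ventral": sign[c["ventral"]] * s}
        for c in base
    }
    for e in sorted(schedule.of_type(JunctionConversion), key=lambda e: e.t0):
        juncs = ("dorsal", "ventral") if e.junction == "both" else (e.junction,)
        for j in juncs:
            start = state[e.interface][j]
            target = sign[e.target] * s
            state[e.interface][j] = start + (target - start) * _ramp(t, e.t0, e.t1)
    configs = []
    for c in base:
        n = c["interface"]
        entry = {"interface": n}
        for j in ("dorsal", "ventral"):
            o = state[n][j]
            entry[j] = "Cross" if abs(o) < 1e-9 else ("RaL" if o > 0 else "LaR")
            entry[f"{j}_offset_deg"] = o
        configs.append(entry)
    return configs, state


def _cell_motion(schedule: MorphogenesisSchedule, cid: CellId, t: float):
    """(rotation angle deg, axial shift um) of one cell at time t."""
    angle = 0.0
    shift = 0.0
    for e in schedule.of_type(RingRotation):
        if cid.ring == e.ring:
            angle += e.signed_angle * _ramp(t, e.t0, e.t1)
    for e in schedule.of_type(PreRotationShift):
        if cid.ring == 2:
            angle += e.angle_deg * _ramp(t, e.t0, e.t1)
    shift_full = sum(e.angle_deg for e in schedule.of_type(PreRotationShift))
    for e in schedule.of_type(Int2Intercalation):
        if cid.ring == 2:
            f = _ramp(t, e.t0, e.t1)
            # closure targets are absolute: the cells meet at the dorsal
            # midline (mode 1) or at 2L's stall point (mode 2), so the
            # completed pre-rotation shift is compensated
            close_at = 0.0 if e.mode == 1 else e.stall_deg
            if cid.hand == "R":
                angle += (close_at + e.gap_deg - shift_full) * f
            else:
                angle += (close_at - e.gap_deg - shift_full) * f
    for e in schedule.of_type(Int5Exchange):
        if cid.ring == 5:
            shift += (e.shift_um if cid.hand == "R" else -e.shift_um) * _ramp(t, e.t0, e.t1)
    return angle, shift


def _rotate_about_axis(mesh: trimesh.Trimesh, angle_deg: float) -> trimesh.Trimesh:
    """Clockwise (anterior view) rotation about the x axis: theta -> theta + angle."""
    a = np.radians(angle_deg)
    rot = np.array(
        [[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]]
    )
    return trimesh.Trimesh(mesh.vertices @ rot.T, mesh.faces, process=False)


def generate_trajectory(
    spec: PackingSpec,
    schedule: MorphogenesisSchedule,
    t_start: float,
    t_end: float,
    dt: float = 8.0,
    configs: Sequence[dict] | None = None,
) -> list[PrimordiumFrame]:
    """Frames at ``dt``-minute intervals (8 min in the reference
    reconstruction) under the scheduled kinematics.

    Rotations are rigid, so cell volumes are conserved exactly during
    rotation; junction conversions reshape footprints continuously.  Every
    frame's ``meta`` records the ground-truth rotation angle and axial
    shift per cell plus the junction state.
    """
    if t_end <= t_start or dt <= 0:
        raise ValueError("need t_start < t_end and dt > 0")
    lo, hi = schedule.span
    if schedule.events and (lo < t_start or hi > t_end):
        raise ValueError(
            f"schedule events [{lo}, {hi}] fall outside the requested "
            f"time range [{t_start}, {t_end}]"
        )
    if configs is None:
        configs = sample_diagonal_configs(spec)
    inter = schedule.of_type(Int2Intercalation)
    gap = inter[0].gap_deg if inter else 0.0
    r_out = spec.radius
    r_in = r_out - spec.radial_thickness
    frames = []
    times = np.arange(t_start, t_end + dt * 0.5, dt)
    # footprints are static outside conversion windows; cache their meshes
    mesh_cache: dict[tuple, trimesh.Trimesh] = {}
    for t in times:
        cfg_t, _ = _configs_at_time(configs, schedule, spec, t)
        fps = _tube_footprints(spec, cfg_t, int2_gap_deg=gap)
        cells = []
        volumes = {}
        motion = {}
        for fp in fps:
            key = (fp.cell.ring, fp.cell.side) + tuple(
                round(v, 9) for v in (fp.x0, fp.x1, fp.us_a, fp.us_p, fp.ue_a, fp.ue_p)
            )
            base_mesh = mesh_cache.get(key)
            if base_mesh is None:
                base_mesh = _prism_mesh(
                    fp, r_in, r_out, True, spec.max_edge_deg, spec.max_edge_ax, spec.n_radial
                )
                mesh_cache[key] = base_mesh
            # meshes are immutable package-wide, so motionless frames can
            # share the cached object (keeping downstream caches warm)
            mesh = base_mesh
            angle, shift = _cell_motion(schedule, fp.cell, t)
            if angle:
                mesh = _rotate_about_axis(mesh, angle)
            if shift:
                mesh = trimesh.Trimesh(
                    mesh.vertices + np.array([shift, 0.0, 0.0]), mesh.faces, process=False
                )
            cells.append(CellMesh(mesh, fp.cell))
            volumes[str(fp.cell)] = _analytic_volume(fp, r_in, r_out, True)
            motion[str(fp.cell)] = {"rotation_deg": angle, "shift_um": shift}
        frame = PrimordiumFrame(float(t), cells, _tube_axis(spec))
        frame.meta["configs"] = cfg_t
        frame.meta["volumes"] = volumes
        frame.meta["motion"] = motion
        frame.meta["int2_gap_deg"] = gap
        frames.append(frame)
    return frames


def trajectory_ground_truth(frames: Sequence[PrimordiumFrame]) -> pd.DataFrame:
    """Tidy per-frame, per-cell ground truth (rotation angle, shift, volume)."""
    rows = []
    for f in frames:
        for cid, m in f.meta.get("motion", {}).items():
            rows.append(
                {
                    "time": f.time,
                    "cell": cid,
                    "rotation_deg": m["rotation_deg"],
                    "shift_um": m["shift_um"],
                    "volume_um3": f.meta["volumes"][cid],
                }
            )
    return pd.DataFrame(rows)


def wt_reference_schedule(int2_mode: int = 1) -> MorphogenesisSchedule:
    """The canonical wild-type event sequence, timed to the reference
    reconstruction: int5 exchange from 273 min, pre-rotation shift of 2L
    from 289 min, int2 intercalation from 329 min (mode 1 in ~27% of
    embryos, else mode 2), and clockwise rotation of rings 2-4 between 337
    and 433 min; posterior junctions convert LaR -> RaL early, the int3/4
    interfaces shortly before rotation.
    """
    events: list[Event] = [
        Int5Exchange(273.0, 297.0, 0.3),
        PreRotationShift(289.0, 305.0, 12.0),
        Int2Intercalation(329.0, 353.0, mode=int2_mode),
        RingRotation(2, 361.0, 433.0, 90.0, "cw"),
        RingRotation(3, 337.0, 433.0, 90.0, "cw"),
        RingRotation(4, 337.0, 433.0, 90.0, "cw"),
    ]
    for n in range(6, 10):  # posterior interfaces convert first
        events.append(JunctionConversion(n, "both", "RaL", 257.0, 297.0))
    for n in (3, 4, 5):
        events.append(JunctionConversion(n, "both", "RaL", 289.0, 329.0))
    return MorphogenesisSchedule(tuple(events))


def wt_reference_trajectory(
    spec: PackingSpec | None = None,
    int2_mode: int = 1,
    t_start: float = 249.0,
    t_end: float = 441.0,
    dt: float = 8.0,
) -> list[PrimordiumFrame]:
    """Canonical wild-type trajectory on a 9-ring, 2-cells-per-ring tube.

    Junctions start LaR (the early-embryo bias) except the int1-int2
    interface, which stays Cross until int2 closes.
    """
    if spec is None:
        spec = PackingSpec()
    base = [{"interface": 2, "dorsal": "Cross", "ventral": "Cross"}] + [
        {"interface": n, "dorsal": "LaR", "ventral": "LaR"}
        for n in range(3, spec.n_rings + 1)
    ]
    return generate_trajectory(
        spec, wt_reference_schedule(int2_mode), t_start, t_end, dt, configs=base
    )


# ---------------------------------------------------------------------------
# voxelization and rendering


def _stack_grid(
    frame: PrimordiumFrame, voxel_xy: float, z_step: float, n_slices: int,
    margin: int = 1,
):
    if voxel_xy <= 0 or z_step <= 0:
        raise ValueError("voxel sizes must be positive")
    if not frame.cells:
        return np.zeros(3), (n_slices, 1, 1)
    lo = np.min([c.mesh.bounds[0] for c in frame.cells], axis=0)
    hi = np.max([c.mesh.bounds[1] for c in frame.cells], axis=0)
    span_z = hi[2] - lo[2]
    if span_z > n_slices * z_step:
        need = int(np.ceil(span_z / z_step)) + 1
        raise ValueError(
            f"frame spans {span_z:.2f} um in z but the stack holds only "
            f"{n_slices} x {z_step} um; needs >= {need} slices"
        )
    nx = int(np.ceil((hi[0] - lo[0]) / voxel_xy)) + 2 * margin
    ny = int(np.ceil((hi[1] - lo[1]) / voxel_xy)) + 2 * margin
    ox = lo[0] - (nx * voxel_xy - (hi[0] - lo[0])) / 2
    oy = lo[1] - (ny * voxel_xy - (hi[1] - lo[1])) / 2
    oz = (lo[2] + hi[2]) / 2 - n_slices * z_step / 2
    # a real acquisition grid is never aligned with the cell geometry;
    # an irrational sub-voxel offset keeps voxel centers off the exact
    # boundary planes of idealized cells (which would otherwise hand
    # whole interface layers to one of the two adjoining cells)
    frac = 0.5 * (np.sqrt(2.0) - 1.0)
    origin = np.array(
        [ox - frac * voxel_xy, oy - frac * voxel_xy, oz - frac * z_step]
    )
    return origin, (n_slices, ny, nx)


def voxelize(
    frame: PrimordiumFrame,
    voxel_xy: float = 0.2,
    z_step: float = 0.5,
    n_slices: int = 49,
) -> tuple[LabelStack, LabelMap]:
    """Voxelize a frame into an integer label stack plus sidecar map.

    Default geometry matches the reference acquisition (49 Z-slices at a
    0.5 um step; xy pixel 0.2 um).  Each voxel gets the label of the cell
    containing its center (0 = background); a frame taller than the stack
    is rejected with the required dimensions.
    """
    origin, shape = _stack_grid(frame, voxel_xy, z_step, n_slices)
    data = np.zeros(shape, dtype=np.uint16)
    cells = sorted(frame.cells, key=lambda c: (c.owner.ring, c.owner.side))
    label_map = LabelMap({i + 1: c.owner for i, c in enumerate(cells)})
    spacing = (z_step, voxel_xy, voxel_xy)
    for i, c in enumerate(cells):
        b = c.mesh.bounds
        ix0 = max(int((b[0][0] - origin[0]) / voxel_xy) - 1, 0)
        iy0 = max(int((b[0][1] - origin[1]) / voxel_xy) - 1, 0)
        iz0 = max(int((b[0][2] - origin[2]) / z_step) - 1, 0)
        ix1 = min(int((b[1][0] - origin[0]) / voxel_xy) + 2, shape[2])
        iy1 = min(int((b[1][1] - origin[1]) / voxel_xy) + 2, shape[1])
        iz1 = min(int((b[1][2] - origin[2]) / z_step) + 2, shape[0])
        if ix0 >= ix1 or iy0 >= iy1 or iz0 >= iz1:
            continue
        sub_origin = (
            origin[2] + iz0 * z_step,
            origin[1] + iy0 * voxel_xy,
            origin[0] + ix0 * voxel_xy,
        )
        mask = fill_volume(
            c.mesh, sub_origin, spacing, (iz1 - iz0, iy1 - iy0, ix1 - ix0)
        )
        view = data[iz0:iz1, iy0:iy1, ix0:ix1]
        write = mask & (view == 0)
        view[write] = i + 1
    stack = LabelStack(data, voxel_xy, z_step, origin)
    return stack, label_map


def render_membranes(
    frame: PrimordiumFrame,
    noise: NoiseModel = NoiseModel(),
    voxel_xy: float = 0.2,
    z_step: float = 0.5,
    n_slices: int = 49,
) -> ImageStack:
    """Render a membrane-reporter-style fluorescence stack.

    Every cell surface deposits signal proportional to its local membrane
    area; where two cells adjoin, both membranes deposit, so the interface
    carries about twice the single-membrane intensity (the line-scan
    doubling criterion used to identify two-membrane contacts).
    """
    margin = max(1, int(np.ceil(3.0 * noise.psf_sigma / voxel_xy)))
    origin, shape = _stack_grid(frame, voxel_xy, z_step, n_slices, margin=margin)
    acc = np.zeros(shape, dtype=float)
    rng = np.random.default_rng(noise.seed)
    voxvol = voxel_xy * voxel_xy * z_step
    spacing = np.array([z_step, voxel_xy, voxel_xy])
    max_edge = 0.5 * min(voxel_xy, z_step)
    for c in frame.cells:
        fine = subdivide_mesh(c.mesh, max_edge)
        pts = fine.triangles_center.copy()
        if noise.surface_jitter > 0:
            pts += rng.normal(0.0, noise.surface_jitter, size=pts.shape)
        w = fine.area_faces
        # trilinear (cloud-in-cell) deposition onto voxel centers: avoids
        # the moire between the subdivision lattice and the voxel grid that
        # nearest-voxel binning produces
        f = (pts[:, ::-1] - origin[::-1]) / spacing - 0.5  # (z, y, x) fractional
        i0 = np.floor(f).astype(int)
        frac = f - i0
        for dz in (0, 1):
            for dy in (0, 1):
                for dx in (0, 1):
                    idx = i0 + (dz, dy, dx)
                    wt = (
                        (frac[:, 0] if dz else 1 - frac[:, 0])
                        * (frac[:, 1] if dy else 1 - frac[:, 1])
                        * (frac[:, 2] if dx else 1 - frac[:, 2])
                    )
                    ok = np.all((idx >= 0) & (idx < shape), axis=1)
                    np.add.at(
                        acc, (idx[ok, 0], idx[ok, 1], idx[ok, 2]), w[ok] * wt[ok]
                    )
    data = noise.background + noise.membrane_intensity * acc / voxvol
    if noise.psf_sigma > 0:
        from scipy.ndimage import gaussian_filter

        data = gaussian_filter(
            data,
            sigma=(noise.psf_sigma / z_step, noise.psf_sigma / voxel_xy, noise.psf_sigma / voxel_xy),
            mode="constant",
            cval=noise.background,
        )
    return ImageStack(data, voxel_xy, z_step, origin)
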