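"""Quantification of circumferential int-ring rotation.

Angular positions are degrees from the dorsal midline, positive clockwise
as seen from the anterior (see :mod:`gutmorph.geometry`).  The wild-type
int2-int4 rings rotate clockwise by about a quarter turn starting near
337 minutes, moving the R/L boundaries at roughly 0.1-0.2 um/min on the
~47 um circumference; int5 exchanges its cells anterior-posterior without
rotating, and int7 begins a counterclockwise rotation late.

Boundary angles are read from the R cell's angular extent: the two
endpoints of the circular arc its surface occupies coincide with the
ring's R/L boundaries whenever the ring is closed, and with the cell's
free edges when the partners have separated (e.g. the pre-closure int2
gap).  Traces are unwrapped over time assuming less than a quarter turn
per frame, safe by ~7x at the observed speeds and 8-minute sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import CellId, CellMesh, PrimordiumFrame, fit_axis, to_cylindrical

__all__ = [
    "RotationTrace",
    "SectorMap",
    "RotationPattern",
    "EventFlags",
    "angular_extent",
    "rotation_trace",
    "boundary_speed",
    "classify_leading_edge",
    "call_rotation_pattern",
    "detect_events",
]


# ---------------------------------------------------------------------------
# circular-interval helpers


def _wrap(theta):
    """Map angles to (-180, 180]."""
    t = np.mod(np.asarray(theta, dtype=float) + 180.0, 360.0) - 180.0
    return np.where(t == -180.0, 180.0, t)


def angular_extent(
    cell: CellMesh, axis, axial_window: tuple[float, float] | None = None
) -> tuple[float, float]:
    """The circular arc (lo, hi) covered by a cell's surface.

    Computed as the complement of the largest empty angular gap among the
    cell's vertex angles; the cell covers lo -> hi going clockwise
    (increasing theta), with lo in (-180, 180] and hi = lo + width.
    ``axial_window`` restricts the vertices to a fractional slice of the
    cell's own anterior-posterior span (e.g. ``(0.0, 0.3)`` for the
    anterior third), which isolates a boundary from packing-driven slants
    at the opposite ring interface.
    """
    theta, z, _ = to_cylindrical(cell.mesh.vertices, axis)
    theta = np.asarray(theta)
    if axial_window is not None:
        z = np.asarray(z)
        z0, z1 = z.min(), z.max()
        lo_f, hi_f = axial_window
        sel = (z >= z0 + lo_f * (z1 - z0)) & (z <= z0 + hi_f * (z1 - z0))
        if sel.any():
            theta = theta[sel]
    t = np.sort(theta)
    gaps = np.diff(t)
    wrap_gap = t[0] + 360.0 - t[-1]
    k = int(np.argmax(gaps)) if gaps.size and gaps.max() > wrap_gap else None
    if k is None:
        lo = float(t[0])
        width = 360.0 - wrap_gap
    else:
        lo = float(t[k + 1])
        width = 360.0 - float(gaps[k])
    return lo, lo + width


def _unwrap_series(values: np.ndarray) -> np.ndarray:
    """Unwrap a deg-angle time series to be continuous (jumps < 180),
    anchored so the first valid value lies in (-180, 180]."""
    out = np.array(values, dtype=float)
    valid = np.flatnonzero(~np.isnan(out))
    if not len(valid):
        return out
    out -= out[valid[0]] - float(_wrap(out[valid[0]]))
    prev = valid[0]
    for i in valid[1:]:
        while out[i] - out[prev] > 180.0:
            out[i] -= 360.0
        while out[i] - out[prev] < -180.0:
            out[i] += 360.0
        prev = i
    return out


# ---------------------------------------------------------------------------
# domain types


@dataclass
class RotationTrace:
    """Angular positions of one ring's two R/L boundaries over time.

    ``theta_boundary_1`` is the boundary nearer the dorsal midline at the
    start of the trace, ``theta_boundary_2`` the ventral-side boundary;
    both are unwrap-continuous (not wrapped to (-180, 180]).  NaN marks
    frames where the ring was missing.
    """

    ring_n: int
    times: np.ndarray
    theta_boundary_1: np.ndarray
    theta_boundary_2: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.theta_boundary_1 = np.asarray(self.theta_boundary_1, dtype=float)
        self.theta_boundary_2 = np.asarray(self.theta_boundary_2, dtype=float)
        n = len(self.times)
        if len(self.theta_boundary_1) != n or len(self.theta_boundary_2) != n:
            raise ValueError("trace series must share one time base")
        for s in (self.theta_boundary_1, self.theta_boundary_2):
            d = np.abs(np.diff(s))
            if np.any(d[~np.isnan(d)] >= 90.0):
                warnings.warn(
                    f"ring {self.ring_n}: boundary moved >= 90 deg between "
                    "frames; unwrapping may be unreliable at this sampling"
                )

    def window(self, t0: float, t1: float) -> "RotationTrace":
        m = (self.times >= t0) & (self.times <= t1)
        return RotationTrace(
            self.ring_n,
            self.times[m],
            self.theta_boundary_1[m],
            self.theta_boundary_2[m],
        )

    @property
    def net_rotation(self) -> float:
        """Mean signed boundary displacement, first to last frame (deg)."""
        deltas = []
        for s in (self.theta_boundary_1, self.theta_boundary_2):
            ok = ~np.isnan(s)
            if ok.sum() >= 2:
                deltas.append(s[ok][-1] - s[ok][0])
        if not deltas:
            raise ValueError("trace has fewer than 2 valid frames")
        return float(np.mean(deltas))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "ring": self.ring_n,
                "theta_boundary_1": self.theta_boundary_1,
                "theta_boundary_2": self.theta_boundary_2,
            }
        )


def _default_sectors() -> tuple[tuple[str, float, float], ...]:
    return (
        ("ventral neurons", -180.0, -160.0),
        ("right ventral hyp", -160.0, -135.0),
        ("right seam", -135.0, -105.0),
        ("right dorsal hyp bz2", -105.0, -75.0),
        ("right muscle", -75.0, -15.0),
        ("dorsal hyp bz1", -15.0, 15.0),
        ("left muscle", 15.0, 75.0),
        ("left dorsal hyp bz2", 75.0, 105.0),
        ("left seam", 105.0, 135.0),
        ("left ventral hyp", 135.0, 160.0),
        ("ventral neurons", 160.0, 180.0),
    )


@dataclass(frozen=True)
class SectorMap:
    """Circumferential map of the tissues surrounding the primordium.

    Sectors are (name, lo, hi] intervals partitioning (-180, 180]: the
    dorsal-hypodermal basal zone bz1 straddles the dorsal midline, flanked
    on each side by a muscle quadrant, the second basal zone bz2, the seam
    cell, the ventral hypodermis, and the ventral neurons around +-180.
    The default angular extents are package choices (no measured extents
    exist) and are written into every report that uses them.
    """

    sectors: tuple[tuple[str, float, float], ...] = field(
        default_factory=_default_sectors
    )

    def __post_init__(self) -> None:
        s = sorted(self.sectors, key=lambda x: x[1])
        if s[0][1] != -180.0 or s[-1][2] != 180.0:
            raise ValueError("sectors must span (-180, 180]")
        for (na, la, ha), (nb, lb, hb) in zip(s, s[1:]):
            if ha != lb:
                raise ValueError(f"sectors {na!r} and {nb!r} do not tile")
            if ha <= la:
                raise ValueError(f"sector {na!r} is empty")
        if not any(lo < 0.0 < hi for _, lo, hi in s):
            raise ValueError("a sector must contain the dorsal midline (0)")

    def label(self, theta: float) -> str:
        t = float(_wrap(theta))
        for name, lo, hi in self.sectors:
            if lo < t <= hi:
                return name
        # theta == -180 wraps onto the +180 end
        return self.sectors[-1][0]

    def mirrored(self) -> "SectorMap":
        """The sector map of the left-right mirrored world: extents stay
        (the surrounding tissues are bilaterally symmetric) but left and
        right labels swap."""

        def swap(name: str) -> str:
            if name.startswith("left"):
                return "right" + name[4:]
            if name.startswith("right"):
                return "left" + name[5:]
            return name

        return SectorMap(tuple((swap(n), lo, hi) for n, lo, hi in self.sectors))

    def to_dict(self) -> dict:
        return {"sectors": [list(s) for s in self.sectors]}


@dataclass(frozen=True)
class RotationPattern:
    """Per-ring full/partial/none rotation plus direction, and the
    combined category over rings 2-4 (the eight columns of the
    full-rotation scoring table)."""

    per_ring: Mapping[int, str]
    direction: Mapping[int, str | None]
    window: tuple[float, float]

    def __post_init__(self) -> None:
        for ring, v in self.per_ring.items():
            if v not in ("full", "partial", "none", "undetermined"):
                raise ValueError(f"bad per-ring flag {v!r} for ring {ring}")

    @property
    def category(self) -> str:
        full = sorted(r for r, v in self.per_ring.items() if v == "full")
        return ",".join(f"int{r}" for r in full) if full else "none"


@dataclass(frozen=True)
class EventFlags:
    """Morphogenesis event detections on one trajectory.

    ``pre_rotation_shift_2L``: did 2L's ventral boundary cross the ventral
    midline clockwise before any ring rotation (None = stage not covered)?
    ``int2_mode``: 1 if both int2 cells closed together at the dorsal
    midline, 2 if 2R crossed the dorsal midline to close the ring, else
    "undetermined".  ``int7_direction``: cw/ccw/none.
    """

    pre_rotation_shift_2L: bool | None
    shift_onset: float | None
    int2_mode: int | str
    int7_direction: str | None


# ---------------------------------------------------------------------------
# operations


def _frame_axis(frame: PrimordiumFrame):
    return frame.axis if frame.axis is not None else fit_axis(frame)


def _cell_extent_series(
    frames: Sequence[PrimordiumFrame],
    cid: CellId,
    axial_window: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(times, lo series, hi series) of one cell's angular extent,
    unwrapped over time; NaN where the cell is missing."""
    times = np.array([f.time for f in frames], dtype=float)
    lo = np.full(len(frames), np.nan)
    hi = np.full(len(frames), np.nan)
    for i, f in enumerate(frames):
        try:
            cell = f.cell(cid)
        except KeyError:
            continue
        a, b = angular_extent(cell, _frame_axis(f), axial_window)
        lo[i], hi[i] = a, b
    return times, _unwrap_series(lo), _unwrap_series(hi)


def rotation_trace(
    frames: Sequence[PrimordiumFrame], ring_n: int
) -> RotationTrace:
    """Boundary-angle trace of one ring across a trajectory.

    The ring's R cell must be present in (at least some) frames; missing
    frames are recorded as NaN gaps.  Boundary 1 is the R cell's
    clockwise extent end (dorsal side before rotation), boundary 2 its
    counterclockwise end (ventral side).
    """
    times, lo, hi = _cell_extent_series(frames, CellId(ring_n, "R"))
    if np.all(np.isnan(lo)):
        raise ValueError(f"ring {ring_n} R cell missing from every frame")
    # boundary 1 = the boundary nearer the dorsal midline at trace start
    first = np.flatnonzero(~np.isnan(lo))[0]
    if abs(_wrap(hi[first])) <= abs(_wrap(lo[first])):
        b1, b2 = hi, lo
    else:
        b1, b2 = lo, hi
    return RotationTrace(ring_n, times, b1, b2)


def boundary_speed(
    trace: RotationTrace,
    circumference: float = 47.0,
    t0: float | None = None,
    t1: float | None = None,
) -> float:
    """Mean boundary speed over the rotation interval, in um/min.

    |net angular displacement| / elapsed time x circumference / 360,
    averaged over the two boundaries.  A quarter turn of int4 between 337
    and 433 minutes on a 47 um circumference gives ~0.12 um/min, inside
    the observed 0.1-0.2 um/min band.
    """
    tr = trace if t0 is None and t1 is None else trace.window(
        trace.times[0] if t0 is None else t0,
        trace.times[-1] if t1 is None else t1,
    )
    speeds = []
    for s in (tr.theta_boundary_1, tr.theta_boundary_2):
        ok = ~np.isnan(s)
        if ok.sum() < 2:
            continue
        dt = tr.times[ok][-1] - tr.times[ok][0]
        if dt <= 0:
            raise ValueError("zero elapsed time in trace window")
        speeds.append(abs(s[ok][-1] - s[ok][0]) / dt)
    if not speeds:
        raise ValueError("trace needs >= 2 timepoints")
    return float(np.mean(speeds) * circumference / 360.0)


def classify_leading_edge(
    frame: PrimordiumFrame,
    ring_n: int,
    sectors: SectorMap = SectorMap(),
    direction: str | None = None,
) -> dict[CellId, str]:
    """Sector of each ring cell's leading pole.

    The leading pole is the extremal boundary angle in the cell's
    direction of motion: for the default clockwise rotation this is the
    clockwise-most surface point (R cells lead with their dorsal-side
    edge).  With ``direction=None`` R cells default to clockwise (the
    wild-type sense) and L cells are scored in the same sense; pass
    ``"ccw"`` for reversed trajectories or ``"undetermined"`` to refuse
    the default.
    """
    if direction not in (None, "cw", "ccw", "undetermined"):
        raise ValueError(f"bad direction {direction!r}")
    if direction == "undetermined":
        return {c.owner: "undetermined" for c in frame.ring(ring_n)}
    sense = direction or "cw"
    axis = _frame_axis(frame)
    out = {}
    for cell in frame.ring(ring_n):
        lo, hi = angular_extent(cell, axis)
        pole = hi if sense == "cw" else lo
        out[cell.owner] = sectors.label(pole)
    return out


def call_rotation_pattern(
    traces: Mapping[int, RotationTrace],
    window: tuple[float, float] = (393.0, 441.0),
    full_threshold: float = 45.0,
    partial_threshold: float = 15.0,
) -> RotationPattern:
    """Full-rotation calls for rings 2-4 over a scoring window.

    A ring counts as fully rotated when its leading (dorsal-side) boundary
    has advanced past the dorsal midline by at least ``full_threshold``
    degrees in its direction of motion by the end of the window (the
    trailing boundary correspondingly passes the ventral midline for a
    rigid ring).  Displacements beyond ``partial_threshold`` but short of
    full count as partial.  Rings whose traces do not cover the window
    are undetermined.
    """
    per_ring = {}
    direction = {}
    for ring, tr in sorted(traces.items()):
        ok = ~np.isnan(tr.theta_boundary_1)
        if (
            not ok.any()
            or tr.times[ok][0] > window[0]
            or tr.times[ok][-1] < window[1]
        ):
            per_ring[ring] = "undetermined"
            direction[ring] = None
            continue
        w = tr.window(*window)
        b1 = w.theta_boundary_1[~np.isnan(w.theta_boundary_1)]
        net = tr.net_rotation
        direction[ring] = "cw" if net > 5.0 else ("ccw" if net < -5.0 else None)
        signed_reach = b1[-1] if net >= 0 else -b1[-1]
        if signed_reach >= full_threshold:
            per_ring[ring] = "full"
        elif abs(net) >= partial_threshold:
            per_ring[ring] = "partial"
        else:
            per_ring[ring] = "none"
    return RotationPattern(per_ring, direction, window)


def detect_events(
    frames: Sequence[PrimordiumFrame],
    rotation_onset_delta: float = 5.0,
    midline_tol: float = 3.0,
) -> EventFlags:
    """Detect the pre-rotation shift of 2L, the int2 closure mode, and the
    int7 rotation direction on a trajectory.

    The pre-rotation shift is called when 2L's ventral boundary moves
    clockwise past the ventral midline before any of rings 2-4 has
    rotated by more than ``rotation_onset_delta`` degrees.  Mode 1 int2
    closure has both cells' dorsal extremes reach the dorsal midline
    within one sampling interval of each other; in mode 2, 2R's dorsal
    extreme crosses the midline onto the left side while 2L stalls short
    of it.  Flags are None/"undetermined" where the trajectory does not
    cover the relevant stage.
    """
    if len(frames) < 2:
        raise ValueError("event detection needs >= 2 frames")
    rings = set()
    for f in frames:
        rings |= {c.owner.ring for c in f.cells}

    # --- rotation onset over rings 2-4
    onset_time = np.inf
    for ring in (2, 3, 4):
        if ring not in rings:
            continue
        try:
            tr = rotation_trace(frames, ring)
        except ValueError:
            continue
        b = tr.theta_boundary_1
        ok = ~np.isnan(b)
        moved = np.abs(b - b[ok][0]) > rotation_onset_delta
        if moved.any():
            onset_time = min(onset_time, float(tr.times[np.argmax(moved)]))

    # int2 boundaries are read in each cell's anterior third, away from
    # packing-driven boundary slants at the int2/int3 interface
    ant = (0.0, 0.3)

    # --- pre-rotation shift of 2L (ventral boundary clockwise past +-180)
    shift = None
    shift_onset = None
    if 2 in rings:
        times, lo2l, hi2l = _cell_extent_series(frames, CellId(2, "L"), ant)
        ok = ~np.isnan(hi2l)
        if ok.any():
            # 2L's ventral boundary is its clockwise (hi) end
            crossed = (hi2l > 180.0 + midline_tol) & ok
            if crossed.any():
                t_cross = float(times[np.argmax(crossed)])
                shift = bool(t_cross <= onset_time)
                shift_onset = t_cross if shift else None
            else:
                shift = False

    # --- int2 closure mode, from where the dorsal gap closes
    int2_mode: int | str = "undetermined"
    if 2 in rings:
        times, lo2l, _ = _cell_extent_series(frames, CellId(2, "L"), ant)
        _, _, hi2r = _cell_extent_series(frames, CellId(2, "R"), ant)
        ok = ~np.isnan(lo2l) & ~np.isnan(hi2r)
        if ok.sum() >= 2:
            t = times[ok]
            gap = lo2l[ok] - hi2r[ok]  # dorsal opening between the cells
            if gap[0] > 2 * midline_tol and (gap <= midline_tol).any():
                i_close = int(np.argmax(gap <= midline_tol))
                meet = hi2r[ok][i_close]  # 2R's dorsal extreme at closure
                if meet > midline_tol and hi2r[ok][0] < meet:
                    int2_mode = 2  # 2R rotated past the midline to close
                elif abs(meet) <= midline_tol:
                    int2_mode = 1  # both cells met at the dorsal midline

    # --- int7 direction
    int7 = None
    if 7 in rings:
        try:
            tr7 = rotation_trace(frames, 7)
            net = tr7.net_rotation
            int7 = "cw" if net > 5.0 else ("ccw" if net < -5.0 else "none")
        except ValueError:
            int7 = None

    return EventFlags(shift, shift_onset, int2_mode, int7)
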