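"""Classification of diagonal contacts between adjacent int rings.

Between two adjacent rings the four cells (R and L of each ring) can make
two kinds of diagonal contact: the posterior R cell touching the anterior
L cell (RaL) or the posterior L touching the anterior R (LaR); when
neither diagonal is present and all four cells meet at a common vertex the
configuration is a Cross.  Because the rings close around a tube, each
interface carries two junctions - one near the dorsal midline, one near
the ventral midline - so a full description of an interface combines two
calls (RaL+RaL, RaL+LaR, LaR+C, ...), and an R cell in a hexagonally
packed region touches two distinct faces of the anterior L cell.

Contacts are scored either over the whole lateral surface or restricted
to a single horizontal plane near the dorsal roof of the primordium
("roof plane"), which is how time-lapse scoring was done at 8-minute
intervals.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._meshdist import points_to_surface_distance, subdivide_mesh
from .contacts import OcclusionConfig, shadow_faces
from .geometry import CellId, CellMesh, PrimordiumFrame, fit_axis, to_cylindrical

__all__ = [
    "DiagonalCall",
    "RingPairCall",
    "ScoringMode",
    "CATEGORIES",
    "classify_pair",
    "contact_area_timeseries",
    "tabulate_calls",
    "call_transition_events",
]


class DiagonalCall(str, enum.Enum):
    """One diagonal-contact configuration between adjacent rings."""

    RaL = "RaL"
    LaR = "LaR"
    Cross = "Cross"

    @property
    def short(self) -> str:
        return "C" if self is DiagonalCall.Cross else self.value


#: pair categories in the order used for contact tables at hatching
CATEGORIES = ("RaL+RaL", "LaR+LaR", "RaL+LaR", "RaL+C", "LaR+C", "C+C")

_ORDER = {DiagonalCall.RaL: 0, DiagonalCall.LaR: 1, DiagonalCall.Cross: 2}


@dataclass(frozen=True)
class RingPairCall:
    """Diagonal configuration between ring ``ring_n`` and ring n-1.

    ``components`` holds one call per junction (two for whole-surface
    scoring - dorsal and ventral - or one for roof-plane scoring) and
    ``areas`` the corresponding contact areas in um^2 (zero for Cross).
    """

    ring_n: int
    components: tuple[DiagonalCall, ...]
    areas: tuple[float, ...] = ()
    junctions: Mapping[str, str] = field(default_factory=dict)
    notes: str = ""

    def __post_init__(self) -> None:
        if self.ring_n < 2:
            raise ValueError("ring_n must be >= 2 (pairs with the anterior ring)")
        if not self.components:
            raise ValueError("a ring-pair call needs at least one component")

    @property
    def category(self) -> str:
        parts = sorted(self.components, key=lambda c: _ORDER[c])
        return "+".join(p.short for p in parts)


@dataclass(frozen=True)
class ScoringMode:
    """Whole-surface scoring, or a single optical plane near the roof.

    ``roof_offset`` is how far (um) below the dorsal-most intestinal
    surface the scoring plane sits (default one 0.5 um optical section);
    ``slab_thickness`` is the plane's thickness.
    """

    mode: str = "whole_surface"
    roof_offset: float = 0.5
    slab_thickness: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("whole_surface", "roof_plane"):
            raise ValueError(f"unknown scoring mode {self.mode!r}")
        if self.roof_offset < 0 or self.slab_thickness <= 0:
            raise ValueError("roof_offset >= 0 and slab_thickness > 0 required")


# ---------------------------------------------------------------------------


def _cells_by_side(frame: PrimordiumFrame, ring: int) -> dict[str, CellMesh]:
    return {c.owner.side: c for c in frame.ring(ring)}


def _anterior_partners(frame: PrimordiumFrame, ring_n: int):
    """(RaL partners, LaR partners) per junction for ring n vs ring n-1.

    For a 2-cell anterior ring both junctions test the same partner; after
    the int1 division the dorsal junction pairs with the dorsal daughters
    (2R-1LD is RaL) and the ventral junction with the ventral daughters
    (2L-1RV is LaR).
    """
    ant = _cells_by_side(frame, ring_n - 1)
    if not ant:
        raise ValueError(f"ring {ring_n - 1} missing from frame")
    if "R" in ant and "L" in ant:
        return (
            {"dorsal": ant["L"], "ventral": ant["L"]},
            {"dorsal": ant["R"], "ventral": ant["R"]},
        )
    needed = {"RD", "RV", "LD", "LV"}
    if set(ant) != needed:
        raise ValueError(
            f"ring {ring_n - 1} has sides {sorted(ant)}; expected R/L or the "
            "four int1 daughters"
        )
    return (
        {"dorsal": ant["LD"], "ventral": ant["LV"]},
        {"dorsal": ant["RD"], "ventral": ant["RV"]},
    )


def _zone_of(theta: np.ndarray) -> np.ndarray:
    """dorsal junction zone |theta| < 90, ventral zone otherwise."""
    return np.where(np.abs(theta) < 90.0, "dorsal", "ventral")


def _frame_axis(frame: PrimordiumFrame):
    return frame.axis if frame.axis is not None else fit_axis(frame)


def _roof_z(frame: PrimordiumFrame) -> float:
    return max(float(c.mesh.vertices[:, 2].max()) for c in frame.cells)


def _diag_area_by_zone(
    cell: CellMesh,
    partners: Mapping[str, CellMesh],
    frame: PrimordiumFrame,
    config: OcclusionConfig,
    mode: ScoringMode,
) -> dict[str, float]:
    """Contact area of ``cell`` against its per-junction partners,
    accumulated per junction zone (or within the roof slab)."""
    axis = _frame_axis(frame)
    out = {"dorsal": 0.0, "ventral": 0.0}
    roof = _roof_z(frame) - mode.roof_offset if mode.mode == "roof_plane" else None
    if partners["dorsal"] is partners["ventral"]:
        items = [(None, partners["dorsal"])]  # one partner, split by zone
    else:
        items = list(partners.items())
    for junction, partner in items:
        areas, cent, mask = shadow_faces(cell, partner, config)
        if not mask.any():
            continue
        theta, _, _ = to_cylindrical(cent[mask], axis)
        zones = _zone_of(theta)
        sel_areas = areas[mask]
        if roof is not None:
            in_slab = np.abs(cent[mask][:, 2] - roof) <= mode.slab_thickness / 2
            sel_areas = np.where(in_slab, sel_areas, 0.0)
        for z in ("dorsal", "ventral"):
            if junction is None or z == junction:
                out[z] += float(sel_areas[zones == z].sum())
    return out


def _cross_at_junction(
    frame: PrimordiumFrame,
    ring_n: int,
    junction: str,
    epsilon: float,
    config: OcclusionConfig,
) -> bool:
    """Do all four cells of the pair approach a common point within
    ``epsilon`` near this junction?"""
    axis = _frame_axis(frame)
    post = _cells_by_side(frame, ring_n)
    ral, lar = _anterior_partners(frame, ring_n)
    others = [post["L"], ral[junction], lar[junction]]
    probe = subdivide_mesh(post["R"].mesh, max(config.face_subdivision, epsilon))
    cent = probe.triangles_center
    theta, _, _ = to_cylindrical(cent, axis)
    sel = _zone_of(theta) == junction
    if not sel.any():
        return False
    pts = cent[sel]
    ok = np.ones(len(pts), dtype=bool)
    for om in others:
        if not ok.any():
            return False
        d = points_to_surface_distance(pts[ok], om.mesh, rmax=epsilon)
        new = np.zeros(len(pts), dtype=bool)
        new[np.nonzero(ok)[0]] = d < epsilon
        ok = new
    return bool(ok.any())


def classify_pair(
    graph,
    frame: PrimordiumFrame,
    ring_n: int,
    mode: ScoringMode = ScoringMode(),
    epsilon: float = 0.25,
    min_area: float = 0.05,
    config: OcclusionConfig = OcclusionConfig(),
) -> RingPairCall:
    """Call the diagonal configuration between ring ``ring_n`` and n-1.

    A junction where all four cells approach a common point within
    ``epsilon`` um is a Cross (the four-cell vertex takes precedence: at a
    vertex both diagonals carry small edge-adjacency bands that would
    otherwise win on area).  Otherwise a diagonal is present when its
    contact area at the junction (restricted to the roof slab in
    roof-plane mode) exceeds ``min_area`` um^2; if both exceed it the
    larger wins and the margin is logged in ``notes``.  ``graph`` (a
    ContactGraph or None) is accepted for API symmetry; the areas are
    recomputed zone-resolved here.
    """
    post = _cells_by_side(frame, ring_n)
    if "R" not in post or "L" not in post:
        raise ValueError(f"ring {ring_n} incomplete: sides {sorted(post)}")
    ral_partners, lar_partners = _anterior_partners(frame, ring_n)
    ral = _diag_area_by_zone(post["R"], ral_partners, frame, config, mode)
    lar = _diag_area_by_zone(post["L"], lar_partners, frame, config, mode)
    junctions = ("dorsal",) if mode.mode == "roof_plane" else ("dorsal", "ventral")
    components = []
    areas = []
    detail = {}
    notes = []
    for j in junctions:
        a_ral, a_lar = ral[j], lar[j]
        if _cross_at_junction(frame, ring_n, j, epsilon, config):
            call, area = DiagonalCall.Cross, 0.0
        elif a_ral > min_area and a_lar > min_area:
            call = DiagonalCall.RaL if a_ral >= a_lar else DiagonalCall.LaR
            notes.append(
                f"{j}: both diagonals present (RaL {a_ral:.2f} vs LaR "
                f"{a_lar:.2f} um^2), margin {abs(a_ral - a_lar):.2f}"
            )
            area = max(a_ral, a_lar)
        elif a_ral > min_area:
            call, area = DiagonalCall.RaL, a_ral
        elif a_lar > min_area:
            call, area = DiagonalCall.LaR, a_lar
        else:
            detail[j] = "none"
            continue
        components.append(call)
        areas.append(area)
        detail[j] = call.value
    if not components:
        raise ValueError(
            f"rings {ring_n - 1}/{ring_n}: no diagonal contact and no shared "
            "vertex within epsilon (cells separated?)"
        )
    return RingPairCall(
        ring_n, tuple(components), tuple(areas), detail, "; ".join(notes)
    )


def contact_area_timeseries(
    frames: Sequence[PrimordiumFrame],
    ring_n: int,
    config: OcclusionConfig = OcclusionConfig(),
) -> pd.DataFrame:
    """Whole-surface RaL and LaR contact areas of one ring pair over time.

    Returns a frame-indexed table with columns ``time``, ``ral_area`` and
    ``lar_area`` (um^2); frames missing either ring get NaN.
    """
    rows = []
    for f in frames:
        try:
            post = _cells_by_side(f, ring_n)
            ral_p, lar_p = _anterior_partners(f, ring_n)
            mode = ScoringMode()
            ral = _diag_area_by_zone(post["R"], ral_p, f, config, mode)
            lar = _diag_area_by_zone(post["L"], lar_p, f, config, mode)
            rows.append(
                {
                    "time": f.time,
                    "ral_area": ral["dorsal"] + ral["ventral"],
                    "lar_area": lar["dorsal"] + lar["ventral"],
                }
            )
        except (ValueError, KeyError):
            rows.append({"time": f.time, "ral_area": np.nan, "lar_area": np.nan})
    return pd.DataFrame(rows)


def tabulate_calls(calls: Iterable[RingPairCall]):
    """Per-ring percentage of each pair category plus n.

    Mirrors the hatching contact table layout: one row per posterior ring,
    one column per category, percentages rounded to the integer.
    """
    from .reporting import ContactTable  # local import; reporting wraps us

    calls = list(calls)
    if not calls:
        raise ValueError("no calls to tabulate")
    rows = {}
    for c in calls:
        rows.setdefault(c.ring_n, []).append(c.category)
    cats = list(CATEGORIES) + sorted(
        {c.category for c in calls} - set(CATEGORIES)
    )
    table = []
    for ring in sorted(rows):
        cl = rows[ring]
        n = len(cl)
        entry = {"int_ring": f"int{ring}"}
        for cat in cats:
            entry[cat] = 100.0 * sum(1 for x in cl if x == cat) / n
        entry["n"] = n
        table.append(entry)
    return ContactTable(pd.DataFrame(table).set_index("int_ring"))


def call_transition_events(
    frames: Sequence[PrimordiumFrame],
    ring_n: int,
    mode: ScoringMode = ScoringMode(mode="roof_plane"),
    epsilon: float = 0.25,
    min_area: float = 0.05,
    config: OcclusionConfig = OcclusionConfig(),
) -> pd.DataFrame:
    """Roof-plane diagonal call of one ring pair per frame.

    Returns columns ``time``, ``call`` (RaL/LaR/Cross/None) and
    ``detached`` - true when the ring's R and L cells have no mutual
    contact in the roof slab (partner separation/detachment from the
    roof).  Consecutive rows expose LaR -> Cross -> RaL transitions.
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames to score transitions")
    rows = []
    for f in frames:
        post = _cells_by_side(f, ring_n)
        if "R" not in post or "L" not in post:
            rows.append({"time": f.time, "call": None, "detached": None})
            continue
        try:
            rp = classify_pair(None, f, ring_n, mode, epsilon, min_area, config)
            call = rp.components[0].value
        except ValueError:
            call = None
        # within-ring partner separation at the roof
        roof = _roof_z(f) - mode.roof_offset
        areas, cent, mask = shadow_faces(post["R"], post["L"], config)
        in_slab = mask & (np.abs(cent[:, 2] - roof) <= mode.slab_thickness / 2)
        detached = not bool(areas[in_slab].sum() > min_area)
        rows.append({"time": f.time, "call": call, "detached": detached})
    return pd.DataFrame(rows)
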