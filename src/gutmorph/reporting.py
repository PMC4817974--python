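"""Statistical comparisons, volume-trend summaries and the report pipeline.

Contact-frequency tables from different genotypes/conditions are compared
with Fisher's exact test after collapsing the multi-category calls to
RaL vs non-RaL (the per-stage sample sizes, 15-36 scored contacts, cannot
support exact tests over six categories); the collapse is configurable.
Star levels follow the convention used for the contact-frequency figures:
one star p < .05, two stars p < 5e-4.  No multiple-testing correction is
applied by default, matching the source presentation; Holm correction is
available as an option.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .contacts import OcclusionConfig, build_contact_graph
from .geometry import PrimordiumFrame, mesh_volume
from .packing import ScoringMode, classify_pair, tabulate_calls
from .rotation import (
    RotationPattern,
    SectorMap,
    boundary_speed,
    call_rotation_pattern,
    classify_leading_edge,
    detect_events,
    rotation_trace,
)
from .synthetic import (
    MorphogenesisSchedule,
    PackingSpec,
    generate_tube,
    generate_trajectory,
    sample_diagonal_configs,
    trajectory_ground_truth,
    voxelize,
    wt_reference_schedule,
)

__all__ = [
    "ContactTable",
    "TestResult",
    "VolumeTrend",
    "fisher_contact_test",
    "volume_series",
    "run_pipeline",
]

log = logging.getLogger("gutmorph")


@dataclass
class ContactTable:
    """Per-ring percentages of each diagonal-contact category plus n."""

    table: pd.DataFrame
    condition: str = ""

    def __post_init__(self) -> None:
        pct = self.table.drop(columns=["n"], errors="ignore")
        sums = pct.sum(axis=1)
        if not np.allclose(sums, 100.0, atol=0.5):
            raise ValueError(f"table rows must sum to 100 +- 0.5, got {list(sums)}")
        if "n" in self.table and (self.table["n"] < 1).any():
            raise ValueError("each row needs n >= 1")

    def write_csv(self, path: str | Path) -> None:
        self.table.to_csv(path)

    def counts(self, collapse: str = "RaL") -> dict[str, np.ndarray]:
        """Per-ring (collapsed, other) integer counts reconstructed from
        percentages and n (used for exact tests)."""
        out = {}
        for ring, row in self.table.iterrows():
            n = int(row["n"])
            pct = row.drop("n")
            hits = sum(
                round(v * n / 100.0) for k, v in pct.items() if collapse in k
            )
            out[ring] = np.array([hits, n - hits], dtype=int)
        return out


@dataclass(frozen=True)
class TestResult:
    """A Fisher comparison: p-value, star level and the counts used."""

    __test__ = False  # not a pytest class, despite the name

    compared: str
    p_value: float
    counts: tuple[tuple[int, int], tuple[int, int]]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    @property
    def stars(self) -> int:
        if self.p_value < 5e-4:
            return 2
        if self.p_value < 0.05:
            return 1
        return 0

    def __str__(self) -> str:
        mark = "*" * self.stars
        return f"{self.compared}: p={self.p_value:.3g} {mark}".rstrip()


def _collapse(counts, collapse: str) -> tuple[int, int]:
    if isinstance(counts, Mapping):
        hit = sum(int(v) for k, v in counts.items() if collapse in str(k))
        other = sum(int(v) for v in counts.values()) - hit
        return hit, other
    a, b = (int(x) for x in counts)
    return a, b


def fisher_contact_test(
    counts_a,
    counts_b,
    collapse: str = "RaL",
    label: str = "A vs B",
) -> TestResult:
    """Two-sided Fisher's exact test between two contact populations.

    ``counts_a``/``counts_b`` are either ``(in-category, other)`` pairs or
    mappings from call category to count, which are collapsed to
    ``collapse`` vs the rest (default RaL vs non-RaL).  The p-value is the
    exact two-sided hypergeometric probability.
    """
    a = _collapse(counts_a, collapse)
    b = _collapse(counts_b, collapse)
    if min(a) < 0 or min(b) < 0:
        raise ValueError("counts must be non-negative")
    table = np.array([a, b])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError(f"degenerate 2x2 table with a zero margin: {table.tolist()}")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return TestResult(label, float(p), (a, b))


@dataclass
class VolumeTrend:
    """Per-cell volumes over time plus a linear-trend permutation test.

    ``flat`` is true when no cell's volume slope is significant at
    ``alpha`` - the expected outcome for rigid kinematics, and what the
    reconstruction showed over the imaged interval.
    """

    volumes: pd.DataFrame  # index time, one column per cell
    slopes: pd.Series
    p_values: pd.Series
    alpha: float = 0.05

    @property
    def flat(self) -> bool:
        return bool((self.p_values >= self.alpha).all())


def volume_series(
    frames: Sequence[PrimordiumFrame],
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> VolumeTrend:
    """Measure every cell's volume per frame and test for a linear trend.

    The trend test permutes the time order of each cell's volumes
    (``n_perm`` draws, seeded) and reports the two-sided fraction of
    permuted slopes at least as extreme as the observed one.
    """
    if len(frames) < 3:
        raise ValueError("volume trend needs >= 3 frames")
    cells = sorted({str(c.owner) for f in frames for c in f.cells})
    times = np.array([f.time for f in frames], dtype=float)
    vols = pd.DataFrame(index=times, columns=cells, dtype=float)
    for f in frames:
        for c in f.cells:
            vols.loc[f.time, str(c.owner)] = mesh_volume(c)
    rng = np.random.default_rng(seed)
    t = (times - times.mean()) / (times.std() or 1.0)
    slopes = {}
    pvals = {}
    for cell in cells:
        v = vols[cell].to_numpy()
        ok = ~np.isnan(v)
        if ok.sum() < 3:
            slopes[cell] = np.nan
            pvals[cell] = np.nan
            continue
        obs = np.polyfit(t[ok], v[ok], 1)[0]
        perm = np.empty(n_perm)
        vv = v[ok]
        tt = t[ok]
        for i in range(n_perm):
            perm[i] = np.polyfit(tt, rng.permutation(vv), 1)[0]
        pvals[cell] = (1 + np.sum(np.abs(perm) >= abs(obs))) / (n_perm + 1)
        slopes[cell] = obs
    return VolumeTrend(vols, pd.Series(slopes), pd.Series(pvals), alpha)


# ---------------------------------------------------------------------------
# pipeline


def _plot_traces(traces, path: Path) -> None:
    """Boundary angles vs time, one panel, degrees from the dorsal midline."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for ring, tr in sorted(traces.items()):
        ax.plot(tr.times, tr.theta_boundary_1, label=f"int{ring} dorsal boundary")
        ax.plot(tr.times, tr.theta_boundary_2, ls="--", label=f"int{ring} ventral")
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("degrees from dorsal midline (cw positive)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config, "rb") as fh:
            return tomllib.load(fh)
    return dict(config)


def _spec_from_config(sim: Mapping, seed: int | None) -> PackingSpec:
    kw = {}
    for key in (
        "n_rings",
        "circumference",
        "ring_height",
        "radial_thickness",
        "p_RaL",
        "p_LaR",
        "p_Cross",
        "diagonal_offset_deg",
    ):
        if key in sim:
            kw[key] = sim[key]
    if sim.get("ring1_cells", 2) == 4:
        kw["cells_per_ring"] = {1: 4}
    kw["seed"] = seed if seed is not None else sim.get("seed", 0)
    return PackingSpec(**kw)


def run_pipeline(config, out_dir: str | Path | None = None, seed: int | None = None) -> dict:
    """Run the configured analyses and write a deterministic report bundle.

    ``config`` is a TOML path or a dict with a ``[simulate]`` block (or
    stack inputs handled upstream) plus optional ``[contacts]``,
    ``[classify]``, ``[rotation]`` and ``[report]`` blocks.  The same
    config and seed produce byte-identical CSV/JSON outputs; progress goes
    to the logger, never into the report files.
    """
    cfg = _load_config(config)
    report_cfg = cfg.get("report", {})
    out = Path(out_dir or report_cfg.get("out_dir", "gutmorph_report"))
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, object] = {"out_dir": str(out)}

    sim = cfg.get("simulate")
    if sim is None:
        raise ValueError("config needs a [simulate] block (label-stack input "
                         "is handled by the imaging API / `gutmorph extract`)")
    spec = _spec_from_config(sim, seed)
    occ = OcclusionConfig(
        contact_threshold=cfg.get("contacts", {}).get("threshold", 0.5),
        face_subdivision=cfg.get("contacts", {}).get("face_subdivision", 0.25),
    )
    log.info("simulating with seed %s", spec.seed)

    if sim.get("trajectory", False):
        stage = "simulate trajectory"
        try:
            mode = int(sim.get("int2_mode", 1))
            schedule = wt_reference_schedule(mode)
            t0 = float(sim.get("t_start", 249.0))
            t1 = float(sim.get("t_end", 441.0))
            dt = float(sim.get("dt", 8.0))
            base = [{"interface": 2, "dorsal": "Cross", "ventral": "Cross"}] + [
                {"interface": n, "dorsal": "LaR", "ventral": "LaR"}
                for n in range(3, spec.n_rings + 1)
            ]
            frames = generate_trajectory(spec, schedule, t0, t1, dt, configs=base)
        except Exception as err:
            raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err
        gt = trajectory_ground_truth(frames)
        gt.to_csv(out / "ground_truth.csv", index=False)
        written["ground_truth"] = str(out / "ground_truth.csv")

        if cfg.get("rotation", {}).get("enabled", True):
            stage = "rotation analysis"
            try:
                rings = cfg.get("rotation", {}).get("rings", [2, 3, 4])
                window = tuple(cfg.get("rotation", {}).get("window", (393.0, 441.0)))
                traces = {r: rotation_trace(frames, r) for r in rings}
                trace_df = pd.concat([t.to_dataframe() for t in traces.values()])
                trace_df.to_csv(out / "rotation_traces.csv", index=False)
                _plot_traces(traces, out / "rotation_traces.png")
                pattern = call_rotation_pattern(traces, window)
                speeds = {
                    r: boundary_speed(tr, spec.circumference)
                    for r, tr in traces.items()
                }
                flags = detect_events(frames)
                sectors = SectorMap()
                leading = classify_leading_edge(frames[-1], rings[0], sectors)
                payload = {
                    "pattern_category": pattern.category,
                    "per_ring": {str(k): v for k, v in pattern.per_ring.items()},
                    "direction": {str(k): v for k, v in pattern.direction.items()},
                    "window_min": list(window),
                    "boundary_speed_um_per_min": speeds,
                    "events": {
                        "pre_rotation_shift_2L": flags.pre_rotation_shift_2L,
                        "shift_onset_min": flags.shift_onset,
                        "int2_mode": flags.int2_mode,
                        "int7_direction": flags.int7_direction,
                    },
                    "leading_edge_final": {str(k): v for k, v in leading.items()},
                    "sector_map": sectors.to_dict(),
                }
                (out / "rotation.json").write_text(json.dumps(payload, indent=1))
                written["rotation"] = str(out / "rotation.json")
            except Exception as err:
                raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

        if cfg.get("volumes", {}).get("enabled", True):
            stage = "volume series"
            try:
                vt = volume_series(frames, seed=spec.seed)
                vt.volumes.to_csv(out / "volumes.csv")
                summary = pd.DataFrame(
                    {"slope": vt.slopes, "p_value": vt.p_values}
                )
                summary.to_csv(out / "volume_trend.csv")
                written["volumes_flat"] = vt.flat
            except Exception as err:
                raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err
        frame_for_contacts = frames[-1]
    else:
        stage = "simulate tube"
        try:
            configs = sample_diagonal_configs(spec)
            frame_for_contacts = generate_tube(spec, configs)
        except Exception as err:
            raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err
        pd.DataFrame(frame_for_contacts.meta["configs"]).to_csv(
            out / "ground_truth.csv", index=False
        )
        written["ground_truth"] = str(out / "ground_truth.csv")
        if sim.get("write_stack", False):
            from .imaging import write_label_stack

            stage = "voxelize"
            try:
                stack, lmap = voxelize(frame_for_contacts)
                write_label_stack(stack, lmap, out / "labels.tif")
                written["stack"] = str(out / "labels.tif")
            except Exception as err:
                raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    if cfg.get("contacts", {}).get("enabled", True):
        stage = "contact graph"
        try:
            graph = build_contact_graph(frame_for_contacts, occ)
            graph.write_csv(out / "contacts.csv")
            written["contacts"] = str(out / "contacts.csv")
        except Exception as err:
            raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err
    else:
        graph = None

    if cfg.get("classify", {}).get("enabled", True):
        stage = "packing classification"
        try:
            mode = ScoringMode(cfg.get("classify", {}).get("mode", "whole_surface"))
            calls = []
            for ring in frame_for_contacts.rings:
                if ring == 1:
                    continue
                try:
                    calls.append(
                        classify_pair(graph, frame_for_contacts, ring, mode, config=occ)
                    )
                except ValueError as err:
                    log.warning("ring %s skipped: %s", ring, err)
            if calls:
                table = tabulate_calls(calls)
                table.write_csv(out / "contact_table.csv")
                written["contact_table"] = str(out / "contact_table.csv")
        except Exception as err:
            raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    manifest = {
        "seed": spec.seed,
        "spec": frame_for_contacts.meta.get("spec", {}),
        "outputs": {k: v for k, v in written.items() if k != "out_dir"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return written
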