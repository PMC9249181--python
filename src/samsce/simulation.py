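"""Tissue initialisation and the two-stage simulation driver.

A run starts from an organised array of 50 circular cells in seven layers
(top row L1, then L2, layers 3-4 apical corpus, 5-7 basal corpus; left/right
columns are non-dividing boundary cells and the bottom row is the heavily
damped stem foundation).  Stage one relaxes the tiling mechanically for 15
simulated minutes with polarizations assigned but no growth or division;
stage two grows the tissue, updating signal fields and behaviours on a fixed
interval, adding cytoplasm nodes, and dividing cells that reach the mitotic
threshold with the configured division-plane mechanism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import growth as growth_mod
from . import signaling
from .config import SimulationConfig, to_dict
from .errors import AreaWindowError
from .mechanics import Engine
from .tissue import Cell, DivisionEvent, Tissue


@dataclass
class RunResult:
    """Everything a single run produces."""

    config: SimulationConfig
    tissue: Tissue
    events: list[DivisionEvent]
    snapshots: list[tuple[float, pd.DataFrame]]  # (time_h, cell summary table)
    relax_residual_trace: list[float]
    metadata: dict = field(default_factory=dict)


def _rngs(seed: int):
    """Independent child generators per subsystem for reproducibility."""
    ss = np.random.SeedSequence(seed)
    names = ("behavior", "cycle", "geometry")
    children = ss.spawn(len(names))
    return dict(zip(names, (np.random.default_rng(c) for c in children)))


def _circle_ring(center, radius, n, phase=0.0):
    ang = phase + 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([center[0] + radius * np.cos(ang),
                            center[1] + radius * np.sin(ang)])


def _sunflower(center, radius, m, rng):
    """Deterministic low-discrepancy disc fill with a small jitter."""
    if m == 0:
        return np.empty((0, 2))
    k = np.arange(1, m + 1)
    r = radius * np.sqrt((k - 0.5) / m)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    ang = k * golden
    pts = np.column_stack([center[0] + r * np.cos(ang),
                           center[1] + r * np.sin(ang)])
    pts += rng.normal(scale=0.02 * radius, size=pts.shape)
    return pts


def build_initial_tissue(config: SimulationConfig) -> Tissue:
    """50 circular cells in 7 staggered layers with initial adhesion pairs."""
    config.validate()
    rngs = _rngs(config.seed)
    geo = rngs["geometry"]
    r0 = config.initial_cell_radius
    pitch_x = 2.0 * r0
    pitch_y = 1.8 * r0  # staggered rows sit closer than one diameter
    rows = config.row_counts
    n_rows = len(rows)
    tissue = Tissue()
    for row, count in enumerate(rows):
        layer = row + 1
        y = (n_rows - 1 - row) * pitch_y
        # alternate quarter-pitch shifts: adjacent rows stagger by half a cell
        x0 = (-0.5 * (count - 1) * pitch_x
              + (0.25 * pitch_x if row % 2 else -0.25 * pitch_x))
        for k in range(count):
            cid = tissue.new_cell_id()
            center = np.array([x0 + k * pitch_x, y])
            ring = _circle_ring(center, r0, config.n_ring_nodes)
            internal = _sunflower(center, 0.55 * r0,
                                  config.initial_internal_nodes, geo)
            stem = row == n_rows - 1
            boundary = k in (0, count - 1) and not stem
            eta = (config.mechanics.eta_stem if stem
                   else config.mechanics.eta_default)
            cell = Cell(cid, ring, internal, layer, eta,
                        boundary=boundary, stem=stem)
            tissue.add_cell(cell)
    tissue.rebuild_adhesion(config.mechanics.adh_pair_cutoff)

    signals = config.effective_signals()
    signaling.update_signals(tissue, signals)
    for cid in tissue.cell_ids():
        cell = tissue.cells[cid]
        signaling.draw_behavior(cell, rngs["behavior"], signals)
        growth_mod.assign_polarization(cell)
        growth_mod.partition_side_end(cell, cell.polarization,
                                      config.growth.side_end_angle_threshold,
                                      config.mechanics)
        signaling.assign_cycle_length(cell, rngs["cycle"], signals)
    return tissue


def relax(tissue: Tissue, config: SimulationConfig,
          engine: Engine | None = None) -> list[float]:
    """Stage one: mechanics-only settling of the initial tiling.

    Returns the max-residual-force trace sampled once per simulated minute.
    """
    engine = engine or Engine(tissue, config.mechanics)
    trace = []
    minutes = int(round(config.relax_duration_min))
    for _ in range(max(minutes, 1)):
        engine.advance(60.0 * config.relax_duration_min / max(minutes, 1),
                       scatter=False)
        trace.append(engine.max_residual_force())
    engine.flat.scatter(tissue)
    return trace


def _cell_summary(tissue: Tissue) -> pd.DataFrame:
    from . import geometry

    rows = []
    for cid in tissue.cell_ids():
        c = tissue.cells[cid]
        try:
            ratio, orient = geometry.aspect_ratio_and_orientation(c.wall)
        except Exception:
            ratio, orient = np.nan, np.nan
        rows.append(dict(cell_id=cid, role=c.role, lineage_layer=c.lineage_layer,
                         wus=c.wus, ck=c.ck, area=c.area(),
                         aspect_ratio=ratio, orientation=orient,
                         M_i=c.n_internal, N_i=c.n_wall,
                         centroid_x=c.centroid()[0], centroid_y=c.centroid()[1],
                         behavior=c.behavior,
                         cycle_length=c.cycle_length))
    return pd.DataFrame(rows)


def run(config: SimulationConfig) -> RunResult:
    """Full two-stage simulation; deterministic given the config and seed."""
    config.validate()
    signals = config.effective_signals()
    tissue = build_initial_tissue(config)
    rngs = _rngs(config.seed + 1)  # distinct streams for the growth stage
    engine = Engine(tissue, config.mechanics)
    residuals = relax(tissue, config, engine)

    snapshots = [(0.0, _cell_summary(tissue))]
    interval_h = config.signal_interval_min / 60.0
    snap_h = config.snapshot_interval_min / 60.0
    next_snap = snap_h
    termination = "completed"
    t = 0.0
    while t < config.run_duration_h - 1e-9:
        dt_h = min(interval_h, config.run_duration_h - t)
        engine.advance(dt_h * 3600.0)
        t += dt_h
        tissue.time = t

        signaling.update_signals(tissue, signals)
        topology_changed = False
        for cid in tissue.cell_ids():
            cell = tissue.cells[cid]
            n_before = cell.n_wall
            added = growth_mod.grow_cell(cell, dt_h, rngs["geometry"],
                                         config.growth, config.mechanics.ell)
            if added or cell.n_wall != n_before:
                topology_changed = True

        for cid in tissue.cell_ids():
            cell = tissue.cells.get(cid)
            if cell is None or not growth_mod.ready_to_divide(cell, config.growth):
                continue
            if len(tissue) >= config.max_cells:
                termination = "max_cells"
                break
            try:
                plane = growth_mod.compute_plane(cell, tissue, config)
            except AreaWindowError:
                continue  # retry at the next interval
            out = growth_mod.execute_division(cell, plane, tissue,
                                              rngs["behavior"], config, signals)
            if out is not None:
                topology_changed = True

        if topology_changed:
            tissue.rebuild_adhesion(config.mechanics.adh_pair_cutoff)
            engine.refresh()
        if termination == "max_cells":
            break
        if t + 1e-9 >= next_snap:
            snapshots.append((t, _cell_summary(tissue)))
            next_snap += snap_h
    if not snapshots or snapshots[-1][0] < t - 1e-9:
        snapshots.append((t, _cell_summary(tissue)))

    meta = dict(seed=config.seed, config_hash=config.config_hash(),
                termination=termination, final_time_h=t,
                n_cells=len(tissue), n_events=len(tissue.events))
    return RunResult(config=config, tissue=tissue, events=tissue.events,
                     snapshots=snapshots, relax_residual_trace=residuals,
                     metadata=meta)


def run_batch(config: SimulationConfig):
    """Replicate runs with seeds seed, seed+1, ... and a pooled summary.

    A failing replicate is recorded (exception text in the summary row) and
    the batch continues.
    """
    from dataclasses import replace

    results: list[RunResult | None] = []
    rows = []
    for i in range(config.replicates):
        cfg = replace(config, seed=config.seed + i, replicates=1)
        try:
            res = run(cfg)
            results.append(res)
            ev = res.events
            n_pc = sum(1 for e in ev if e.classification == "periclinal")
            rows.append(dict(replicate=i, seed=cfg.seed, status="ok",
                             n_cells=len(res.tissue), n_events=len(ev),
                             periclinal_fraction=(n_pc / len(ev)) if ev else np.nan))
        except Exception as exc:  # pragma: no cover - defensive
            results.append(None)
            rows.append(dict(replicate=i, seed=cfg.seed,
                             status=f"failed: {exc}", n_cells=0, n_events=0,
                             periclinal_fraction=np.nan))
    summary = pd.DataFrame(rows)
    n_ev = sum(len(r.events) for r in results if r is not None)
    n_pc = sum(sum(1 for e in r.events if e.classification == "periclinal")
               for r in results if r is not None)
    # pooled fraction = event-count-weighted mean of the replicate fractions
    summary.attrs["pooled_periclinal_fraction"] = (n_pc / n_ev) if n_ev else None
    return results, summary
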