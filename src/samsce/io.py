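"""CSV/JSON output of tissue snapshots, division logs and run metadata."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig, dump_config
from .tissue import REGION_NAMES, DivisionEvent, Tissue

NODE_COLUMNS = ["cell_id", "node_kind", "ring_index", "x", "y", "region_label",
                "adhesion_partner_cell", "adhesion_partner_index"]
EVENT_COLUMNS = ["time_h", "mother_id", "daughter_a", "daughter_b", "mechanism",
                 "plane_x1", "plane_y1", "plane_x2", "plane_y2",
                 "plane_angle_deg", "classification", "area_ratio",
                 "mother_lineage_layer", "mother_role", "window_widened"]


def nodes_frame(tissue: Tissue) -> pd.DataFrame:
    rows = []
    for cid in tissue.cell_ids():
        c = tissue.cells[cid]
        for j in range(c.n_wall):
            rows.append((cid, "wall", j, c.wall[j, 0], c.wall[j, 1],
                         REGION_NAMES[int(c.region[j])],
                         int(c.adh_cell[j]), int(c.adh_idx[j])))
        for j in range(c.n_internal):
            rows.append((cid, "internal", j, c.internal[j, 0], c.internal[j, 1],
                         "", -1, -1))
    return pd.DataFrame(rows, columns=NODE_COLUMNS)


def events_frame(events: list[DivisionEvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        (x1, y1), (x2, y2) = e.plane
        rows.append((e.time, e.mother_id, e.daughter_ids[0], e.daughter_ids[1],
                     e.mechanism, x1, y1, x2, y2, e.plane_angle_deg,
                     e.classification, e.area_ratio, e.mother_lineage_layer,
                     e.mother_role, e.window_widened))
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_run(result, outdir) -> Path:
    """Write snapshots, the division log and run metadata under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for t, frame in result.snapshots:
        frame.to_csv(out / f"cells_t{t:07.2f}h.csv", index=False,
                     float_format="%.6f")
    nodes_frame(result.tissue).to_csv(out / "nodes_final.csv", index=False,
                                      float_format="%.6f")
    events_frame(result.events).to_csv(out / "events.csv", index=False)
    (out / "config.yaml").write_text(dump_config(result.config))
    with open(out / "metadata.json", "w") as fh:
        json.dump(result.metadata, fh, indent=2, default=str)
    return out


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path)
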