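"""Steady-state WUS/CK fields, the Hill behaviour switch and cycle lengths.

WUSCHEL (WUS) and cytokinin (CK) concentrations are prescribed steady-state
exponential gradients, radially symmetric about dynamically tracked signal
centres located below the apex of the tissue:

    [WUS] = wus0 * exp(-mu_wus * (r_wus * alpha_wus))
    [CK]  = ck0  * exp(-mu_ck  * (r_ck  * alpha_ck))

with r the distance from a cell centroid to the respective centre.  CK is
held at zero in the tunica (L1/L2), which lacks CK responsiveness.  A cell's
periclinal/anticlinal behaviour is a Bernoulli draw with a Hill response in
the signal ratio lambda = [CK]/[WUS]; cycle lengths are normal draws whose
mean increases affinely with [WUS] (central high-WUS cells cycle slower).
"""

from __future__ import annotations

import numpy as np

from .config import SignalParams
from .errors import InvalidTissueError
from .tissue import Cell, Tissue


def locate_signal_centers(tissue: Tissue) -> tuple[np.ndarray, np.ndarray]:
    """WUS and CK signal centres tracking the growing apex.

    The central L1 cell is the L1 cell with the apically highest centroid;
    the centres sit directly below it at depths of two (WUS) and three (CK)
    mean tunica cell diameters.  Recomputed at every signal update so the
    centres follow the dome.
    """
    l1 = tissue.layer_cells(1)
    if not l1:
        raise InvalidTissueError("tissue has no L1 cells")
    apex = max(l1, key=lambda c: c.centroid()[1])
    apex_centroid = apex.centroid()
    tunica = tissue.tunica_cells()
    d = float(np.mean([c.equivalent_diameter() for c in tunica]))
    wus_center = apex_centroid - np.array([0.0, 2.0 * d])
    ck_center = apex_centroid - np.array([0.0, 3.0 * d])
    return wus_center, ck_center


def signal_levels(cell: Cell, centers, params: SignalParams) -> tuple[float, float]:
    """([WUS], [CK]) for one cell given the current signal centres."""
    wus_center, ck_center = centers
    c = cell.centroid()
    r_wus = float(np.linalg.norm(c - wus_center))
    wus = params.wus0 * np.exp(-params.mu_wus * (r_wus * params.alpha_wus))
    if cell.is_tunica:
        ck = 0.0
    else:
        r_ck = float(np.linalg.norm(c - ck_center))
        ck = params.ck0 * np.exp(-params.mu_ck * (r_ck * params.alpha_ck))
    return float(wus), float(ck)


def update_signals(tissue: Tissue, params: SignalParams) -> None:
    """Recompute centres and all per-cell signal levels in place."""
    centers = locate_signal_centers(tissue)
    tissue.wus_center, tissue.ck_center = centers
    for cid in tissue.cell_ids():
        cell = tissue.cells[cid]
        cell.wus, cell.ck = signal_levels(cell, centers, params)


def compute_k_hill(params: SignalParams, diameter: float | None = None) -> float:
    """Hill threshold: the signal ratio at the midpoint of the two domains.

    The midpoint sits at depth 2.5 d below the apex, i.e. half a cell
    diameter from each centre, so by construction a cell there has equally
    probable periclinal and anticlinal behaviour.
    """
    d = params.ref_cell_diameter if diameter is None else diameter
    r = 0.5 * d
    wus = params.wus0 * np.exp(-params.mu_wus * (r * params.alpha_wus))
    ck = params.ck0 * np.exp(-params.mu_ck * (r * params.alpha_ck))
    return float(ck / wus)


def resolved_k_hill(params: SignalParams) -> float:
    return params.k_hill if params.k_hill is not None else compute_k_hill(params)


def periclinal_probability(wus: float, ck: float, params: SignalParams) -> float:
    """Hill response in lambda = [CK]/[WUS].

    p = 1 / (1 + (K/lambda)^N); p -> 0 as CK -> 0.  The WUS = 0 corner, not
    defined by the ratio, takes its continuity limit: 1 if CK > 0 else 0.
    """
    if ck <= 0.0:
        return 0.0
    if wus <= 0.0:
        return 1.0
    lam = ck / wus
    k = resolved_k_hill(params)
    return float(1.0 / (1.0 + (k / lam) ** params.n_hill))


def draw_behavior(cell: Cell, rng: np.random.Generator,
                  params: SignalParams) -> str:
    """Bernoulli behaviour draw, cached on the cell until its next division."""
    p = periclinal_probability(cell.wus, cell.ck, params)
    cell.behavior = "periclinal" if rng.random() < p else "anticlinal"
    return cell.behavior


def assign_cycle_length(cell: Cell, rng: np.random.Generator,
                        params: SignalParams) -> float:
    """Cycle length (h) drawn at birth from Normal(mean([WUS]), sd)."""
    mean = params.cycle_mean(cell.wus)
    sd = params.cycle_sd_frac * mean
    draw = rng.normal(mean, sd) if sd > 0 else mean
    cell.cycle_length = float(max(draw, 0.1 * mean))
    return cell.cycle_length
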