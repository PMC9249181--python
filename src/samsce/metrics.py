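"""Cell- and tissue-level readouts used to compare division mechanisms.

All comparisons between mechanisms and conditions in this package go through
these metrics: division classification proportions, mother/daughter and
elongation classifications, cell heights and widths, layer-organisation
deviation, dome width-to-height ratio and surface curvature, WUS distribution
summaries, mean wall tensile stress, and periclinal "strip" detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry, mechanics
from .config import MechanicsParams, SignalParams
from .tissue import DivisionEvent, Tissue

ELONGATION_THRESHOLD = 1.3  # aspect ratio above which a cell counts as elongated

CORPUS_REGIONS = {"apical_corpus": (3, 4), "basal_corpus": (5, 6, 7),
                  "corpus": (3, 4, 5, 6, 7), "L1": (1,), "L2": (2,),
                  "tunica": (1, 2)}


def _region_layers(region: str) -> tuple[int, ...]:
    try:
        return CORPUS_REGIONS[region]
    except KeyError:
        raise ValueError(f"unknown region {region!r}") from None


def classify_cells(tissue: Tissue) -> pd.DataFrame:
    """Mother/daughter (by area vs the tissue mean) and elongated flags.

    A cell is a "mother" if its area exceeds the tissue-mean area (recently
    divided daughters are small), and "elongated" if its aspect ratio exceeds
    1.3, the threshold above which a planar section reliably reflects the
    cell's three-dimensional elongation axis.
    """
    rows = []
    for cid in tissue.cell_ids():
        c = tissue.cells[cid]
        try:
            ratio, orient = geometry.aspect_ratio_and_orientation(c.wall)
        except Exception:
            ratio, orient = np.nan, np.nan
        rows.append(dict(cell_id=cid, role=c.role, lineage_layer=c.lineage_layer,
                         area=c.area(), aspect_ratio=ratio, orientation=orient))
    df = pd.DataFrame(rows)
    mean_area = df["area"].mean()
    # strict comparison with an fp guard: identical areas are all daughters
    df["is_mother"] = df["area"] > mean_area * (1 + 1e-9)
    df["is_elongated"] = df["aspect_ratio"] > ELONGATION_THRESHOLD
    return df


def periclinal_fraction(events: list[DivisionEvent], region: str) -> float | None:
    """Fraction of periclinal divisions among events of mothers in a region.

    Returns ``None`` (an undefined flag, not zero) when the region recorded
    no events.
    """
    layers = _region_layers(region)
    sel = [e for e in events if e.mother_lineage_layer in layers]
    if not sel:
        return None
    return sum(e.classification == "periclinal" for e in sel) / len(sel)


def heights_widths(cells) -> np.ndarray:
    """(n, 2) array of per-cell (height, width): bounding-box extents in um."""
    out = []
    for c in cells:
        w = c.wall
        out.append((w[:, 1].max() - w[:, 1].min(), w[:, 0].max() - w[:, 0].min()))
    return np.asarray(out)


def layer_deviation(tissue: Tissue, lineage_layer: int,
                    window: int = 5) -> float | None:
    """RMS perpendicular residual of a layer's centroids from a smooth curve.

    Centroids are ordered by x and fit with a moving-window quadratic
    (window of 5); the score is the RMS distance of each centroid from its
    local fit, corrected for the local slope.  Zero for a perfectly layered
    (collinear or smoothly curved) arrangement; roughly half the inter-row
    distance when two stacked rows are tagged as one layer.  ``None`` if the
    layer has fewer than 3 cells.
    """
    cells = tissue.layer_cells(lineage_layer)
    if len(cells) < 3:
        return None
    pts = np.array([c.centroid() for c in cells])
    pts = pts[np.argsort(pts[:, 0], kind="stable")]
    n = len(pts)
    half = window // 2
    res = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        xs, ys = pts[lo:hi, 0], pts[lo:hi, 1]
        deg = min(2, len(xs) - 1)
        coef = np.polyfit(xs, ys, deg)
        fit = np.polyval(coef, pts[i, 0])
        slope = np.polyval(np.polyder(coef), pts[i, 0]) if deg >= 1 else 0.0
        res[i] = (pts[i, 1] - fit) / np.sqrt(1.0 + slope * slope)
    return float(np.sqrt(np.mean(res ** 2)))


def _surface_nodes(tissue: Tissue) -> np.ndarray:
    """Outer (partner-less, upper) wall nodes of L1 cells: the dome surface."""
    pts = []
    for c in tissue.layer_cells(1):
        cy = c.centroid()[1]
        free = (c.adh_cell < 0) & (c.wall[:, 1] >= cy)
        pts.append(c.wall[free])
    return np.vstack(pts) if pts else np.empty((0, 2))


def fit_circle(points: np.ndarray):
    """Least-squares (Kasa) circle fit; returns (cx, cy, R) or None."""
    x, y = points[:, 0], points[:, 1]
    A = np.column_stack([x, y, np.ones_like(x)])
    b = x * x + y * y
    try:
        sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    except np.linalg.LinAlgError:
        return None
    if rank < 3:  # collinear points: no unique circle
        return None
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cx * cx + cy * cy
    if not np.isfinite(r2) or r2 <= 0:
        return None
    return cx, cy, float(np.sqrt(r2))


def dome_shape(tissue: Tissue) -> tuple[float, float]:
    """(width-to-height ratio, global surface curvature 1/um) of the dome.

    Width is the horizontal span of the L1 surface nodes; dome height the
    vertical distance from the top of the stem row to the apex node;
    curvature is 1/R of the least-squares circle through the surface nodes
    (0 for a collinear/singular surface).
    """
    surf = _surface_nodes(tissue)
    if len(surf) == 0:
        raise ValueError("tissue has no L1 surface nodes")
    width = float(surf[:, 0].max() - surf[:, 0].min())
    stem = [c for c in tissue.cells.values() if c.stem]
    stem_top = max(float(c.wall[:, 1].max()) for c in stem) if stem else \
        float(min(surf[:, 1]))
    apex_y = float(surf[:, 1].max())
    height = max(apex_y - stem_top, 1e-9)
    fit = fit_circle(surf)
    if fit is None:
        curvature = 0.0
    else:
        _, _, r = fit
        # collinear points produce a huge fitted radius -> curvature ~ 0
        curvature = 1.0 / r if np.isfinite(r) and r > 1e-9 else 0.0
    return width / height, curvature


def wus_summaries(tissue: Tissue, params: SignalParams,
                  threshold_frac: float = 0.5,
                  bin_width: float | None = None):
    """(radial WUS profile, high-WUS L1 count).

    The profile is the mean [WUS] in horizontal-distance bins from the apex
    axis (bin width of one reference cell diameter by default).  The count is
    the number of L1 cells whose [WUS] exceeds ``threshold_frac`` times the
    tissue maximum.
    """
    l1 = tissue.layer_cells(1)
    if not l1:
        raise ValueError("tissue has no L1 cells")
    apex_x = max(l1, key=lambda c: c.centroid()[1]).centroid()[0]
    bw = bin_width or params.ref_cell_diameter
    cells = [tissue.cells[cid] for cid in tissue.cell_ids()]
    r = np.array([abs(c.centroid()[0] - apex_x) for c in cells])
    wus = np.array([c.wus for c in cells])
    nbins = int(np.ceil((r.max() + 1e-9) / bw)) or 1
    idx = np.minimum((r / bw).astype(int), nbins - 1)
    profile = np.full(nbins, np.nan)
    for b in range(nbins):
        sel = idx == b
        if sel.any():
            profile[b] = wus[sel].mean()
    wmax = wus.max()
    high = sum(1 for c in l1 if c.wus > threshold_frac * wmax)
    return profile, int(high)


def region_stress(tissue: Tissue, region: str,
                  params: MechanicsParams) -> float | None:
    """Mean in-plane tensile wall stress over a region's wall nodes."""
    layers = _region_layers(region)
    vals = []
    for cid in tissue.cell_ids():
        c = tissue.cells[cid]
        if c.lineage_layer in layers:
            vals.append(mechanics.cell_stresses(c, params))
    if not vals:
        return None
    return float(np.concatenate(vals).mean())


def strip_histogram(events: list[DivisionEvent],
                    live_cell_ids=None) -> dict[int, int]:
    """Histogram of periclinal strip sizes from the division log.

    A strip is a maximal clonal group whose internal divisions were all
    periclinal: k-1 sequential periclinal divisions yield one strip of k
    stacked cells.  An anticlinal division splits the chain (its daughters
    found fresh singleton components).  Only strips of size >= 2 are
    reported; if ``live_cell_ids`` is given, components are counted over
    those cells, otherwise over all leaves of the lineage forest.
    """
    comp: dict[int, int] = {}
    next_comp = 0
    alive: set[int] = set()
    for e in events:
        mother_comp = comp.get(e.mother_id)
        if mother_comp is None:
            mother_comp = next_comp
            next_comp += 1
        alive.discard(e.mother_id)
        for d in e.daughter_ids:
            if e.classification == "periclinal":
                comp[d] = mother_comp
            else:
                comp[d] = next_comp
                next_comp += 1
            alive.add(d)
    if live_cell_ids is not None:
        alive = set(live_cell_ids) & set(comp)
    sizes: dict[int, int] = {}
    for cid in alive:
        sizes[comp[cid]] = sizes.get(comp[cid], 0) + 1
    hist: dict[int, int] = {}
    for k in sizes.values():
        if k >= 2:
            hist[k] = hist.get(k, 0) + 1
    return dict(sorted(hist.items()))


def strip_histogram_by_region(events, region: str,
                              live_cell_ids=None) -> dict[int, int]:
    layers = _region_layers(region)
    sel = [e for e in events if e.mother_lineage_layer in layers]
    return strip_histogram(sel, live_cell_ids)


@dataclass
class MetricsReport:
    """Bundle of all readouts of one run."""

    periclinal_fractions: dict = field(default_factory=dict)
    region_stresses: dict = field(default_factory=dict)
    cell_table: pd.DataFrame | None = None
    layer_deviations: dict = field(default_factory=dict)
    width_height_ratio: float = np.nan
    global_curvature: float = np.nan
    wus_radial_profile: np.ndarray | None = None
    high_wus_l1_count: int = 0
    strip_size_histogram: dict = field(default_factory=dict)


def compute_report(tissue: Tissue, events, mech: MechanicsParams,
                   signals: SignalParams) -> MetricsReport:
    rep = MetricsReport()
    for region in ("apical_corpus", "basal_corpus", "tunica"):
        rep.periclinal_fractions[region] = periclinal_fraction(events, region)
        rep.region_stresses[region] = region_stress(tissue, region, mech)
    rep.cell_table = classify_cells(tissue)
    for layer in (1, 2):
        rep.layer_deviations[layer] = layer_deviation(tissue, layer)
    rep.width_height_ratio, rep.global_curvature = dome_shape(tissue)
    rep.wus_radial_profile, rep.high_wus_l1_count = wus_summaries(tissue, signals)
    rep.strip_size_histogram = strip_histogram(events,
                                               live_cell_ids=set(tissue.cells))
    return rep
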