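"""Polarized growth, wall maintenance and the division-plane mechanisms.

Growth direction polarization
-----------------------------
A cell's cached behaviour draw sets its elongation axis ``v``: periclinal
(CK-dominant) cells polarize apical-basally, anticlinal (WUS-dominant) cells
radially; boundary cells grow isotropically.  Wall segments aligned with
``v`` (within a threshold angle) are "sides" carrying stiff, flat rotational
springs; the rest are "ends" with loose springs preferring a circular
arrangement, so turgor-driven expansion is channelled along ``v``.

Division mechanisms
-------------------
* ``CAE-E``: shortest wall evenly dividing the area (Errera's rule).
* ``CAE-M``: plane anchored at the wall node under maximal in-plane tensile
  stress, closed by the partner that best balances the daughter areas.
* ``CED``: chemically determined: a horizontal plane when the behaviour draw
  is periclinal, a vertical one otherwise, placed to balance areas.
* L1/L2 cells always divide anticlinally, normal to the local surface
  (perpendicular to the segment joining their in-layer neighbours' centres).
* ``combined``: apical-corpus lineages (initial layers 3-4) divide by CAE-M,
  basal-corpus lineages (layers 5-7) by CED.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import geometry, mechanics, signaling
from .config import GrowthParams, MechanicsParams, SimulationConfig
from .errors import AreaWindowError, ConfigError
from .tissue import END, SIDE, Cell, DivisionEvent, Tissue

PERICLINAL_AXIS = np.array([0.0, 1.0])  # apical-basal elongation
ANTICLINAL_AXIS = np.array([1.0, 0.0])  # radial elongation


@dataclass(frozen=True)
class Plane:
    """A division plane anchored at two wall nodes of the mother ring."""

    node_a: int
    node_b: int
    mechanism: str  # CAE-E | CAE-M | CED | L1L2
    widened: bool = False


# ---------------------------------------------------------------------------
# polarization and wall-node partition

def assign_polarization(cell: Cell, rng=None) -> np.ndarray | None:
    """Elongation axis from the cached behaviour; boundary cells isotropic."""
    if cell.boundary:
        cell.polarization = None
    elif cell.behavior == "periclinal":
        cell.polarization = PERICLINAL_AXIS.copy()
    else:
        cell.polarization = ANTICLINAL_AXIS.copy()
    return cell.polarization


def partition_side_end(cell: Cell, v: np.ndarray | None, threshold_deg: float,
                       mech: MechanicsParams) -> None:
    """Label wall nodes side/end relative to ``v`` and set spring parameters.

    For each ring segment the acute angle to ``v`` is computed; segments
    within the threshold mark both flanking nodes as sides (stiff, flat
    equilibrium); all other nodes are ends (loose, circular equilibrium).
    ``v = None`` labels every node an end with uniform loose parameters.
    """
    n = cell.n_wall
    cell.region[:] = END
    if v is not None:
        seg = np.roll(cell.wall, -1, axis=0) - cell.wall
        seg_len = np.linalg.norm(seg, axis=1)
        safe = np.where(seg_len < 1e-12, 1.0, seg_len)
        cos_t = np.abs(seg @ np.asarray(v, float)) / safe
        ang = np.degrees(np.arccos(np.clip(cos_t, -1.0, 1.0)))
        aligned = ang < threshold_deg
        idx = np.nonzero(aligned)[0]
        cell.region[idx] = SIDE
        cell.region[(idx + 1) % n] = SIDE
    cell.k_bend = np.where(cell.region == SIDE, mech.k_bend_high, mech.k_bend_low)
    cell.refresh_theta_eq()


# ---------------------------------------------------------------------------
# growth

def grow_cell(cell: Cell, dt_h: float, rng: np.random.Generator,
              growth: GrowthParams, ell: float) -> int:
    """Add internal nodes linearly in time and maintain wall resolution.

    Cytoplasm nodes are added at rate (trigger - M_birth) / cycle_length so a
    newborn cell reaches the mitotic threshold after one cycle; each node is
    placed uniformly at random inside a disc of radius ``ell`` around the
    centroid (at the centroid after 10 failed in-polygon attempts).  Wall
    segments stretched beyond ``wall_insert_factor * ell`` get a midpoint
    node.  Non-dividing (boundary/stem) cells stop at the trigger count.
    """
    trigger = growth.division_trigger_nodes
    added = 0
    if np.isfinite(cell.cycle_length) and cell.cycle_length > 0:
        rate = max(trigger - cell.m_birth, 0) / cell.cycle_length
        cell.growth_quota += rate * dt_h
        n_add = int(cell.growth_quota)
        if not cell.divides:
            n_add = min(n_add, max(trigger - cell.n_internal, 0))
        else:
            # a cell whose division is deferred pauses shortly above the
            # trigger instead of inflating without bound
            cap = int(1.5 * trigger)
            n_add = min(n_add, max(cap - cell.n_internal, 0))
        if n_add > 0:
            cell.growth_quota -= n_add
            centroid = cell.centroid()
            pts = []
            for _ in range(n_add):
                pt = centroid
                for _attempt in range(10):
                    r = ell * math.sqrt(rng.random())
                    phi = 2.0 * math.pi * rng.random()
                    cand = centroid + r * np.array([math.cos(phi), math.sin(phi)])
                    if geometry.points_in_polygon(cell.wall, cand[None, :])[0]:
                        pt = cand
                        break
                pts.append(pt)
            cell.internal = np.vstack([cell.internal, np.asarray(pts)])
            added = n_add
    # wall maintenance: split overstretched segments (repeat for very long
    # ones) and merge crowded ones so compression cannot zigzag-fold the ring
    for _round in range(5):
        nxt = np.roll(cell.wall, -1, axis=0)
        spacing = np.linalg.norm(nxt - cell.wall, axis=1)
        over = np.nonzero(spacing > growth.wall_insert_factor * ell)[0]
        if len(over) == 0:
            break
        for j in sorted(over.tolist(), reverse=True):
            mid = 0.5 * (cell.wall[j] + cell.wall[(j + 1) % len(cell.wall)])
            cell.insert_wall_node(j, mid)
    # a node whose two edges would merge into a single short edge is excess
    # resolution left behind by compression; drop it so the rest length of
    # the ring tracks the actual perimeter
    for _round in range(24):  # one removal per pass; indices shift
        n = cell.n_wall
        if n <= 12:
            break
        merged = np.linalg.norm(np.roll(cell.wall, -1, axis=0)
                                - np.roll(cell.wall, 1, axis=0), axis=1)
        under = np.nonzero(merged < growth.wall_remove_factor * ell)[0]
        if len(under) == 0:
            break
        cell.remove_wall_node(int(under[np.argmin(merged[under])]))
    return added


def ready_to_divide(cell: Cell, growth: GrowthParams) -> bool:
    """Mitosis triggers at the internal-node threshold; boundary/stem never.

    A cell whose wall ring is still too coarse to carry a sensible plane
    (fewer than 12 nodes), is smaller than the size checkpoint, or is
    transiently tangled waits for growth, wall maintenance and mechanical
    relaxation to catch up first.
    """
    return (cell.divides and cell.n_internal >= growth.division_trigger_nodes
            and cell.n_wall >= 12 and cell.area() >= growth.min_division_area
            and geometry.is_simple_ring(cell.wall))


# ---------------------------------------------------------------------------
# plane constructions

def _pair_candidates(ring: np.ndarray, loss_per_len: float = 0.0):
    """Chord-split area ratios and distances for every node pair.

    ``loss_per_len`` accounts for the thin strip each daughter cedes when its
    new wall is offset off the chord at construction time (half an adhesion
    rest length per unit chord length); the ratio is evaluated on the
    corrected areas so the realised daughters satisfy the window.
    """
    a1, a2, valid = geometry.pair_split_areas(ring)
    diff = ring[None, :, :] - ring[:, None, :]
    dist = np.hypot(diff[..., 0], diff[..., 1])
    if loss_per_len:
        a1 = a1 - loss_per_len * dist
        a2 = a2 - loss_per_len * dist
    small = np.minimum(a1, a2)
    big = np.maximum(a1, a2)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(small > 1e-12, big / np.maximum(small, 1e-300), np.inf)
    return ratio, dist, valid


def _contained(ring: np.ndarray, i: int, j: int) -> bool:
    import shapely

    seg = shapely.LineString([ring[i], ring[j]])
    return bool(seg.covered_by(shapely.Polygon(ring)))


def directional_plane(ring: np.ndarray, direction: np.ndarray,
                      growth: GrowthParams, mechanism: str,
                      max_window: float = 3.0, loss_per_len: float = 0.0) -> Plane:
    """Even-area plane as close as possible to a prescribed direction.

    Among node pairs within the even-area window, pick the chord whose
    direction deviates least from ``direction`` (ties: shorter chord, then
    lower indices); the window is widened stepwise if infeasible.
    """
    ratio, dist, valid = _pair_candidates(ring, loss_per_len)
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    diff = ring[None, :, :] - ring[:, None, :]
    safe = np.where(dist < 1e-12, 1.0, dist)
    cos_t = np.abs(diff[..., 0] * d[0] + diff[..., 1] * d[1]) / safe
    ang = np.degrees(np.arccos(np.clip(cos_t, -1.0, 1.0)))
    window = growth.area_ratio_max
    widened = False
    while window <= max_window + 1e-9:
        mask = valid & (ratio <= window)
        if mask.any():
            ii, jj = np.nonzero(mask)
            order = np.lexsort((jj, ii, dist[ii, jj], np.round(ang[ii, jj], 3)))
            for k in order:
                i, j = int(ii[k]), int(jj[k])
                if _contained(ring, i, j):
                    return Plane(i, j, mechanism, widened)
        window += growth.area_window_widen_step
        widened = True
    raise AreaWindowError("no even-area plane exists for this ring")


def errera_plane(cell: Cell, growth: GrowthParams,
                 loss_per_len: float = 0.0, max_window: float = 3.0,
                 ring: np.ndarray | None = None) -> Plane:
    """Shortest wall evenly dividing the area (CAE-E)."""
    ring = cell.wall if ring is None else ring
    if len(ring) < 8:
        raise AreaWindowError("ring too coarse for a division plane")
    ratio, dist, valid = _pair_candidates(ring, loss_per_len)
    window = growth.area_ratio_max
    widened = False
    while window <= max_window + 1e-9:
        mask = valid & (ratio <= window)
        if mask.any():
            ii, jj = np.nonzero(mask)
            order = np.lexsort((jj, ii, dist[ii, jj]))
            for k in order:
                i, j = int(ii[k]), int(jj[k])
                if _contained(ring, i, j):
                    return Plane(i, j, "CAE-E", widened)
        window += growth.area_window_widen_step
        widened = True
    raise AreaWindowError("no even-area plane exists for this ring")


def stress_plane(cell: Cell, mech: MechanicsParams,
                 growth: GrowthParams, max_window: float = 3.0,
                 loss_per_len: float = 0.0,
                 ring: np.ndarray | None = None) -> Plane:
    """Plane anchored at the maximally stressed wall node (CAE-M).

    The partner anchor is the node that, paired with the stress anchor,
    best balances the daughter areas (ties broken by chord length).  A fully
    relaxed ring (all stresses ~0) falls back to the shortest-wall rule.
    A refined search ring (real nodes interleaved with edge midpoints) may be
    passed; the stress anchor always remains a real wall node.
    """
    s = mechanics.cell_stresses(cell, mech)
    if float(s.max()) < 1e-9 * max(mech.k_lin * mech.ell, 1.0):
        p = errera_plane(cell, growth, loss_per_len, ring=ring)
        return Plane(p.node_a, p.node_b, "CAE-M", p.widened)
    refined = ring is not None and len(ring) != cell.n_wall
    if ring is None:
        ring = cell.wall
    ratio, dist, valid = _pair_candidates(ring, loss_per_len)
    # anchors in decreasing stress order: if the most-stressed node admits no
    # containable even-area partner (curved cells), the next one is tried
    # before any window widening
    anchors = np.argsort(-s, kind="stable")[:10]
    window = growth.area_ratio_max
    widened = False
    while window <= max_window + 1e-9:
        for amax in anchors:
            jmax = int(amax) * 2 if refined else int(amax)
            cand = np.nonzero(valid[jmax, :] | valid[:, jmax])[0]
            r_row = np.where(valid[jmax, cand], ratio[jmax, cand],
                             ratio[cand, jmax])
            d_row = dist[jmax, cand]
            ok = r_row <= window
            if not ok.any():
                continue
            sel = cand[ok]
            order = np.lexsort((sel, d_row[ok], np.round(r_row[ok], 6)))
            for k in order:
                j = int(sel[k])
                if _contained(ring, jmax, j):
                    a, b = (jmax, j) if jmax < j else (j, jmax)
                    return Plane(a, b, "CAE-M", widened)
        window += growth.area_window_widen_step
        widened = True
    raise AreaWindowError("no even-area partner for the maximal-stress anchor")


def chemical_plane(cell: Cell, growth: GrowthParams,
                   loss_per_len: float = 0.0,
                   ring: np.ndarray | None = None) -> Plane:
    """Horizontal (periclinal draw) or vertical (anticlinal) even-area plane."""
    if cell.behavior == "periclinal":
        direction = np.array([1.0, 0.0])  # horizontal new wall
    else:
        direction = np.array([0.0, 1.0])
    return directional_plane(cell.wall if ring is None else ring, direction,
                             growth, "CED", loss_per_len=loss_per_len)


def l1_l2_plane(cell: Cell, tissue: Tissue, growth: GrowthParams,
                loss_per_len: float = 0.0,
                ring: np.ndarray | None = None) -> Plane:
    """Anticlinal plane normal to the local surface for tunica cells.

    The plane is perpendicular to the segment joining the centroids of the
    cell's nearest in-layer neighbours on either side; missing a neighbour
    (tissue edge), the surface tangent is estimated from the cell's own free
    (partner-less) wall nodes instead.
    """
    cx = cell.centroid()[0]
    peers = [c for c in tissue.layer_cells(cell.lineage_layer) if c.id != cell.id]
    left = [c for c in peers if c.centroid()[0] < cx]
    right = [c for c in peers if c.centroid()[0] > cx]
    if left and right:
        lc = max(left, key=lambda c: c.centroid()[0]).centroid()
        rc = min(right, key=lambda c: c.centroid()[0]).centroid()
        tangent = rc - lc
    else:
        free = cell.wall[cell.adh_cell < 0]
        pts = free if len(free) >= 2 else cell.wall
        pts = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts, full_matrices=False)
        tangent = vt[0]
    normal = np.array([-tangent[1], tangent[0]])
    return directional_plane(cell.wall if ring is None else ring, normal,
                             growth, "L1L2", loss_per_len=loss_per_len)


def select_mechanism(cell: Cell, config: SimulationConfig) -> str:
    """Which division rule applies to this cell under the configured model."""
    if cell.is_tunica:
        return "L1L2"
    if config.mechanism in ("CAE-E", "CAE-M", "CED"):
        return config.mechanism
    if config.mechanism == "combined":
        return "CAE-M" if cell.lineage_layer in (3, 4) else "CED"
    raise ConfigError(f"unknown mechanism {config.mechanism!r}")


def _interleaved(ring: np.ndarray) -> np.ndarray:
    """Ring with an edge midpoint between every pair of adjacent nodes."""
    mids = 0.5 * (ring + np.roll(ring, -1, axis=0))
    out = np.empty((2 * len(ring), 2))
    out[0::2] = ring
    out[1::2] = mids
    return out


def _realize_refined_anchors(cell: Cell, ri: int, rj: int) -> tuple[int, int]:
    """Turn anchors found on an interleaved ring into real wall nodes.

    Midpoint anchors (odd interleaved indices) are inserted into the cell's
    ring; returns the final (ascending) ring indices of both anchors.
    """
    final: dict[int, int] = {}
    for r in sorted({ri, rj}, reverse=True):
        if r % 2 == 0:
            final[r] = r // 2
        else:
            k = r // 2
            mid = 0.5 * (cell.wall[k] + cell.wall[(k + 1) % cell.n_wall])
            cell.insert_wall_node(k, mid)
            for key in final:
                if final[key] > k:
                    final[key] += 1
            final[r] = k + 1
    a, b = final[ri], final[rj]
    return (a, b) if a < b else (b, a)


def _plane_for_rule(cell, tissue, config, rule, loss, ring=None):
    if rule == "L1L2":
        return l1_l2_plane(cell, tissue, config.growth, loss, ring=ring)
    if rule == "CAE-E":
        return errera_plane(cell, config.growth, loss, ring=ring)
    if rule == "CAE-M":
        return stress_plane(cell, config.mechanics, config.growth,
                            loss_per_len=loss, ring=ring)
    return chemical_plane(cell, config.growth, loss, ring=ring)


def compute_plane(cell: Cell, tissue: Tissue, config: SimulationConfig) -> Plane:
    """Division plane for a cell under the configured mechanism.

    Planes are selected on chord-split areas corrected for the thin strip
    each daughter cedes along its offset new wall, so the realised daughters
    satisfy the even-area window.  If no node pair fits the window (coarse
    rings quantise the split areas), the search is repeated with edge
    midpoints as extra candidate anchors; a chosen midpoint becomes a real
    wall node.  Only if that also fails is the window widened stepwise.
    """
    # the ceded strip is half an adhesion rest length wide; select with a
    # conservative 1.5x margin so realised ratios stay inside the window
    loss = 0.75 * config.mechanics.ell_adh
    rule = select_mechanism(cell, config)
    plane = _plane_for_rule(cell, tissue, config, rule, loss)
    if not plane.widened:
        return plane
    refined = _interleaved(cell.wall)
    plane2 = _plane_for_rule(cell, tissue, config, rule, loss, ring=refined)
    if plane2.widened:
        return plane  # refinement did not help; keep the node-pair plane
    a, b = _realize_refined_anchors(cell, plane2.node_a, plane2.node_b)
    return Plane(a, b, plane2.mechanism, False)


# ---------------------------------------------------------------------------
# division

def classify_plane(u: np.ndarray) -> tuple[float, str]:
    """(angle to horizontal in degrees, periclinal/anticlinal label).

    A new wall within 45 degrees of horizontal stacks daughters vertically:
    periclinal; otherwise anticlinal.
    """
    ang = float(np.degrees(np.arctan2(abs(u[1]), abs(u[0]))))
    return ang, ("periclinal" if ang < 45.0 else "anticlinal")


def execute_division(cell: Cell, plane: Plane, tissue: Tissue,
                     rng: np.random.Generator, config: SimulationConfig,
                     signals=None):
    """Split a mother cell along a plane into two adhered daughters.

    The mother's wall splits into two arcs at the anchors; each daughter gets
    its own new wall built along the plane (nodes at ``new_wall_spacing``,
    offset half an adhesion rest length toward the daughter so the two new
    walls sit at the adhesion spring's rest separation), internal nodes are
    assigned by side of the plane, and daughters draw fresh behaviour,
    polarization and cycle length.  Returns ``(daughter_a, daughter_b,
    event)`` or ``None`` if the split would produce a self-intersecting ring
    (the caller retries later with a recomputed plane).
    """
    if signals is None:
        signals = config.effective_signals()
    mech = config.mechanics
    growth = config.growth
    ring = cell.wall
    n = len(ring)
    i, j = plane.node_a % n, plane.node_b % n
    if i > j:
        i, j = j, i
    a_pt, b_pt = ring[i].copy(), ring[j].copy()
    u = b_pt - a_pt
    length = float(np.linalg.norm(u))
    if length < 1e-9:
        return None
    u_hat = u / length
    n_hat = np.array([-u_hat[1], u_hat[0]])

    def cross_z(rel):
        rel = np.atleast_2d(rel)
        return u[0] * rel[:, 1] - u[1] * rel[:, 0]

    arc_a = ring[i:j + 1]
    arc_b = np.vstack([ring[j:], ring[:i + 1]])
    if len(arc_a) > 2:
        side_a = math.copysign(1.0, float(cross_z(arc_a[1:-1].mean(axis=0) - a_pt)[0]))
    else:
        side_a = 1.0
    side_b = -side_a

    m_new = max(int(round(length / growth.new_wall_spacing)) - 1, 0)
    ts = np.linspace(0.0, 1.0, m_new + 2)[1:-1]
    wall_pts = a_pt[None, :] + ts[:, None] * u[None, :]
    delta = 0.5 * mech.ell_adh

    def build_ring(arc, side):
        shift = side * delta * n_hat
        pieces = [arc.copy()]
        pieces[0][0] += 0.5 * shift  # anchor copies open slightly
        pieces[0][-1] += 0.5 * shift
        if m_new:
            # traverse the new wall back from the arc's last anchor to its first
            newpts = wall_pts + shift
            if np.allclose(arc[0], a_pt):
                newpts = newpts[::-1]
            pieces.append(newpts)
        return np.vstack(pieces)

    ring_a = build_ring(arc_a, side_a)
    ring_b = build_ring(arc_b, side_b)
    if not (geometry.is_simple_ring(ring_a) and geometry.is_simple_ring(ring_b)):
        return None

    # internal nodes by side of the plane
    cross = cross_z(cell.internal - a_pt[None, :])
    to_a = cross * side_a > 0
    on_plane = np.isclose(cross, 0.0)
    area_a = geometry.polygon_area(ring_a)
    area_b = geometry.polygon_area(ring_b)
    if on_plane.any():
        to_a[on_plane] = area_a <= area_b
    int_a = cell.internal[to_a]
    int_b = cell.internal[~to_a]

    id_a = tissue.new_cell_id()
    id_b = tissue.new_cell_id()
    daughters = []
    for cid, ring_d, int_d in ((id_a, ring_a, int_a), (id_b, ring_b, int_b)):
        if len(int_d) == 0:
            int_d = geometry.polygon_centroid(ring_d)[None, :]
        d = Cell(cid, ring_d, int_d, cell.lineage_layer, cell.eta,
                 boundary=cell.boundary, stem=cell.stem, birth_time=tissue.time)
        centers = (tissue.wus_center, tissue.ck_center)
        if centers[0] is not None:
            d.wus, d.ck = signaling.signal_levels(d, centers, signals)
        else:
            d.wus, d.ck = cell.wus, cell.ck
        signaling.draw_behavior(d, rng, signals)
        assign_polarization(d)
        partition_side_end(d, d.polarization, growth.side_end_angle_threshold, mech)
        signaling.assign_cycle_length(d, rng, signals)
        daughters.append(d)
    da, db = daughters

    big, small = max(area_a, area_b), min(area_a, area_b)
    angle, label = classify_plane(u)
    if plane.mechanism == "L1L2":
        # tunica planes are normal to the local surface: anticlinal by
        # construction, whatever their angle in the tissue frame
        label = "anticlinal"
    event = DivisionEvent(
        time=tissue.time, mother_id=cell.id, daughter_ids=(id_a, id_b),
        plane=(tuple(a_pt), tuple(b_pt)), mechanism=plane.mechanism,
        area_ratio=big / max(small, 1e-300), classification=label,
        mother_lineage_layer=cell.lineage_layer, mother_role=cell.role,
        plane_angle_deg=angle, window_widened=plane.widened,
    )
    del tissue.cells[cell.id]
    tissue.add_cell(da)
    tissue.add_cell(db)
    tissue.events.append(event)
    tissue.rebuild_adhesion(mech.adh_pair_cutoff)
    return da, db, event
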