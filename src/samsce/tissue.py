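"""Cells, tissues and division events.

Cells store their wall ring and internal (cytoplasm) nodes as numpy arrays
for speed; :class:`WallNode` is a lightweight per-node view used by the
operation-level API and the snapshot writer.  A tissue owns the cells, the
simulated clock, the current signal-centre positions and the division log.

Roles
-----
``lineage_layer`` records the initial layer (1-7) of a cell's founding
ancestor and never changes.  Layers 1 and 2 are the tunica (L1/L2), layers
3-4 the apical corpus and 5-7 the basal corpus.  Cells on the left/right
edges of the tiling are boundary cells and the bottom row is the stem
foundation; both are flagged separately and reported as their own roles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import geometry
from .errors import InvalidGeometryError

SIDE, END = 0, 1
REGION_NAMES = {SIDE: "side", END: "end"}


def layer_role(lineage_layer: int) -> str:
    if lineage_layer == 1:
        return "L1"
    if lineage_layer == 2:
        return "L2"
    if lineage_layer in (3, 4):
        return "apical_corpus"
    if lineage_layer in (5, 6, 7):
        return "basal_corpus"
    raise ValueError(f"lineage_layer must be 1-7, got {lineage_layer}")


@dataclass(frozen=True)
class WallNode:
    """View of one wall node: position, ring index, spring state, adhesion."""

    position: np.ndarray
    ring_index: int
    k_bend: float
    theta_eq: float
    region_label: str
    adhesion_partner: tuple[int, int] | None  # (cell id, ring index) or None


@dataclass
class DivisionEvent:
    time: float  # hours
    mother_id: int
    daughter_ids: tuple[int, int]
    plane: tuple[tuple[float, float], tuple[float, float]]
    mechanism: str  # CAE-E | CAE-M | CED | L1L2
    area_ratio: float  # larger/smaller daughter area
    classification: str  # periclinal | anticlinal
    mother_lineage_layer: int
    mother_role: str
    plane_angle_deg: float
    window_widened: bool = False


class Cell:
    """One cell: a closed wall ring plus internal nodes and its state."""

    __slots__ = (
        "id", "wall", "region", "k_bend", "theta_eq", "adh_cell", "adh_idx",
        "internal", "eta", "wus", "ck", "polarization", "behavior",
        "cycle_length", "birth_time", "lineage_layer", "boundary", "stem",
        "m_birth", "growth_quota",
    )

    def __init__(self, cell_id: int, wall: np.ndarray, internal: np.ndarray,
                 lineage_layer: int, eta: float, boundary: bool = False,
                 stem: bool = False, birth_time: float = 0.0):
        self.id = cell_id
        self.wall = np.ascontiguousarray(wall, dtype=float)
        n = len(self.wall)
        if n < 3:
            raise InvalidGeometryError("cell wall ring needs >= 3 nodes")
        self.internal = np.ascontiguousarray(internal, dtype=float).reshape(-1, 2)
        self.region = np.full(n, END, dtype=np.uint8)
        self.k_bend = np.zeros(n)
        self.theta_eq = np.full(n, np.pi * (n - 2) / n)
        self.adh_cell = np.full(n, -1, dtype=np.int64)
        self.adh_idx = np.full(n, -1, dtype=np.int64)
        self.eta = eta
        self.wus = 0.0
        self.ck = 0.0
        self.polarization: np.ndarray | None = None  # None = isotropic
        self.behavior = "anticlinal"
        self.cycle_length = np.inf
        self.birth_time = birth_time
        self.lineage_layer = lineage_layer
        self.boundary = boundary
        self.stem = stem
        self.m_birth = len(self.internal)
        self.growth_quota = 0.0

    # -- basic geometry -----------------------------------------------------
    @property
    def n_wall(self) -> int:
        return len(self.wall)

    @property
    def n_internal(self) -> int:
        return len(self.internal)

    def area(self) -> float:
        return geometry.polygon_area(self.wall)

    def centroid(self) -> np.ndarray:
        return geometry.polygon_centroid(self.wall)

    def equivalent_diameter(self) -> float:
        """Diameter of the circle with the same area."""
        return 2.0 * np.sqrt(self.area() / np.pi)

    # -- roles --------------------------------------------------------------
    @property
    def layer_role(self) -> str:
        return layer_role(self.lineage_layer)

    @property
    def role(self) -> str:
        if self.stem:
            return "stem"
        if self.boundary:
            return "boundary"
        return self.layer_role

    @property
    def is_tunica(self) -> bool:
        return self.lineage_layer in (1, 2)

    @property
    def divides(self) -> bool:
        return not (self.boundary or self.stem)

    # -- node views ---------------------------------------------------------
    def wall_node(self, j: int) -> WallNode:
        partner = None
        if self.adh_cell[j] >= 0:
            partner = (int(self.adh_cell[j]), int(self.adh_idx[j]))
        return WallNode(
            position=self.wall[j].copy(),
            ring_index=j,
            k_bend=float(self.k_bend[j]),
            theta_eq=float(self.theta_eq[j]),
            region_label=REGION_NAMES[int(self.region[j])],
            adhesion_partner=partner,
        )

    def wall_nodes(self) -> list[WallNode]:
        return [self.wall_node(j) for j in range(self.n_wall)]

    def refresh_theta_eq(self) -> None:
        """Re-derive equilibrium angles after the ring size changed.

        Side nodes prefer a flat wall (theta_eq = pi); end nodes prefer the
        regular-polygon angle pi(N-2)/N so an all-end ring relaxes circular.
        """
        n = self.n_wall
        circ = np.pi * (n - 2) / n
        self.theta_eq = np.where(self.region == SIDE, np.pi, circ)

    def insert_wall_node(self, j: int, position: np.ndarray) -> None:
        """Insert a node after ring index j (adhesion is re-paired later)."""
        pos = np.asarray(position, dtype=float)
        self.wall = np.insert(self.wall, j + 1, pos, axis=0)
        jn = (j + 1) % (len(self.wall) - 1)
        # inherit side label only if both flanking nodes are sides
        lab = SIDE if (self.region[j] == SIDE and self.region[jn] == SIDE) else END
        self.region = np.insert(self.region, j + 1, lab)
        self.k_bend = np.insert(self.k_bend, j + 1, self.k_bend[j])
        self.adh_cell = np.insert(self.adh_cell, j + 1, -1)
        self.adh_idx = np.insert(self.adh_idx, j + 1, -1)
        self.theta_eq = np.insert(self.theta_eq, j + 1, self.theta_eq[j])
        self.refresh_theta_eq()

    def remove_wall_node(self, j: int) -> None:
        """Delete ring node j (used when compression crowds nodes together)."""
        if len(self.wall) <= 3:
            raise InvalidGeometryError("cannot reduce a ring below 3 nodes")
        self.wall = np.delete(self.wall, j, axis=0)
        self.region = np.delete(self.region, j)
        self.k_bend = np.delete(self.k_bend, j)
        self.adh_cell = np.delete(self.adh_cell, j)
        self.adh_idx = np.delete(self.adh_idx, j)
        self.theta_eq = np.delete(self.theta_eq, j)
        self.refresh_theta_eq()

    def internal_nodes_inside(self, tol: float) -> bool:
        """All internal nodes within `tol` of the wall polygon."""
        if self.n_internal == 0:
            return True
        import shapely

        poly = shapely.Polygon(self.wall).buffer(tol)
        pts = shapely.points(self.internal[:, 0], self.internal[:, 1])
        return bool(np.all(shapely.covers(poly, pts)))


class Tissue:
    """All cells plus global simulation state."""

    def __init__(self):
        self.cells: dict[int, Cell] = {}
        self.time: float = 0.0  # hours
        self.wus_center: np.ndarray | None = None
        self.ck_center: np.ndarray | None = None
        self.events: list[DivisionEvent] = []
        self._next_id = 0

    # -- cell management ----------------------------------------------------
    def new_cell_id(self) -> int:
        cid = self._next_id
        self._next_id += 1
        return cid

    def add_cell(self, cell: Cell) -> None:
        self.cells[cell.id] = cell
        self._next_id = max(self._next_id, cell.id + 1)

    def cell_ids(self) -> list[int]:
        return sorted(self.cells)

    def __len__(self) -> int:
        return len(self.cells)

    def cells_by_role(self, *roles: str) -> list[Cell]:
        return [c for cid in self.cell_ids() for c in [self.cells[cid]]
                if c.role in roles]

    def tunica_cells(self) -> list[Cell]:
        return [self.cells[cid] for cid in self.cell_ids()
                if self.cells[cid].is_tunica]

    def layer_cells(self, lineage_layer: int) -> list[Cell]:
        return [self.cells[cid] for cid in self.cell_ids()
                if self.cells[cid].lineage_layer == lineage_layer]

    # -- adhesion -----------------------------------------------------------
    def rebuild_adhesion(self, cutoff: float) -> int:
        """Re-derive middle-lamella partners as mutual nearest foreign nodes.

        Every wall node is paired with its nearest wall node belonging to a
        different cell, provided the match is mutual and within ``cutoff``.
        Mutuality makes the partnership symmetric by construction.  Returns
        the number of pairs formed.
        """
        ids = self.cell_ids()
        if not ids:
            return 0
        pts, owner, ring = [], [], []
        for cid in ids:
            c = self.cells[cid]
            pts.append(c.wall)
            owner.append(np.full(c.n_wall, cid, dtype=np.int64))
            ring.append(np.arange(c.n_wall, dtype=np.int64))
            c.adh_cell.fill(-1)
            c.adh_idx.fill(-1)
        pts = np.concatenate(pts)
        owner = np.concatenate(owner)
        ring = np.concatenate(ring)
        tree = cKDTree(pts)
        # nearest foreign node: query a handful of neighbors, take the first
        # with a different owner
        # ring neighbours up to +-3 spacings away can sit within the cutoff,
        # so search enough neighbours to always reach a foreign node
        k = min(len(pts), 12)
        dist, idx = tree.query(pts, k=k)
        best = np.full(len(pts), -1, dtype=np.int64)
        for col in range(1, k):
            cand = idx[:, col]
            ok = (best < 0) & (owner[cand] != owner) & (dist[:, col] <= cutoff)
            best[ok] = cand[ok]
        n_pairs = 0
        for a in range(len(pts)):
            b = best[a]
            if b < 0 or b <= a:
                continue
            if best[b] != a:
                continue
            ca, cb = self.cells[int(owner[a])], self.cells[int(owner[b])]
            ja, jb = int(ring[a]), int(ring[b])
            ca.adh_cell[ja], ca.adh_idx[ja] = cb.id, jb
            cb.adh_cell[jb], cb.adh_idx[jb] = ca.id, ja
            n_pairs += 1
        return n_pairs

    def adhesion_is_symmetric(self) -> bool:
        for cid in self.cell_ids():
            c = self.cells[cid]
            for j in range(c.n_wall):
                pc, pj = int(c.adh_cell[j]), int(c.adh_idx[j])
                if pc < 0:
                    continue
                if pc == cid:
                    return False
                other = self.cells.get(pc)
                if other is None or pj >= other.n_wall:
                    return False
                if int(other.adh_cell[pj]) != cid or int(other.adh_idx[pj]) != j:
                    return False
        return True


@dataclass
class FlatState:
    """Flattened node arrays for the mechanics engine.

    Wall nodes of all cells come first (cell by cell in id order, ring order
    preserved), then all internal nodes.  ``ring_prev``/``ring_next`` are -1
    for internal nodes.
    """

    pos: np.ndarray  # (n, 2)
    eta: np.ndarray  # (n,)
    is_wall: np.ndarray  # (n,) bool
    ring_prev: np.ndarray  # (n,) int
    ring_next: np.ndarray  # (n,) int
    k_bend: np.ndarray  # (n,)
    theta_eq: np.ndarray  # (n,)
    cell_of: np.ndarray  # (n,) cell id per node
    wall_slices: dict[int, slice] = field(default_factory=dict)
    internal_slices: dict[int, slice] = field(default_factory=dict)
    iw_pairs: np.ndarray = None  # (P, 2) wall-internal, same cell
    ii_pairs: np.ndarray = None  # (P, 2) internal-internal, same cell
    adh_pairs: np.ndarray = None  # (P, 2) adhered wall nodes, cross cell

    @property
    def n_nodes(self) -> int:
        return len(self.pos)

    def scatter(self, tissue: Tissue) -> None:
        """Write positions back into the cells."""
        for cid, sl in self.wall_slices.items():
            tissue.cells[cid].wall = self.pos[sl].copy()
        for cid, sl in self.internal_slices.items():
            tissue.cells[cid].internal = self.pos[sl].copy()


def flatten(tissue: Tissue) -> FlatState:
    ids = tissue.cell_ids()
    n_wall = sum(tissue.cells[c].n_wall for c in ids)
    n_int = sum(tissue.cells[c].n_internal for c in ids)
    n = n_wall + n_int
    pos = np.empty((n, 2))
    eta = np.empty(n)
    is_wall = np.zeros(n, dtype=bool)
    ring_prev = np.full(n, -1, dtype=np.int64)
    ring_next = np.full(n, -1, dtype=np.int64)
    k_bend = np.zeros(n)
    theta_eq = np.zeros(n)
    cell_of = np.empty(n, dtype=np.int64)
    wall_slices: dict[int, slice] = {}
    internal_slices: dict[int, slice] = {}
    off = 0
    for cid in ids:
        c = tissue.cells[cid]
        m = c.n_wall
        sl = slice(off, off + m)
        wall_slices[cid] = sl
        pos[sl] = c.wall
        eta[sl] = c.eta
        is_wall[sl] = True
        idx = np.arange(off, off + m)
        ring_prev[sl] = np.roll(idx, 1)
        ring_next[sl] = np.roll(idx, -1)
        k_bend[sl] = c.k_bend
        theta_eq[sl] = c.theta_eq
        cell_of[sl] = cid
        off += m
    for cid in ids:
        c = tissue.cells[cid]
        m = c.n_internal
        sl = slice(off, off + m)
        internal_slices[cid] = sl
        if m:
            pos[sl] = c.internal
            eta[sl] = c.eta
            cell_of[sl] = cid
        off += m

    iw, ii, adh = [], [], []
    for cid in ids:
        c = tissue.cells[cid]
        w0 = wall_slices[cid].start
        i0 = internal_slices[cid].start
        nw, ni = c.n_wall, c.n_internal
        if ni:
            wi = np.arange(w0, w0 + nw)
            inti = np.arange(i0, i0 + ni)
            grid_w, grid_i = np.meshgrid(wi, inti, indexing="ij")
            iw.append(np.column_stack([grid_w.ravel(), grid_i.ravel()]))
            if ni > 1:
                ia, ib = np.triu_indices(ni, k=1)
                ii.append(np.column_stack([inti[ia], inti[ib]]))
        for j in range(nw):
            pc, pj = int(c.adh_cell[j]), int(c.adh_idx[j])
            if pc < 0:
                continue
            a = w0 + j
            b = wall_slices[pc].start + pj
            if a < b:
                adh.append((a, b))
    empty = np.empty((0, 2), dtype=np.int64)
    return FlatState(
        pos=pos, eta=eta, is_wall=is_wall, ring_prev=ring_prev,
        ring_next=ring_next, k_bend=k_bend, theta_eq=theta_eq, cell_of=cell_of,
        wall_slices=wall_slices, internal_slices=internal_slices,
        iw_pairs=np.vstack(iw).astype(np.int64) if iw else empty,
        ii_pairs=np.vstack(ii).astype(np.int64) if ii else empty,
        adh_pairs=np.asarray(adh, dtype=np.int64) if adh else empty,
    )


def wwd_pairs(flat: FlatState, cutoff: float) -> np.ndarray:
    """Cross-cell wall-wall node pairs within ``cutoff`` (volume exclusion)."""
    wall_idx = np.nonzero(flat.is_wall)[0]
    if len(wall_idx) == 0:
        return np.empty((0, 2), dtype=np.int64)
    pts = flat.pos[wall_idx]
    tree = cKDTree(pts)
    raw = tree.query_pairs(cutoff, output_type="ndarray")
    if len(raw) == 0:
        return np.empty((0, 2), dtype=np.int64)
    a = wall_idx[raw[:, 0]]
    b = wall_idx[raw[:, 1]]
    keep = flat.cell_of[a] != flat.cell_of[b]
    return np.column_stack([a[keep], b[keep]]).astype(np.int64)
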