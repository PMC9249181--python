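"""Node mechanics: potentials, force assembly, integration and wall stress.

The model's mechanics is deterministic overdamped dynamics: the printed
equations of motion carry damping but no thermal noise term, so all
stochasticity in the model lives in the behaviour draws and cycle lengths.

Potentials
----------
* ``E_WWS``: linear springs along ring edges (stiffness ``k_lin``, rest
  length ``ell``) plus a rotational spring at each wall node with stiffness
  ``k_bend`` and equilibrium angle ``theta_eq``.  Each edge is a single
  spring, which is also the convention the in-plane stress measure uses.
* ``E_IW`` / ``E_II``: Morse interactions of a cell's internal nodes with its
  wall and with each other; together they coarse-grain turgor pressure.
* ``E_WWD``: short-range Morse repulsion between wall nodes of different
  cells (volume exclusion).
* ``E_Adh``: linear springs between adhered wall nodes of adjacent cells
  (middle lamella).
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .config import MechanicsParams, MorseParams
from .errors import (DegenerateGeometryError, NumericalBlowupError,
                     SingularConfigurationError)
from .tissue import Cell, FlatState, Tissue, flatten, wwd_pairs

_EMPTY_PAIRS = np.empty((0, 2), dtype=np.int64)


# ---------------------------------------------------------------------------
# elementary potentials (operation-level API; plain numpy)

def wall_spring_energy(triplet, k_lin, ell, k_bend, theta_eq) -> float:
    """E_WWS of a 3-node ring fragment (two edges + the central angle)."""
    p0, p1, p2 = (np.asarray(p, float) for p in triplet)
    r01 = np.linalg.norm(p1 - p0)
    r12 = np.linalg.norm(p2 - p1)
    if r01 < 1e-12 or r12 < 1e-12:
        raise DegenerateGeometryError("coincident adjacent wall nodes")
    e = 0.5 * k_lin * ((r01 - ell) ** 2 + (r12 - ell) ** 2)
    a = p0 - p1
    b = p2 - p1
    cos_t = np.clip(a @ b / (r01 * r12), -1.0, 1.0)
    theta = np.arccos(cos_t)
    return float(e + 0.5 * k_bend * (theta - theta_eq) ** 2)


def wall_spring_force(triplet, k_lin, ell, k_bend, theta_eq) -> np.ndarray:
    """-grad E_WWS on the three nodes of an adjacent ring triplet.

    Returns a (3, 2) array of forces; being internal forces they sum to the
    zero vector.
    """
    p0, p1, p2 = (np.asarray(p, float) for p in triplet)
    f = np.zeros((3, 2))
    for (i, j) in ((0, 1), (1, 2)):
        a, b = (p0, p1, p2)[i], (p0, p1, p2)[j]
        d = b - a
        r = np.linalg.norm(d)
        if r < 1e-12:
            raise DegenerateGeometryError("coincident adjacent wall nodes")
        fv = k_lin * (r - ell) * d / r
        f[i] += fv
        f[j] -= fv
    a = p0 - p1
    b = p2 - p1
    ra, rb = np.linalg.norm(a), np.linalg.norm(b)
    cos_t = float(np.clip(a @ b / (ra * rb), -1.0, 1.0))
    theta = np.arccos(cos_t)
    sin_t = np.sqrt(max(1.0 - cos_t * cos_t, 0.0))
    if sin_t >= 1e-8:
        coef = -k_bend * (theta - theta_eq)
        ga = (cos_t * a / ra - b / rb) / (ra * sin_t)
        gb = (cos_t * b / rb - a / ra) / (rb * sin_t)
        f[0] += coef * ga
        f[2] += coef * gb
        f[1] -= coef * (ga + gb)
    return f


def morse_energy(p, q, params: MorseParams) -> float:
    r = float(np.linalg.norm(np.asarray(p, float) - np.asarray(q, float)))
    if r < 1e-12:
        raise SingularConfigurationError("Morse pair at zero separation")
    return params.U * np.exp(-r / params.xi) - params.W * np.exp(-r / params.gamma)


def morse_force(p, q, params: MorseParams) -> np.ndarray:
    """-grad_p of the Morse pair energy (force on p; swap args for q)."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    d = p - q
    r = float(np.linalg.norm(d))
    if r < 1e-12:
        raise SingularConfigurationError("Morse pair at zero separation")
    dEdr = (-params.U / params.xi * np.exp(-r / params.xi)
            + params.W / params.gamma * np.exp(-r / params.gamma))
    return -dEdr * d / r


def morse_equilibrium_distance(params: MorseParams) -> float:
    """Separation at which the Morse force vanishes (repulsion = attraction)."""
    from scipy.optimize import brentq

    def dEdr(r):
        return (-params.U / params.xi * np.exp(-r / params.xi)
                + params.W / params.gamma * np.exp(-r / params.gamma))

    hi = 10.0 * max(params.xi, params.gamma)
    return float(brentq(dEdr, 1e-9, hi))


def adhesion_energy(node, partner, k_adh, ell_adh) -> float:
    if partner is None:
        return 0.0
    r = float(np.linalg.norm(np.asarray(node, float) - np.asarray(partner, float)))
    return 0.5 * k_adh * (r - ell_adh) ** 2


def adhesion_force(node, partner, k_adh, ell_adh) -> np.ndarray:
    """Linear spring force on ``node`` toward its adhesion partner.

    A missing partner is a no-op (zero force).  At zero separation the spring
    pushes along an arbitrary fixed direction of magnitude k_adh * ell_adh.
    """
    if partner is None:
        return np.zeros(2)
    node = np.asarray(node, float)
    partner = np.asarray(partner, float)
    d = partner - node
    r = float(np.linalg.norm(d))
    if r < 1e-12:
        return np.array([k_adh * ell_adh, 0.0])
    return k_adh * (r - ell_adh) * d / r


# ---------------------------------------------------------------------------
# assembly, energy and integration over a flat state

def _kernel_args(flat: FlatState, params: MechanicsParams, wwd: np.ndarray):
    ii = params.morse_ii
    iw = params.morse_iw
    wd = params.morse_wwd
    return (
        flat.ring_prev, flat.ring_next, flat.k_bend, flat.theta_eq,
        params.k_lin, params.ell,
        flat.iw_pairs, iw.U, iw.W, iw.xi, iw.gamma,
        flat.ii_pairs, ii.U, ii.W, ii.xi, ii.gamma,
        wwd, wd.U, wd.W, wd.xi, wd.gamma, params.wwd_cutoff,
        flat.adh_pairs, params.k_adh, params.ell_adh,
    )


def compute_forces_flat(flat: FlatState, params: MechanicsParams,
                        wwd: np.ndarray | None = None) -> np.ndarray:
    if wwd is None:
        wwd = wwd_pairs(flat, params.wwd_cutoff)
    out = np.zeros_like(flat.pos)
    _kernels.compute_forces(flat.pos, *_kernel_args(flat, params, wwd), out)
    return out


def total_energy(flat: FlatState, params: MechanicsParams,
                 wwd: np.ndarray | None = None) -> float:
    """Total potential energy of a flat state (finite-difference oracle hook)."""
    if wwd is None:
        wwd = wwd_pairs(flat, params.wwd_cutoff)
    pos = flat.pos
    e = 0.0
    wall = np.nonzero(flat.is_wall)[0]
    for j in wall:
        nx = flat.ring_next[j]
        r = np.linalg.norm(pos[nx] - pos[j])
        e += 0.5 * params.k_lin * (r - params.ell) ** 2
        p = flat.ring_prev[j]
        a = pos[p] - pos[j]
        b = pos[nx] - pos[j]
        ra, rb = np.linalg.norm(a), np.linalg.norm(b)
        if ra > 1e-12 and rb > 1e-12 and flat.k_bend[j] != 0.0:
            cos_t = float(np.clip(a @ b / (ra * rb), -1.0, 1.0))
            theta = np.arccos(cos_t)
            e += 0.5 * flat.k_bend[j] * (theta - flat.theta_eq[j]) ** 2

    def _morse_sum(pairs, mp, cutoff=np.inf):
        s = 0.0
        for a_, b_ in pairs:
            r = np.linalg.norm(pos[a_] - pos[b_])
            if r > cutoff:
                continue
            s += mp.U * np.exp(-r / mp.xi) - mp.W * np.exp(-r / mp.gamma)
        return s

    e += _morse_sum(flat.iw_pairs, params.morse_iw)
    e += _morse_sum(flat.ii_pairs, params.morse_ii)
    e += _morse_sum(wwd, params.morse_wwd, params.wwd_cutoff)
    for a_, b_ in flat.adh_pairs:
        r = np.linalg.norm(pos[a_] - pos[b_])
        e += 0.5 * params.k_adh * (r - params.ell_adh) ** 2
    return float(e)


def assemble_forces(tissue: Tissue, params: MechanicsParams):
    """Force on every node of the tissue.

    Returns ``(flat, forces)`` with forces aligned to the flat node order;
    use the flat state's slices to look up a given cell's nodes.
    """
    flat = flatten(tissue)
    return flat, compute_forces_flat(flat, params)


def euler_step(tissue: Tissue, params: MechanicsParams,
               flat: FlatState | None = None,
               forces: np.ndarray | None = None) -> FlatState:
    """One explicit Euler step: position += (dt / eta_i) * force."""
    if flat is None:
        flat = flatten(tissue)
    if not np.all(np.isfinite(flat.pos)):
        bad = int(np.nonzero(~np.isfinite(flat.pos).all(axis=1))[0][0])
        raise NumericalBlowupError(
            f"non-finite position at node {bad} (cell {int(flat.cell_of[bad])}) "
            f"before an Euler step"
        )
    if forces is None:
        forces = compute_forces_flat(flat, params)
    flat.pos += (params.dt / flat.eta)[:, None] * forces
    if not np.all(np.isfinite(flat.pos)):
        bad = int(np.nonzero(~np.isfinite(flat.pos).all(axis=1))[0][0])
        raise NumericalBlowupError(
            f"non-finite position at node {bad} (cell {int(flat.cell_of[bad])}) "
            f"after an Euler step"
        )
    flat.scatter(tissue)
    return flat


class Engine:
    """Runs blocks of Euler steps over a flattened tissue.

    Cross-cell volume-exclusion pairs are rebuilt every
    ``neighbor_refresh_steps`` with a search margin on top of the interaction
    cutoff, so the pair list stays valid while nodes drift between rebuilds.
    """

    #: extra search radius (um) added to the cutoff when building pair lists
    MARGIN = 0.6

    def __init__(self, tissue: Tissue, params: MechanicsParams):
        self.tissue = tissue
        self.params = params
        self.steps_done = 0
        self.refresh()

    def refresh(self) -> None:
        """Re-flatten after any topology change (growth, division...)."""
        self.flat = flatten(self.tissue)
        self._forces = np.zeros_like(self.flat.pos)

    def advance(self, seconds: float, scatter: bool = True) -> None:
        """Advance the mechanics by ``seconds`` of simulated time."""
        p = self.params
        n_steps = max(1, int(round(seconds / p.dt)))
        block = max(1, p.neighbor_refresh_steps)
        done = 0
        while done < n_steps:
            take = min(block, n_steps - done)
            wwd = wwd_pairs(self.flat, p.wwd_cutoff + self.MARGIN)
            _kernels.integrate(self.flat.pos, self.flat.eta, take, p.dt,
                               *_kernel_args(self.flat, p, wwd), self._forces)
            if not np.all(np.isfinite(self.flat.pos)):
                bad = int(np.nonzero(~np.isfinite(self.flat.pos).all(axis=1))[0][0])
                raise NumericalBlowupError(
                    f"non-finite position at node {bad} "
                    f"(cell {int(self.flat.cell_of[bad])}) near step "
                    f"{self.steps_done + done + take}"
                )
            done += take
            self.steps_done += take
        if scatter:
            self.flat.scatter(self.tissue)

    def max_residual_force(self) -> float:
        f = compute_forces_flat(self.flat, self.params)
        return float(np.max(np.hypot(f[:, 0], f[:, 1]))) if len(f) else 0.0


# ---------------------------------------------------------------------------
# in-plane tensile stress

def in_plane_tensile_stress(cell: Cell, node_index: int,
                            params: MechanicsParams) -> float:
    """Scalar wall stress at one node.

    The average magnitude of the tangential projections of the linear-spring
    forces exerted by the node's two ring neighbours; the tangent is the unit
    vector along (next - prev).
    """
    n = cell.n_wall
    j = node_index % n
    w = cell.wall
    prev = w[(j - 1) % n]
    nxt = w[(j + 1) % n]
    tau = nxt - prev
    t_norm = np.linalg.norm(tau)
    if t_norm < 1e-12:
        raise DegenerateGeometryError("coincident ring neighbours: tangent undefined")
    tau = tau / t_norm
    s = 0.0
    for nb in (prev, nxt):
        d = nb - w[j]
        r = np.linalg.norm(d)
        if r < 1e-12:
            raise DegenerateGeometryError("coincident adjacent wall nodes")
        s += 0.5 * abs(float(tau @ (d / r))) * params.k_lin * abs(r - params.ell)
    return s


def cell_stresses(cell: Cell, params: MechanicsParams) -> np.ndarray:
    """Vectorised in-plane tensile stress for every wall node of a cell."""
    w = cell.wall
    prev = np.roll(w, 1, axis=0)
    nxt = np.roll(w, -1, axis=0)
    tau = nxt - prev
    tn = np.linalg.norm(tau, axis=1)
    tn = np.where(tn < 1e-12, 1.0, tn)
    tau = tau / tn[:, None]
    s = np.zeros(len(w))
    for nb in (prev, nxt):
        d = nb - w
        r = np.linalg.norm(d, axis=1)
        safe = np.where(r < 1e-12, 1.0, r)
        proj = np.abs(np.sum(tau * d / safe[:, None], axis=1))
        s += 0.5 * proj * params.k_lin * np.abs(r - params.ell)
    return s
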