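"""Structured configuration for the meristem growth model.

Parameter conventions
---------------------
Lengths are micrometres, forces in nanonewtons, energies nN*um, time in
seconds for the mechanics integrator and hours at the simulation level.
Signal concentrations are arbitrary units (a.u.) normalised so the wildtype
peak WUSCHEL level is 1.

The default values reproduce the study conditions of the model: 50 cells in
seven layers, 15 minutes of elastic relaxation, 40 hours of growth, a 30
internal-node mitotic trigger, and WUS-dependent cell cycles spanning roughly
18-36 h.  ``desk_scale`` derives a faithful but reduced variant (shorter
cycles and run, lower mitotic trigger) used for fast seeded experiments.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field, replace

import yaml

from .errors import ConfigError

CONDITIONS = ("wildtype", "ectopic_wus", "ectopic_ck")
MECHANISMS = ("CAE-E", "CAE-M", "CED", "combined")


@dataclass(frozen=True)
class MorseParams:
    """Morse pair potential U*exp(-r/xi) - W*exp(-r/gamma)."""

    U: float
    W: float
    xi: float
    gamma: float

    def validate(self, name: str) -> None:
        for f in ("U", "W", "xi", "gamma"):
            if getattr(self, f) <= 0:
                raise ConfigError(f"Morse parameter {name}.{f} must be > 0")


@dataclass(frozen=True)
class MechanicsParams:
    """Parameters of the node-spring / Morse mechanics."""

    k_lin: float = 8.0  # linear wall spring stiffness (nN/um)
    ell: float = 0.4  # equilibrium wall-node spacing (um)
    k_bend_high: float = 2.0  # rotational stiffness, microfibril-bound sides
    k_bend_low: float = 0.3  # rotational stiffness, freely growing ends
    k_adh: float = 1.5  # middle-lamella adhesion spring (nN/um)
    ell_adh: float = 0.25  # adhesion rest length (um)
    morse_ii: MorseParams = MorseParams(U=0.5, W=0.02, xi=0.7, gamma=2.2)
    morse_iw: MorseParams = MorseParams(U=0.3, W=0.02, xi=0.8, gamma=2.6)
    morse_wwd: MorseParams = MorseParams(U=1.5, W=0.05, xi=0.12, gamma=0.9)
    eta_default: float = 80.0  # damping (nN*s/um)
    eta_stem: float = 8000.0  # stem-row foundation damping
    dt: float = 0.4  # integration step (s)
    wwd_cutoff_factor: float = 1.8  # cutoff = factor * max(xi, gamma) of WWD
    neighbor_refresh_steps: int = 100  # steps between cross-cell pair rebuilds
    adh_pair_cutoff: float = 0.8  # max separation to form an adhesion pair (um)

    @property
    def wwd_cutoff(self) -> float:
        return self.wwd_cutoff_factor * max(self.morse_wwd.xi, self.morse_wwd.gamma)

    def validate(self) -> None:
        for f in ("k_lin", "ell", "k_bend_high", "k_bend_low", "k_adh", "ell_adh",
                  "eta_default", "eta_stem", "dt"):
            if getattr(self, f) <= 0:
                raise ConfigError(f"mechanics.{f} must be > 0")
        self.morse_ii.validate("morse_ii")
        self.morse_iw.validate("morse_iw")
        self.morse_wwd.validate("morse_wwd")
        ratio = self.dt * self.k_lin / self.eta_default
        if ratio > 0.1 + 1e-12:
            raise ConfigError(
                f"stability ratio dt*k_lin/eta_default = {ratio:.3f} exceeds 0.1"
            )


@dataclass(frozen=True)
class SignalParams:
    """Steady-state WUS/CK fields, Hill behaviour model and cell cycle map."""

    wus0: float = 1.0  # peak WUS concentration (a.u.)
    ck0: float = 1.0  # peak CK concentration (a.u.)
    mu_wus: float = 0.12  # WUS decay rate (1/um)
    mu_ck: float = 0.12  # CK decay rate (1/um)
    alpha_wus: float = 1.0  # distribution-width scaling (1 = wildtype)
    alpha_ck: float = 1.0
    n_hill: float = 4.0  # Hill exponent of the behaviour switch
    k_hill: float | None = None  # threshold ratio; None -> computed from fields
    ref_cell_diameter: float = 5.0  # nominal tunica cell diameter (um)
    cycle_base_h: float = 18.0  # cycle mean at [WUS] = 0 (h)
    cycle_slope_h: float = 18.0  # increase of cycle mean per unit [WUS] (h/a.u.)
    cycle_sd_frac: float = 0.15  # sd as a fraction of the mean

    def validate(self) -> None:
        for f in ("wus0", "ck0", "mu_wus", "mu_ck", "alpha_wus", "alpha_ck",
                  "n_hill", "ref_cell_diameter", "cycle_base_h"):
            if getattr(self, f) <= 0:
                raise ConfigError(f"signals.{f} must be > 0")
        if self.cycle_sd_frac < 0:
            raise ConfigError("signals.cycle_sd_frac must be >= 0")

    def cycle_mean(self, wus: float) -> float:
        """Affine map [WUS] -> mean cycle length in hours (high WUS = slower)."""
        return self.cycle_base_h + self.cycle_slope_h * wus


@dataclass(frozen=True)
class GrowthParams:
    """Growth, wall maintenance and division-trigger parameters."""

    division_trigger_nodes: int = 30  # internal-node count triggering mitosis
    side_end_angle_threshold: float = 45.0  # degrees
    wall_insert_factor: float = 1.4  # spacing multiple triggering node insertion
    wall_remove_factor: float = 1.2  # merged-edge multiple below which a node drops
    new_wall_spacing: float = 0.4  # spacing of nodes on a freshly built wall (um)
    min_division_area: float = 3.2  # size checkpoint (um^2): smaller cells wait
    area_ratio_max: float = 1.11  # even-area window on daughter areas
    area_window_widen_step: float = 0.05

    def validate(self) -> None:
        if self.division_trigger_nodes < 2:
            raise ConfigError("growth.division_trigger_nodes must be >= 2")
        if not 0 < self.side_end_angle_threshold < 90:
            raise ConfigError("growth.side_end_angle_threshold must be in (0, 90)")
        for f in ("wall_insert_factor", "new_wall_spacing"):
            if getattr(self, f) <= 0:
                raise ConfigError(f"growth.{f} must be > 0")
        if not 0 < self.wall_remove_factor < self.wall_insert_factor:
            raise ConfigError(
                "wall_remove_factor must stay below wall_insert_factor "
                "(otherwise insertion and merging thrash)"
            )


@dataclass(frozen=True)
class SimulationConfig:
    """Every knob of a simulation run."""

    mechanics: MechanicsParams = field(default_factory=MechanicsParams)
    signals: SignalParams = field(default_factory=SignalParams)
    growth: GrowthParams = field(default_factory=GrowthParams)
    condition: str = "wildtype"
    mechanism: str = "combined"
    seed: int = 0
    relax_duration_min: float = 15.0
    run_duration_h: float = 40.0
    snapshot_interval_min: float = 30.0
    signal_interval_min: float = 6.0  # interval between signal/growth updates
    replicates: int = 1
    max_cells: int = 400
    # initial tiling
    n_ring_nodes: int = 40
    initial_internal_nodes: int = 10
    row_counts: tuple[int, ...] = (8, 8, 7, 7, 7, 7, 6)  # top (L1) to bottom (stem)
    allow_combined_perturbed: bool = False
    # condition-preset scalings (applied by `effective_signals`)
    ectopic_wus_level_factor: float = 2.0 / 3.0
    ectopic_alpha_factor: float = 0.5

    def validate(self) -> None:
        self.mechanics.validate()
        self.signals.validate()
        self.growth.validate()
        if self.condition not in CONDITIONS:
            raise ConfigError(f"unknown condition {self.condition!r}")
        if self.mechanism not in MECHANISMS:
            raise ConfigError(f"unknown mechanism {self.mechanism!r}")
        if (self.mechanism == "combined" and self.condition != "wildtype"
                and not self.allow_combined_perturbed):
            raise ConfigError(
                "the combined mechanism is only simulated under wildtype "
                "conditions; set allow_combined_perturbed=True to override"
            )
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if len(self.row_counts) != 7:
            raise ConfigError("the initial tiling uses exactly 7 cell layers")
        if sum(self.row_counts) != 50:
            raise ConfigError("the initial tiling uses exactly 50 cells")
        for f in ("relax_duration_min", "snapshot_interval_min", "signal_interval_min"):
            if getattr(self, f) <= 0:
                raise ConfigError(f"{f} must be > 0")
        if self.run_duration_h < 0:
            raise ConfigError("run_duration_h must be >= 0")
        if self.n_ring_nodes < 8:
            raise ConfigError("n_ring_nodes must be >= 8")

    @property
    def initial_cell_radius(self) -> float:
        """Radius putting the initial ring exactly at the rest spacing."""
        return self.n_ring_nodes * self.mechanics.ell / (2.0 * math.pi)

    def effective_signals(self) -> SignalParams:
        """Signal parameters after applying the condition preset.

        Ectopic WUS lowers the peak level to 2/3 of wildtype and expands the
        spatial distribution (alpha_wus scaled down); ectopic CK expands the
        CK distribution only (alpha_ck scaled down; CK acts in the corpus
        only, so no layer restriction is needed on the scaling itself).
        """
        s = self.signals
        if self.condition == "ectopic_wus":
            s = replace(s, wus0=s.wus0 * self.ectopic_wus_level_factor,
                        alpha_wus=s.alpha_wus * self.ectopic_alpha_factor)
        elif self.condition == "ectopic_ck":
            s = replace(s, alpha_ck=s.alpha_ck * self.ectopic_alpha_factor)
        return s

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(to_dict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def desk_scale(config: SimulationConfig | None = None, **overrides) -> SimulationConfig:
    """A reduced variant of the study conditions for fast seeded experiments.

    Keeps the tissue layout, mechanics and signal fields of the full model but
    shortens cell cycles (0.6-1.2 h instead of 18-36 h), lowers the mitotic
    trigger to 8 internal nodes, runs 4 simulated hours, and takes a slightly
    larger integration step (still within the stability bound).  Cell- and
    tissue-level readouts from these runs are comparative, not absolute.
    """
    cfg = config or SimulationConfig()
    cfg = replace(
        cfg,
        mechanics=replace(cfg.mechanics, dt=0.5, eta_default=40.0,
                          eta_stem=4000.0),
        signals=replace(cfg.signals, cycle_base_h=1.0, cycle_slope_h=1.0),
        growth=replace(cfg.growth, division_trigger_nodes=8),
        run_duration_h=4.0,
        snapshot_interval_min=60.0,
        initial_internal_nodes=3,
        max_cells=450,
    )
    if overrides:
        cfg = replace(cfg, **overrides)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# (de)serialisation


def to_dict(obj) -> dict:
    """Nested plain-dict form of a config dataclass (YAML/JSON friendly)."""
    d = dataclasses.asdict(obj)

    def _clean(v):
        if isinstance(v, dict):
            return {k: _clean(x) for k, x in v.items()}
        if isinstance(v, tuple):
            return list(v)
        return v

    return _clean(d)


def from_dict(d: dict) -> SimulationConfig:
    d = dict(d)

    def _sub(cls, key, morse_keys=()):
        if key not in d:
            return cls()
        sub = dict(d.pop(key))
        for mk in morse_keys:
            if mk in sub and isinstance(sub[mk], dict):
                sub[mk] = MorseParams(**sub[mk])
        return cls(**sub)

    mech = _sub(MechanicsParams, "mechanics", ("morse_ii", "morse_iw", "morse_wwd"))
    sig = _sub(SignalParams, "signals")
    grow = _sub(GrowthParams, "growth")
    if "row_counts" in d:
        d["row_counts"] = tuple(d["row_counts"])
    cfg = SimulationConfig(mechanics=mech, signals=sig, growth=grow, **d)
    cfg.validate()
    return cfg


def load_config(path) -> SimulationConfig:
    """Load a YAML config whose keys mirror the dataclass field names."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return from_dict(data)


def dump_config(config: SimulationConfig) -> str:
    """Resolved parameter set as YAML text (for provenance)."""
    return yaml.safe_dump(to_dict(config), sort_keys=True)
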