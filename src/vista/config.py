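"""Model configuration: every tunable parameter of the simulator in one place.

The shipped defaults constitute the reference parameterisation
(version-stamped via :data:`CONFIG_VERSION`); all blocks round-trip
through YAML so a run is fully described by (config, seed, forcing).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional

import yaml

CONFIG_VERSION = "1.0"

#: Species codes used on the lattice.
BARE, GRASS, SHRUB, TREE = 0, 1, 2, 3
SPECIES_NAMES = {BARE: "bare", GRASS: "grass", SHRUB: "shrub", TREE: "tree"}
SPECIES_CODES = {v: k for k, v in SPECIES_NAMES.items()}

#: Meteorological seasons, southern hemisphere order (wet summer first).
SEASONS = ("DJF", "MAM", "JJA", "SON")


@dataclass
class SpeciesParams:
    """Growth-pathway and response parameters for one plant functional type.

    growth_units are the abstract increments along the predetermined
    nonlinear growth pathway; biomass/height follow a normalised logistic
    of growth_units so both are 0 at the pathway origin and saturate at
    (b_max, h_max) at ``g_max``.
    """

    g_max: float            # growth-unit ceiling of the pathway
    lifespan_seasons: int   # age cap, in 3-month seasons
    b_max: float            # biomass at g_max (kg, relative scale)
    h_max: float            # canopy height at g_max (m)
    porosity: float         # aerodynamic porosity, 0 = bluff body, 1 = transparent
    harsh_mm: float         # seasonal precip below which growth units are lost
    optimum_mm: float       # seasonal precip at/above which growth = +1 unit
    sediment_tol_slabs: float  # |net slab change|/season that saturates burial stress
    burn_probability: float    # chance of being killed by a fire event
    palatability: float        # grazing preference weight (grass >> shrub, tree 0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.porosity <= 1.0:
            raise ValueError(f"porosity must be in [0,1], got {self.porosity}")
        if self.harsh_mm >= self.optimum_mm:
            raise ValueError("harsh_mm must be below optimum_mm")


def _default_species() -> dict:
    # Declared stand-in parameterisation: grass fast/short-lived and bluff,
    # tree slow/long-lived and tall, shrub intermediate but aerodynamically
    # porous. Harsh (drought) thresholds ordered grass < shrub < tree —
    # drier sites keep grasses and lose trees first. Grass optimum is the
    # highest: summer-growing grasses keep responding to rainfall where
    # woody growth has saturated, so wetter summers shift the balance
    # toward grass.
    return {
        GRASS: SpeciesParams(
            g_max=8.0, lifespan_seasons=20, b_max=2.0, h_max=0.5,
            porosity=0.15, harsh_mm=15.0, optimum_mm=220.0,
            sediment_tol_slabs=2.0, burn_probability=0.35, palatability=1.0,
        ),
        SHRUB: SpeciesParams(
            g_max=40.0, lifespan_seasons=160, b_max=30.0, h_max=2.0,
            porosity=0.55, harsh_mm=30.0, optimum_mm=110.0,
            sediment_tol_slabs=5.0, burn_probability=0.70, palatability=0.05,
        ),
        TREE: SpeciesParams(
            g_max=100.0, lifespan_seasons=400, b_max=400.0, h_max=8.0,
            porosity=0.40, harsh_mm=45.0, optimum_mm=160.0,
            sediment_tol_slabs=8.0, burn_probability=0.15, palatability=0.0,
        ),
    }


@dataclass
class EcologyConfig:
    """Vegetation-module parameters: growth, interaction, stress, recruitment."""

    species: dict = field(default_factory=_default_species)
    #: signed shell weights, facilitation (+) close in, competition (−) far out;
    #: applied per (focal, neighbour) pair after scaling by pair_scale.
    shell_weights: tuple = (1.0, 0.5, -0.4, -0.6, -0.8)
    #: multiplier on shell weights per (focal, neighbour) species pair;
    #: default: all pairs interact identically.
    pair_scale: Optional[dict] = None
    #: logistic gain turning the signed interaction sum into a [0,1] stress.
    neighbourhood_gain: float = 2.0
    #: compound-stress weights: (neighbourhood, precipitation, biomass, age,
    #: sediment_balance, grazing, fire); must be non-negative and sum to 1.
    stress_weights: tuple = (0.15, 0.30, 0.15, 0.15, 0.10, 0.075, 0.075)
    #: background mortality floor per season.
    p0: float = 0.01
    #: exponent sharpening the stress→mortality map.
    mortality_gamma: float = 3.0
    #: fraction of lifespan over which age stress ramps 0→1 (final quartile).
    age_ramp_fraction: float = 0.25
    #: sediment-balance stress exponent (1 = linear to saturation).
    sediment_gamma: float = 1.0
    #: recruitment: P(establish) = base × best moisture response × (1 + gain·facil)
    recruit_base: float = 0.4
    recruit_facilitation_gain: float = 0.5
    #: species prior for establishment on bare soil (no occupied shell-1/2 cells).
    bare_soil_prior: tuple = (0.75, 0.20, 0.05)  # grass, shrub, tree
    #: pseudo-count added to neighbour copying so rare species can still appear.
    copy_epsilon: float = 0.05
    #: growth units granted to a fresh recruit.
    recruit_growth_units: float = 1.0
    #: growth-unit stubble left ungrazed.
    grazing_floor_gu: float = 0.5
    #: growth units consumed per LSU per season (spatially averaged demand).
    intake_gu_per_lsu_season: float = 2.0e5

    def __post_init__(self) -> None:
        w = self.stress_weights
        if len(w) != 7 or any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("stress_weights must be 7 non-negative values summing to 1")
        if len(self.shell_weights) != 5:
            raise ValueError("shell_weights needs one weight per shell (5)")


@dataclass
class WindConfig:
    """Wake-corridor and topographic-compression parameters."""

    #: recovery length L = c · height · (1 − porosity), in metres.
    recovery_coefficient: float = 7.0
    #: corridor width in cells per species (crown footprint).
    corridor_width_cells: dict = field(
        default_factory=lambda: {GRASS: 1, SHRUB: 1, TREE: 1})
    #: wake-combination rule: "min" (strongest shelter wins) or "product".
    combine: str = "min"
    #: residual wake factor reached at a recovery length (defines the e-folding).
    recovered_fraction: float = 0.99
    #: logistic steepness for the tree wake profile.
    tree_logistic_k: float = 10.0
    #: topographic compression u × (1 + alpha·tan(upwind slope)), capped.
    compression_alpha: float = 0.5
    compression_cap: float = 1.5


@dataclass
class TransportConfig:
    """Slab-transport parameters (Werner-style CA with a Dong-form flux law)."""

    slab_height_m: float = 0.1
    bulk_density: float = 2000.0       # kg m⁻³
    entrainment_threshold: float = 5.1  # m s⁻¹
    #: Dong-form flux q(u) = A·(u−u_t)·u², pre-scaled to slabs per cell per
    #: event; default calibrated so u = 10 m/s over bare sand moves ~1 slab.
    flux_coefficient: float = 1.0 / ((10.0 - 5.1) * 10.0 ** 2)
    shadow_angle_deg: float = 15.0
    repose_bare_deg: float = 30.0
    repose_vegetated_deg: float = 40.0
    p_deposit_bare: float = 0.6
    p_deposit_vegetated: float = 1.0
    p_erode_bare: float = 1.0
    #: multiplier on p_erode when the source cell is vegetated.
    p_erode_vegetated_factor: float = 0.3
    max_avalanche_sweeps: int = 100_000
    max_hops: int = 10_000


@dataclass
class GridConfig:
    width: int = 150
    height: int = 150
    cell_size: float = 1.0       # metres per cell edge
    boundary_mode: str = "periodic"   # or "open"
    cover_fraction: float = 0.90
    species_mix: dict = field(
        default_factory=lambda: {GRASS: 0.55, SHRUB: 0.30, TREE: 0.15})
    sand_seed_range: tuple = (5, 15)  # uniform initial slab depth (inclusive)
    base_height_slabs: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"grid dimensions must be positive, got "
                             f"{self.width}x{self.height}")
        if not 0.0 <= self.cover_fraction <= 1.0:
            raise ValueError(f"cover_fraction must be in [0,1], got "
                             f"{self.cover_fraction}")
        if self.boundary_mode not in ("periodic", "open"):
            raise ValueError(f"boundary_mode must be periodic|open, got "
                             f"{self.boundary_mode!r}")


@dataclass
class VistaConfig:
    """Top-level configuration bundle."""

    grid: GridConfig = field(default_factory=GridConfig)
    ecology: EcologyConfig = field(default_factory=EcologyConfig)
    wind: WindConfig = field(default_factory=WindConfig)
    transport: TransportConfig = field(default_factory=TransportConfig)
    version: str = CONFIG_VERSION

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: conv(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj
        return conv(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "VistaConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw or {})

    @classmethod
    def from_dict(cls, raw: dict) -> "VistaConfig":
        cfg = cls()
        for block_name, block_cls in (("grid", GridConfig),
                                      ("ecology", EcologyConfig),
                                      ("wind", WindConfig),
                                      ("transport", TransportConfig)):
            if block_name not in raw:
                continue
            block_raw = dict(raw[block_name])
            if block_name == "ecology" and "species" in block_raw:
                block_raw["species"] = {
                    int(k): SpeciesParams(**v) if isinstance(v, dict) else v
                    for k, v in block_raw["species"].items()}
            for tup_field in ("shell_weights", "stress_weights",
                              "bare_soil_prior", "sand_seed_range",
                              "species_mix", "corridor_width_cells"):
                if tup_field in block_raw and isinstance(block_raw[tup_field], list):
                    block_raw[tup_field] = tuple(block_raw[tup_field])
                if tup_field in block_raw and isinstance(block_raw[tup_field], dict):
                    block_raw[tup_field] = {int(k): v for k, v
                                            in block_raw[tup_field].items()}
            setattr(cfg, block_name, block_cls(**block_raw))
        return cfg

    def hash(self) -> str:
        """Stable short hash identifying this parameterisation."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def smoke_profile() -> VistaConfig:
    """Small, fast configuration for tests and smoke runs (30×30 lattice)."""
    cfg = VistaConfig()
    cfg.grid = GridConfig(width=30, height=30)
    return cfg


def full_profile() -> VistaConfig:
    """Reference full-scale configuration (150×150 lattice)."""
    return VistaConfig()
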