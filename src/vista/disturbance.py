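"""Fire and grazing disturbances.

Fire is a periodic, domain-wide probabilistic event in the late dry
season (SON): each plant burns with a species-specific probability
(grass most flammable, trees least), burned cells become bare and carry
a one-season fire-stress echo. There is no fire-front propagation.

Grazing is spatially averaged: a seasonal forage demand proportional to
the stocking rate (LSU per hectare) is removed from standing growth
units, preferentially from grasses, then shrubs; trees are not browsed.
Each grazed plant receives a grazing-stress component proportional to
its relative offtake.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import GRASS, SHRUB, EcologyConfig
from .grid import ModelClock, SimulationGrid
from .vegetation import GrowthPathways

#: named fire regimes: mean interval between fires, years.
FIRE_INTERVALS = {"low": 10, "medium": 5, "high": 2, "none": None}
#: named grazing regimes: stocking rate, LSU per hectare.
STOCKING_RATES = {"low": 0.001, "medium": 0.01, "high": 0.06, "none": 0.0}

#: season in which fires occur (late dry season).
FIRE_SEASON_INDEX = 3   # SON


@dataclass(frozen=True)
class DisturbanceRegime:
    """A fire-frequency / stocking-rate combination."""

    fire_interval_years: Optional[int] = None   # None = no fire
    stocking_rate: float = 0.0                  # LSU per hectare

    def __post_init__(self):
        if self.fire_interval_years is not None \
                and self.fire_interval_years < 1:
            raise ValueError("fire interval must be >= 1 year or None")
        if self.stocking_rate < 0:
            raise ValueError("stocking rate must be non-negative")

    @classmethod
    def from_labels(cls, fire: str = "none", grazing="none"
                    ) -> "DisturbanceRegime":
        stocking = STOCKING_RATES[grazing] if isinstance(grazing, str) \
            else float(grazing)
        return cls(fire_interval_years=FIRE_INTERVALS[fire],
                   stocking_rate=stocking)


def fire_due(clock: ModelClock, regime: DisturbanceRegime,
             start_year: int) -> bool:
    """True exactly in fire years (every interval-th year from the start)
    during the fire season."""
    if regime.fire_interval_years is None:
        return False
    return (clock.season_index == FIRE_SEASON_INDEX
            and (clock.year - start_year) % regime.fire_interval_years == 0)


def apply_fire(grid: SimulationGrid, rng: np.random.Generator,
               pathways: GrowthPathways = None) -> int:
    """Burn the landscape once; returns the number of cells burned.

    Each occupied cell loses its plant with the species burn
    probability; burned cells become bare and keep a fire-stress flag
    for the following season's stress vector.
    """
    pathways = pathways or GrowthPathways()
    burn_p = pathways._array("burn_probability", 0.0)[grid.species]
    burns = grid.occupied & (rng.random(grid.shape) < burn_p)
    grid.species[burns] = 0
    grid.growth_units[burns] = 0.0
    grid.age[burns] = 0
    grid.fire_stress[burns] = 1.0
    return int(burns.sum())


def grazing_demand(stocking_rate: float, grid: SimulationGrid,
                   eco: EcologyConfig = None) -> float:
    """Seasonal forage demand in growth units: stocking × area × intake."""
    eco = eco or EcologyConfig()
    return stocking_rate * grid.area_ha * eco.intake_gu_per_lsu_season


def apply_grazing(grid: SimulationGrid, stocking_rate: float,
                  rng: np.random.Generator,
                  eco: EcologyConfig = None) -> float:
    """Remove one season's forage demand from standing growth units.

    Demand is taken from grasses first (down to an ungrazeable stubble),
    the remainder from shrubs, spread uniformly over each pool in
    proportion to grazeable growth units. Sets the per-plant
    grazing-stress component to the relative offtake. Returns the
    growth units actually removed.
    """
    eco = eco or EcologyConfig()
    if stocking_rate < 0:
        raise ValueError("stocking rate must be non-negative")
    demand = grazing_demand(stocking_rate, grid, eco)
    if demand == 0:
        return 0.0
    removed = 0.0
    floor = eco.grazing_floor_gu
    pathways = GrowthPathways(eco.species)
    palat_grass = pathways.params(GRASS).palatability
    for code in (GRASS, SHRUB):
        if demand <= removed:
            break
        mask = grid.species == code
        grazeable = np.where(mask,
                             np.maximum(0.0, grid.growth_units - floor), 0.0)
        pool = float(grazeable.sum())
        if pool <= 0:
            continue
        # residual demand switches to browse at reduced intensity
        want = demand - removed
        if code == SHRUB and palat_grass > 0:
            want *= pathways.params(SHRUB).palatability / palat_grass
        frac = min(1.0, want / pool)
        offtake = grazeable * frac
        before = grid.growth_units.copy()
        grid.growth_units = grid.growth_units - offtake
        removed += float(offtake.sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(mask & (before > 0), offtake / np.maximum(before,
                                                                     1e-12),
                           0.0)
        grid.grazing_stress = np.clip(grid.grazing_stress + rel, 0.0, 1.0)
    return removed
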