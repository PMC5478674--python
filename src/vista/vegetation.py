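"""Vegetation dynamics: growth pathways, neighbourhood interaction,
compound stress, mortality and recruitment.

Runs once per season, synchronously: every decision is computed from a
snapshot of the lattice taken at the start of the update plus three
per-cell uniform fields drawn in a fixed order (mortality,
establishment, species choice), so the result is independent of any
cell iteration order.

The stress model combines the neighbourhood interaction with six
factors — precipitation response, biomass, age, sediment balance,
grazing and fire — into a compound stress that maps to a seasonal
mortality probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage

from .config import BARE, GRASS, SHRUB, TREE, EcologyConfig, SpeciesParams
from .grid import N_SHELLS, SimulationGrid, shells

PLANT_CODES = (GRASS, SHRUB, TREE)
RING_SIZES = tuple(8 * k for k in range(1, N_SHELLS + 1))

_LOGISTIC_K = 6.0


def _logistic_norm(x: np.ndarray) -> np.ndarray:
    """Normalised logistic on [0,1]: 0 at 0, 1 at 1, monotone increasing."""
    x = np.clip(x, 0.0, 1.0)
    s = 1.0 / (1.0 + np.exp(-_LOGISTIC_K * (x - 0.5)))
    s0 = 1.0 / (1.0 + np.exp(_LOGISTIC_K / 2.0))
    s1 = 1.0 / (1.0 + np.exp(-_LOGISTIC_K / 2.0))
    return (s - s0) / (s1 - s0)


class GrowthPathways:
    """Species growth pathways: growth_units → biomass, height, porosity.

    Biomass and height follow a normalised logistic of the pathway
    position g/g_max (nonlinear, monotone, saturating); porosity is a
    species constant. Code-indexed parameter arrays (index 0 = bare,
    harmless dummies) support vectorised field operations.
    """

    def __init__(self, species: Optional[Dict[int, SpeciesParams]] = None):
        self.species = species or EcologyConfig().species

    def params(self, code: int) -> SpeciesParams:
        return self.species[code]

    def _array(self, attr: str, bare_value: float) -> np.ndarray:
        out = np.full(4, bare_value, dtype=float)
        for code in PLANT_CODES:
            out[code] = getattr(self.species[code], attr)
        return out

    def g_max_array(self) -> np.ndarray:
        return self._array("g_max", 1.0)

    def lifespan_array(self) -> np.ndarray:
        return self._array("lifespan_seasons", 1e9)

    def biomass(self, code: int, g: float) -> float:
        p = self.species[code]
        return float(p.b_max * _logistic_norm(np.asarray(g / p.g_max)))

    def height(self, code: int, g: float) -> float:
        p = self.species[code]
        return float(p.h_max * _logistic_norm(np.asarray(g / p.g_max)))

    def porosity(self, code: int) -> float:
        return self.species[code].porosity

    # -- vectorised field helpers -------------------------------------
    def relative_biomass_field(self, species: np.ndarray,
                               growth_units: np.ndarray) -> np.ndarray:
        """biomass / b_max per cell (0 on bare cells)."""
        g_max = self.g_max_array()[species]
        rel = _logistic_norm(growth_units / g_max)
        rel[species == BARE] = 0.0
        return rel

    def height_field(self, species: np.ndarray,
                     growth_units: np.ndarray) -> np.ndarray:
        h_max = self._array("h_max", 0.0)[species]
        return h_max * _logistic_norm(
            growth_units / self.g_max_array()[species])

    def porosity_field(self, species: np.ndarray) -> np.ndarray:
        return self._array("porosity", 1.0)[species]


# ---------------------------------------------------------------------------
# moisture response
# ---------------------------------------------------------------------------

def moisture_delta(species: np.ndarray, season_precip: float,
                   pathways: GrowthPathways) -> np.ndarray:
    """Seasonal growth-unit increment in [−1, +1] from available moisture.

    Piecewise linear: +1 at/above the species optimum, falling to 0 at
    the harsh threshold, then negative (growth units are lost) down to
    −1 at zero precipitation.
    """
    if season_precip < 0:
        raise ValueError("season_precip must be non-negative")
    harsh = pathways._array("harsh_mm", 1.0)[species]
    opt = pathways._array("optimum_mm", 2.0)[species]
    p = float(season_precip)
    above = np.clip((p - harsh) / (opt - harsh), 0.0, 1.0)
    below = np.where(harsh > 0, np.clip((p - harsh) / harsh, -1.0, 0.0), 0.0)
    return np.where(p >= harsh, above, below)


def moisture_growth_increment(plant, season_precip: float,
                              pathways: GrowthPathways) -> float:
    """Scalar moisture response for one plant (see :func:`moisture_delta`)."""
    return float(moisture_delta(np.asarray(plant.species), season_precip,
                                pathways))


# ---------------------------------------------------------------------------
# neighbourhood interaction
# ---------------------------------------------------------------------------

@dataclass
class InteractionKernel:
    """Signed plant-interaction weights over the five shells.

    Positive weights are facilitation, negative competition; the default
    facilitates at shells 1–2 and competes at shells 3–5 (short-range
    facilitation, longer-range competition). Weights are normalised by
    ring size so a full ring of maximum-biomass neighbours contributes
    exactly the shell weight.
    """

    shell_weights: Tuple[float, ...] = (1.0, 0.5, -0.4, -0.6, -0.8)
    pair_scale: Optional[dict] = None   # (focal, neighbour) -> multiplier
    gain: float = 2.0                   # logistic squash gain

    @classmethod
    def from_config(cls, eco: EcologyConfig) -> "InteractionKernel":
        return cls(shell_weights=tuple(eco.shell_weights),
                   pair_scale=eco.pair_scale, gain=eco.neighbourhood_gain)

    def weight(self, focal: int, neighbour: int, shell: int) -> float:
        """Per-neighbour weight at a shell (1-based), ring-size normalised."""
        scale = 1.0
        if self.pair_scale:
            scale = self.pair_scale.get((focal, neighbour), 1.0)
        return self.shell_weights[shell - 1] * scale / RING_SIZES[shell - 1]

    def footprint(self, focal: int, neighbour: int) -> np.ndarray:
        """11×11 convolution kernel combining all five shells."""
        size = 2 * N_SHELLS + 1
        k = np.zeros((size, size))
        for dr in range(-N_SHELLS, N_SHELLS + 1):
            for dc in range(-N_SHELLS, N_SHELLS + 1):
                d = max(abs(dr), abs(dc))
                if 1 <= d <= N_SHELLS:
                    k[dr + N_SHELLS, dc + N_SHELLS] = \
                        self.weight(focal, neighbour, d)
        return k


def squash_interaction(s, gain: float = 2.0):
    """Map a signed interaction sum to a [0,1] stress (0.5 = neutral)."""
    return 1.0 / (1.0 + np.exp(gain * np.asarray(s, dtype=float)))


def interaction_sum(grid: SimulationGrid, cell: tuple,
                    kernel: InteractionKernel,
                    pathways: GrowthPathways) -> float:
    """Signed shell sum for one focal cell by direct enumeration."""
    r, c = cell
    focal = int(grid.species[r, c])
    if focal == BARE:
        raise ValueError(f"cell {cell} is unoccupied")
    total = 0.0
    for k, ring in enumerate(shells(grid, cell), start=1):
        for (rr, cc) in ring:
            nb = int(grid.species[rr, cc])
            if nb == BARE:
                continue
            rel_b = grid.growth_units[rr, cc] / pathways.params(nb).g_max
            rel_b = float(_logistic_norm(np.asarray(rel_b)))
            total += kernel.weight(focal, nb, k) * rel_b
    return total


def neighbourhood_stress(grid: SimulationGrid, cell: tuple,
                         kernel: InteractionKernel,
                         pathways: Optional[GrowthPathways] = None) -> float:
    """Neighbourhood stress component for one occupied cell.

    Facilitation (positive interaction sum) lowers stress below the
    neutral 0.5; competition raises it.
    """
    pathways = pathways or GrowthPathways()
    return float(squash_interaction(
        interaction_sum(grid, cell, kernel, pathways), kernel.gain))


def interaction_sum_fields(species: np.ndarray, rel_biomass: np.ndarray,
                           kernel: InteractionKernel,
                           boundary_mode: str) -> np.ndarray:
    """Signed interaction sum per cell and focal species, vectorised.

    Returns an array of shape (3, H, W): the sum a plant of each focal
    species would experience at every cell.
    """
    mode = "wrap" if boundary_mode == "periodic" else "constant"
    out = np.zeros((3,) + species.shape)
    sources = {t: rel_biomass * (species == t) for t in PLANT_CODES}
    for fi, focal in enumerate(PLANT_CODES):
        for t in PLANT_CODES:
            out[fi] += ndimage.convolve(sources[t],
                                        kernel.footprint(focal, t),
                                        mode=mode, cval=0.0)
    return out


# ---------------------------------------------------------------------------
# scalar stress components
# ---------------------------------------------------------------------------

def sediment_balance_stress(cell_sand_delta: float, species: int,
                            pathways: GrowthPathways,
                            gamma: float = 1.0) -> float:
    """Burial/exposure stress: 0 at zero net change, saturating at the
    species tolerance for either sign of imbalance."""
    tol = pathways.params(species).sediment_tol_slabs
    return float(np.clip(abs(cell_sand_delta) / tol, 0.0, 1.0) ** gamma)


@dataclass(frozen=True)
class StressVector:
    """Per-plant stress components, each in [0,1]."""

    neighbourhood: float
    precipitation: float
    biomass: float
    age: float
    sediment_balance: float
    grazing: float
    fire: float

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"stress component {name}={v} outside [0,1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.neighbourhood, self.precipitation, self.biomass,
                         self.age, self.sediment_balance, self.grazing,
                         self.fire])


def compound_stress(vector, weights, p0: float = 0.01,
                    gamma: float = 3.0) -> float:
    """Seasonal mortality probability from a stress vector.

    p = p0 + (1 − p0) · (Σ wᵢ sᵢ)^γ — exactly p0 when every component is
    zero, exactly 1 when every component is one, and monotone
    non-decreasing in each component.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    s = vector.as_array() if isinstance(vector, StressVector) \
        else np.asarray(vector, dtype=float)
    if len(s) != len(w):
        raise ValueError(f"stress vector length {len(s)} != weights {len(w)}")
    m = float(np.dot(w, s))
    return float(np.clip(p0 + (1.0 - p0) * m ** gamma, 0.0, 1.0))


# ---------------------------------------------------------------------------
# the seasonal update
# ---------------------------------------------------------------------------

def _stress_fields(grid: SimulationGrid, season_precip: float,
                   eco: EcologyConfig, kernel: InteractionKernel,
                   pathways: GrowthPathways):
    """All per-cell stress fields from the current (snapshot) state."""
    sp = grid.species
    rel_b = pathways.relative_biomass_field(sp, grid.growth_units)
    delta = moisture_delta(sp, season_precip, pathways)
    precip_stress = (1.0 - delta) / 2.0
    biomass_stress = 1.0 - rel_b
    life = pathways.lifespan_array()[sp]
    ramp = eco.age_ramp_fraction
    age_stress = np.clip((grid.age - (1.0 - ramp) * life) / (ramp * life),
                         0.0, 1.0)
    tol = pathways._array("sediment_tol_slabs", 1.0)[sp]
    sed_stress = np.clip(np.abs(grid.sand_delta) / tol, 0.0, 1.0) \
        ** eco.sediment_gamma
    s_all = interaction_sum_fields(sp, rel_b, kernel, grid.boundary_mode)
    s_focal = np.zeros(grid.shape)
    for fi, code in enumerate(PLANT_CODES):
        s_focal[sp == code] = s_all[fi][sp == code]
    neigh_stress = squash_interaction(s_focal, kernel.gain)
    facil_sum_empty = s_all.mean(axis=0)   # for recruitment on empty cells
    return (delta, precip_stress, biomass_stress, age_stress, sed_stress,
            neigh_stress, facil_sum_empty, rel_b)


def vegetation_step(grid: SimulationGrid, season_precip: float,
                    eco: EcologyConfig, rng: np.random.Generator,
                    kernel: Optional[InteractionKernel] = None,
                    pathways: Optional[GrowthPathways] = None) -> dict:
    """One synchronous seasonal vegetation update, in place.

    Every occupant ages one season, gains or loses growth units from the
    moisture response, and dies with its compound-stress probability (or
    at its lifespan cap). Cells that are empty afterwards may recruit a
    new plant: establishment needs a positive moisture response, is
    boosted by net facilitation, and the species is drawn grass-biased
    on bare soil or by neighbour copying otherwise.

    Exactly three uniform fields are drawn from ``rng``, in the order
    mortality, establishment, species choice — the update is therefore
    independent of any cell ordering.
    """
    kernel = kernel or InteractionKernel.from_config(eco)
    pathways = pathways or GrowthPathways(eco.species)
    sp = grid.species.copy()
    gu = grid.growth_units.copy()
    age = grid.age.copy()
    occ = sp > BARE

    (delta, precip_stress, biomass_stress, age_stress, sed_stress,
     neigh_stress, facil_empty, _rel_b) = _stress_fields(
        grid, season_precip, eco, kernel, pathways)

    w = np.asarray(eco.stress_weights)
    m = (w[0] * neigh_stress + w[1] * precip_stress + w[2] * biomass_stress
         + w[3] * age_stress + w[4] * sed_stress + w[5] * grid.grazing_stress
         + w[6] * grid.fire_stress)
    p_die = np.clip(eco.p0 + (1.0 - eco.p0) * m ** eco.mortality_gamma,
                    0.0, 1.0)

    u_mort = rng.random(grid.shape)
    life = pathways.lifespan_array()[sp]
    dies = occ & ((u_mort < p_die) | (age >= life))
    survives = occ & ~dies

    # --- recruitment (decisions from the snapshot state) ---------------
    g_max = pathways.g_max_array()
    moisture_w = {t: max(0.0, float(moisture_delta(np.asarray(t),
                                                   season_precip, pathways)))
                  for t in PLANT_CODES}
    best_w = max(moisture_w.values())
    empty_after = ~survives

    mode = "wrap" if grid.boundary_mode == "periodic" else "constant"
    near = np.zeros((2 * 2 + 1,) * 2)
    near[:] = 1.0
    near[2, 2] = 0.0     # shells 1–2 ones-kernel
    # neighbour influence on species choice is biomass-weighted: a heavily
    # defoliated canopy seeds its surroundings weakly
    counts = np.stack([ndimage.convolve(np.where(sp == t, _rel_b, 0.0), near,
                                        mode=mode, cval=0.0)
                       for t in PLANT_CODES])

    facil_term = (0.5 - squash_interaction(facil_empty, kernel.gain)) * 2.0
    p_est = np.clip(eco.recruit_base * best_w
                    * (1.0 + eco.recruit_facilitation_gain * facil_term),
                    0.0, 1.0)
    u_est = rng.random(grid.shape)
    recruits = empty_after & (u_est < p_est) & (best_w > 0)

    prior = np.asarray(eco.bare_soil_prior, dtype=float)[:, None, None]
    # freshly burned ground recruits like bare soil: grasses preferentially
    # recolonise bare areas
    bare_soil = (counts.sum(axis=0) == 0) | (grid.fire_stress >= 1.0)
    # pure pioneer prior on bare soil; neighbour copying, still modulated
    # by the pioneer prior, elsewhere
    base_weight = np.where(bare_soil[None], prior,
                           (counts + eco.copy_epsilon) * prior)
    mw = np.array([moisture_w[t] for t in PLANT_CODES])[:, None, None]
    sp_weight = base_weight * mw
    tot = sp_weight.sum(axis=0)
    ok = tot > 0
    recruits &= ok
    with np.errstate(invalid="ignore", divide="ignore"):
        cum = np.cumsum(sp_weight / np.where(ok, tot, 1.0)[None], axis=0)
    u_sp = rng.random(grid.shape)
    chosen_idx = (u_sp > cum[0]).astype(np.int8) + (u_sp > cum[1])
    chosen_species = np.array(PLANT_CODES, dtype=np.int8)[chosen_idx]

    # --- apply synchronously -------------------------------------------
    new_sp = np.where(survives, sp, BARE).astype(np.int8)
    new_gu = np.where(survives,
                      np.clip(gu + delta, 0.0, g_max[sp]), 0.0)
    new_age = np.where(survives, age + 1, 0)
    new_sp[recruits] = chosen_species[recruits]
    new_gu[recruits] = np.minimum(eco.recruit_growth_units,
                                  g_max[chosen_species][recruits])
    new_age[recruits] = 0

    grid.species = new_sp
    grid.growth_units = new_gu
    grid.age = new_age.astype(np.int64)
    # seasonal accumulators are consumed by this update; the fire flag
    # echoes at half strength into one further season before clearing
    grid.sand_delta[:] = 0.0
    grid.grazing_stress[:] = 0.0
    grid.fire_stress = np.where(grid.fire_stress >= 1.0, 0.5, 0.0)
    return {"deaths": int(dies.sum()), "recruits": int(recruits.sum()),
            "mean_mortality_p": float(p_die[occ].mean()) if occ.any() else 0.0}
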