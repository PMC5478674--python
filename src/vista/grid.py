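"""Lattice world state: cells, clock, neighbourhood shells, initialisation.

The world is a rectangular lattice of square cells. Each cell carries a
sand column measured in discrete slabs on top of an immobile substrate,
and at most one plant (grass, shrub or tree) described by its position
along a species growth pathway. Seasonal bookkeeping needed by the
stress model (net slab change, grazing offtake, fire flags) also lives
per cell and is reset by each vegetation update.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .config import (BARE, GRASS, SEASONS, SHRUB, TREE, GridConfig,
                     SPECIES_NAMES, VistaConfig)

# ---------------------------------------------------------------------------
# clock
# ---------------------------------------------------------------------------

WIND_EVENTS_PER_SEASON = 20


@dataclass
class ModelClock:
    """Simulation calendar: 4 seasons a year, 20 wind events a season.

    The vegetation module runs once per season, after the season's wind
    events.
    """

    year: int = 0
    season_index: int = 0          # 0=DJF, 1=MAM, 2=JJA, 3=SON
    wind_event_index: int = 0      # 0–19 within the season

    @property
    def season(self) -> str:
        return SEASONS[self.season_index]

    def advance_wind_event(self) -> bool:
        """Advance one wind event; returns True when a season rolled over.

        The season advances automatically after every 20th event — the
        vegetation update is due exactly when this returns True.
        """
        self.wind_event_index += 1
        if self.wind_event_index >= WIND_EVENTS_PER_SEASON:
            self.advance_season()
            return True
        return False

    def advance_season(self) -> None:
        self.wind_event_index = 0
        self.season_index += 1
        if self.season_index == len(SEASONS):
            self.season_index = 0
            self.year += 1


# ---------------------------------------------------------------------------
# plant view
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantState:
    """Immutable view of one plant (storage is array-of-cells, not objects)."""

    species: int                  # GRASS | SHRUB | TREE
    growth_units: float
    age: int = 0                  # seasons

    def __post_init__(self):
        if self.species not in (GRASS, SHRUB, TREE):
            raise ValueError(f"not a plant species code: {self.species}")
        if self.growth_units < 0:
            raise ValueError("growth_units must be non-negative")

    @property
    def species_name(self) -> str:
        return SPECIES_NAMES[self.species]


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------

class SimulationGrid:
    """The single mutable world state.

    Attributes
    ----------
    sand_height, base_height : int arrays (slabs)
    species : int8 array, 0 bare / 1 grass / 2 shrub / 3 tree
    growth_units, age : plant state arrays (meaningless where bare)
    sand_delta : net slab change since the last vegetation update
    grazing_stress, fire_stress : [0,1] stress components set by the
        disturbance sub-modules, consumed and cleared by the vegetation step
    """

    def __init__(self, width: int, height: int, cell_size: float = 1.0,
                 boundary_mode: str = "periodic", slab_height: float = 0.1):
        if width <= 0 or height <= 0:
            raise ValueError(f"grid dimensions must be positive, got "
                             f"{width}x{height}")
        if boundary_mode not in ("periodic", "open"):
            raise ValueError(f"boundary_mode must be periodic|open, got "
                             f"{boundary_mode!r}")
        self.width = int(width)       # columns (x, eastward)
        self.height = int(height)     # rows (y, southward)
        self.cell_size = float(cell_size)
        self.slab_height = float(slab_height)
        self.boundary_mode = boundary_mode
        shape = (self.height, self.width)
        self.sand_height = np.zeros(shape, dtype=np.int64)
        self.base_height = np.zeros(shape, dtype=np.int64)
        self.species = np.zeros(shape, dtype=np.int8)
        self.growth_units = np.zeros(shape, dtype=np.float64)
        self.age = np.zeros(shape, dtype=np.int64)
        self.soil_nutrients = np.zeros(shape, dtype=np.float64)  # placeholder attribute
        self.sand_delta = np.zeros(shape, dtype=np.float64)
        self.grazing_stress = np.zeros(shape, dtype=np.float64)
        self.fire_stress = np.zeros(shape, dtype=np.float64)
        self.clock = ModelClock()

    # -- geometry ------------------------------------------------------
    @property
    def shape(self) -> tuple:
        return (self.height, self.width)

    @property
    def n_cells(self) -> int:
        return self.width * self.height

    @property
    def area_ha(self) -> float:
        """Domain area in hectares."""
        return self.n_cells * self.cell_size ** 2 / 1.0e4

    def surface_m(self) -> np.ndarray:
        """Total surface elevation (substrate + sand), metres."""
        return (self.base_height + self.sand_height) * self.slab_height

    # -- occupancy -----------------------------------------------------
    @property
    def occupied(self) -> np.ndarray:
        return self.species > BARE

    def occupant(self, row: int, col: int) -> Optional[PlantState]:
        if self.species[row, col] == BARE:
            return None
        return PlantState(int(self.species[row, col]),
                          float(self.growth_units[row, col]),
                          int(self.age[row, col]))

    def place(self, row: int, col: int, plant: PlantState) -> None:
        """Put a plant in a cell (one occupant max, enforced by overwrite)."""
        self.species[row, col] = plant.species
        self.growth_units[row, col] = plant.growth_units
        self.age[row, col] = plant.age

    def clear(self, row: int, col: int) -> None:
        self.species[row, col] = BARE
        self.growth_units[row, col] = 0.0
        self.age[row, col] = 0

    def total_sand(self) -> int:
        return int(self.sand_height.sum())

    def copy(self) -> "SimulationGrid":
        g = SimulationGrid(self.width, self.height, self.cell_size,
                           self.boundary_mode, self.slab_height)
        for name in ("sand_height", "base_height", "species", "growth_units",
                     "age", "soil_nutrients", "sand_delta", "grazing_stress",
                     "fire_stress"):
            setattr(g, name, getattr(self, name).copy())
        g.clock = replace(self.clock)
        return g

    # -- snapshots -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows, cols = np.indices(self.shape)
        return pd.DataFrame({
            "row": rows.ravel(), "col": cols.ravel(),
            "sand_height": self.sand_height.ravel(),
            "base_height": self.base_height.ravel(),
            "species_code": self.species.ravel(),
            "growth_units": self.growth_units.ravel(),
            "age": self.age.ravel(),
        })

    def save_snapshot(self, path, seed: Optional[int] = None,
                      config: Optional[VistaConfig] = None) -> None:
        """Write the grid as a long-format CSV (gzipped if path ends .gz).

        A commented header records the provenance metadata (seed, clock,
        config hash) so snapshots are self-describing.
        """
        import gzip
        meta = (f"# vista-snapshot width={self.width} height={self.height} "
                f"cell_size={self.cell_size} slab_height={self.slab_height} "
                f"boundary={self.boundary_mode} year={self.clock.year} "
                f"season={self.clock.season} seed={seed} "
                f"config_hash={config.hash() if config else 'none'}\n")
        body = self.to_frame().to_csv(index=False)
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "wt") as fh:
            fh.write(meta)
            fh.write(body)

    @classmethod
    def load_snapshot(cls, path) -> "SimulationGrid":
        import gzip
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as fh:
            header = fh.readline()
            if not header.startswith("# vista-snapshot"):
                raise ValueError(f"{path}: not a vista snapshot file")
            meta = dict(tok.split("=", 1) for tok in header[2:].split()
                        if "=" in tok)
            df = pd.read_csv(fh)
        g = cls(int(meta["width"]), int(meta["height"]),
                float(meta["cell_size"]), meta["boundary"],
                float(meta["slab_height"]))
        idx = (df["row"].to_numpy(), df["col"].to_numpy())
        g.sand_height[idx] = df["sand_height"].to_numpy()
        g.base_height[idx] = df["base_height"].to_numpy()
        g.species[idx] = df["species_code"].to_numpy()
        g.growth_units[idx] = df["growth_units"].to_numpy()
        g.age[idx] = df["age"].to_numpy()
        return g


# ---------------------------------------------------------------------------
# neighbourhood shells (extended-Moore, five concentric rings)
# ---------------------------------------------------------------------------

N_SHELLS = 5


@dataclass(frozen=True)
class NeighbourhoodShells:
    """Five ordered rings of cell coordinates at Chebyshev distances 1–5."""

    focal: tuple
    rings: tuple  # tuple of 5 tuples of (row, col)

    def __iter__(self) -> Iterator[tuple]:
        return iter(self.rings)


def shells(grid: SimulationGrid, cell: tuple) -> NeighbourhoodShells:
    """Extended-Moore neighbourhood of a cell as five concentric shells.

    Ring k holds exactly the cells at Chebyshev distance k, wrapped under
    periodic boundaries and truncated (not erroneous) at open boundaries.
    On grids too small for distinct wrapped rings (periodic and
    min(side) < 11) wrapped duplicates are dropped so rings stay disjoint.
    """
    r0, c0 = cell
    if not (0 <= r0 < grid.height and 0 <= c0 < grid.width):
        raise ValueError(f"cell {cell} outside {grid.height}x{grid.width} grid")
    periodic = grid.boundary_mode == "periodic"
    seen = {(r0, c0)}
    rings = []
    for k in range(1, N_SHELLS + 1):
        ring = []
        for dr in range(-k, k + 1):
            for dc in range(-k, k + 1):
                if max(abs(dr), abs(dc)) != k:
                    continue
                r, c = r0 + dr, c0 + dc
                if periodic:
                    r %= grid.height
                    c %= grid.width
                elif not (0 <= r < grid.height and 0 <= c < grid.width):
                    continue
                if (r, c) in seen:   # wrapped duplicate on a tiny torus
                    continue
                seen.add((r, c))
                ring.append((r, c))
        rings.append(tuple(ring))
    return NeighbourhoodShells(focal=(r0, c0), rings=tuple(rings))


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------

def init_grid(width: int, height: int, cover_fraction: float,
              species_mix: dict, sand_seed_range: tuple,
              rng: np.random.Generator, *, cell_size: float = 1.0,
              boundary_mode: str = "periodic", slab_height: float = 0.1,
              initial_growth_units: float = None) -> SimulationGrid:
    """Random initial landscape: given vegetation cover, random sand depth.

    Exactly ``round(cover_fraction × n_cells)`` cells are occupied, with
    species drawn from ``species_mix`` (proportions over grass/shrub/tree
    summing to 1); sand depth is uniform over the inclusive slab range
    ``sand_seed_range``. Fully deterministic given ``rng``.
    """
    if not 0.0 <= cover_fraction <= 1.0:
        raise ValueError(f"cover_fraction must be in [0,1], got {cover_fraction}")
    mix_items = [(k, v) for k, v in species_mix.items() if v > 0]
    if any(k not in (GRASS, SHRUB, TREE) for k, _ in mix_items):
        bad = [k for k, _ in mix_items if k not in (GRASS, SHRUB, TREE)]
        raise ValueError(f"species_mix contains invalid species codes: {bad}")
    total = sum(v for _, v in mix_items)
    if cover_fraction > 0 and abs(total - 1.0) > 1e-6:
        raise ValueError(f"species_mix proportions must sum to 1, got {total}")

    grid = SimulationGrid(width, height, cell_size, boundary_mode, slab_height)
    lo, hi = sand_seed_range
    if lo < 0 or hi < lo:
        raise ValueError(f"sand_seed_range must be 0 <= lo <= hi, got "
                         f"{sand_seed_range}")
    grid.sand_height[:] = rng.integers(lo, hi + 1, size=grid.shape)

    n_occ = round(cover_fraction * grid.n_cells)
    if n_occ:
        flat = rng.choice(grid.n_cells, size=n_occ, replace=False)
        codes = np.array([k for k, _ in mix_items])
        probs = np.array([v for _, v in mix_items], dtype=float)
        probs /= probs.sum()
        drawn = rng.choice(codes, size=n_occ, p=probs)
        rr, cc = np.unravel_index(flat, grid.shape)
        grid.species[rr, cc] = drawn.astype(np.int8)
        if initial_growth_units is None:
            # start plants partway up their pathways so the initial canopy
            # is aerodynamically active
            from .vegetation import GrowthPathways
            gmax = GrowthPathways().g_max_array()
            grid.growth_units[rr, cc] = (
                rng.uniform(0.2, 0.6, size=n_occ) * gmax[drawn])
        else:
            grid.growth_units[rr, cc] = initial_growth_units
        grid.age[rr, cc] = rng.integers(0, 8, size=n_occ)
    return grid
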