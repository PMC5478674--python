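"""Deterministic validation fixtures for the transport rules.

Small constructed landscapes whose correct behaviour is known in closed
form: the relaxed angle of a sand column (the angle of repose) and the
cutoff angle of the lee-side shadow boundary (15°). Used by the test
suite and the acceptance script.
"""

from __future__ import annotations

import math

import numpy as np

from .config import GRASS, TransportConfig
from .grid import SimulationGrid
from .sediment import avalanche_relax, max_slope_deg, shadow_mask


def relaxed_column_max_slope(vegetated: bool, seed: int = 0,
                             size: int = 50, column_slabs: int = 200,
                             cfg: TransportConfig = None) -> float:
    """Max 8-neighbour slope angle (deg) after relaxing a central sand
    column on an otherwise flat grid, bare or fully vegetated."""
    cfg = cfg or TransportConfig()
    grid = SimulationGrid(size, size, 1.0, "periodic", cfg.slab_height_m)
    if vegetated:
        grid.species[:] = GRASS
        grid.growth_units[:] = 4.0
    grid.sand_height[size // 2, size // 2] = column_slabs
    before = grid.total_sand()
    avalanche_relax(grid, np.random.default_rng(seed), cfg)
    assert grid.total_sand() == before, "avalanche must conserve sand"
    return max_slope_deg(grid)


def shadow_cutoff_angle(heights_slabs=None, cfg: TransportConfig = None
                        ) -> float:
    """Asymptotic lee-side shadow boundary angle (deg).

    For a sweep of isolated block heights on a flat strip, the furthest
    shadowed cell downwind of the crest is located; regressing that
    distance on crest height recovers the cutoff slope, whose angle
    converges on the configured shadow angle as resolution increases.
    """
    cfg = cfg or TransportConfig()
    heights = np.asarray(heights_slabs if heights_slabs is not None
                         else np.arange(10, 201, 10))
    tan_cut = math.tan(math.radians(cfg.shadow_angle_deg))
    distances = []
    for h in heights:
        h_m = h * cfg.slab_height_m
        n_cols = int(h_m / tan_cut) + 10
        grid = SimulationGrid(n_cols, 3, 1.0, "open", cfg.slab_height_m)
        grid.base_height[:, 0] = h
        mask = shadow_mask(grid, 270.0, cfg).mask   # wind from west
        cols = np.flatnonzero(mask[1])
        distances.append(cols.max() * grid.cell_size if cols.size else 0.0)
    slope, _ = np.polyfit(heights * cfg.slab_height_m, distances, 1)
    return math.degrees(math.atan(1.0 / slope))
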