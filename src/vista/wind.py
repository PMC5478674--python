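"""Per-cell wind velocity: wake corridors behind plants, topographic
compression.

Every plant casts a rectangular wake corridor downwind. Velocity inside
a corridor starts at a porosity-scaled residual of the incident speed
and recovers over a length L = c · height · (1 − porosity): porous
shrubs shelter less than bluff-bodied grasses of the same height.
Recovery is exponential behind grasses and shrubs and logistic (slow
initial rise) behind trees. Overlapping wakes combine by taking the
minimum recovery factor (strongest shelter wins; a product rule is
available). Wind is accelerated on upwind-facing slopes by a capped
compression factor.

Directions are snapped to the 16-point compass and corridors rasterised
along the bearing with Chebyshev (Bresenham-style) steps, so no grid
rotation is ever needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .climate import DIRECTION_BIN_WIDTH, WindEvent
from .config import GRASS, SHRUB, TREE, WindConfig
from .grid import SimulationGrid
from .vegetation import GrowthPathways


# ---------------------------------------------------------------------------
# direction geometry
# ---------------------------------------------------------------------------

def snap_direction(direction: float) -> float:
    """Snap a bearing (degrees from north) to the nearest of 16 bins."""
    return (round(direction / DIRECTION_BIN_WIDTH) % 16) * DIRECTION_BIN_WIDTH


def downwind_step(direction: float) -> tuple:
    """Unit Chebyshev step (drow, dcol) pointing downwind.

    ``direction`` is where the wind blows FROM; the step advances with
    the flow. Rows grow southward, columns eastward. The step is scaled
    so max(|drow|, |dcol|) = 1 (one lattice ring per step).
    """
    azimuth = math.radians(snap_direction(direction) + 180.0)
    dcol = math.sin(azimuth)
    drow = -math.cos(azimuth)
    m = max(abs(drow), abs(dcol))
    return (drow / m, dcol / m)


def step_offsets(step: tuple, k: int) -> tuple:
    """Integer lattice offset after k Chebyshev steps (Bresenham rounding)."""
    return (int(np.rint(k * step[0])), int(np.rint(k * step[1])))


def shift2d(arr: np.ndarray, dr: int, dc: int, periodic: bool,
            fill: float = 0.0) -> np.ndarray:
    """Shift a field so dest[r, c] = src[r − dr, c − dc]."""
    if periodic:
        return np.roll(arr, (dr, dc), axis=(0, 1))
    out = np.full_like(arr, fill, dtype=arr.dtype if
                       np.issubdtype(arr.dtype, np.floating) else float)
    h, w = arr.shape
    rs, re = max(dr, 0), min(h + dr, h)
    cs, ce = max(dc, 0), min(w + dc, w)
    out[rs:re, cs:ce] = arr[rs - dr:re - dr, cs - dc:ce - dc]
    return out


# ---------------------------------------------------------------------------
# wake geometry
# ---------------------------------------------------------------------------

def wake_recovery_length(element_height: float, element_porosity: float,
                         coefficient: float = 7.0) -> float:
    """Downwind recovery length L = c · h · (1 − porosity), metres.

    Taller elements shelter further; porous elements shelter less.
    """
    if element_height < 0:
        raise ValueError("element_height must be non-negative")
    if not 0.0 <= element_porosity <= 1.0:
        raise ValueError("porosity must be in [0,1]")
    return coefficient * element_height * (1.0 - element_porosity)


def wake_profile(species: int, distance_fraction, residual: float = None,
                 cfg: WindConfig = None):
    """Velocity recovery factor at a fractional downwind distance.

    ``distance_fraction`` = downwind distance / recovery length. The
    factor starts at the porosity-scaled residual at the element and
    reaches the configured recovered fraction (0.99) at one recovery
    length: exponentially for grasses and shrubs, logistically (slow
    initial rise) for trees.
    """
    cfg = cfg or WindConfig()
    if residual is None:
        residual = GrowthPathways().porosity(species)
    x = np.clip(np.asarray(distance_fraction, dtype=float), 0.0, None)
    r0 = float(np.clip(residual, 0.0, 1.0))
    rec = cfg.recovered_fraction
    if r0 >= rec:
        out = np.ones_like(x)
    elif species == TREE:
        k = cfg.tree_logistic_k
        g = lambda t: 1.0 / (1.0 + np.exp(-k * (t - 0.5)))
        g0, g1 = g(0.0), g(1.0)
        out = r0 + (1.0 - r0) * (g(np.minimum(x, 1.0)) - g0) / (g1 - g0)
    else:
        k_e = math.log((1.0 - r0) / (1.0 - rec))
        out = 1.0 - (1.0 - r0) * np.exp(-k_e * x)
    out = np.where(x >= 1.0, 1.0, np.minimum(out, 1.0))
    return float(out) if np.isscalar(distance_fraction) else out


# ---------------------------------------------------------------------------
# the velocity field
# ---------------------------------------------------------------------------

@dataclass
class VelocityField:
    """Per-cell horizontal wind velocity for one event."""

    u: np.ndarray             # m/s per cell
    event: WindEvent
    step: tuple               # downwind unit Chebyshev step (drow, dcol)
    step_length: float        # metres advanced per step


def compute_velocity_field(grid: SimulationGrid, event: WindEvent,
                           cfg: WindConfig = None,
                           pathways: GrowthPathways = None) -> VelocityField:
    """Incident wind modulated by wake corridors and topography.

    On a flat bare lattice the field equals the incident speed
    everywhere; it never exceeds incident × compression cap.
    """
    cfg = cfg or WindConfig()
    pathways = pathways or GrowthPathways()
    periodic = grid.boundary_mode == "periodic"
    step = downwind_step(event.direction)
    step_len = grid.cell_size * math.hypot(*step)

    heights = pathways.height_field(grid.species, grid.growth_units)
    por = pathways.porosity_field(grid.species)
    L = cfg.recovery_coefficient * heights * (1.0 - por)
    active = grid.occupied & (L > 0)

    factor = np.ones(grid.shape)
    use_min = cfg.combine == "min"

    def combine(acc, contrib):
        return np.minimum(acc, contrib) if use_min else acc * contrib

    # in-canopy residual at the element cell itself
    src0 = np.where(active, por, 1.0)
    factor = combine(factor, src0)

    widths = np.ones(grid.shape, dtype=int)
    for code, w in (cfg.corridor_width_cells or {}).items():
        widths[grid.species == code] = w
    max_w = int(widths[active].max()) if active.any() else 1
    perp = (step[1], -step[0])   # lateral unit vector

    if active.any():
        k_max = int(math.ceil(L.max() / step_len))
        with np.errstate(divide="ignore"):
            inv_l = np.where(active, 1.0 / np.where(L > 0, L, 1.0), 0.0)
        profiles = np.ones(grid.shape)
        for k in range(1, k_max + 1):
            frac = np.where(active, k * step_len * inv_l, 2.0)
            in_wake = active & (frac < 1.0)
            if not in_wake.any():
                break
            profiles[:] = 1.0
            for code in (GRASS, SHRUB, TREE):
                msk = in_wake & (grid.species == code)
                if msk.any():
                    profiles[msk] = wake_profile(
                        code, frac[msk], residual=pathways.porosity(code),
                        cfg=cfg)
            dr, dc = step_offsets(step, k)
            for j in range(-(max_w // 2), max_w // 2 + 1):
                src = profiles if max_w == 1 else np.where(
                    in_wake & (widths > 2 * abs(j)), profiles, 1.0)
                ldr = dr + int(np.rint(j * perp[0]))
                ldc = dc + int(np.rint(j * perp[1]))
                factor = combine(factor,
                                 shift2d(src, ldr, ldc, periodic, fill=1.0))

    # topographic compression on upwind-facing slopes
    surf = grid.surface_m()
    dr1, dc1 = step_offsets(step, 1)
    upwind_surf = shift2d(surf, dr1, dc1, periodic, fill=np.nan)
    slope = (surf - upwind_surf) / step_len
    slope = np.where(np.isfinite(slope), slope, 0.0)
    compression = np.clip(1.0 + cfg.compression_alpha * np.maximum(slope, 0.0),
                          1.0, cfg.compression_cap)

    u = event.speed * np.clip(factor, 0.0, 1.0) * compression
    return VelocityField(u=u, event=event, step=step, step_length=step_len)
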