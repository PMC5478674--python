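"""Slab-based aeolian sediment transport (Werner-style cellular automaton).

Sand is carried in discrete slabs. Each wind event polls every cell
once in random order; a cell that is not shadowed, whose local velocity
exceeds the 5.1 m/s entrainment threshold and which passes its erosion
probability releases a slab count given by a Dong-form flux law
q(u) = A·(u − u_t)·u². Released slabs hop one cell downwind at a time,
depositing at each visited cell with a probability that is elevated on
vegetated cells and certain inside shadow zones. Shadow zones fill the
lee of topography below a 15° line from upwind crests. Avalanching
restores the angle of repose (30° on bare sand, 40° under vegetation).

Under periodic boundaries every eroded slab is re-deposited, so total
sand is conserved exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import BARE, TransportConfig
from .grid import SimulationGrid
from .wind import VelocityField, downwind_step, shift2d, step_offsets


@dataclass
class TransportTally:
    """Per-event (and accumulable) transport bookkeeping."""

    eroded_slabs: int = 0
    deposited_slabs: int = 0
    exported_slabs: int = 0        # slabs lost over open boundaries
    slab_volume_m3: float = 0.1    # volume of one slab (cell area × height)
    bulk_density: float = 2000.0   # kg m⁻³

    @property
    def transported_volume_m3(self) -> float:
        return self.eroded_slabs * self.slab_volume_m3

    @property
    def transported_mass_kg(self) -> float:
        return self.transported_volume_m3 * self.bulk_density

    def merge(self, other: "TransportTally") -> None:
        self.eroded_slabs += other.eroded_slabs
        self.deposited_slabs += other.deposited_slabs
        self.exported_slabs += other.exported_slabs


# ---------------------------------------------------------------------------
# erosion magnitude
# ---------------------------------------------------------------------------

def erosion_volume(u: float, available_slabs: int,
                   cfg: TransportConfig = None) -> float:
    """Slab count eroded at a cell with local velocity ``u``.

    Dong-form flux q(u) = A·(u − u_t)·u², zero at or below the
    entrainment threshold, pre-scaled to slabs per event and capped by
    the sand available in the cell.
    """
    cfg = cfg or TransportConfig()
    if u < 0:
        raise ValueError("velocity must be non-negative")
    if u <= cfg.entrainment_threshold:
        return 0.0
    q = cfg.flux_coefficient * (u - cfg.entrainment_threshold) * u ** 2
    return float(min(q, available_slabs))


# ---------------------------------------------------------------------------
# shadow zones
# ---------------------------------------------------------------------------

@dataclass
class ShadowMask:
    """Per-cell flag: in the 15° lee shadow of upwind topography."""

    mask: np.ndarray
    direction: float


def shadow_mask(grid: SimulationGrid, direction: float,
                cfg: TransportConfig = None) -> ShadowMask:
    """Cells strictly below the 15° line descending from upwind crests.

    The shadow line is propagated downwind one Chebyshev step at a time:
    S ← max(surface, S − step·tan 15°); a cell is shadowed when the
    propagated line from some upwind crest lies strictly above its own
    surface.
    """
    cfg = cfg or TransportConfig()
    periodic = grid.boundary_mode == "periodic"
    step = downwind_step(direction)
    step_len = grid.cell_size * math.hypot(*step)
    drop = step_len * math.tan(math.radians(cfg.shadow_angle_deg))
    surf = grid.surface_m()

    relief = float(surf.max() - surf.min())
    n_steps = int(math.ceil(relief / drop)) if relief > 0 else 0
    n_steps = min(n_steps, max(grid.shape) if periodic else
                  int(math.hypot(*grid.shape)) + 1)
    dr, dc = step_offsets(step, 1)
    line = surf.copy()
    shadowed = np.zeros(grid.shape, dtype=bool)
    for _ in range(n_steps):
        line = shift2d(line, dr, dc, periodic, fill=-np.inf) - drop
        shadowed |= line > surf + 1e-9
        line = np.maximum(line, surf)
    return ShadowMask(mask=shadowed, direction=direction)


# ---------------------------------------------------------------------------
# transport iteration
# ---------------------------------------------------------------------------

def transport_iteration(grid: SimulationGrid, vfield: VelocityField,
                        rng: np.random.Generator,
                        cfg: TransportConfig = None,
                        shadow: ShadowMask = None
                        ) -> TransportTally:
    """One wind event of slab transport; mutates the grid in place.

    Cells are polled exactly once in random order. Slabs hop one cell
    per deposition trial along the straight downwind ray and deposit
    with probability p_d (0.6 bare, 1.0 on vegetated or shadowed
    cells). Fractional erosion volumes are realised by stochastic
    rounding so the mean matches the flux law while slabs stay integer.
    """
    cfg = cfg or TransportConfig()
    shadow = shadow or shadow_mask(grid, vfield.event.direction, cfg)
    periodic = grid.boundary_mode == "periodic"
    h, w = grid.shape
    step = vfield.step
    tally = TransportTally(
        slab_volume_m3=grid.cell_size ** 2 * grid.slab_height,
        bulk_density=cfg.bulk_density)

    u = vfield.u
    candidates = (~shadow.mask) & (u > cfg.entrainment_threshold) \
        & (grid.sand_height > 0)
    if not candidates.any():
        return tally

    order = rng.permutation(grid.n_cells)
    rows, cols = np.unravel_index(order, grid.shape)
    vegetated = grid.occupied
    in_shadow = shadow.mask

    for r, c in zip(rows, cols):
        if not candidates[r, c] or grid.sand_height[r, c] == 0:
            continue
        p_e = cfg.p_erode_bare
        if vegetated[r, c]:
            p_e *= cfg.p_erode_vegetated_factor
        if rng.random() >= p_e:
            continue
        vol = erosion_volume(float(u[r, c]), int(grid.sand_height[r, c]), cfg)
        n = int(vol) + (rng.random() < (vol - int(vol)))
        if n == 0:
            continue
        grid.sand_height[r, c] -= n
        grid.sand_delta[r, c] -= n
        tally.eroded_slabs += n
        for _ in range(n):
            rr, cc = float(r), float(c)
            for _hop in range(cfg.max_hops):
                rr += step[0]
                cc += step[1]
                ir, ic = int(np.rint(rr)), int(np.rint(cc))
                if periodic:
                    ir %= h
                    ic %= w
                elif not (0 <= ir < h and 0 <= ic < w):
                    tally.exported_slabs += 1
                    break
                p_d = cfg.p_deposit_vegetated if (vegetated[ir, ic]
                                                  or in_shadow[ir, ic]) \
                    else cfg.p_deposit_bare
                if rng.random() < p_d:
                    grid.sand_height[ir, ic] += 1
                    grid.sand_delta[ir, ic] += 1
                    tally.deposited_slabs += 1
                    break
            else:
                # safety: force deposit after max_hops trials
                grid.sand_height[ir, ic] += 1
                grid.sand_delta[ir, ic] += 1
                tally.deposited_slabs += 1
    return tally


# ---------------------------------------------------------------------------
# avalanching
# ---------------------------------------------------------------------------

_NEIGHBOURS_8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                 (0, 1), (1, -1), (1, 0), (1, 1)]


def _critical_tan(grid: SimulationGrid, cfg: TransportConfig) -> np.ndarray:
    crit = np.where(grid.occupied,
                    math.tan(math.radians(cfg.repose_vegetated_deg)),
                    math.tan(math.radians(cfg.repose_bare_deg)))
    return crit


def max_slope_deg(grid: SimulationGrid) -> float:
    """Steepest surface slope between any 8-neighbour pair, degrees."""
    surf = grid.surface_m()
    periodic = grid.boundary_mode == "periodic"
    worst = 0.0
    for dr, dc in _NEIGHBOURS_8:
        dist = grid.cell_size * math.hypot(dr, dc)
        nb = shift2d(surf, dr, dc, periodic, fill=np.nan)
        s = (nb - surf) / dist
        s = s[np.isfinite(s)]
        if s.size:
            worst = max(worst, float(np.abs(s).max()))
    return math.degrees(math.atan(worst))


def avalanche_relax(grid: SimulationGrid, rng: np.random.Generator = None,
                    cfg: TransportConfig = None) -> int:
    """Move sand slabs downslope until no slope exceeds the local angle
    of repose (30° bare, 40° vegetated, judged at the upper cell).

    Only sand moves — the substrate is immobile, so a cell with no sand
    left cannot shed further. Steepest-descent moves, seeded random
    tie-breaks. Returns the number of slabs moved; raises RuntimeError
    if the sweep guard is exceeded.
    """
    cfg = cfg or TransportConfig()
    rng = rng if rng is not None else np.random.default_rng(0)
    periodic = grid.boundary_mode == "periodic"
    h, w = grid.shape
    crit = _critical_tan(grid, cfg)
    dists = np.array([grid.cell_size * math.hypot(dr, dc)
                      for dr, dc in _NEIGHBOURS_8])
    moves = 0

    for _sweep in range(cfg.max_avalanche_sweeps):
        surf = grid.surface_m()
        unstable = np.zeros(grid.shape, dtype=bool)
        for (dr, dc), dist in zip(_NEIGHBOURS_8, dists):
            nb = shift2d(surf, dr, dc, periodic, fill=np.inf)
            unstable |= (surf - nb) / dist > crit + 1e-12
        unstable &= grid.sand_height > 0
        idx = np.flatnonzero(unstable)
        if idx.size == 0:
            return moves
        for flat in rng.permutation(idx):
            r, c = divmod(int(flat), w)
            if grid.sand_height[r, c] == 0:
                continue
            here = (grid.base_height[r, c] + grid.sand_height[r, c]) \
                * grid.slab_height
            best, best_slope = [], crit[r, c]
            for (dr, dc), dist in zip(_NEIGHBOURS_8, dists):
                rr, cc = r + dr, c + dc
                if periodic:
                    rr %= h
                    cc %= w
                elif not (0 <= rr < h and 0 <= cc < w):
                    continue
                nb_h = (grid.base_height[rr, cc]
                        + grid.sand_height[rr, cc]) * grid.slab_height
                slope = (here - nb_h) / dist
                if slope > best_slope + 1e-12:
                    best, best_slope = [(rr, cc)], slope
                elif best and abs(slope - best_slope) <= 1e-12:
                    best.append((rr, cc))
            if not best:
                continue
            rr, cc = best[int(rng.integers(len(best)))] if len(best) > 1 \
                else best[0]
            grid.sand_height[r, c] -= 1
            grid.sand_height[rr, cc] += 1
            moves += 1
    raise RuntimeError(
        f"avalanche did not converge within {cfg.max_avalanche_sweeps} "
        f"sweeps (inconsistent slab geometry?)")
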