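"""Experiment drivers and landscape statistics.

Three experiment families:

* equilibrium — stationary seasonal forcing (the 21-year window means
  around a key year), run for a fixed number of model years; landscape
  characteristics are means (with coefficients of variation) over the
  final 10 years, separated by season, optionally normalised to a
  baseline run.
* transient — a year-by-year precipitation trajectory with stochastic
  realisations (noise sigma from 5-year moving seasonal standard
  deviations), an ensemble of runs, min–max envelopes and 3-year moving
  averages.
* fire × grazing matrix — factorial disturbance regimes over a
  transient trajectory, summarised over the 11-year windows centred on
  key years.

All randomness is drawn from child generators keyed on
(seed, year, season, stage, event), so every entry point is
bit-reproducible from its seed and any stage can be skipped without
shifting another stage's stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .climate import (ClimateSeries, WindClimatology, perturb_around_trajectory,
                      sample_wind_event)
from .config import BARE, GRASS, SEASONS, SHRUB, TREE, VistaConfig
from .disturbance import (DisturbanceRegime, apply_fire, apply_grazing,
                          fire_due)
from .grid import WIND_EVENTS_PER_SEASON, SimulationGrid, init_grid
from .sediment import TransportTally, transport_iteration, avalanche_relax
from .vegetation import GrowthPathways, InteractionKernel, vegetation_step
from .wind import compute_velocity_field

# RNG stage codes
_STAGE_INIT, _STAGE_WIND, _STAGE_TRANSPORT, _STAGE_AVALANCHE, \
    _STAGE_GRAZING, _STAGE_FIRE, _STAGE_VEGETATION, _STAGE_NOISE = range(8)


def stage_rng(seed: int, *key: int) -> np.random.Generator:
    """Child generator keyed on (seed, *key); skip-safe and reproducible."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2 ** 31), *[int(k) for k in key]]))


# ---------------------------------------------------------------------------
# landscape statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LandscapeStats:
    """Whole-domain landscape characteristics for one instant/period."""

    population_density: float     # occupied cells / total cells
    grass_cover: float            # grass cells / total cells
    shrub_cover: float
    tree_cover: float
    grass_shrub_ratio: float      # +inf sentinel when shrubs absent
    ratio_defined: bool
    total_transport_m3: float = 0.0
    total_transport_kg: float = 0.0

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def landscape_stats(grid: SimulationGrid,
                    tally: Optional[TransportTally] = None) -> LandscapeStats:
    """Exhaustive-count landscape statistics of the current grid state."""
    n = grid.n_cells
    grass = int((grid.species == GRASS).sum())
    shrub = int((grid.species == SHRUB).sum())
    tree = int((grid.species == TREE).sum())
    occupied = grass + shrub + tree
    if shrub > 0:
        ratio, defined = grass / shrub, True
    else:
        ratio, defined = math.inf, False
    return LandscapeStats(
        population_density=occupied / n,
        grass_cover=grass / n, shrub_cover=shrub / n, tree_cover=tree / n,
        grass_shrub_ratio=ratio, ratio_defined=defined,
        total_transport_m3=tally.transported_volume_m3 if tally else 0.0,
        total_transport_kg=tally.transported_mass_kg if tally else 0.0)


def normalise_stats(stats: Dict[str, float],
                    baseline: Dict[str, float]) -> Dict[str, float]:
    """Divide each statistic by its baseline value (NaN where baseline 0)."""
    out = {}
    for k, v in stats.items():
        b = baseline.get(k)
        if isinstance(v, (int, float)) and isinstance(b, (int, float)):
            out[k] = v / b if b else math.nan
    return out


# ---------------------------------------------------------------------------
# core season loop
# ---------------------------------------------------------------------------

PrecipLookup = Callable[[int, str], float]


def _as_precip_lookup(forcing) -> PrecipLookup:
    if callable(forcing):
        return forcing
    if isinstance(forcing, ClimateSeries):
        return forcing.value
    if isinstance(forcing, dict):            # stationary per-season means
        return lambda year, season: forcing[season]
    raise TypeError(f"cannot interpret forcing of type {type(forcing)!r}")


def simulate_season(grid: SimulationGrid, precip: PrecipLookup,
                    climatology: WindClimatology, config: VistaConfig,
                    seed: int, regime: Optional[DisturbanceRegime] = None,
                    start_year: int = 0,
                    pathways: Optional[GrowthPathways] = None,
                    kernel: Optional[InteractionKernel] = None
                    ) -> LandscapeStats:
    """Advance one season: 20 wind events, disturbances, vegetation update.

    Statistics are taken on the state at the end of the season (after
    the vegetation update); the clock advances afterwards.
    """
    pathways = pathways or GrowthPathways(config.ecology.species)
    kernel = kernel or InteractionKernel.from_config(config.ecology)
    year, si = grid.clock.year, grid.clock.season_index
    season = grid.clock.season
    season_tally = TransportTally(
        slab_volume_m3=grid.cell_size ** 2 * grid.slab_height,
        bulk_density=config.transport.bulk_density)

    threshold = config.transport.entrainment_threshold
    for ev in range(WIND_EVENTS_PER_SEASON):
        event = sample_wind_event(
            climatology, season, stage_rng(seed, year, si, _STAGE_WIND, ev))
        if event.speed * config.wind.compression_cap <= threshold:
            continue    # cannot move sand anywhere; streams are skip-safe
        vfield = compute_velocity_field(grid, event, config.wind, pathways)
        if vfield.u.max() <= threshold:
            continue
        tally = transport_iteration(
            grid, vfield, stage_rng(seed, year, si, _STAGE_TRANSPORT, ev),
            config.transport)
        season_tally.merge(tally)
        if tally.eroded_slabs:
            avalanche_relax(grid,
                            stage_rng(seed, year, si, _STAGE_AVALANCHE, ev),
                            config.transport)

    if regime is not None and regime.stocking_rate > 0:
        apply_grazing(grid, regime.stocking_rate,
                      stage_rng(seed, year, si, _STAGE_GRAZING),
                      config.ecology)
    if regime is not None and fire_due(grid.clock, regime, start_year):
        apply_fire(grid, stage_rng(seed, year, si, _STAGE_FIRE), pathways)

    vegetation_step(grid, precip(year, season), config.ecology,
                    stage_rng(seed, year, si, _STAGE_VEGETATION),
                    kernel, pathways)
    stats = landscape_stats(grid, season_tally)
    grid.clock.advance_season()
    return stats


def run_years(grid: SimulationGrid, forcing, climatology: WindClimatology,
              config: VistaConfig, seed: int, n_years: int,
              regime: Optional[DisturbanceRegime] = None,
              start_year: Optional[int] = None) -> pd.DataFrame:
    """Run whole model years, returning one stats record per season."""
    precip = _as_precip_lookup(forcing)
    pathways = GrowthPathways(config.ecology.species)
    kernel = InteractionKernel.from_config(config.ecology)
    if start_year is None:
        start_year = grid.clock.year
    rows = []
    for _ in range(n_years * len(SEASONS)):
        year, season = grid.clock.year, grid.clock.season
        stats = simulate_season(grid, precip, climatology, config, seed,
                                regime, start_year, pathways, kernel)
        rows.append({"year": year, "season": season, **stats.as_dict()})
    return pd.DataFrame(rows)


def new_grid_from_config(config: VistaConfig, rng: np.random.Generator,
                         start_year: int = 0) -> SimulationGrid:
    g = config.grid
    grid = init_grid(g.width, g.height, g.cover_fraction, dict(g.species_mix),
                     tuple(g.sand_seed_range), rng, cell_size=g.cell_size,
                     boundary_mode=g.boundary_mode,
                     slab_height=config.transport.slab_height_m)
    grid.base_height[:] = g.base_height_slabs
    grid.clock.year = start_year
    return grid


# ---------------------------------------------------------------------------
# equilibrium experiments
# ---------------------------------------------------------------------------

@dataclass
class EquilibriumResult:
    """History plus end-of-run summaries of an equilibrium run."""

    history: pd.DataFrame
    final_grid: SimulationGrid
    seed: int
    summary_years: int = 10

    _STATS = ("population_density", "grass_cover", "shrub_cover",
              "tree_cover", "grass_shrub_ratio", "total_transport_m3")

    def season_summary(self, season: str) -> Dict[str, Dict[str, float]]:
        """Mean and coefficient of variation over the final summary
        window, for one season."""
        h = self.history
        last = h["year"].max() - self.summary_years + 1
        win = h[(h["year"] >= last) & (h["season"] == season)]
        out = {}
        for stat in self._STATS:
            v = win[stat].replace([np.inf, -np.inf], np.nan).dropna()
            mean = float(v.mean()) if len(v) else math.nan
            cv = float(v.std(ddof=0) / mean) if len(v) and mean else math.nan
            out[stat] = {"mean": mean, "cv": cv}
        return out

    def annual_baseline(self) -> Dict[str, float]:
        """All-season mean over the final window (normalisation basis)."""
        h = self.history
        last = h["year"].max() - self.summary_years + 1
        win = h[h["year"] >= last].replace([np.inf, -np.inf], np.nan)
        return {stat: float(win[stat].dropna().mean())
                for stat in self._STATS}


def run_equilibrium(forcing: Dict[str, float], config: VistaConfig,
                    seed: int, n_years: int = 200,
                    climatology: Optional[WindClimatology] = None,
                    regime: Optional[DisturbanceRegime] = None,
                    summary_years: int = 10) -> EquilibriumResult:
    """Equilibrium run under stationary per-season forcing.

    ``forcing`` maps season → mean seasonal total (mm), typically from
    :func:`vista.climate.equilibrium_year_forcing`.
    """
    climatology = climatology or WindClimatology()
    grid = new_grid_from_config(config, stage_rng(seed, _STAGE_INIT))
    history = run_years(grid, forcing, climatology, config, seed, n_years,
                        regime)
    return EquilibriumResult(history=history, final_grid=grid, seed=seed,
                             summary_years=summary_years)


# ---------------------------------------------------------------------------
# transient experiments
# ---------------------------------------------------------------------------

@dataclass
class TransientEnsemble:
    """Per-run seasonal series plus ensemble aggregates."""

    runs: List[pd.DataFrame]
    scenario: str = "synthetic"

    def envelope(self, stat: str) -> pd.DataFrame:
        """Pointwise min–max across runs, per (year, season)."""
        stacked = pd.concat(
            [r.set_index(["year", "season"])[stat] for r in self.runs],
            axis=1)
        return pd.DataFrame({"min": stacked.min(axis=1),
                             "max": stacked.max(axis=1),
                             "mean": stacked.mean(axis=1)}).reset_index()

    def moving_average(self, stat: str, years: int = 3) -> pd.DataFrame:
        """Centred moving average over ``years``×4 seasonal records,
        per run."""
        window = years * len(SEASONS)
        out = {}
        for i, r in enumerate(self.runs):
            s = r[stat].replace([np.inf, -np.inf], np.nan)
            out[f"run{i}"] = s.rolling(window, center=True,
                                       min_periods=1).mean()
        frame = self.runs[0][["year", "season"]].copy()
        return pd.concat([frame, pd.DataFrame(out)], axis=1)


def run_transient(series: ClimateSeries, config: VistaConfig, seed: int,
                  n_runs: int = 10,
                  climatology: Optional[WindClimatology] = None,
                  regime: Optional[DisturbanceRegime] = None,
                  initial_grid: Optional[SimulationGrid] = None,
                  add_noise: bool = True) -> TransientEnsemble:
    """Ensemble of transient runs along a precipitation trajectory.

    Each run adds an independent noise realisation (sigma from 5-year
    moving seasonal standard deviations) around the trajectory and
    starts from a copy of ``initial_grid`` (typically the final state of
    an equilibrium run for the first year) or a fresh random landscape.
    """
    climatology = climatology or WindClimatology()
    years = series.years
    start_year = int(years.min())
    n_years = int(years.max()) - start_year + 1
    runs = []
    for r in range(n_runs):
        run_seed = int(np.random.SeedSequence([seed % (2 ** 31), r])
                       .generate_state(1)[0] % (2 ** 31))
        forcing = (perturb_around_trajectory(
            series, stage_rng(run_seed, _STAGE_NOISE)) if add_noise
            else series)
        if initial_grid is not None:
            grid = initial_grid.copy()
            grid.clock.year = start_year
            grid.clock.season_index = 0
            grid.clock.wind_event_index = 0
        else:
            grid = new_grid_from_config(config, stage_rng(run_seed,
                                                          _STAGE_INIT),
                                        start_year)
        df = run_years(grid, forcing, climatology, config, run_seed, n_years,
                       regime, start_year)
        df["run"] = r
        runs.append(df)
    return TransientEnsemble(runs=runs, scenario=series.scenario)


# ---------------------------------------------------------------------------
# fire × grazing matrices
# ---------------------------------------------------------------------------

def run_fire_grazing_matrix(series: ClimateSeries, config: VistaConfig,
                            seed: int,
                            fire_levels: Sequence[str] = ("low", "medium",
                                                          "high"),
                            grazing_levels: Sequence[str] = ("low", "medium",
                                                             "high"),
                            n_runs: int = 3,
                            key_years: Sequence[int] = (2030, 2060),
                            climatology: Optional[WindClimatology] = None,
                            initial_grid: Optional[SimulationGrid] = None,
                            window_half: int = 5, keep_runs: bool = False):
    """Factorial fire × grazing experiment.

    For every regime combination the model is run ``n_runs`` times over
    the trajectory; density and grass:shrub ratio are summarised as the
    mean (and standard deviation) over the 11-year windows centred on
    each key year, pooled across seasons and runs. With ``keep_runs``
    the per-run seasonal series are returned alongside the matrix.
    """
    rows = []
    kept = {}
    for fi, fire in enumerate(fire_levels):
        for gi, grazing in enumerate(grazing_levels):
            regime = DisturbanceRegime.from_labels(fire, grazing)
            combo_seed = int(np.random.SeedSequence(
                [seed % (2 ** 31), fi, gi])
                .generate_state(1)[0] % (2 ** 31))
            ens = run_transient(series, config, combo_seed, n_runs,
                                climatology, regime, initial_grid)
            if keep_runs:
                kept[(fire, grazing)] = ens
            pooled = pd.concat(ens.runs)
            for key_year in key_years:
                win = pooled[(pooled["year"] >= key_year - window_half)
                             & (pooled["year"] <= key_year + window_half)]
                win = win.replace([np.inf, -np.inf], np.nan)
                rows.append({
                    "fire": fire, "grazing": grazing, "key_year": key_year,
                    "density_mean": float(win["population_density"].mean()),
                    "density_sd": float(win["population_density"].std()),
                    "ratio_mean": float(win["grass_shrub_ratio"]
                                        .dropna().mean()),
                    "ratio_sd": float(win["grass_shrub_ratio"]
                                      .dropna().std()),
                })
    matrix = pd.DataFrame(rows)
    return (matrix, kept) if keep_runs else matrix


# ---------------------------------------------------------------------------
# threshold / cumulative-frequency analysis
# ---------------------------------------------------------------------------

def threshold_frequency(cover_series: Iterable[float],
                        threshold: float = 0.20):
    """Fraction of seasonal records strictly below a cover threshold,
    plus the cumulative-frequency curve.

    Returns ``(fraction, curve)`` where curve is a DataFrame with the
    sorted cover values and their cumulative frequencies.
    """
    values = np.asarray(list(cover_series), dtype=float)
    if values.size == 0:
        raise ValueError("empty cover series")
    fraction = float((values < threshold).mean())
    order = np.sort(values)
    curve = pd.DataFrame({
        "cover": order,
        "cumulative_frequency": np.arange(1, order.size + 1) / order.size})
    return fraction, curve
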