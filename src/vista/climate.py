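"""Synthetic climate forcing: seasonal rainfall trajectories and wind events.

Rainfall reaches the simulator as per-season totals (mm) over a year
range. Trajectories are either read from plain CSV tables or generated
synthetically as a linear seasonal trend plus Gaussian interannual
noise, with the annual-equivalent standard deviation partitioned
equally across the four seasons (sigma_season = sigma_annual / 2, so four
independent seasonal deviates recompose the annual variance). Negative
draws are truncated at zero.

Wind arrives as discrete events: a speed drawn from a seasonal Weibull
distribution and a direction drawn from a 16-bin compass probability
table, mirroring how a multi-decadal station record is summarised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from .config import SEASONS

#: annual-equivalent interannual sigma (mm) of the two stationary
#: variability regimes used by the equilibrium experiments.
SIGMA_LOW_MM = 30.0
SIGMA_HIGH_MM = 160.0

#: 16-point compass, clockwise from north.
N_DIRECTION_BINS = 16
DIRECTION_BIN_WIDTH = 360.0 / N_DIRECTION_BINS
DIRECTION_BIN_CENTRES = np.arange(N_DIRECTION_BINS) * DIRECTION_BIN_WIDTH


# ---------------------------------------------------------------------------
# precipitation series container
# ---------------------------------------------------------------------------

class ClimateSeries:
    """Per-(year, season) precipitation totals with scenario metadata.

    Thin wrapper over a tidy DataFrame (year, season, precip_mm); every
    year in the range must carry all four seasons and totals must be
    non-negative.
    """

    def __init__(self, data: pd.DataFrame, site: str = "synthetic",
                 scenario: str = "synthetic"):
        df = data.copy()
        required = {"year", "season", "precip_mm"}
        if not required.issubset(df.columns):
            raise ValueError(f"climate table needs columns {sorted(required)}, "
                             f"got {list(df.columns)}")
        if (df["precip_mm"] < 0).any():
            bad = df.index[df["precip_mm"] < 0][0]
            raise ValueError(f"negative precipitation at row {bad}")
        unknown = set(df["season"]) - set(SEASONS)
        if unknown:
            raise ValueError(f"unknown season labels: {sorted(unknown)}")
        for year, grp in df.groupby("year"):
            missing = set(SEASONS) - set(grp["season"])
            if missing:
                raise ValueError(f"year {year} missing seasons "
                                 f"{sorted(missing)}")
        self.data = (df.sort_values(["year", "season"],
                                    key=lambda s: s.map(
                                        {s_: i for i, s_ in enumerate(SEASONS)})
                                    if s.name == "season" else s)
                       .reset_index(drop=True))
        self.site = site
        self.scenario = scenario

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.data["year"].unique())

    def value(self, year: int, season: str) -> float:
        sel = self.data[(self.data["year"] == year)
                        & (self.data["season"] == season)]
        if sel.empty:
            raise KeyError(f"no record for {year} {season}")
        return float(sel["precip_mm"].iloc[0])

    def season_series(self, season: str) -> pd.Series:
        sel = self.data[self.data["season"] == season]
        return pd.Series(sel["precip_mm"].to_numpy(),
                         index=sel["year"].to_numpy(), name=season)

    def annual_totals(self) -> pd.Series:
        return self.data.groupby("year")["precip_mm"].sum()

    def subset(self, year_start: int, year_end: int) -> "ClimateSeries":
        mask = (self.data["year"] >= year_start) & (self.data["year"] <= year_end)
        return ClimateSeries(self.data[mask], self.site, self.scenario)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.data)


def load_climate_table(path, site: str = None, scenario: str = None
                       ) -> ClimateSeries:
    """Read a headered CSV (year, season, precip_mm) into a ClimateSeries.

    Malformed rows are reported with their line number.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse climate table: {exc}") from exc
    required = {"year", "season", "precip_mm"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns "
                         f"{sorted(required - set(df.columns))}")
    for i, row in df.iterrows():
        try:
            int(row["year"])
            float(row["precip_mm"])
        except (TypeError, ValueError):
            raise ValueError(f"{path}: malformed row at line {i + 2}: "
                             f"{row.to_dict()}") from None
    return ClimateSeries(df, site or "file", scenario or "file")


# ---------------------------------------------------------------------------
# synthetic trajectory generation
# ---------------------------------------------------------------------------

@dataclass
class ScenarioSpec:
    """Recipe for a synthetic seasonal precipitation trajectory.

    season_means are the seasonal totals (mm) at ``year_start``;
    season_trends are linear drifts (mm per year, typically negative for
    drying scenarios). ``sigma_annual_mm`` is the annual-equivalent
    interannual standard deviation; each season receives sigma_annual/2.
    """

    site: str = "synthetic"
    scenario: str = "synthetic"
    year_start: int = 1960
    year_end: int = 2100
    season_means: Dict[str, float] = field(
        default_factory=lambda: {"DJF": 180.0, "MAM": 80.0,
                                 "JJA": 10.0, "SON": 90.0})
    season_trends: Dict[str, float] = field(
        default_factory=lambda: {"DJF": -0.30, "MAM": -0.10,
                                 "JJA": 0.0, "SON": -0.10})
    sigma_annual_mm: float = 0.0

    def __post_init__(self):
        if self.year_end < self.year_start:
            raise ValueError(f"empty year range {self.year_start}–{self.year_end}")
        missing = set(SEASONS) - set(self.season_means)
        if missing:
            raise ValueError(f"season_means missing {sorted(missing)}")

    @property
    def sigma_season_mm(self) -> float:
        # sum of 4 independent N(0, sigma/2) deviates has sd sigma_annual
        return self.sigma_annual_mm / 2.0

    def deterministic_value(self, year: int, season: str) -> float:
        drift = self.season_trends.get(season, 0.0) * (year - self.year_start)
        return max(0.0, self.season_means[season] + drift)


def generate_precip_trajectory(spec: ScenarioSpec,
                               rng: Optional[np.random.Generator] = None
                               ) -> ClimateSeries:
    """Linear seasonal trend plus seeded Gaussian noise, truncated at zero.

    With ``sigma_annual_mm = 0`` the output equals the deterministic
    trend exactly.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    years = np.arange(spec.year_start, spec.year_end + 1)
    rows = []
    sigma = spec.sigma_season_mm
    for year in years:
        for season in SEASONS:
            base = spec.deterministic_value(year, season)
            noise = rng.normal(0.0, sigma) if sigma > 0 else 0.0
            rows.append((year, season, max(0.0, base + noise)))
    df = pd.DataFrame(rows, columns=["year", "season", "precip_mm"])
    return ClimateSeries(df, spec.site, spec.scenario)


def moving_sigma(series: ClimateSeries, window: int = 5) -> pd.DataFrame:
    """Per-season interannual sigma from a centred moving window.

    Returns a DataFrame indexed by year with one sigma column per
    season. Sample standard deviation (ddof=1); windows shrink at the
    edges (minimum two years).
    """
    years = series.years
    if len(years) < window:
        raise ValueError(f"need at least {window} years, have {len(years)}")
    out = {}
    for season in SEASONS:
        s = series.season_series(season)
        out[season] = s.rolling(window, center=True, min_periods=2).std()
        out[season] = out[season].bfill().ffill()
    return pd.DataFrame(out, index=years)


def perturb_around_trajectory(series: ClimateSeries,
                              rng: np.random.Generator,
                              window: int = 5) -> ClimateSeries:
    """One stochastic realisation around a projected trajectory.

    Adds normal noise with a per-(year, season) sigma taken from the
    5-year moving standard deviation of the trajectory itself — the
    variability scheme of the transient experiments.
    """
    sig = moving_sigma(series, window)
    df = series.data.copy()
    noise = np.array([rng.normal(0.0, max(0.0, sig.loc[y, s]))
                      for y, s in zip(df["year"], df["season"])])
    df["precip_mm"] = np.maximum(0.0, df["precip_mm"].to_numpy() + noise)
    return ClimateSeries(df, series.site, series.scenario + "+noise")


def equilibrium_year_forcing(series: ClimateSeries, key_year: int
                             ) -> Dict[str, float]:
    """Per-season mean over the 21-year window centred on a key year.

    An aggregate 'year' used by the equilibrium experiments: e.g. the
    2020–2040 means stand for the year 2030.
    """
    lo, hi = key_year - 10, key_year + 10
    years = set(series.years)
    missing = sorted(set(range(lo, hi + 1)) - years)
    if missing:
        raise ValueError(f"window {lo}–{hi} around {key_year} missing years "
                         f"{missing}")
    window = series.data[(series.data["year"] >= lo)
                         & (series.data["year"] <= hi)]
    return {season: float(grp["precip_mm"].mean())
            for season, grp in window.groupby("season")}


# ---------------------------------------------------------------------------
# wind climatology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindEvent:
    """One sampled wind episode."""

    speed: float        # m/s, >= 0
    direction: float    # degrees from north the wind blows FROM, [0, 360)

    def __post_init__(self):
        if not np.isfinite(self.speed) or self.speed < 0:
            raise ValueError(f"speed must be finite and >= 0, got {self.speed}")
        if not 0.0 <= self.direction < 360.0:
            raise ValueError(f"direction must be in [0, 360), got "
                             f"{self.direction}")


@dataclass
class WindClimatology:
    """Seasonal Weibull speed parameters plus a 16-bin direction table."""

    #: season -> (shape k, scale lambda in m/s)
    weibull: Dict[str, tuple] = field(
        default_factory=lambda: {"DJF": (2.2, 5.5), "MAM": (2.0, 4.8),
                                 "JJA": (2.1, 5.2), "SON": (2.3, 6.5)})
    #: probability per compass bin (bin i centred at i*22.5 deg); default is
    #: a synthetic northerly-dominated regime.
    direction_probs: np.ndarray = field(
        default_factory=lambda: _default_direction_probs())

    def __post_init__(self):
        self.direction_probs = np.asarray(self.direction_probs, dtype=float)
        if self.direction_probs.shape != (N_DIRECTION_BINS,):
            raise ValueError(f"direction table needs {N_DIRECTION_BINS} bins")
        if abs(self.direction_probs.sum() - 1.0) > 1e-6:
            raise ValueError(f"direction probabilities must sum to 1, got "
                             f"{self.direction_probs.sum():.6f}")
        for season, (k, lam) in self.weibull.items():
            if k <= 0 or lam < 0:
                raise ValueError(f"{season}: Weibull shape/scale must be "
                                 f"positive, got ({k}, {lam})")

    def mean_speed(self, season: str) -> float:
        """Closed-form Weibull mean: scale * Gamma(1 + 1/shape)."""
        from scipy.special import gamma
        k, lam = self.weibull[season]
        return lam * gamma(1.0 + 1.0 / k)

    # -- serialisation -------------------------------------------------
    def to_file(self, path) -> None:
        payload = {"weibull": {s: list(v) for s, v in self.weibull.items()},
                   "direction_probs": self.direction_probs.tolist()}
        text = (json.dumps(payload, indent=1) if str(path).endswith(".json")
                else yaml.safe_dump(payload))
        with open(path, "w") as fh:
            fh.write(text)

    @classmethod
    def from_file(cls, path) -> "WindClimatology":
        with open(path) as fh:
            raw = (json.load(fh) if str(path).endswith(".json")
                   else yaml.safe_load(fh))
        return cls(weibull={s: tuple(v) for s, v in raw["weibull"].items()},
                   direction_probs=np.asarray(raw["direction_probs"]))


def _default_direction_probs() -> np.ndarray:
    # unimodal synthetic regime peaking at N–NNW with a WNW shoulder
    w = np.array([4.0, 2.0, 1.0, 0.5, 0.3, 0.3, 0.3, 0.5,
                  0.8, 1.0, 1.2, 1.5, 2.0, 2.5, 3.0, 3.5])
    return w / w.sum()


def sample_wind_event(climatology: WindClimatology, season: str,
                      rng: np.random.Generator) -> WindEvent:
    """Draw one event: Weibull speed + compass-bin direction.

    Directions are reported as the sampled bin centre (resolution
    22.5 deg, matching the corridor rasteriser).
    """
    if season not in SEASONS:
        raise ValueError(f"unknown season {season!r}")
    k, lam = climatology.weibull[season]
    speed = float(lam * rng.weibull(k))
    bin_idx = int(rng.choice(N_DIRECTION_BINS, p=climatology.direction_probs))
    return WindEvent(speed=speed,
                     direction=float(DIRECTION_BIN_CENTRES[bin_idx]))


# ---------------------------------------------------------------------------
# synthetic site presets
# ---------------------------------------------------------------------------

def site_preset(name: str) -> ScenarioSpec:
    """Synthetic per-site scenario presets (declared fixtures, not data).

    Three Kalahari-like sites spanning a wetness gradient: 'maun'
    (wettest, tree-supporting), 'tshane' (intermediate) and 'tsabong'
    (driest, near collapse), each with a mild drying trend.
    """
    presets = {
        "maun": ScenarioSpec(
            site="maun",
            season_means={"DJF": 250.0, "MAM": 100.0, "JJA": 5.0, "SON": 105.0},
            season_trends={"DJF": -0.35, "MAM": -0.12, "JJA": 0.0, "SON": -0.10}),
        "tshane": ScenarioSpec(
            site="tshane",
            season_means={"DJF": 190.0, "MAM": 80.0, "JJA": 5.0, "SON": 80.0},
            season_trends={"DJF": -0.30, "MAM": -0.10, "JJA": 0.0, "SON": -0.08}),
        "tsabong": ScenarioSpec(
            site="tsabong",
            season_means={"DJF": 150.0, "MAM": 65.0, "JJA": 8.0, "SON": 60.0},
            season_trends={"DJF": -0.25, "MAM": -0.08, "JJA": 0.0, "SON": -0.06}),
    }
    try:
        return presets[name.lower()]
    except KeyError:
        raise ValueError(f"unknown site {name!r}; choose from "
                         f"{sorted(presets)}") from None
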