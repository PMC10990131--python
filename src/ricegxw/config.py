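"""Configuration objects for the synthetic study system and its ground truth.

The synthetic generator emulates the structure of the historical southern US
rice system: ~110 rice-growing counties observed 1970-2015, ~150 inbred
varieties with release years spanning a century, 3-7 varieties grown per
county-year, a mean variety market life of ~6.3 years, and county-year
weather for the four agronomically decisive variables (April mean
temperature and cumulative precipitation; July maximum temperature and
cumulative precipitation) within their observed historical ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

#: The four weather covariates used throughout the package, in canonical order.
WEATHER_VARS = ("april_tavg", "april_prcp", "july_tmax", "july_prcp")

#: Observed historical county-level ranges (1970-2015) used as default bounds:
#: April mean temperature 14.7-20.7 degC, April precipitation 28.6-283 mm,
#: July maximum temperature 31.4-36.5 degC, July precipitation 48.2-179.8 mm.
DEFAULT_WEATHER_RANGES: dict[str, tuple[float, float]] = {
    "april_tavg": (14.7, 20.7),
    "april_prcp": (28.6, 283.0),
    "july_tmax": (31.4, 36.5),
    "july_prcp": (48.2, 179.8),
}

#: Default per-decade drift added on top of the stationary draw. Temperature
#: drifts upward (~0.1-0.3 degC/decade range reported for the region) and
#: rainfall drifts slightly downward (about -2 mm/decade).
DEFAULT_TREND: dict[str, float] = {
    "april_tavg": 0.29,
    "april_prcp": -2.2,
    "july_tmax": 0.14,
    "july_prcp": -1.1,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study system.

    Defaults mirror the historical system the package models; tests and the
    acceptance pipeline use :meth:`compact` for a scaled-down version with
    the same statistical structure.
    """

    n_counties: int = 110
    year_start: int = 1970
    year_end: int = 2015
    n_varieties: int = 153
    n_markers: int = 500
    varieties_per_county_year: tuple[int, int] = (3, 7)
    mean_market_life: float = 6.3
    release_year_range: tuple[int, int] = (1911, 2015)
    weather_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WEATHER_RANGES)
    )
    trend: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_TREND))
    missing_rate: float = 0.02
    modern_marker_fraction: float = 0.1
    ungenotyped_fraction: float = 0.1
    # ground-truth yield model knobs (see default_ground_truth)
    n_effect_markers: int = 20
    marker_effect_sd: float = 150.0
    weather_effects: Mapping[str, float] = field(
        default_factory=lambda: {
            "april_tavg": 20.0,
            "april_prcp": -0.8,
            "july_tmax": -60.0,
            "july_prcp": 0.5,
        }
    )
    n_interaction_markers: int = 6
    interaction_effect: float = 40.0
    intercept: float = 7000.0
    noise_sd: float = 900.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_counties <= 0 or self.n_varieties <= 0 or self.n_markers <= 0:
            raise ValueError("counts (counties, varieties, markers) must be positive")
        if self.year_end < self.year_start:
            raise ValueError("year range is empty")
        lo, hi = self.varieties_per_county_year
        if not (1 <= lo <= hi):
            raise ValueError("varieties_per_county_year must satisfy 1 <= min <= max")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.mean_market_life < 1:
            raise ValueError("mean_market_life must be at least one year")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        for var, (lo_w, hi_w) in self.weather_ranges.items():
            if lo_w >= hi_w:
                raise ValueError(f"weather bounds for {var} must satisfy low < high")

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_end + 1)

    @classmethod
    def compact(cls, seed: int = 0, **overrides) -> "SyntheticConfig":
        """A scaled-down system (20 counties x 30 years, 300 markers, 80
        varieties) preserving the default structure; used for simulation
        studies where the full-size system would be slow."""
        params = dict(
            n_counties=20,
            year_start=1986,
            year_end=2015,
            n_varieties=80,
            n_markers=300,
            release_year_range=(1946, 2015),
            seed=seed,
        )
        params.update(overrides)
        return cls(**params)


@dataclass(frozen=True)
class GroundTruth:
    """The data-generating yield model: linear in allele frequencies (G),
    weather (W), and their products (GxW), with an optional piecewise-linear
    July heat-stress term.

    Effects are in kg/ha per unit of their regressor: per unit allele
    frequency for ``marker_effects``, per degC or per mm for
    ``weather_effects``, and per unit frequency-times-weather product for
    ``interaction_effects`` (keyed by ``(marker_id, weather_var)``).
    """

    intercept: float
    marker_effects: Mapping[str, float]
    weather_effects: Mapping[str, float]
    interaction_effects: Mapping[tuple[str, str], float]
    heat_threshold: float | None = None
    heat_slope: float = 0.0

    def __post_init__(self) -> None:
        for (_, wvar) in self.interaction_effects:
            if wvar not in WEATHER_VARS:
                raise ValueError(f"unknown weather variable in interaction: {wvar}")

    def evaluate(self, freqs, weather):
        """Noise-free yield for aligned frequency and weather tables.

        Parameters
        ----------
        freqs : DataFrame with marker columns, one row per county-year.
        weather : DataFrame with the four weather columns, same row order.
        """
        import numpy as np

        y = np.full(len(freqs), float(self.intercept))
        for marker, beta in self.marker_effects.items():
            if marker in freqs.columns:
                y += beta * freqs[marker].to_numpy(float)
        for var, gamma in self.weather_effects.items():
            y += gamma * weather[var].to_numpy(float)
        for (marker, var), delta in self.interaction_effects.items():
            if marker in freqs.columns:
                y += delta * freqs[marker].to_numpy(float) * weather[var].to_numpy(float)
        if self.heat_threshold is not None and self.heat_slope != 0.0:
            excess = np.clip(weather["july_tmax"].to_numpy(float) - self.heat_threshold, 0.0, None)
            y += self.heat_slope * excess
        return y
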