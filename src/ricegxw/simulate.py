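"""Synthetic study system with a known ground-truth yield model.

Generates every input the pipeline consumes — genotypes with release-year
structure, county acreage histories with realistic variety turnover,
county-year weather under historical and projected scenarios, nursery-style
trial records — and yields from an explicit ``G + W + GxW`` model, so each
downstream stage can be tested against known truth without external data.

Counties are treated as exchangeable: each year has a regional weather
anomaly shared by all counties plus independent county noise. Real weather
is spatially correlated along the Gulf Coast; that structure is not
emulated and nothing downstream depends on it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .alleles import GenotypeMatrix
from .config import WEATHER_VARS, GroundTruth, SyntheticConfig

SCENARIOS = ("historical", "future-mild", "future-hot")

#: Additional end-of-century warming (degC) applied as a linear ramp over the
#: projection years, mimicking a mild (SSP1-2.6-like) and a severe
#: (SSP5-8.5-like) pathway. The severe pathway deliberately pushes a share of
#: July maxima above the 40 degC physiological limit so the scenario filter
#: has work to do.
_SCENARIO_RAMP_2100 = {
    "future-mild": {"april_tavg": 0.8, "july_tmax": 1.5},
    "future-hot": {"april_tavg": 2.5, "july_tmax": 6.0},
}

PROGRAMS = ("AR", "LA", "TX")


def _stream_rng(config: SyntheticConfig, code: int) -> np.random.Generator:
    """Independent, reproducible stream per generator stage."""
    return np.random.default_rng(np.random.SeedSequence([config.seed, code]))


_STREAMS = {"genotypes": 11, "acreage": 23, "historical": 31, "future-mild": 37,
            "future-hot": 41, "yields": 53, "truth": 61, "trials": 71}


def generate_genotypes(config: SyntheticConfig) -> GenotypeMatrix:
    """Binary variety x marker calls with release-year structure.

    A designated "modern" subset of markers (``modern_marker_fraction``)
    has allele probability rising with the variety's release year, emulating
    alleles swept in by breeding (semidwarf, blast resistance, introgressed
    California ancestry); the rest are stationary. Calls go missing
    completely at random at ``missing_rate``, as in real reduced-
    representation sequencing data.
    """
    rng = _stream_rng(config, _STREAMS["genotypes"])
    n_v, n_m = config.n_varieties, config.n_markers

    variety_ids = [f"VAR{i + 1:04d}" for i in range(n_v)]
    marker_ids = [f"M{j + 1:05d}" for j in range(n_m)]

    lo, hi = config.release_year_range
    release = np.sort(rng.integers(lo, hi + 1, size=n_v))
    # shuffle ids so release order is not alphabetical order of ids
    rng.shuffle(release)

    n_modern = max(1, int(round(config.modern_marker_fraction * n_m)))
    modern = marker_ids[:n_modern]

    span = max(hi - lo, 1)
    z = (release - (lo + hi) / 2.0) / (span / 6.0)  # ~[-3, 3] across the range
    p_modern = 1.0 / (1.0 + np.exp(-z))  # old ~0.05, new ~0.95

    base = rng.uniform(0.1, 0.9, size=n_m)
    probs = np.tile(base, (n_v, 1))
    probs[:, :n_modern] = p_modern[:, None]

    calls = (rng.random((n_v, n_m)) < probs).astype(float)
    if config.missing_rate > 0:
        calls[rng.random((n_v, n_m)) < config.missing_rate] = np.nan

    sd1 = rng.random(n_v) < 1.0 / (1.0 + np.exp(-(release - (lo + 0.55 * span)) / 6.0))
    ca = rng.random(n_v) < 1.0 / (1.0 + np.exp(-(release - (lo + 0.7 * span)) / 8.0))
    meta = pd.DataFrame(
        {
            "release_year": release,
            "program": rng.choice(PROGRAMS, size=n_v),
            "sd1": sd1,
            "ca_ancestry": ca,
        },
        index=pd.Index(variety_ids, name="variety"),
    )
    return GenotypeMatrix(
        calls=pd.DataFrame(calls, index=meta.index, columns=marker_ids),
        meta=meta,
        modern_markers=list(modern),
    )


def generate_acreage(config: SyntheticConfig, genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Long-format (county, year, variety, acres) records.

    Each variety enters the market at its release year (clipped to the data
    window) and stays for a contiguous geometric span with the configured
    mean; there is no re-entry after exit. Each county-year plants between
    the configured min and max varieties, sampled from the active pool with
    variety-specific popularity weights, with strictly positive lognormal
    acreages. A configurable share of varieties is withheld from the
    genotype matrix downstream, so some acreage rows refer to ungenotyped
    varieties (exercising the coverage filter).
    """
    rng = _stream_rng(config, _STREAMS["acreage"])
    y0, y1 = config.year_start, config.year_end
    k_min, k_max = config.varieties_per_county_year

    meta = genotypes.meta
    varieties = meta.index.to_numpy()
    release = meta["release_year"].to_numpy()

    entry = release.copy()
    duration = rng.geometric(1.0 / config.mean_market_life, size=len(varieties))
    exit_year = entry + duration - 1

    active_by_year: dict[int, np.ndarray] = {}
    for year in config.years:
        active = varieties[(entry <= year) & (exit_year >= year)]
        if len(active) < k_min:
            # keep the market populated: extend the most recently exited /
            # nearest-release varieties into this year
            gap = np.abs(release - year)
            order = varieties[np.argsort(gap, kind="stable")]
            extra = [v for v in order if v not in active]
            active = np.concatenate([active, extra[: k_min - len(active)]])
        active_by_year[year] = active

    # regional popularity times a persistent county preference: counties
    # adopt different varieties, so genetic composition varies across space
    # within a year, not only across years
    counties = [f"C{c + 1:03d}" for c in range(config.n_counties)]
    popularity = rng.lognormal(mean=0.0, sigma=1.0, size=len(varieties))
    county_pref = rng.lognormal(mean=0.0, sigma=1.0, size=(len(counties), len(varieties)))
    pop = pd.DataFrame(
        county_pref * popularity[None, :], index=counties, columns=varieties
    )

    records = []
    for year in config.years:
        active = active_by_year[year]
        for county in counties:
            w = pop.loc[county, active].to_numpy()
            w = w / w.sum()
            k = int(rng.integers(k_min, k_max + 1))
            k = min(k, len(active))
            chosen = rng.choice(active, size=k, replace=False, p=w)
            acres = rng.lognormal(mean=np.log(2000.0), sigma=0.7, size=k)
            for v, a in zip(chosen, acres):
                records.append((county, year, v, float(a)))
    return pd.DataFrame(records, columns=["county", "year", "variety", "acres"])


def withhold_genotypes(
    config: SyntheticConfig, genotypes: GenotypeMatrix
) -> GenotypeMatrix:
    """Drop a random ``ungenotyped_fraction`` of varieties from the genotype
    matrix (their acreage records remain), emulating varieties grown but
    never genotyped."""
    if config.ungenotyped_fraction <= 0:
        return genotypes
    rng = _stream_rng(config, _STREAMS["genotypes"] + 1)
    n_drop = int(round(config.ungenotyped_fraction * len(genotypes.variety_ids)))
    drop = rng.choice(genotypes.variety_ids.to_numpy(), size=n_drop, replace=False)
    keep = ~genotypes.variety_ids.isin(drop)
    return GenotypeMatrix(
        calls=genotypes.calls.loc[keep],
        meta=genotypes.meta.loc[genotypes.calls.index[keep]],
        modern_markers=genotypes.modern_markers,
    )


def generate_weather(
    config: SyntheticConfig,
    scenario: str = "historical",
    years: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """County-year weather table for a scenario.

    Historical values are a shared regional annual anomaly plus county
    noise, clipped to the configured bounds, then shifted by the per-decade
    trend. Future scenarios continue the historical process and add a
    linear warming ramp reaching the scenario's end-of-century increment.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    rng = _stream_rng(config, _STREAMS[scenario])

    if years is None:
        years = (config.year_start, config.year_end) if scenario == "historical" else (2016, 2100)
    y0, y1 = years
    year_list = list(range(y0, y1 + 1))
    counties = [f"C{c + 1:03d}" for c in range(config.n_counties)]

    n_y, n_c = len(year_list), len(counties)
    out = {
        "county": np.repeat(counties, n_y),
        "year": np.tile(year_list, n_c),
    }
    ramp = _SCENARIO_RAMP_2100.get(scenario, {})
    yr = np.tile(year_list, n_c).astype(float)
    for var in WEATHER_VARS:
        lo, hi = config.weather_ranges[var]
        centre, width = (lo + hi) / 2.0, (hi - lo)
        regional = rng.normal(centre, width / 5.0, size=n_y)
        county_noise = rng.normal(0.0, width / 8.0, size=(n_c, n_y))
        vals = np.clip((regional[None, :] + county_noise).ravel(), lo, hi)
        vals = vals + config.trend.get(var, 0.0) * (yr - config.year_start) / 10.0
        if var in ramp:
            frac = np.clip((yr - 2016.0) / (2100.0 - 2016.0), 0.0, 1.0)
            vals = vals + ramp[var] * frac
        out[var] = vals
    return pd.DataFrame(out)


def default_ground_truth(config: SyntheticConfig, genotypes: GenotypeMatrix) -> GroundTruth:
    """Draw the ground-truth effect maps implied by a config.

    ``n_effect_markers`` random markers get additive effects drawn from
    N(0, marker_effect_sd); the four weather variables get the configured
    main effects (warm Aprils help stand establishment, hot Julys hurt
    flowering); and ``n_interaction_markers`` of the designated modern
    markers get a positive (marker x July-tmax) interaction — modern
    alleles buffer heat — which is the structure the forecasting stage is
    expected to recover.
    """
    rng = _stream_rng(config, _STREAMS["truth"])
    markers = genotypes.marker_ids.to_numpy()
    chosen = rng.choice(markers, size=min(config.n_effect_markers, len(markers)), replace=False)
    marker_effects = {m: float(e) for m, e in
                      zip(chosen, rng.normal(0.0, config.marker_effect_sd, size=len(chosen)))}
    modern = [m for m in genotypes.modern_markers if m in markers]
    n_int = min(config.n_interaction_markers, len(modern))
    interaction = {(m, "july_tmax"): float(config.interaction_effect) for m in modern[:n_int]}
    return GroundTruth(
        intercept=config.intercept,
        marker_effects=marker_effects,
        weather_effects=dict(config.weather_effects),
        interaction_effects=interaction,
    )


def generate_yields(
    freqs,
    weather: pd.DataFrame,
    truth: GroundTruth,
    noise_sd: float,
    seed: int,
) -> pd.DataFrame:
    """County-year yields (kg/ha) from the ground-truth model plus
    N(0, noise_sd) noise.

    ``freqs`` may be an AlleleFrequencyTable or its (county, year)-indexed
    frequency DataFrame; every county-year in it must have a weather row.
    """
    freq_df = getattr(freqs, "freqs", freqs)
    wx = weather.set_index(["county", "year"])
    missing = freq_df.index.difference(wx.index)
    if len(missing):
        raise KeyError(f"county-years without weather: {list(missing[:5])}")
    wx = wx.loc[freq_df.index]
    y = truth.evaluate(freq_df, wx)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=len(y))
    out = freq_df.index.to_frame(index=False)
    out["yield_kg_ha"] = y
    return out


def generate_trials(
    config: SyntheticConfig,
    genotypes: GenotypeMatrix,
    truth: GroundTruth,
    n_sites: int = 4,
    entries_per_year: int = 20,
    site_effect_sd: float = 250.0,
    trial_noise_sd: float = 350.0,
    management_bonus: float = 1200.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Nursery-style replicated trial records plus site weather.

    Each year, a changing roster of varieties (biased toward recent
    releases) is evaluated at a handful of state breeding stations. A
    variety's trial yield is the ground-truth model evaluated at its own
    genotype and the site-year weather, plus a persistent site effect, a
    uniform management bonus (research plots outyield commercial
    production), and plot noise.

    Returns ``(trials, site_weather)`` with trials columns
    (year, site, variety, yield_kg_ha).
    """
    rng = _stream_rng(config, _STREAMS["trials"])
    sites = [f"S{s + 1:02d}" for s in range(n_sites)]

    site_cfg = SyntheticConfig(
        n_counties=n_sites,
        year_start=config.year_start,
        year_end=config.year_end,
        n_varieties=config.n_varieties,
        n_markers=config.n_markers,
        weather_ranges=dict(config.weather_ranges),
        trend=dict(config.trend),
        seed=config.seed + 101,
    )
    site_weather = generate_weather(site_cfg, "historical")
    site_weather["county"] = site_weather["county"].map(
        dict(zip([f"C{c + 1:03d}" for c in range(n_sites)], sites))
    )
    site_weather = site_weather.rename(columns={"county": "site"})
    wx = site_weather.set_index(["site", "year"])

    site_effects = dict(zip(sites, rng.normal(0.0, site_effect_sd, size=n_sites)))
    calls = genotypes.imputed_calls("mean")
    release = genotypes.meta["release_year"]

    records = []
    for year in config.years:
        # roster biased toward varieties released within ~15 y of the trial
        recency = np.exp(-np.abs(release.to_numpy() - year) / 10.0)
        w = recency / recency.sum()
        n_entries = min(entries_per_year, len(calls))
        roster = rng.choice(calls.index.to_numpy(), size=n_entries, replace=False, p=w)
        for site in sites:
            weather_row = wx.loc[(site, year)]
            freq_block = calls.loc[roster]
            w_block = pd.DataFrame(
                {v: np.full(len(roster), float(weather_row[v])) for v in WEATHER_VARS}
            )
            base = truth.evaluate(freq_block.reset_index(drop=True), w_block)
            noise = rng.normal(0.0, trial_noise_sd, size=len(roster))
            for v, b, e in zip(roster, base, noise):
                records.append(
                    (year, site, v, float(b + site_effects[site] + management_bonus + e))
                )
    trials = pd.DataFrame(records, columns=["year", "site", "variety", "yield_kg_ha"])
    return trials, site_weather
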