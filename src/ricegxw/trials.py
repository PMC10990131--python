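"""External evaluation against nursery-style replicated trials.

Mirrors the regional-nursery comparison: for each trial year, the
genotyped varieties entered that year form a yearly CVG with equal
weights; its pooled allele frequencies plus each station's weather give a
model prediction per (year, site), compared against the observed mean
trial yield of those same CVG members at that site-year.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .alleles import CVGDefinition, GenotypeMatrix, cvg_frequencies
from .config import WEATHER_VARS
from .features import build_features
from .metrics import MetricReport, pearson_r, rmse

logger = logging.getLogger(__name__)


def yearly_cvg(
    trials: pd.DataFrame, genotypes: GenotypeMatrix, year: int
) -> tuple[pd.Series, dict]:
    """Pooled allele frequencies of the genotyped varieties entered in a
    trial year (equal weight 1/n each).

    Returns the frequency vector and an info dict with the member list and
    the count of ungenotyped entries excluded.
    """
    entries = trials.loc[trials["year"] == year, "variety"].unique()
    members = sorted(v for v in entries if v in genotypes.variety_ids)
    excluded = len(entries) - len(members)
    if not members:
        raise ValueError(f"no genotyped varieties in trial year {year}")
    cvg = CVGDefinition(name=f"trial_{year}", members=members)
    info = {"members": members, "n_members": len(members), "n_excluded": excluded}
    return cvg_frequencies(cvg, genotypes), info


def evaluate_trials(
    model,
    trials: pd.DataFrame,
    genotypes: GenotypeMatrix,
    site_weather: pd.DataFrame,
) -> dict:
    """Predicted vs observed trial means per (year, site).

    The prediction uses the yearly CVG frequencies with that site-year's
    weather; the observed comparator is the mean trial yield of the CVG's
    member varieties at that site-year. Site-years without weather are
    skipped with a warning. Returns a dict with the per-cell table, a
    MetricReport (r, RMSE over all cells; r is NaN if predictions are
    constant), and per-year cross-site means and SDs of both series.
    """
    wx = site_weather.set_index(["site", "year"])
    cells = []
    for year in sorted(trials["year"].unique()):
        try:
            freq, info = yearly_cvg(trials, genotypes, year)
        except ValueError:
            logger.warning("trial year %s has no genotyped varieties; skipped", year)
            continue
        year_rows = trials[trials["year"] == year]
        for site in sorted(year_rows["site"].unique()):
            if (site, year) not in wx.index:
                logger.warning("no weather for site %s year %s; cell skipped", site, year)
                continue
            weather_row = wx.loc[[(site, year)], list(WEATHER_VARS)]
            weather_row.index = pd.MultiIndex.from_tuples(
                [(site, year)], names=["county", "year"]
            )
            freqs = pd.DataFrame(
                [freq.to_numpy(float)], index=weather_row.index, columns=freq.index
            )
            pred = float(model.predict(build_features(freqs, weather_row))[0])
            obs_rows = year_rows[
                (year_rows["site"] == site) & year_rows["variety"].isin(info["members"])
            ]
            if obs_rows.empty:
                continue
            cells.append(
                {
                    "year": year,
                    "site": site,
                    "predicted": pred,
                    "observed": float(obs_rows["yield_kg_ha"].mean()),
                    "n_members": info["n_members"],
                }
            )
    table = pd.DataFrame(cells)
    if len(table) < 2:
        raise ValueError("fewer than 2 evaluable trial cells")
    report = MetricReport(
        nse=float("nan") if table["observed"].std() == 0 else
        1.0 - np.sum((table["observed"] - table["predicted"]) ** 2)
        / np.sum((table["observed"] - table["observed"].mean()) ** 2),
        r=pearson_r(table["observed"], table["predicted"]),
        rmse=rmse(table["observed"], table["predicted"]),
        n=len(table),
        phase="external",
    )
    yearly = (
        table.groupby("year")[["predicted", "observed"]]
        .agg(["mean", "std"])
        .pipe(lambda d: d.set_axis(["_".join(c) for c in d.columns], axis=1))
        .reset_index()
    )
    return {"cells": table, "report": report, "yearly": yearly}
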