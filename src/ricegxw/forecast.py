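"""Composite-variety-group backcasting and forecasting.

CVGs are built either by a release-year sliding window (bins of 20
varieties, step 1) or by classification (semidwarf vs wild, California
ancestry vs not, breeding program of origin). Each CVG's pooled allele
frequencies are paired with every county-year weather row of a period and
pushed through the fitted ensemble; the headline statistic is the relative
yield change, the mean forecast (projected weather, 2016-2100) relative to
the mean backcast (historical weather, 1970-2015) of the same group:

    relative_change_pct = 100 * (forecast_mean - backcast_mean) / backcast_mean

Projected county-years whose July maximum exceeds 40 degC are removed
before forecasting: above that anthesis temperature empirical yield models
extrapolate outside physiological validity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alleles import CVGDefinition, GenotypeMatrix, cvg_frequencies
from .config import WEATHER_VARS
from .features import build_features

logger = logging.getLogger(__name__)

CLASSIFICATION_SCHEMES = {
    "semidwarf": ("sd1", {True: "sd", False: "wild"}),
    "ca_ancestry": ("ca_ancestry", {True: "CA", False: "non_CA"}),
    "program": ("program", None),
}


def sliding_window_cvgs(
    genotypes: GenotypeMatrix, window: int = 20, step: int = 1
) -> list[CVGDefinition]:
    """Release-year-ordered CVGs: bin ``window`` varieties, slide by ``step``.

    Varieties are sorted by release year (ties by variety id); CVG *t*
    contains varieties [t*step, t*step + window) with equal weights. The
    release-year range of each window is recorded in its metadata.
    """
    meta = genotypes.meta
    if "release_year" not in meta.columns or meta["release_year"].isna().any():
        raise ValueError("every variety needs a release year")
    if len(meta) < window:
        raise ValueError(f"need at least {window} varieties, have {len(meta)}")
    order = meta.assign(_id=meta.index).sort_values(["release_year", "_id"], kind="stable")
    ids = order.index.to_list()
    years = order["release_year"].to_list()

    cvgs = []
    for t, start in enumerate(range(0, len(ids) - window + 1, step)):
        members = ids[start : start + window]
        span = years[start : start + window]
        cvgs.append(
            CVGDefinition(
                name=f"cvg_{t:03d}",
                members=members,
                metadata={
                    "release_min": int(min(span)),
                    "release_max": int(max(span)),
                    "window_index": t,
                },
            )
        )
    return cvgs


def classify_cvgs(genotypes: GenotypeMatrix, scheme: str) -> list[CVGDefinition]:
    """Partition varieties into labelled CVGs by a metadata flag.

    Schemes: ``semidwarf`` (sd vs wild), ``ca_ancestry`` (CA vs non_CA),
    ``program`` (one group per breeding program). Empty groups are returned
    with no members so callers can report them.
    """
    if scheme not in CLASSIFICATION_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    column, labels = CLASSIFICATION_SCHEMES[scheme]
    meta = genotypes.meta
    if column not in meta.columns:
        raise ValueError(f"metadata lacks column {column!r} required by {scheme!r}")

    cvgs = []
    if labels is not None:  # boolean flag -> two labelled groups
        for value, label in labels.items():
            members = meta.index[meta[column] == value].to_list()
            cvgs.append(
                CVGDefinition(name=label, members=members, metadata={"scheme": scheme})
            )
    else:  # categorical -> one group per level
        for level in sorted(meta[column].unique()):
            members = meta.index[meta[column] == level].to_list()
            cvgs.append(
                CVGDefinition(name=str(level), members=members, metadata={"scheme": scheme})
            )
    return cvgs


def scenario_filter(
    weather: pd.DataFrame, tmax_limit: float = 40.0
) -> tuple[pd.DataFrame, dict]:
    """Drop projected rows whose July maximum strictly exceeds the limit.

    Exceedance is strict — a row at exactly 40.0 degC is retained. Returns
    the filtered table and a report dict (n_kept, n_dropped, drop_fraction).
    """
    if "july_tmax" not in weather.columns:
        raise ValueError("weather table lacks july_tmax")
    keep = weather["july_tmax"] <= tmax_limit
    filtered = weather[keep].reset_index(drop=True)
    n_dropped = int((~keep).sum())
    report = {
        "n_kept": int(keep.sum()),
        "n_dropped": n_dropped,
        "drop_fraction": n_dropped / len(weather) if len(weather) else 0.0,
        "tmax_limit": tmax_limit,
    }
    logger.info(
        "scenario filter at %.1f degC: dropped %d of %d rows (%.1f%%)",
        tmax_limit,
        n_dropped,
        len(weather),
        100 * report["drop_fraction"],
    )
    return filtered, report


@dataclass
class ForecastResult:
    """Backcast/forecast summary for one CVG.

    ``relative_change`` is recomputed from the stored means, so the
    identity 100*(forecast - backcast)/backcast always holds exactly.
    """

    cvg: str
    backcast_mean: float
    forecast_mean: float
    n_backcast: int
    n_forecast: int
    n_rows_dropped: int = 0
    valid: bool = True
    metadata: dict = field(default_factory=dict)

    @property
    def relative_change(self) -> float:
        """Percent yield change of the forecast mean vs the backcast mean."""
        if not self.valid:
            return float("nan")
        return 100.0 * (self.forecast_mean - self.backcast_mean) / self.backcast_mean


def _predict_cvg(model, freq: pd.Series, weather: pd.DataFrame) -> np.ndarray:
    wx = weather.set_index(["county", "year"]) if "county" in weather.columns else weather
    freqs = pd.DataFrame(
        np.tile(freq.to_numpy(float), (len(wx), 1)), index=wx.index, columns=freq.index
    )
    features = build_features(freqs, wx)
    return model.predict(features)


def backcast_forecast(
    model,
    cvg: CVGDefinition,
    genotypes: GenotypeMatrix,
    historical: pd.DataFrame,
    future: pd.DataFrame,
    filter_report: dict | None = None,
) -> ForecastResult:
    """Predict a CVG's mean yield over historical vs projected weather.

    The CVG's pooled frequency vector is paired with every (county, year)
    weather row of each period, features are built exactly as in training,
    and period means are taken over all retained rows pooled. ``future``
    must already be scenario-filtered; pass the filter report to record the
    drop count. An empty future table yields an invalid result.
    """
    freq = cvg_frequencies(cvg, genotypes)
    back = _predict_cvg(model, freq, historical)
    meta = dict(cvg.metadata)
    n_dropped = int(filter_report["n_dropped"]) if filter_report else 0
    if len(future) == 0:
        return ForecastResult(
            cvg=cvg.name,
            backcast_mean=float(back.mean()),
            forecast_mean=float("nan"),
            n_backcast=len(back),
            n_forecast=0,
            n_rows_dropped=n_dropped,
            valid=False,
            metadata=meta,
        )
    fore = _predict_cvg(model, freq, future)
    return ForecastResult(
        cvg=cvg.name,
        backcast_mean=float(back.mean()),
        forecast_mean=float(fore.mean()),
        n_backcast=len(back),
        n_forecast=len(fore),
        n_rows_dropped=n_dropped,
        metadata=meta,
    )


def forecast_results_frame(results) -> pd.DataFrame:
    """Tabulate ForecastResults (one row per CVG) for reporting."""
    rows = []
    for r in results:
        rows.append(
            {
                "cvg": r.cvg,
                "release_min": r.metadata.get("release_min"),
                "release_max": r.metadata.get("release_max"),
                "backcast_mean": r.backcast_mean,
                "forecast_mean": r.forecast_mean,
                "relative_change_pct": r.relative_change,
                "rows_kept": r.n_forecast,
                "rows_dropped": r.n_rows_dropped,
                "valid": r.valid,
            }
        )
    return pd.DataFrame(rows)


def trait_frequency_table(
    cvgs: list[CVGDefinition], genotypes: GenotypeMatrix, flags=("sd1", "ca_ancestry")
) -> pd.DataFrame:
    """Heatmap-ready breeding-trend table: fraction of each CVG's members
    carrying each boolean trait flag."""
    meta = genotypes.meta
    rows = []
    for cvg in cvgs:
        if not cvg.members:
            continue
        sub = meta.loc[cvg.members]
        rows.append({"cvg": cvg.name, **{f: float(sub[f].mean()) for f in flags}})
    return pd.DataFrame(rows)


def response_sweep(
    model,
    cvg: CVGDefinition,
    genotypes: GenotypeMatrix,
    variable: str,
    grid,
    baseline_weather: pd.DataFrame,
) -> pd.DataFrame:
    """Predicted yield as one weather variable sweeps a grid.

    The other three variables are fixed at their historical county means;
    predictions are averaged over counties at each grid point. Grid points
    outside the historical range of ``variable`` are flagged as
    extrapolation. Returns a DataFrame (value, predicted_mean, extrapolated).
    """
    if variable not in WEATHER_VARS:
        raise ValueError(f"unknown weather variable {variable!r}")
    grid = list(grid)
    if not grid:
        raise ValueError("empty grid")

    freq = cvg_frequencies(cvg, genotypes)
    county_means = baseline_weather.groupby("county")[list(WEATHER_VARS)].mean()
    lo, hi = baseline_weather[variable].min(), baseline_weather[variable].max()

    rows = []
    for value in grid:
        wx = county_means.copy()
        wx[variable] = float(value)
        wx.index = pd.MultiIndex.from_arrays(
            [wx.index, np.zeros(len(wx), dtype=int)], names=["county", "year"]
        )
        pred = _predict_cvg(model, freq, wx)
        rows.append(
            {
                "value": float(value),
                "predicted_mean": float(pred.mean()),
                "extrapolated": bool(value < lo or value > hi),
            }
        )
    return pd.DataFrame(rows)
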