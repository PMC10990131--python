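"""End-to-end pipeline stages shared by the CLI and the analysis scripts.

Each stage reads its inputs from / writes its artifacts to a run
directory using fixed filenames, and records a JSON manifest (config
snapshot, seed, row counts) so a rerun under the same config is
byte-identical and auditable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from . import io as rio
from .alleles import bag_of_alleles, coverage_filter
from .config import WEATHER_VARS, SyntheticConfig
from .ensemble import cross_validate, reports_to_frame
from .features import build_features
from .forecast import (
    backcast_forecast,
    classify_cvgs,
    forecast_results_frame,
    scenario_filter,
    sliding_window_cvgs,
    trait_frequency_table,
)
from .simulate import (
    default_ground_truth,
    generate_acreage,
    generate_genotypes,
    generate_trials,
    generate_weather,
    generate_yields,
    withhold_genotypes,
)
from .trials import evaluate_trials

logger = logging.getLogger(__name__)

FILES = {
    "calls": "genotypes.tsv",
    "meta": "variety_meta.csv",
    "acreage": "acreage.csv",
    "weather_hist": "weather_historical.csv",
    "yields": "yields.csv",
    "trials": "trials.csv",
    "site_weather": "site_weather.csv",
    "truth": "ground_truth.json",
    "freqs": "allele_freqs.csv",
    "coverage": "coverage_report.csv",
    "metrics": "metrics.csv",
    "model": "model_bundle.joblib",
    "weights": "stacking_weights.csv",
}


def _write_manifest(outdir: Path, command: str, config: dict, counts: dict) -> None:
    from . import __version__

    manifest = {
        "command": command,
        "version": __version__,
        "config": config,
        "row_counts": counts,
    }
    path = outdir / f"manifest_{command}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))


def run_simulate(config: SyntheticConfig, outdir) -> dict:
    """Generate and write every synthetic input plus the ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    full = generate_genotypes(config)
    observed = withhold_genotypes(config, full)
    acreage = generate_acreage(config, full)
    weather_hist = generate_weather(config, "historical")
    truth = default_ground_truth(config, full)

    filtered, _report = coverage_filter(acreage, observed, threshold=0.8, mode="count")
    freqs = bag_of_alleles(filtered, observed)
    yields = generate_yields(freqs, weather_hist, truth, config.noise_sd, config.seed + 7)
    trials, site_weather = generate_trials(config, observed, truth)

    rio.write_genotypes_tsv(observed, outdir / FILES["calls"], outdir / FILES["meta"])
    rio.write_frame(acreage, outdir / FILES["acreage"])
    rio.write_frame(weather_hist, outdir / FILES["weather_hist"])
    for scenario in ("future-mild", "future-hot"):
        rio.write_frame(generate_weather(config, scenario), outdir / f"weather_{scenario}.csv")
    rio.write_frame(yields, outdir / FILES["yields"])
    rio.write_frame(trials, outdir / FILES["trials"])
    rio.write_frame(site_weather, outdir / FILES["site_weather"])
    (outdir / FILES["truth"]).write_text(
        json.dumps(
            {
                "intercept": truth.intercept,
                "marker_effects": truth.marker_effects,
                "weather_effects": truth.weather_effects,
                "interaction_effects": {
                    f"{m}|{w}": v for (m, w), v in truth.interaction_effects.items()
                },
            },
            indent=2,
            sort_keys=True,
        )
    )
    counts = {
        "varieties_genotyped": len(observed.variety_ids),
        "acreage_rows": len(acreage),
        "weather_rows": len(weather_hist),
        "yield_rows": len(yields),
        "trial_rows": len(trials),
    }
    _write_manifest(outdir, "simulate", dataclasses.asdict(config), counts)
    return counts


def run_aggregate(outdir, threshold: float = 0.8, mode: str = "count") -> dict:
    outdir = Path(outdir)
    genotypes = rio.read_genotypes_tsv(outdir / FILES["calls"], outdir / FILES["meta"])
    acreage = rio.read_acreage(outdir / FILES["acreage"])
    filtered, report = coverage_filter(acreage, genotypes, threshold=threshold, mode=mode)
    coverage = report.set_index(["county", "year"])["coverage"]
    freqs = bag_of_alleles(filtered, genotypes, coverage=coverage)

    out = freqs.freqs.copy()
    out.insert(0, "coverage", freqs.coverage)
    rio.write_frame(out.reset_index(), outdir / FILES["freqs"])
    rio.write_frame(report, outdir / FILES["coverage"])
    counts = {
        "county_years_in": int(report.shape[0]),
        "county_years_retained": int(report["retained"].sum()),
    }
    _write_manifest(outdir, "aggregate", {"threshold": threshold, "mode": mode}, counts)
    return counts


def _load_freqs(outdir: Path) -> pd.DataFrame:
    df = pd.read_csv(outdir / FILES["freqs"]).set_index(["county", "year"])
    return df.drop(columns=["coverage"], errors="ignore")


def run_train(
    outdir,
    n_components: int = 85,
    split: float = 0.75,
    n_folds: int = 5,
    seed: int = 0,
    hyperparameters: dict | None = None,
) -> dict:
    outdir = Path(outdir)
    freqs = _load_freqs(outdir)
    weather = rio.read_weather(outdir / FILES["weather_hist"])
    yields = rio.read_yields(outdir / FILES["yields"]).set_index(["county", "year"])

    common = freqs.index.intersection(yields.index)
    features = build_features(freqs.loc[common], weather)
    y = yields.loc[common, "yield_kg_ha"].to_numpy()

    result = cross_validate(
        features,
        y,
        split=split,
        seed=seed,
        n_components=n_components,
        n_folds=n_folds,
        hyperparameters=hyperparameters,
    )
    rio.write_frame(reports_to_frame(result["reports"]), outdir / FILES["metrics"])
    rio.write_frame(
        result["model"].stacking_weights.rename("weight").rename_axis("learner").reset_index(),
        outdir / FILES["weights"],
    )
    joblib.dump(result["model"], outdir / FILES["model"])
    counts = {"rows": len(common), "train_n": result["train"].n, "test_n": result["test"].n}
    _write_manifest(
        outdir,
        "train",
        {"n_components": n_components, "split": split, "n_folds": n_folds, "seed": seed},
        counts,
    )
    return {
        **counts,
        "test_nse": result["test"].nse,
        "train_nse": result["train"].nse,
        "test_rmse": result["test"].rmse,
    }


def run_forecast(
    outdir,
    scenario: str = "future-mild",
    window: int = 20,
    step: int = 1,
    tmax_limit: float = 40.0,
    schemes: tuple[str, ...] = ("semidwarf", "ca_ancestry", "program"),
) -> dict:
    outdir = Path(outdir)
    model = joblib.load(outdir / FILES["model"])
    genotypes = rio.read_genotypes_tsv(outdir / FILES["calls"], outdir / FILES["meta"])
    hist = rio.read_weather(outdir / FILES["weather_hist"])
    future = rio.read_weather(outdir / f"weather_{scenario}.csv")
    future_kept, report = scenario_filter(future, tmax_limit=tmax_limit)

    cvgs = sliding_window_cvgs(genotypes, window=window, step=step)
    results = [
        backcast_forecast(model, cvg, genotypes, hist, future_kept, filter_report=report)
        for cvg in cvgs
    ]
    table = forecast_results_frame(results)
    rio.write_frame(table, outdir / "forecast_sliding.csv")
    rio.write_frame(trait_frequency_table(cvgs, genotypes), outdir / "trait_freqs.csv")

    for scheme in schemes:
        group_results = [
            backcast_forecast(model, cvg, genotypes, hist, future_kept, filter_report=report)
            for cvg in classify_cvgs(genotypes, scheme)
            if cvg.members
        ]
        rio.write_frame(
            forecast_results_frame(group_results), outdir / f"forecast_{scheme}.csv"
        )

    valid = table[table["valid"]]
    counts = {
        "n_cvgs": len(table),
        "future_rows_kept": report["n_kept"],
        "future_rows_dropped": report["n_dropped"],
    }
    _write_manifest(
        outdir,
        "forecast",
        {"scenario": scenario, "window": window, "step": step, "tmax_limit": tmax_limit},
        counts,
    )
    return {
        **counts,
        "relative_change_q1": float(valid["relative_change_pct"].quantile(0.25)),
        "relative_change_q3": float(valid["relative_change_pct"].quantile(0.75)),
    }


def run_evaluate(outdir) -> dict:
    outdir = Path(outdir)
    model = joblib.load(outdir / FILES["model"])
    genotypes = rio.read_genotypes_tsv(outdir / FILES["calls"], outdir / FILES["meta"])
    trials = pd.read_csv(outdir / FILES["trials"])
    site_weather = pd.read_csv(outdir / FILES["site_weather"])

    result = evaluate_trials(model, trials, genotypes, site_weather)
    rio.write_frame(result["cells"], outdir / "trial_cells.csv")
    rio.write_frame(result["yearly"], outdir / "trial_yearly.csv")
    summary = {
        "r": result["report"].r,
        "rmse": result["report"].rmse,
        "nse": result["report"].nse,
        "n": result["report"].n,
    }
    (outdir / "trial_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    _write_manifest(outdir, "evaluate", {}, {"cells": result["report"].n})
    return summary


def run_report(outdir) -> dict:
    """Collate the manifests of completed stages into one run report."""
    outdir = Path(outdir)
    report = {}
    for path in sorted(outdir.glob("manifest_*.json")):
        report[path.stem.removeprefix("manifest_")] = json.loads(path.read_text())
    (outdir / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
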