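"""Shared fixtures: a tiny system for fast unit tests and one compact
simulated study (with its fitted ensemble) reused across the slower
model-level tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ricegxw import (
    SyntheticConfig,
    bag_of_alleles,
    build_features,
    coverage_filter,
    fit_ensemble,
)
from ricegxw.simulate import (
    default_ground_truth,
    generate_acreage,
    generate_genotypes,
    generate_weather,
    generate_yields,
    withhold_genotypes,
)


@pytest.fixture(scope="session")
def tiny_config() -> SyntheticConfig:
    return SyntheticConfig(
        n_counties=5,
        year_start=2000,
        year_end=2009,
        n_varieties=25,
        n_markers=40,
        release_year_range=(1980, 2009),
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_system(tiny_config):
    full = generate_genotypes(tiny_config)
    observed = withhold_genotypes(tiny_config, full)
    acreage = generate_acreage(tiny_config, full)
    weather = generate_weather(tiny_config, "historical")
    truth = default_ground_truth(tiny_config, full)
    return {
        "config": tiny_config,
        "full": full,
        "observed": observed,
        "acreage": acreage,
        "weather": weather,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def compact_study():
    """The compact simulated study: 20 counties x 30 years, 300 markers,
    default ground truth and noise, aggregated and feature-built."""
    cfg = SyntheticConfig.compact(seed=1)
    full = generate_genotypes(cfg)
    observed = withhold_genotypes(cfg, full)
    acreage = generate_acreage(cfg, full)
    weather = generate_weather(cfg, "historical")
    truth = default_ground_truth(cfg, full)
    filtered, report = coverage_filter(acreage, observed)
    freqs = bag_of_alleles(filtered, observed)
    yields = generate_yields(freqs, weather, truth, cfg.noise_sd, seed=1)
    features = build_features(freqs, weather)
    return {
        "config": cfg,
        "full": full,
        "observed": observed,
        "acreage": acreage,
        "weather": weather,
        "truth": truth,
        "freqs": freqs,
        "yields": yields,
        "y": yields["yield_kg_ha"].to_numpy(),
        "features": features,
        "coverage_report": report,
    }


@pytest.fixture(scope="session")
def fitted_model(compact_study):
    """Ensemble fitted on the full compact study (used by forecast and
    trial-evaluation tests; cross-validation skill has its own tests)."""
    return fit_ensemble(compact_study["features"], compact_study["y"], seed=1)


class LinearStubModel:
    """Deterministic stand-in for a fitted ensemble: a fixed linear
    functional of the feature row. Lets contract tests run without a fit."""

    def __init__(self, columns, coefs: dict[str, float] | None = None, intercept=6000.0):
        self.feature_columns = pd.Index(columns)
        self.coefs = coefs or {}
        self.intercept = intercept

    def predict(self, features):
        df = features.values if hasattr(features, "provenance") else features
        out = np.full(len(df), float(self.intercept))
        for col, coef in self.coefs.items():
            out += coef * df[col].to_numpy(float)
        return out


@pytest.fixture
def linear_stub_factory():
    return LinearStubModel
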