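"""G / W / GxW design matrix assembly and PCA reduction.

The design matrix concatenates three column blocks: allele frequencies
(G, one column per marker), weather (W, the four covariates), and all
pairwise marker-by-weather products (GxW), giving M + K + M*K columns for
M markers and K weather variables. With the historical marker panel
(M = 8,755, K = 4) this is 43,779 columns against ~2,800 county-year
rows, so the matrix is standardized and reduced with PCA (85 components
by default) before model fitting. PCA centre/scale/loadings are always
fitted on training rows only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .config import WEATHER_VARS

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """County-year feature rows with per-column provenance.

    ``values`` is indexed by (county, year); ``provenance`` has one row per
    column recording its block (G, W, GxW or extra) and, for interaction
    columns, exactly which marker and weather variable it is the product of.
    """

    values: pd.DataFrame
    provenance: pd.DataFrame

    @property
    def columns(self) -> pd.Index:
        return self.values.columns

    def __len__(self) -> int:
        return len(self.values)


def as_frame(features) -> pd.DataFrame:
    """Feature rows as a DataFrame, whether given a FeatureMatrix or frame."""
    return features.values if isinstance(features, FeatureMatrix) else features


def build_features(
    freqs,
    weather: pd.DataFrame,
    extra_covariates: pd.DataFrame | None = None,
) -> FeatureMatrix:
    """Assemble the [G | W | GxW] design matrix for county-year rows.

    ``freqs`` is an AlleleFrequencyTable or its (county, year)-indexed
    DataFrame; ``weather`` a long table with county/year columns or a
    (county, year)-indexed frame. Every frequency row must have a weather
    row. Interaction column ``m*w`` is the elementwise product of marker
    ``m``'s frequency and weather variable ``w``. Optional extra covariates
    (e.g. nitrogen rate) are appended as their own block.
    """
    freq_df = getattr(freqs, "freqs", freqs)
    if {"county", "year"}.issubset(weather.columns):
        wx = weather.set_index(["county", "year"])
    else:
        wx = weather
    missing = freq_df.index.difference(wx.index)
    if len(missing):
        raise KeyError(f"county-years without weather rows: {list(missing[:5])}")
    wx = wx.loc[freq_df.index, list(WEATHER_VARS)]

    G = freq_df.to_numpy(float)
    W = wx.to_numpy(float)
    if not np.isfinite(G).all() or not np.isfinite(W).all():
        raise ValueError("non-finite values in inputs")

    markers = list(freq_df.columns)
    inter = (G[:, :, None] * W[:, None, :]).reshape(len(G), -1)
    inter_names = [f"{m}*{w}" for m in markers for w in WEATHER_VARS]

    blocks = [G, W, inter]
    names = markers + list(WEATHER_VARS) + inter_names
    prov = (
        [("G", m, "") for m in markers]
        + [("W", "", w) for w in WEATHER_VARS]
        + [("GxW", m, w) for m in markers for w in WEATHER_VARS]
    )
    if extra_covariates is not None:
        extra = extra_covariates.loc[freq_df.index]
        if not np.isfinite(extra.to_numpy(float)).all():
            raise ValueError("non-finite values in extra covariates")
        blocks.append(extra.to_numpy(float))
        names += list(extra.columns)
        prov += [("extra", "", "") for _ in extra.columns]

    values = pd.DataFrame(np.hstack(blocks), index=freq_df.index, columns=names)
    provenance = pd.DataFrame(prov, columns=["block", "marker", "weather_var"], index=names)
    return FeatureMatrix(values=values, provenance=provenance)


@dataclass
class PCATransform:
    """Fitted standardize-then-project transform.

    Zero-variance columns (on the training rows) are dropped, the rest are
    centred and scaled to unit variance, and the PCA loadings map the
    standardized rows to ``n_components`` orthonormal component scores.
    """

    columns: pd.Index
    center: np.ndarray
    scale: np.ndarray
    components: np.ndarray  # (n_components, n_kept_columns)
    explained_variance_ratio: np.ndarray
    n_dropped: int = 0

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def _standardize(self, features) -> np.ndarray:
        df = as_frame(features)
        if isinstance(df, pd.DataFrame):
            if not df.columns.equals(self.columns):
                df = df.reindex(columns=self.columns)
                if df.isna().to_numpy().any():
                    raise KeyError("feature columns do not match the fitted transform")
            X = df.to_numpy(float)
        else:
            X = np.asarray(df, float)
        return (X - self.center) / self.scale

    def transform(self, features) -> np.ndarray:
        """Component scores for feature rows (training or held-out)."""
        return self._standardize(features) @ self.components.T

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        """Back-project scores to the standardized feature space."""
        return np.asarray(scores, float) @ self.components


def fit_pca(features, n_components: int = 85) -> PCATransform:
    """Fit the standardizer and PCA on training rows only.

    ``n_components`` defaults to 85, the value at which held-out accuracy
    peaked over a 1-300 grid in the historical analysis; it must not exceed
    min(rows, kept columns).
    """
    df = as_frame(features)
    X = df.to_numpy(float)
    center_all = X.mean(axis=0)
    sd_all = X.std(axis=0, ddof=0)
    keep = sd_all > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d zero-variance feature columns before PCA", n_dropped)
    Xk = (X[:, keep] - center_all[keep]) / sd_all[keep]

    bound = min(Xk.shape)
    if n_components > bound:
        raise ValueError(
            f"n_components={n_components} exceeds min(rows, columns)={bound}"
        )
    pca = PCA(n_components=n_components, svd_solver="auto", random_state=0)
    pca.fit(Xk)
    return PCATransform(
        columns=df.columns[keep],
        center=center_all[keep],
        scale=sd_all[keep],
        components=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        n_dropped=n_dropped,
    )


def select_n_components(
    features,
    yields: np.ndarray | pd.Series,
    candidate_grid,
    model_factory=None,
    val_fraction: float = 0.25,
    seed: int = 0,
):
    """Pick the component count maximizing held-out accuracy (NSE).

    For each grid value a PCA is fitted on a training split, the model from
    ``model_factory`` (default: ridge regression) is fitted on the training
    scores, and NSE is measured on the held-out split. Grid values
    exceeding the rank bound are skipped with a warning. Returns
    ``(best_n, curve)`` where curve is a DataFrame (n_components, nse).
    """
    from sklearn.linear_model import Ridge

    from .metrics import nse

    grid = sorted(set(int(g) for g in candidate_grid))
    if not grid:
        raise ValueError("candidate grid is empty")
    if model_factory is None:
        model_factory = lambda: Ridge(alpha=1.0)

    df = as_frame(features)
    y = np.asarray(yields, float)
    rng = np.random.default_rng(seed)
    n = len(df)
    perm = rng.permutation(n)
    n_train = max(2, int(round((1 - val_fraction) * n)))
    tr, va = perm[:n_train], perm[n_train:]

    rows = []
    for g in grid:
        try:
            pca = fit_pca(df.iloc[tr], n_components=g)
        except ValueError:
            warnings.warn(f"skipping n_components={g}: exceeds rank bound")
            continue
        Zt, Zv = pca.transform(df.iloc[tr]), pca.transform(df.iloc[va])
        model = model_factory()
        model.fit(Zt, y[tr])
        rows.append((g, nse(y[va], model.predict(Zv))))
    if not rows:
        raise ValueError("no grid value satisfied the rank bound")
    curve = pd.DataFrame(rows, columns=["n_components", "nse"])
    best = int(curve.loc[curve["nse"].idxmax(), "n_components"])
    return best, curve
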