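"""Model skill metrics: Nash-Sutcliffe efficiency, Pearson r, RMSE."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _check(obs, pred) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(obs, float)
    pred = np.asarray(pred, float)
    if obs.shape != pred.shape:
        raise ValueError("obs and pred must have equal length")
    if obs.size < 2:
        raise ValueError("need at least 2 observations")
    return obs, pred


def nse(obs, pred) -> float:
    """Nash-Sutcliffe efficiency: 1 - SS_err / SS_tot.

    1 means perfect prediction, 0 means no better than the observed mean,
    negative means worse than the mean. Undefined (raises) for constant
    observations.
    """
    obs, pred = _check(obs, pred)
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("NSE undefined for constant observations")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot


def rmse(obs, pred) -> float:
    obs, pred = _check(obs, pred)
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def pearson_r(obs, pred) -> float:
    """Pearson correlation; NaN when either side is constant."""
    obs, pred = _check(obs, pred)
    if np.std(obs) == 0 or np.std(pred) == 0:
        return float("nan")
    return float(np.corrcoef(obs, pred)[0, 1])


@dataclass(frozen=True)
class MetricReport:
    """Skill summary for one model on one phase (train or test)."""

    nse: float
    r: float
    rmse: float
    n: int
    phase: str
    learner: str = "ensemble"

    @classmethod
    def from_predictions(
        cls, obs, pred, phase: str, learner: str = "ensemble"
    ) -> "MetricReport":
        return cls(
            nse=nse(obs, pred),
            r=pearson_r(obs, pred),
            rmse=rmse(obs, pred),
            n=len(np.asarray(obs)),
            phase=phase,
            learner=learner,
        )
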