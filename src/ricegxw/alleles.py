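"""Acreage-weighted "bag of alleles" aggregation.

A county-year's genetic composition is the acreage-proportion-weighted
average of the binary genotypes of the varieties grown there:

    c_j = sum_i A_i * m_ij

where ``A_i`` is variety *i*'s acreage proportion in that county-year and
``m_ij`` its binary call at marker *j*. County-years in which too small a
share of the grown varieties were genotyped are filtered out before
aggregation (the historical analysis retained county-years with at least
80% of grown varieties genotyped).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ACREAGE_COLUMNS = ("county", "year", "variety", "acres")

MissingPolicy = Literal["mean", "strict"]


@dataclass
class GenotypeMatrix:
    """Varieties x markers binary calls plus per-variety metadata.

    ``calls`` is a float DataFrame indexed by variety id with marker-id
    columns; entries are 0.0, 1.0 or NaN (missing). ``meta`` is indexed by
    the same variety ids and carries at least ``release_year``; the
    generator also populates ``program`` and boolean trait flags
    (``sd1``, ``ca_ancestry``).

    Heterozygous or multi-allelic codings are rejected: calls are strictly
    binary relative to a fixed (opaque) reference allele per marker.
    """

    calls: pd.DataFrame
    meta: pd.DataFrame
    modern_markers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.calls.index.has_duplicates:
            raise ValueError("variety ids must be unique")
        if self.calls.columns.has_duplicates:
            raise ValueError("marker ids must be unique")
        vals = self.calls.to_numpy(float)
        ok = np.isnan(vals) | (vals == 0.0) | (vals == 1.0)
        if not ok.all():
            bad = np.unique(vals[~ok])
            raise ValueError(f"calls must be 0, 1 or missing; found {bad[:5]}")
        if not self.calls.index.isin(self.meta.index).all():
            raise ValueError("every variety in calls needs a metadata row")

    @property
    def variety_ids(self) -> pd.Index:
        return self.calls.index

    @property
    def marker_ids(self) -> pd.Index:
        return self.calls.columns

    def imputed_calls(self, policy: MissingPolicy = "mean") -> pd.DataFrame:
        """Calls with missing entries resolved.

        ``mean`` fills each marker's missing calls with that marker's mean
        call across all genotyped varieties; ``strict`` raises on any
        missing call.
        """
        if policy == "strict":
            if self.calls.isna().to_numpy().any():
                raise ValueError("missing genotype calls under strict policy")
            return self.calls
        if policy == "mean":
            means = self.calls.mean(axis=0, skipna=True)
            return self.calls.fillna(means)
        raise ValueError(f"unknown missing policy: {policy!r}")


@dataclass
class AlleleFrequencyTable:
    """County-year allele-frequency vectors with genotyping coverage.

    ``freqs`` is indexed by (county, year) with marker-id columns, entries
    in [0, 1]. ``coverage`` is the genotyped fraction (of acreage or of
    variety count, per the filter mode) for each retained county-year.
    """

    freqs: pd.DataFrame
    coverage: pd.Series | None = None

    def __post_init__(self) -> None:
        vals = self.freqs.to_numpy(float)
        if vals.size and (np.nanmin(vals) < -1e-9 or np.nanmax(vals) > 1 + 1e-9):
            raise ValueError("allele frequencies must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.freqs)


@dataclass
class CVGDefinition:
    """A composite variety group: a named set of varieties whose pooled
    allele frequencies act as one synthetic population (default equal
    weights)."""

    name: str
    members: list[str]
    weights: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.weights is None and self.members:
            self.weights = np.full(len(self.members), 1.0 / len(self.members))
        if self.weights is not None:
            w = np.asarray(self.weights, float)
            if len(w) != len(self.members):
                raise ValueError("weights must match members")
            if (w < 0).any():
                raise ValueError("weights must be non-negative")
            s = w.sum()
            if self.members and abs(s - 1.0) > 1e-9:
                raise ValueError("weights must sum to 1")
            self.weights = w


def _validate_acreage(acreage: pd.DataFrame) -> None:
    missing = set(ACREAGE_COLUMNS) - set(acreage.columns)
    if missing:
        raise ValueError(f"acreage table missing columns: {sorted(missing)}")
    if len(acreage) == 0:
        raise ValueError("acreage table is empty")
    if (acreage["acres"] <= 0).any():
        raise ValueError("acres must be strictly positive")
    if acreage.duplicated(["county", "year", "variety"]).any():
        raise ValueError("(county, year, variety) records must be unique")


def coverage_filter(
    acreage: pd.DataFrame,
    genotypes: GenotypeMatrix,
    threshold: float = 0.8,
    mode: Literal["count", "acreage"] = "count",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain county-years whose genotyped coverage meets ``threshold``.

    Coverage is the genotyped share of grown varieties (``mode="count"``)
    or of planted acreage (``mode="acreage"``); the boundary is inclusive,
    so exactly-at-threshold county-years are retained. Within retained
    county-years, rows for ungenotyped varieties are dropped so downstream
    aggregation sees genotyped varieties only.

    Returns the filtered acreage table and a coverage report with one row
    per input county-year: (county, year, coverage, retained).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    if mode not in ("count", "acreage"):
        raise ValueError(f"unknown coverage mode: {mode!r}")
    _validate_acreage(acreage)

    df = acreage.copy()
    df["_genotyped"] = df["variety"].isin(genotypes.variety_ids)
    if mode == "count":
        cov = df.groupby(["county", "year"], sort=True)["_genotyped"].mean()
    else:
        weighted = df.assign(_gacres=df["acres"] * df["_genotyped"])
        g = weighted.groupby(["county", "year"], sort=True)
        cov = g["_gacres"].sum() / g["acres"].sum()
    retained = cov >= threshold - 1e-12

    report = cov.rename("coverage").reset_index()
    report["retained"] = retained.to_numpy()

    keep_keys = retained[retained].index
    mask = df.set_index(["county", "year"]).index.isin(keep_keys)
    filtered = df[mask & df["_genotyped"]].drop(columns="_genotyped").reset_index(drop=True)
    logger.info(
        "coverage filter (%s, >= %.2f): %d of %d county-years retained",
        mode,
        threshold,
        int(retained.sum()),
        len(retained),
    )
    return filtered, report


def bag_of_alleles(
    acreage: pd.DataFrame,
    genotypes: GenotypeMatrix,
    missing_policy: MissingPolicy = "mean",
    coverage: pd.Series | None = None,
    totals: pd.Series | None = None,
) -> AlleleFrequencyTable:
    """Aggregate genotypes into county-year allele frequencies.

    For each county-year, acreage proportions ``A_i`` are computed over the
    (genotyped) varieties present and the frequency of marker *j* is
    ``c_j = sum_i A_i m_ij``. The acreage table must already be
    coverage-filtered; a variety without a genotype raises.

    By default proportions are renormalised over the genotyped varieties
    present (``sum A_i = 1``). Passing ``totals`` — a (county, year)-indexed
    Series of total planted acres including ungenotyped varieties — divides
    by those totals instead, leaving ``sum A_i`` at the genotyped acreage
    share.
    """
    _validate_acreage(acreage)
    unknown = set(acreage["variety"]) - set(genotypes.variety_ids)
    if unknown:
        raise KeyError(
            f"varieties without genotypes in acreage table (coverage filter "
            f"should have removed them): {sorted(unknown)[:5]}"
        )

    calls = genotypes.imputed_calls(missing_policy)
    wide = acreage.pivot_table(
        index=["county", "year"], columns="variety", values="acres", fill_value=0.0
    )
    if totals is not None:
        denom = totals.reindex(wide.index)
        if denom.isna().any():
            raise KeyError("totals must cover every county-year in the acreage table")
    else:
        denom = wide.sum(axis=1)
    props = wide.div(denom, axis=0)
    freqs = props.to_numpy() @ calls.reindex(wide.columns).to_numpy()
    out = pd.DataFrame(freqs, index=wide.index, columns=calls.columns).clip(0.0, 1.0)
    cov = coverage.reindex(out.index) if coverage is not None else None
    return AlleleFrequencyTable(freqs=out, coverage=cov)


def cvg_frequencies(
    cvg: CVGDefinition,
    genotypes: GenotypeMatrix,
    missing_policy: MissingPolicy = "mean",
) -> pd.Series:
    """Pooled allele frequencies of a composite variety group: the weighted
    mean of member call vectors (equal weights by default)."""
    if not cvg.members:
        raise ValueError(f"CVG {cvg.name!r} has no members")
    missing = [v for v in cvg.members if v not in genotypes.variety_ids]
    if missing:
        raise KeyError(f"CVG {cvg.name!r} members without genotypes: {missing[:5]}")
    calls = genotypes.imputed_calls(missing_policy).loc[cvg.members]
    freq = pd.Series(cvg.weights @ calls.to_numpy(), index=genotypes.marker_ids)
    return freq.clip(0.0, 1.0)
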