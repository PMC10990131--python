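"""On-disk formats: genotype TSV/VCF, acreage/weather/yield CSV.

Genotypes travel as a TSV matrix (rows = varieties, columns = markers,
cells in {0, 1, NA}) plus a metadata CSV (variety, release_year, program,
sd1, ca_ancestry), or as a VCF whose homozygous GT calls collapse to 0/1.
Heterozygous or multi-allelic VCF genotypes are rejected: the aggregation
model is defined on strictly binary inbred-variety calls.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .alleles import ACREAGE_COLUMNS, GenotypeMatrix
from .config import WEATHER_VARS

_META_BOOL = ("sd1", "ca_ancestry")


def write_genotypes_tsv(genotypes: GenotypeMatrix, calls_path, meta_path) -> None:
    out = genotypes.calls.copy()
    out.index.name = "variety"
    # integers where present, NA where missing
    out = out.map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    out.to_csv(calls_path, sep="\t")
    genotypes.meta.to_csv(meta_path)


def read_genotypes_tsv(calls_path, meta_path) -> GenotypeMatrix:
    calls = pd.read_csv(calls_path, sep="\t", index_col="variety", na_values=["NA"])
    meta = pd.read_csv(meta_path, index_col="variety")
    for col in _META_BOOL:
        if col in meta.columns:
            meta[col] = meta[col].astype(bool)
    return GenotypeMatrix(calls=calls.astype(float), meta=meta)


def read_genotypes_vcf(vcf_path, meta_path) -> GenotypeMatrix:
    """Genotypes from a VCF: samples are varieties, sites are markers.

    Homozygous reference/alternate calls map to 0/1; missing calls to NA;
    anything else (heterozygous, multi-allelic) raises.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    varieties = list(vcf.samples)
    marker_ids, columns = [], []
    for variant in vcf:
        marker = variant.ID or f"{variant.CHROM}:{variant.POS}"
        col = np.full(len(varieties), np.nan)
        for i, gt in enumerate(variant.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            if not alleles:
                continue  # missing
            if any(a not in (0, 1) for a in alleles) or len(set(alleles)) > 1:
                raise ValueError(
                    f"non-binary genotype at {marker} sample {varieties[i]}: "
                    "only homozygous biallelic calls are supported"
                )
            col[i] = float(alleles[0])
        marker_ids.append(marker)
        columns.append(col)
    calls = pd.DataFrame(
        np.column_stack(columns) if columns else np.empty((len(varieties), 0)),
        index=pd.Index(varieties, name="variety"),
        columns=marker_ids,
    )
    meta = pd.read_csv(meta_path, index_col="variety")
    for col in _META_BOOL:
        if col in meta.columns:
            meta[col] = meta[col].astype(bool)
    return GenotypeMatrix(calls=calls, meta=meta)


def read_acreage(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(ACREAGE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"acreage CSV missing columns: {sorted(missing)}")
    return df


def read_weather(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"year", *WEATHER_VARS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"weather CSV missing columns: {sorted(missing)}")
    return df


def read_yields(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"county", "year", "yield_kg_ha"} - set(df.columns)
    if missing:
        raise ValueError(f"yield CSV missing columns: {sorted(missing)}")
    return df


def write_frame(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index)
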