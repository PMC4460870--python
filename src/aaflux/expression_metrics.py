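"""Translation efficiency, ribosome density, and the reliability filters.

Translation efficiency (TE) is protein abundance (ppm) divided by mRNA level
(molecules/cell): the protein yield per mRNA.  Ribosome density (RD) is the
ribosome-footprint RPKM divided by the mRNA-fragment RPKM, each averaged over
replicates: bound ribosomes per mRNA.  The two mRNA denominators come from
different measurements and are never substituted for each other.

Reliability filters (all thresholds strict):

* mRNA-level filter — keep genes with mRNA level > 0.5 molecules/cell;
* RPKM filter — keep genes where, for BOTH the footprint and the
  mRNA-fragment replicate series, the replicate mean is > 1 RPKM and the
  max/min replicate ratio is < 1.5 (single-replicate series pass vacuously).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionRecord",
    "GeneMetrics",
    "translation_efficiency",
    "ribosome_density",
    "filter_mrna_level",
    "filter_rpkm",
    "passes_rpkm_series",
    "compute_metrics",
    "build_gene_table",
]

MRNA_LEVEL_MIN = 0.5  # molecules/cell, strict
RPKM_MEAN_MIN = 1.0  # strict
RPKM_FOLD_MAX = 1.5  # max/min across replicates, strict


@dataclass
class ExpressionRecord:
    gene_id: str
    mrna_level: float | None = None  # molecules/cell
    protein_abundance: float | None = None  # ppm
    footprint_rpkm: list[float] = field(default_factory=list)  # per replicate
    mrna_rpkm: list[float] = field(default_factory=list)  # per replicate


@dataclass(frozen=True)
class GeneMetrics:
    gene_id: str
    te: float | None
    rd: float | None
    passed_te_filter: bool
    passed_rd_filter: bool


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def translation_efficiency(protein_abundance, mrna_level) -> float | None:
    """TE = protein abundance / mRNA level; missing on a zero or absent denominator."""
    if _missing(protein_abundance) or _missing(mrna_level) or mrna_level <= 0:
        return None
    return float(protein_abundance) / float(mrna_level)


def ribosome_density(footprint_rpkm_mean, mrna_rpkm_mean) -> float | None:
    """RD = footprint RPKM / mRNA-fragment RPKM (replicate means)."""
    if _missing(footprint_rpkm_mean) or _missing(mrna_rpkm_mean) or mrna_rpkm_mean <= 0:
        return None
    return float(footprint_rpkm_mean) / float(mrna_rpkm_mean)


def filter_mrna_level(records: list[ExpressionRecord]) -> list[ExpressionRecord]:
    """Keep genes with mRNA level strictly above 0.5 molecules/cell."""
    return [
        r
        for r in records
        if not _missing(r.mrna_level) and r.mrna_level > MRNA_LEVEL_MIN
    ]


def passes_rpkm_series(series: list[float]) -> bool:
    """Replicate-series rule: mean > 1 and max/min fold < 1.5 (strict).

    A single-replicate series has fold ratio 1 by definition; any zero
    replicate alongside a positive one makes the ratio infinite.
    """
    if not series:
        return False
    vals = [float(v) for v in series]
    if any(_missing(v) for v in vals):
        return False
    if np.mean(vals) <= RPKM_MEAN_MIN:
        return False
    lo, hi = min(vals), max(vals)
    if len(vals) == 1:
        return True
    if lo <= 0:
        return False
    return hi / lo < RPKM_FOLD_MAX


def filter_rpkm(records: list[ExpressionRecord]) -> list[ExpressionRecord]:
    """Keep genes whose footprint AND mRNA-fragment series pass the RPKM rule."""
    return [
        r
        for r in records
        if passes_rpkm_series(r.footprint_rpkm) and passes_rpkm_series(r.mrna_rpkm)
    ]


def compute_metrics(records: list[ExpressionRecord]) -> list[GeneMetrics]:
    """TE, RD and filter flags per gene; values are missing, not dropped."""
    kept_te = {r.gene_id for r in filter_mrna_level(records)}
    kept_rd = {r.gene_id for r in filter_rpkm(records)}
    out = []
    for r in records:
        fp_mean = float(np.mean(r.footprint_rpkm)) if r.footprint_rpkm else None
        mr_mean = float(np.mean(r.mrna_rpkm)) if r.mrna_rpkm else None
        out.append(
            GeneMetrics(
                gene_id=r.gene_id,
                te=translation_efficiency(r.protein_abundance, r.mrna_level),
                rd=ribosome_density(fp_mean, mr_mean),
                passed_te_filter=r.gene_id in kept_te,
                passed_rd_filter=r.gene_id in kept_rd,
            )
        )
    return out


def _check_unique(ids: pd.Series, what: str) -> None:
    dup = ids[ids.duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicated id(s) in {what}: {sorted(dup.unique())}")


def build_gene_table(
    supply: pd.DataFrame,
    metrics: pd.DataFrame,
    features: pd.DataFrame | None = None,
    id_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Inner-join supply, expression metrics and sequence features per gene.

    Each input is a DataFrame with a ``gene_id`` column (``protein_id`` is
    accepted for the supply table and renamed).  ``id_map`` translates
    protein ids to gene ids before the join.  Missing covariates stay as NaN;
    an empty id intersection is an error.
    """
    sup = supply.rename(columns={"protein_id": "gene_id"}).copy()
    if id_map is not None:
        sup["gene_id"] = sup["gene_id"].map(lambda g: id_map.get(g, g))
    _check_unique(sup["gene_id"], "supply table")
    _check_unique(metrics["gene_id"], "metrics table")
    table = sup.merge(metrics, on="gene_id", how="inner")
    if features is not None:
        _check_unique(features["gene_id"], "features table")
        table = table.merge(features, on="gene_id", how="left")
    if table.empty:
        raise ValueError("no genes shared between supply and metrics tables")
    return table.reset_index(drop=True)
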