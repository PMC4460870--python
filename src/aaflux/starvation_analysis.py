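"""Ribosome-density change under amino-acid starvation, split by supply.

Genes are split at the median amino-acid supply into WAAS (well supplied,
top 50%) and PAAS (poorly supplied) groups, and the ribosome-density fold
change (starved / normal, a plain ratio) is compared between the groups with
a one-sided Wilcoxon rank-sum test (WAAS < PAAS).  A smaller WAAS fold
change indicates that internal amino-acid supply buffers ribosome stalling
when external amino acids disappear.  A second comparison asks whether genes
whose density rose more than a threshold fold (default 2.0, strict) have
lower mRNA levels than the rest — the transcriptional side of keeping the
free ribosome pool stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .robust_stats import RankSumResult, wilcoxon_ranksum_one_sided

__all__ = [
    "StarvationRecord",
    "GroupComparison",
    "rd_fold_change",
    "split_waas_paas",
    "compare_fold_changes",
    "rd_increased_mrna_comparison",
]

RD_INCREASE_THRESHOLD = 2.0


@dataclass(frozen=True)
class StarvationRecord:
    gene_id: str
    rd_normal: float
    rd_starved: float
    fold_change: float
    supply: float
    mrna_level: float | None = None


@dataclass(frozen=True)
class GroupComparison:
    group_a_label: str
    group_b_label: str
    median_a: float
    median_b: float
    n_a: int
    n_b: int
    p_value: float
    alternative: str
    empty_group: bool = False


def rd_fold_change(rd_starved, rd_normal) -> float | None:
    """Fold change rd_starved / rd_normal (a ratio, not a log)."""
    if rd_normal is None or rd_starved is None:
        return None
    if not rd_normal > 0:
        return None
    return float(rd_starved) / float(rd_normal)


def split_waas_paas(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split genes at the median supply: WAAS = top 50%, PAAS = rest.

    With odd n the WAAS group is the larger; ties at the median go to WAAS
    in stable input order.  ``records`` needs a ``supply`` column.
    """
    supply = records["supply"].to_numpy(dtype=float)
    if np.isnan(supply).any():
        raise ValueError("missing supply values; drop them before splitting")
    n = len(records)
    # stable descending order: ties keep input order
    order = np.argsort(-supply, kind="stable")
    n_waas = (n + 1) // 2
    waas = records.iloc[np.sort(order[:n_waas])].reset_index(drop=True)
    paas = records.iloc[np.sort(order[n_waas:])].reset_index(drop=True)
    return waas, paas


def compare_fold_changes(waas: pd.DataFrame, paas: pd.DataFrame) -> GroupComparison:
    """One-sided rank-sum test of WAAS fold change < PAAS fold change."""
    fc_w = waas["fold_change"].to_numpy(dtype=float)
    fc_p = paas["fold_change"].to_numpy(dtype=float)
    if len(fc_w) == 0 or len(fc_p) == 0:
        raise ValueError("both groups must be non-empty")
    res: RankSumResult = wilcoxon_ranksum_one_sided(fc_w, fc_p, alternative="x_less")
    return GroupComparison(
        group_a_label="WAAS",
        group_b_label="PAAS",
        median_a=res.median_x,
        median_b=res.median_y,
        n_a=res.n_x,
        n_b=res.n_y,
        p_value=res.p_value,
        alternative="WAAS fold change < PAAS fold change",
    )


def rd_increased_mrna_comparison(
    records: pd.DataFrame, fc_threshold: float = RD_INCREASE_THRESHOLD
) -> GroupComparison:
    """mRNA level of RD-increased genes (fold change > threshold, strict) vs the rest.

    One-sided rank-sum with alternative increased < others.  When no gene
    clears the threshold the result is flagged (``empty_group=True``) with a
    p-value of NaN.
    """
    fc = records["fold_change"].to_numpy(dtype=float)
    mrna = records["mrna_level"].to_numpy(dtype=float)
    keep = ~(np.isnan(fc) | np.isnan(mrna))
    fc, mrna = fc[keep], mrna[keep]
    increased = fc > fc_threshold
    if not increased.any() or increased.all():
        return GroupComparison(
            group_a_label="RD-increased",
            group_b_label="others",
            median_a=float(np.median(mrna[increased])) if increased.any() else math.nan,
            median_b=float(np.median(mrna[~increased])) if (~increased).any() else math.nan,
            n_a=int(increased.sum()),
            n_b=int((~increased).sum()),
            p_value=math.nan,
            alternative="RD-increased mRNA < others",
            empty_group=True,
        )
    res = wilcoxon_ranksum_one_sided(mrna[increased], mrna[~increased], alternative="x_less")
    return GroupComparison(
        group_a_label="RD-increased",
        group_b_label="others",
        median_a=res.median_x,
        median_b=res.median_y,
        n_a=res.n_x,
        n_b=res.n_y,
        p_value=res.p_value,
        alternative="RD-increased mRNA < others",
    )
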