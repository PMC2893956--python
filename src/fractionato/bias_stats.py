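"""Fractionation-bias statistics per orthologous region.

Under the null model of unbiased fractionation, any single gene deletion is
equally likely to strike either homeolog, so the split of deletions between
the two homeologs is Binomial(n, 1/2).  The test reported here is the exact
one-sided cumulative probability P(X <= min(a, b)), which reproduces the
published per-region values; a two-sided test would give ~1.0 for a
perfectly balanced region rather than the published 0.58.

Symbol-to-homeolog mapping: code ``1`` means the gene survives only on
homeolog 1 — i.e. a deletion on homeolog 2 — and vice versa.  That mapping
lives in :data:`DELETION_SYMBOL_FOR_HOMEOLOG` and nowhere else.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .region_io import CodeTable, RegionCode

__all__ = [
    "DELETION_SYMBOL_FOR_HOMEOLOG",
    "BiasResult",
    "KsPairSet",
    "binomial_bias_test",
    "region_bias",
    "retention_stats",
    "trim_extreme_ks_ratios",
    "bias_table",
]

logger = logging.getLogger("fractionato")

#: Which code symbol marks a deletion on each homeolog: the gene coded ``2``
#: survives only on homeolog 2, so its homeolog-1 copy was deleted.
DELETION_SYMBOL_FOR_HOMEOLOG = {1: "2", 2: "1"}


class UndefinedTestError(ValueError):
    """Both deletion counts are zero; the binomial test is undefined."""


def binomial_bias_test(n_del_a: int, n_del_b: int) -> float:
    """Exact one-sided binomial probability of a deletion split this biased.

    Returns P(X <= min(a, b)) for X ~ Binomial(a + b, 1/2).  Symmetric in
    its arguments; >= 0.5 whenever the split is balanced.

    >>> round(binomial_bias_test(11, 11), 2)
    0.58
    """
    if n_del_a < 0 or n_del_b < 0:
        raise ValueError("deletion counts must be non-negative")
    n = n_del_a + n_del_b
    if n == 0:
        raise UndefinedTestError("no deletions on either homeolog")
    return float(stats.binom.cdf(min(n_del_a, n_del_b), n, 0.5))


@dataclass(frozen=True)
class BiasResult:
    """Per-region deletion-bias summary (one published-table row)."""

    region_id: str
    deletions_on_homeolog1: int  # symbol-2 genes
    deletions_on_homeolog2: int  # symbol-1 genes
    retained: int
    p_value: Optional[float]
    under_label: str
    over_label: str
    ratio_under_over: Optional[float]
    tie: bool

    @property
    def total_genes(self) -> int:
        return self.retained + self.deletions_on_homeolog1 + self.deletions_on_homeolog2


def region_bias(region: RegionCode) -> BiasResult:
    """Count deletions per homeolog in a reduced region and test for bias.

    The homeolog with fewer deletions is labelled under-fractionated; ties
    are flagged (reported as "o = u") and excluded from aggregate
    under/over ratios by callers.
    """
    if not region.reduced:
        raise ValueError("region_bias requires a reduced region")
    del_h1 = region.count(DELETION_SYMBOL_FOR_HOMEOLOG[1])
    del_h2 = region.count(DELETION_SYMBOL_FOR_HOMEOLOG[2])
    retained = region.count("B")
    lab1, lab2 = region.homeolog_labels
    try:
        p: Optional[float] = binomial_bias_test(del_h1, del_h2)
    except UndefinedTestError:
        p = None
    tie = del_h1 == del_h2
    if del_h1 <= del_h2:
        under_label, over_label = lab1, lab2
        n_under, n_over = del_h1, del_h2
    else:
        under_label, over_label = lab2, lab1
        n_under, n_over = del_h2, del_h1
    ratio = n_under / n_over if n_over > 0 else None
    return BiasResult(
        region_id=region.region_id,
        deletions_on_homeolog1=del_h1,
        deletions_on_homeolog2=del_h2,
        retained=retained,
        p_value=p,
        under_label=under_label,
        over_label=over_label,
        ratio_under_over=ratio,
        tie=tie,
    )


def bias_table(regions: list[RegionCode]) -> pd.DataFrame:
    """One BiasResult row per region, as a DataFrame mirroring the published
    table's p-value / deletion-count / retained / ratio columns."""
    rows = []
    for r in regions:
        b = region_bias(r)
        rows.append(
            {
                "region_id": b.region_id,
                "under": b.under_label if not b.tie else f"{b.under_label} = {b.over_label}",
                "over": b.over_label,
                "p_value": b.p_value,
                "deletions_under": min(b.deletions_on_homeolog1, b.deletions_on_homeolog2),
                "deletions_over": max(b.deletions_on_homeolog1, b.deletions_on_homeolog2),
                "retained": b.retained,
                "total": b.total_genes,
                "ratio_under_over": b.ratio_under_over,
                "tie": b.tie,
            }
        )
    return pd.DataFrame(rows)


def retention_stats(table: CodeTable) -> dict:
    """Genome-wide retention summary over valid shared genes (codes B, 1, 2).

    Returns total shared genes, the count and percentage retained as pairs
    (code B), and a per-region breakdown.
    """
    df = table.rows
    shared = df[df["code"].isin(["B", "1", "2"])]
    if shared.empty:
        raise ValueError("no valid shared genes (codes B/1/2) in table")
    n_shared = len(shared)
    n_b = int((shared["code"] == "B").sum())
    per_region = (
        shared.assign(is_b=shared["code"] == "B")
        .groupby("region_id", sort=False)
        .agg(shared_genes=("code", "size"), retained=("is_b", "sum"))
        .reset_index()
    )
    per_region["pct_retained"] = 100.0 * per_region["retained"] / per_region["shared_genes"]
    return {
        "shared_genes": n_shared,
        "retained_pairs": n_b,
        "pct_retained": 100.0 * n_b / n_shared,
        "per_region": per_region,
    }


@dataclass
class KsPairSet:
    """Per-gene-pair synonymous divergence (Ks) on the two homeologs.

    ``ratio`` is Ks(over-fractionated)/Ks(under-fractionated) per retained
    pair; equal divergence of the two homeologs from the outgroup predicts
    ratios centred on 1.
    """

    rows: pd.DataFrame  # columns: gene_pair_id, ks_under, ks_over

    def __post_init__(self) -> None:
        required = {"gene_pair_id", "ks_under", "ks_over"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ValueError(f"Ks table missing columns: {sorted(missing)}")

    @property
    def ratios(self) -> pd.Series:
        return self.rows["ks_over"] / self.rows["ks_under"]


def trim_extreme_ks_ratios(
    pairs: KsPairSet, fraction: float = 0.16
) -> tuple[KsPairSet, dict]:
    """Drop the most extreme Ks ratios relative to the median.

    Ratios (ks_over/ks_under) are ranked by absolute log-distance from the
    median ratio and the top ``ceil(fraction * n)`` are removed — gross
    outliers typically reflect misalignments or pseudogene alignments.
    Non-positive Ks values are excluded (and counted) before ranking.

    Returns the surviving pairs plus summary statistics (mean/SD/median of
    surviving ratios, and the removal bookkeeping).
    """
    if not (0 <= fraction < 1):
        raise ValueError("fraction must be in [0, 1)")
    df = pairs.rows
    valid = df[(df["ks_under"] > 0) & (df["ks_over"] > 0)].copy()
    n_invalid = len(df) - len(valid)
    if n_invalid:
        logger.info("ks-trim: excluded %d pairs with non-positive Ks", n_invalid)
    if valid.empty:
        raise ValueError("no pairs with positive Ks values")
    ratio = valid["ks_over"] / valid["ks_under"]
    med = float(ratio.median())
    extremeness = (np.log(ratio) - math.log(med)).abs()
    n_remove = math.ceil(fraction * len(valid))
    if n_remove:
        drop_idx = extremeness.nlargest(n_remove).index
        survivors = valid.drop(index=drop_idx)
    else:
        survivors = valid
    surv_ratio = survivors["ks_over"] / survivors["ks_under"]
    summary = {
        "n_input": len(df),
        "n_invalid": n_invalid,
        "n_removed": n_remove,
        "n_surviving": len(survivors),
        "mean_ratio": float(surv_ratio.mean()),
        "sd_ratio": float(surv_ratio.std(ddof=1)) if len(survivors) > 1 else float("nan"),
        "median_ratio": float(surv_ratio.median()),
    }
    return KsPairSet(rows=survivors.reset_index(drop=True)), summary
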