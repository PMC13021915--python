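"""Region-stratified differential composition and functional statistics.

All group tests run on per-sample summaries — one value per biological
replicate (individual), with a sample's ROIs pooled first — never on
per-cell values, which would pseudoreplicate.  The primary test is the
two-sided Wilcoxon rank-sum (exact by enumeration for small tie-free
samples, normal approximation with tie and continuity correction
otherwise); a Welch two-sample t-test is reported alongside for
confirmation, and Benjamini–Hochberg adjustment is applied to the
Wilcoxon p-values within each analysis table.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .celltable import CellTable
from .errors import ValidationError

log = logging.getLogger(__name__)

#: largest combined sample size for which the exact Wilcoxon path is used
EXACT_WILCOXON_MAX_N = 14


class TestResult(NamedTuple):
    statistic: float
    pvalue: float


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact p by enumeration when n+m ≤ 14 with no ties; otherwise the
    normal approximation with tie correction and continuity correction.
    The statistic is W, the rank sum of ``x`` in the pooled sample.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("wilcoxon_rank_sum needs non-empty samples")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= EXACT_WILCOXON_MAX_N and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    w = float(res.statistic) + x.size * (x.size + 1) / 2.0  # U -> rank-sum W
    return TestResult(w, float(res.pvalue))


def t_test_two_sample(x: np.ndarray, y: np.ndarray) -> float:
    """Welch two-sided t-test p-value (confirmatory).

    Degenerate zero-variance-in-both input returns 1 for equal means and
    0 for unequal (the limit of the statistic), with a warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("t_test_two_sample needs at least 2 values per group")
    if np.var(x) == 0.0 and np.var(y) == 0.0:
        log.warning("t-test on zero-variance groups; returning degenerate p")
        return 1.0 if np.mean(x) == np.mean(y) else 0.0
    return float(stats.ttest_ind(x, y, equal_var=False).pvalue)


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    p_adj(i) = min_{j: rank(j) ≥ rank(i)} m·p(j)/rank(j), capped at 1.
    Order-preserving and never below the raw p.
    """
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def stars(p_adj: float) -> str:
    if not np.isfinite(p_adj):
        return "NA"
    if p_adj < 0.001:
        return "***"
    if p_adj < 0.01:
        return "**"
    if p_adj < 0.05:
        return "*"
    return "ns."


# ---------------------------------------------------------------------
# per-sample summaries
# ---------------------------------------------------------------------

def per_sample_proportions(
    cells: CellTable,
    level: str = "level1",
    stratum: str = "all",
) -> pd.DataFrame:
    """Per-sample label proportions, optionally restricted to one region.

    ``stratum`` is 'all', a region name, or 'by-region' (one block per
    region).  ROIs of a sample are pooled before proportioning; the
    denominator is every cell in the stratum, including unclassified.
    Labels absent from a sample get proportion 0; samples with zero
    cells in the stratum are excluded and logged.
    """
    if level not in cells.data.columns:
        raise ValidationError(f"cells carry no {level!r} labels; classify first")
    df = cells.data
    if stratum == "by-region":
        blocks = []
        for region in sorted(df["region"].dropna().unique()):
            if region == "none":
                continue
            blocks.append(per_sample_proportions(cells, level, stratum=region))
        return pd.concat(blocks, ignore_index=True) if blocks else pd.DataFrame()
    if stratum != "all":
        if "region" not in df.columns:
            raise ValidationError("region-stratified proportions need region assignment")
        df = df[df["region"] == stratum]
    df = df[df[level].notna()]
    labels = sorted(df[level].unique())
    rows = []
    for sample_id, sub in df.groupby("sample_id", observed=True):
        total = len(sub)
        if total == 0:  # pragma: no cover - groupby yields non-empty groups
            continue
        counts = sub[level].value_counts()
        for lab in labels:
            rows.append(
                {
                    "sample_id": sample_id,
                    "group": sub["group"].iloc[0],
                    "stratum": stratum,
                    "label": lab,
                    "proportion": counts.get(lab, 0) / total,
                    "n_cells": total,
                }
            )
    excluded = set(cells.data["sample_id"].unique()) - {r["sample_id"] for r in rows}
    if excluded:
        log.info("per_sample_proportions: samples with no cells in %s: %s", stratum, sorted(excluded))
    return pd.DataFrame(rows)


def positive_fraction(
    cells: CellTable,
    positivity: pd.DataFrame,
    marker: str,
    stratum: str = "all",
    cell_type: str | None = None,
    level: str = "level1",
) -> pd.DataFrame:
    """Per-sample fraction of marker-positive cells in a stratum/type."""
    if marker not in positivity.columns:
        raise ValidationError(f"no positivity calls for marker {marker!r}")
    df = cells.data.copy()
    df["_pos"] = positivity[marker].to_numpy()
    if stratum != "all":
        df = df[df["region"] == stratum]
    if cell_type is not None:
        df = df[df[level] == cell_type]
    rows = []
    for sample_id, sub in df.groupby("sample_id", observed=True):
        rows.append(
            {
                "sample_id": sample_id,
                "group": sub["group"].iloc[0],
                "stratum": stratum,
                "label": marker if cell_type is None else f"{marker}|{cell_type}",
                "proportion": float(sub["_pos"].mean()),
                "n_cells": len(sub),
            }
        )
    empty = set(cells.data["sample_id"].unique()) - {r["sample_id"] for r in rows}
    if empty:
        log.info("positive_fraction: empty denominator for samples %s", sorted(empty))
    return pd.DataFrame(rows)


def differential_table(
    summaries: pd.DataFrame,
    group_a: str = "Control",
    group_b: str = "ONJ",
    value: str = "proportion",
    min_samples: int = 3,
) -> pd.DataFrame:
    """Group comparison per (stratum, label) on per-sample values.

    One row per (stratum, label) with group medians and IQRs, Wilcoxon
    and Welch p-values, BH-adjusted Wilcoxon p (family = all rows of this
    table with a computable p), and significance stars.
    """
    rows = []
    for (stratum, label), sub in summaries.groupby(["stratum", "label"], observed=True):
        va = sub.loc[sub["group"] == group_a, value].to_numpy(float)
        vb = sub.loc[sub["group"] == group_b, value].to_numpy(float)
        row = {
            "stratum": stratum,
            "label": label,
            f"median_{group_a}": float(np.median(va)) if va.size else np.nan,
            f"median_{group_b}": float(np.median(vb)) if vb.size else np.nan,
            f"iqr_{group_a}": float(np.subtract(*np.percentile(va, [75, 25]))) if va.size else np.nan,
            f"iqr_{group_b}": float(np.subtract(*np.percentile(vb, [75, 25]))) if vb.size else np.nan,
            "n_" + group_a: va.size,
            "n_" + group_b: vb.size,
        }
        if va.size >= min_samples and vb.size >= min_samples:
            row["p_wilcoxon"] = wilcoxon_rank_sum(va, vb).pvalue
            row["p_ttest"] = t_test_two_sample(va, vb) if min(va.size, vb.size) >= 2 else np.nan
        else:
            row["p_wilcoxon"] = np.nan
            row["p_ttest"] = np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["p_adj"] = np.nan
    ok = out["p_wilcoxon"].notna()
    if ok.any():
        out.loc[ok, "p_adj"] = bh_adjust(out.loc[ok, "p_wilcoxon"].to_numpy())
    out["stars"] = [stars(p) for p in out["p_adj"]]
    return out
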