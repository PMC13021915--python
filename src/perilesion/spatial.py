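"""Cross-type spatial attraction/avoidance statistics.

For two cell types a and b in a rectangular ROI window W, the empirical
cross-type Ripley K at radius r is

    K̂_ab(r) = |W| / (n_a n_b) · Σ_i Σ_j e_ij · 1[d_ij ≤ r]

summing over ordered pairs (i in a, j in b); for a = b self-pairs are
excluded and the denominator is n(n−1).  The translation edge correction
weights each pair by e_ij = |W| / ((w − |Δx|)(h − |Δy|)); with no
correction e_ij = 1.  The variance-stabilised interaction score is

    u = L̂_ab(r) − r = sqrt(K̂_ab(r)/π) − r,

zero in expectation under complete spatial randomness, positive for
attraction and negative for avoidance.  Pairs with fewer than
``min_count`` cells of either type in an ROI are marked invalid rather
than scored — sparse types produce wildly unstable L estimates.

ROI scores are pooled to one value per biological sample (weighted by
n_a·n_b), and groups are contrasted per (pair, radius) with a two-sided
Wilcoxon rank-sum test on the per-sample scores, BH-adjusted across all
pairs within each radius.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .celltable import CellTable
from .diffstats import bh_adjust, wilcoxon_rank_sum
from .errors import ParameterError

log = logging.getLogger(__name__)

DEFAULT_RADII = (50.0, 100.0)
DEFAULT_MIN_COUNT = 10


@dataclass(frozen=True)
class InteractionScore:
    roi_id: str
    type_a: str
    type_b: str
    radius: float
    n_a: int
    n_b: int
    u: float            # L̂_ab(r) − r; NaN when invalid
    valid: bool


def cross_k(
    points_a: np.ndarray,
    points_b: np.ndarray,
    window: tuple[float, float],
    r: float,
    correction: str = "translation",
    same: bool | None = None,
) -> float:
    """Cross-type Ripley K̂_ab(r) on a rectangular window (μm²).

    ``window`` is (width, height) with the origin at (0, 0).  ``same``
    marks a self-pair analysis (self-pairs excluded, denominator
    n(n−1)); by default it is inferred from array identity/equality.
    """
    if r <= 0:
        raise ParameterError(f"radius must be positive, got {r}")
    w, h = float(window[0]), float(window[1])
    if w <= 0 or h <= 0:
        raise ParameterError(f"window must have positive area, got {window}")
    if r > min(w, h) / 2:
        log.warning(
            "radius %.1f exceeds half the window size; edge correction unreliable", r
        )
    if correction not in ("none", "translation"):
        raise ParameterError(f"unknown edge correction {correction!r}")
    pa = np.atleast_2d(np.asarray(points_a, float))
    pb = np.atleast_2d(np.asarray(points_b, float))
    if same is None:
        same = pa is pb or (pa.shape == pb.shape and np.array_equal(pa, pb))
    n_a, n_b = len(pa), len(pb)
    if n_a < 1 or n_b < 1 or (same and n_a < 2):
        raise ParameterError("need at least one point of each type (two for same-type)")

    tree_a = cKDTree(pa)
    tree_b = cKDTree(pb)
    pairs = tree_a.query_ball_tree(tree_b, r)
    total = 0.0
    area = w * h
    for i, neigh in enumerate(pairs):
        if not neigh:
            continue
        jj = np.asarray(neigh)
        if same:
            jj = jj[jj != i]
            if jj.size == 0:
                continue
        if correction == "translation":
            dx = np.abs(pa[i, 0] - pb[jj, 0])
            dy = np.abs(pa[i, 1] - pb[jj, 1])
            total += float(np.sum(area / ((w - dx) * (h - dy))))
        else:
            total += float(jj.size)
    denom = n_a * (n_a - 1) if same else n_a * n_b
    return area * total / denom


def interaction_score(
    points_a: np.ndarray,
    points_b: np.ndarray,
    window: tuple[float, float],
    r: float,
    min_count: int = DEFAULT_MIN_COUNT,
    correction: str = "translation",
    roi_id: str = "",
    type_a: str = "a",
    type_b: str = "b",
    same: bool | None = None,
) -> InteractionScore:
    """L̂_ab(r) − r, or an invalid record when either type is too sparse."""
    pa = np.atleast_2d(np.asarray(points_a, float)) if len(points_a) else np.empty((0, 2))
    pb = np.atleast_2d(np.asarray(points_b, float)) if len(points_b) else np.empty((0, 2))
    n_a, n_b = len(pa), len(pb)
    if same is None:
        same = type_a == type_b
    if n_a < min_count or n_b < min_count:
        return InteractionScore(roi_id, type_a, type_b, r, n_a, n_b, float("nan"), False)
    k = cross_k(pa, pb, window, r, correction=correction, same=same)
    u = float(np.sqrt(k / np.pi) - r)
    return InteractionScore(roi_id, type_a, type_b, r, n_a, n_b, u, True)


def roi_interaction_scores(
    cells: CellTable,
    level: str = "level1",
    radii: tuple[float, ...] = DEFAULT_RADII,
    windows: dict[tuple[str, str], tuple[float, float]] | None = None,
    default_window: tuple[float, float] | None = None,
    min_count: int = DEFAULT_MIN_COUNT,
    types: list[str] | None = None,
    types_b: list[str] | None = None,
    level_b: str | None = None,
    exclude: tuple[str, ...] = ("unclassified",),
) -> pd.DataFrame:
    """Per-ROI interaction scores for every type pair at every radius.

    ``windows`` maps (sample_id, roi_id) to the ROI's (width, height) in
    μm; ``default_window`` is used for ROIs not listed (and must be given
    when ``windows`` is None).  ``level_b``/``types_b`` allow asymmetric
    analyses such as immune subtypes versus basic types.
    """
    if default_window is None and windows is None:
        raise ParameterError("need ROI windows or a default window")
    df = cells.data
    level_b = level_b or level
    rows = []
    for (sample_id, roi_id), roi in df.groupby(["sample_id", "roi_id"], observed=True):
        win = (windows or {}).get((sample_id, roi_id), default_window)
        if win is None:
            raise ParameterError(f"no window for ROI ({sample_id}, {roi_id})")
        la = roi[level].dropna()
        lb = roi[level_b].dropna()
        ta = types or sorted(x for x in la.unique() if x not in exclude)
        tb = types_b or (ta if level_b == level else sorted(x for x in lb.unique() if x not in exclude))
        for a in ta:
            for b in tb:
                if level_b == level and b < a:
                    continue  # symmetric estimator: keep one orientation
                pa = roi.loc[roi[level] == a, ["x", "y"]].to_numpy(float)
                pb = roi.loc[roi[level_b] == b, ["x", "y"]].to_numpy(float)
                for r in radii:
                    s = interaction_score(
                        pa, pb, win, r,
                        min_count=min_count,
                        roi_id=str(roi_id),
                        type_a=str(a), type_b=str(b),
                        same=(level_b == level and a == b),
                    )
                    rows.append(
                        {
                            "sample_id": sample_id,
                            "roi_id": roi_id,
                            "group": roi["group"].iloc[0],
                            "type_a": a,
                            "type_b": b,
                            "radius": r,
                            "n_a": s.n_a,
                            "n_b": s.n_b,
                            "u": s.u,
                            "valid": s.valid,
                        }
                    )
    return pd.DataFrame(rows)


def aggregate_to_sample(scores: pd.DataFrame) -> pd.DataFrame:
    """Pool ROI scores to one value per (sample, pair, radius).

    Weighted mean of valid ROI scores with weights n_a·n_b (ROIs with
    more cells of both types estimate L more precisely).  Samples with
    no valid ROI for a pair are dropped and logged.
    """
    valid = scores[scores["valid"]].copy()
    dropped = (
        scores.groupby(["sample_id", "type_a", "type_b", "radius"], observed=True)["valid"]
        .any()
    )
    n_dropped = int((~dropped).sum())
    if n_dropped:
        log.info("aggregate_to_sample: %d sample-pair-radius cells had no valid ROI", n_dropped)
    if valid.empty:
        return pd.DataFrame(
            columns=["sample_id", "group", "type_a", "type_b", "radius", "u", "weight"]
        )
    valid["weight"] = valid["n_a"] * valid["n_b"]
    valid["wu"] = valid["weight"] * valid["u"]
    agg = (
        valid.groupby(["sample_id", "group", "type_a", "type_b", "radius"], observed=True)[
            ["wu", "weight"]
        ]
        .sum()
        .reset_index()
    )
    agg["u"] = agg["wu"] / agg["weight"]
    return agg.drop(columns="wu")


def contrast_groups(
    sample_u: pd.DataFrame,
    group_a: str = "Control",
    group_b: str = "ONJ",
    min_samples: int = 3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Group contrast per (pair, radius) on per-sample interaction scores.

    Two-sided Wilcoxon rank-sum; BH adjustment across all pairs within
    each radius (radii are reported separately, so they form separate
    families).  Pairs with fewer than ``min_samples`` per group get
    p = NA and are excluded from the BH family.
    """
    rows = []
    for (a, b, r), sub in sample_u.groupby(["type_a", "type_b", "radius"], observed=True):
        ua = sub.loc[sub["group"] == group_a, "u"].to_numpy(float)
        ub = sub.loc[sub["group"] == group_b, "u"].to_numpy(float)
        row = {
            "type_a": a,
            "type_b": b,
            "radius": r,
            f"mean_u_{group_a}": float(np.mean(ua)) if ua.size else np.nan,
            f"mean_u_{group_b}": float(np.mean(ub)) if ub.size else np.nan,
            "n_" + group_a: ua.size,
            "n_" + group_b: ub.size,
        }
        row["diff"] = row[f"mean_u_{group_b}"] - row[f"mean_u_{group_a}"]
        if ua.size >= min_samples and ub.size >= min_samples:
            _, row["p"] = wilcoxon_rank_sum(ua, ub)
        else:
            row["p"] = np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        out["p_adj"] = []
        out["significant"] = []
        return out
    out["p_adj"] = np.nan
    for r, idx in out.groupby("radius").groups.items():
        sub = out.loc[idx, "p"]
        ok = sub.notna()
        if ok.any():
            out.loc[sub.index[ok], "p_adj"] = bh_adjust(sub[ok].to_numpy())
    out["significant"] = out["p_adj"] < alpha
    return out
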