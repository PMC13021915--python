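"""Wilcoxon, Welch, BH, per-sample summaries and differential tables."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perilesion.celltable import CellTable
from perilesion.diffstats import (
    bh_adjust,
    differential_table,
    per_sample_proportions,
    positive_fraction,
    stars,
    t_test_two_sample,
    wilcoxon_rank_sum,
)
from perilesion.errors import ValidationError

from conftest import make_tiny_table


def exact_wilcoxon_oracle(x, y):
    """Two-sided exact p by full enumeration of rank assignments.

    p = P(|W - E[W]| >= |W_obs - E[W]|) over all C(n+m, n) splits of the
    pooled tie-free sample.
    """
    pooled = np.sort(np.concatenate([x, y]))
    n, m = len(x), len(y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in x)
    center = n * (n + m + 1) / 2
    count = 0
    total = comb(n + m, n)
    for subset in combinations(range(1, n + m + 1), n):
        if abs(sum(subset) - center) >= abs(w_obs - center) - 1e-12:
            count += 1
    return count / total


class TestWilcoxon:
    def test_worked_example_one_tenth(self):
        w, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert w == 6.0  # ranks 1+2+3
        assert p == pytest.approx(2 / 20, rel=1e-12)

    def test_identical_sets_with_ties_approximation_path(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        _, p = wilcoxon_rank_sum(x, x)
        assert p == pytest.approx(1.0)

    def test_exact_path_matches_enumeration_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            n = int(rng.integers(2, 8))
            m = int(rng.integers(2, 8))
            if n + m > 14:
                continue
            pooled = rng.permutation(np.arange(1.0, n + m + 1))  # tie-free
            x, y = pooled[:n], pooled[n:]
            _, p = wilcoxon_rank_sum(x, y)
            assert p == pytest.approx(exact_wilcoxon_oracle(x, y), rel=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_rank_sum([], [1.0])


class TestTTest:
    def test_identical_groups_p_one(self):
        x = [1.0, 2.0, 3.0]
        assert t_test_two_sample(x, x) == pytest.approx(1.0)

    def test_statistic_matches_welch_closed_form(self):
        from scipy import stats

        x = np.array([1.2, 2.3, 3.1, 4.8, 2.2])
        y = np.array([2.9, 3.8, 4.4, 5.1])
        # closed-form Welch t and df
        t = (x.mean() - y.mean()) / np.sqrt(x.var(ddof=1) / len(x) + y.var(ddof=1) / len(y))
        num = (x.var(ddof=1) / len(x) + y.var(ddof=1) / len(y)) ** 2
        den = (x.var(ddof=1) / len(x)) ** 2 / (len(x) - 1) + (
            y.var(ddof=1) / len(y)
        ) ** 2 / (len(y) - 1)
        df = num / den
        p_closed = 2 * stats.t.sf(abs(t), df)
        assert t_test_two_sample(x, y) == pytest.approx(p_closed, rel=1e-12)

    def test_zero_variance_degenerate(self):
        assert t_test_two_sample([1.0, 1.0], [1.0, 1.0]) == 1.0
        assert t_test_two_sample([1.0, 1.0], [2.0, 2.0]) == 0.0

    def test_p_decreases_with_planted_shift(self):
        rng = np.random.default_rng(4)
        base = rng.normal(0, 1, 30)
        ps = []
        for shift in (0.0, 0.5, 1.0, 2.0):
            ps.append(t_test_two_sample(base, base + shift + rng.normal(0, 0.01, 30)))
        assert ps[0] > ps[1] > ps[2] > ps[3]


class TestBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_hand_applied_step_up(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=150, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_monotone_order_invariant_idempotent(self, pvals):
        p = np.asarray(pvals)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)
        # order invariance up to permutation
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(bh_adjust(p[perm]), adj[perm], atol=1e-12)


class TestPerSampleSummaries:
    def _labeled_table(self, panel, rows):
        t = make_tiny_table(panel, n=len(rows), seed=0)
        t.data["sample_id"] = [r[0] for r in rows]
        t.data["group"] = [r[1] for r in rows]
        t.data["level1"] = [r[2] for r in rows]
        t.data["region"] = [r[3] for r in rows]
        return t

    def test_worked_proportion(self, panel):
        rows = [("s1", "Control", "epithelial", "stroma")] * 50 + [
            ("s1", "Control", "fibroblast", "stroma")
        ] * 150
        out = per_sample_proportions(self._labeled_table(panel, rows))
        epi = out.loc[out["label"] == "epithelial", "proportion"].iloc[0]
        assert epi == pytest.approx(0.25)

    def test_proportions_sum_to_one_per_sample(self, panel):
        rng = np.random.default_rng(6)
        rows = [
            (f"s{rng.integers(3)}", "Control", rng.choice(["a_t", "b_t", "unclassified"]), "stroma")
            for _ in range(200)
        ]
        rows = [(s, g, l, r) for (s, g, l, r) in rows]
        t = make_tiny_table(panel, n=len(rows), seed=1)
        t.data["sample_id"] = [r[0] for r in rows]
        t.data["level1"] = [r[2] for r in rows]
        t.data["region"] = "stroma"
        out = per_sample_proportions(t)
        sums = out.groupby("sample_id")["proportion"].sum()
        np.testing.assert_allclose(sums, 1.0)

    def test_matches_groupby_oracle(self, panel):
        rng = np.random.default_rng(8)
        n = 400
        t = make_tiny_table(panel, n=n, seed=2)
        t.data["sample_id"] = rng.choice(["s1", "s2"], n)
        t.data["level1"] = rng.choice(["x_t", "y_t"], n)
        t.data["region"] = "stroma"
        out = per_sample_proportions(t)
        df = t.data
        for _, row in out.iterrows():
            sub = df[df["sample_id"] == row["sample_id"]]
            expected = (sub["level1"] == row["label"]).mean()
            assert row["proportion"] == pytest.approx(expected)

    def test_positive_fraction_extremes_and_oracle(self, panel):
        n = 60
        t = make_tiny_table(panel, n=n, seed=3)
        t.data["region"] = "stroma"
        pos = pd.DataFrame({"Ki67": [True] * n})
        out = positive_fraction(t, pos, "Ki67")
        assert out["proportion"].iloc[0] == 1.0
        pos = pd.DataFrame({"Ki67": [False] * n})
        assert positive_fraction(t, pos, "Ki67")["proportion"].iloc[0] == 0.0
        rng = np.random.default_rng(0)
        flags = rng.uniform(size=n) < 0.3
        pos = pd.DataFrame({"Ki67": flags})
        assert positive_fraction(t, pos, "Ki67")["proportion"].iloc[0] == pytest.approx(
            flags.mean()
        )


class TestDifferentialTable:
    def _summaries(self, control_vals, onj_vals, label="epithelial"):
        rows = []
        for i, v in enumerate(control_vals):
            rows.append({"sample_id": f"C{i}", "group": "Control", "stratum": "all",
                         "label": label, "proportion": v})
        for i, v in enumerate(onj_vals):
            rows.append({"sample_id": f"P{i}", "group": "ONJ", "stratum": "all",
                         "label": label, "proportion": v})
        return pd.DataFrame(rows)

    def test_stars_consistent_with_padj(self):
        df = self._summaries(np.arange(8) * 0.01, 0.5 + np.arange(6) * 0.01)
        out = differential_table(df)
        p_adj = out["p_adj"].iloc[0]
        assert out["stars"].iloc[0] == stars(p_adj)
        assert p_adj < 0.01

    def test_too_few_samples_gives_na(self):
        df = self._summaries([0.1, 0.2], [0.3, 0.4, 0.5])
        out = differential_table(df)
        assert np.isnan(out["p_wilcoxon"].iloc[0])
        assert out["stars"].iloc[0] == "NA"

    def test_medians_and_iqr_reported(self):
        c = [0.1, 0.2, 0.3, 0.4]
        o = [0.5, 0.6, 0.7]
        out = differential_table(self._summaries(c, o))
        assert out["median_Control"].iloc[0] == pytest.approx(np.median(c))
        assert out["iqr_ONJ"].iloc[0] == pytest.approx(
            np.percentile(o, 75) - np.percentile(o, 25)
        )


class TestPlantedShiftPower:
    def test_planted_treg_shift_detected_across_seeds(self):
        """2% vs 6% Treg proportion, 8 vs 6 individuals: detected with the
        correct sign in most cohorts (CSR placement; per-sample values)."""
        from perilesion.synthetic import CohortDesign, PlantedEffects, generate_cohort

        design = CohortDesign(
            width_um=400, height_um=400, pixel_size=2.0, band_depth_um=120,
            n_vessels=1, vessel_radius_um=25, total_density=2.5e-3,
            rois_min=2, rois_max=2,
        )
        effects = PlantedEffects(spatial_modes=())
        detected = 0
        n_seeds = 15
        for seed in range(n_seeds):
            cells, _, _ = generate_cohort(design, effects, seed=900 + seed,
                                          draw_markers=False)
            rows = []
            for sample_id, sub in cells.groupby("sample_id"):
                rows.append({
                    "sample_id": sample_id, "group": sub["group"].iloc[0],
                    "stratum": "all", "label": "Treg",
                    "proportion": float((sub["true_type"] == "Treg").mean()),
                })
            out = differential_table(pd.DataFrame(rows))
            if (out["p_adj"].iloc[0] < 0.05
                    and out["median_ONJ"].iloc[0] > out["median_Control"].iloc[0]):
                detected += 1
        assert detected / n_seeds >= 0.8
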