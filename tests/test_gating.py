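"""Thresholding and four-level classification."""

import numpy as np
import pandas as pd
import pytest

from perilesion.celltable import CellTable
from perilesion.errors import ConfigurationError, ValidationError
from perilesion.gating import (
    GatingConfig,
    GatingRule,
    call_positivity,
    classify_level1,
    classify_level2,
    classify_level3,
    classify_level4,
    classify_table,
    default_gating_config,
    dominant_state,
    estimate_thresholds,
    level4_to_string,
)
from perilesion.preprocess import preprocess_table
from perilesion.synthetic import CohortDesign, generate_cohort

from conftest import make_tiny_table


def positivity_frame(panel, rows: list[set]) -> pd.DataFrame:
    markers = panel.lineage + panel.functional
    return pd.DataFrame(
        [{m: (m in row) for m in markers} for row in rows]
    )


@pytest.fixture(scope="module")
def config(panel):
    return default_gating_config(panel)


class TestThresholds:
    def _table_from_values(self, panel, values):
        t = make_tiny_table(panel, n=len(values), seed=0)
        for m in panel.names:
            t.data[m] = values
        t.data["nuc_YAP1"] = values
        return CellTable(t.data, panel, "arcsinh")

    def test_recovers_planted_mixture_boundary(self, panel):
        rng = np.random.default_rng(0)
        values = np.concatenate(
            [rng.normal(0.3, 0.2, 3500), rng.normal(2.5, 0.2, 1500)]
        )
        rng.shuffle(values)
        t = self._table_from_values(panel, values)
        thr = estimate_thresholds(t, markers=[panel.names[0]])
        assert 1.0 <= thr[panel.names[0]] <= 1.8

    def test_fixed_override_returned_verbatim(self, panel):
        t = self._table_from_values(panel, np.random.default_rng(1).normal(1, 0.3, 500))
        thr = estimate_thresholds(
            t, overrides={panel.names[0]: 1.5}, markers=[panel.names[0]]
        )
        assert thr[panel.names[0]] == 1.5
        assert thr.method[panel.names[0]] == "fixed"

    def test_unimodal_input_triggers_documented_fallback(self, panel):
        rng = np.random.default_rng(2)
        values = rng.normal(1.0, 0.02, 1000)  # means collapse within 0.1
        t = self._table_from_values(panel, values)
        thr = estimate_thresholds(t, markers=[panel.names[0]])
        assert panel.names[0] in thr.flagged
        lo, hi = np.percentile(values, [10, 90])
        assert thr[panel.names[0]] == pytest.approx((lo + hi) / 2)

    def test_too_few_cells_rejected(self, panel):
        t = self._table_from_values(panel, np.ones(50))
        with pytest.raises(ValidationError, match="200"):
            estimate_thresholds(t, markers=[panel.names[0]])


class TestPositivity:
    def test_strictly_greater_than_threshold(self, panel):
        t = make_tiny_table(panel, n=3, seed=0)
        m = panel.names[0]
        t.data[m] = [1.0, 2.0, 3.0]
        table = CellTable(t.data, panel, "arcsinh")
        from perilesion.gating import PositivityThresholds

        pos = call_positivity(table, PositivityThresholds({m: 2.0}))
        assert pos[m].tolist() == [False, False, True]

    def test_all_zero_cell_all_negative(self, panel):
        t = make_tiny_table(panel, n=1, seed=0)
        for m in panel.names:
            t.data[m] = 0.0
        t.data["nuc_YAP1"] = 0.0
        table = CellTable(t.data, panel, "arcsinh")
        thr = {m: 0.5 for m in panel.lineage + panel.functional}
        from perilesion.gating import PositivityThresholds

        pos = call_positivity(table, PositivityThresholds(thr))
        assert not pos.to_numpy().any()

    def test_matrix_equals_elementwise_oracle(self, panel):
        rng = np.random.default_rng(7)
        t = make_tiny_table(panel, n=200, seed=7)
        table = CellTable(t.data, panel, "arcsinh")
        thr = {m: float(rng.uniform(0.5, 2)) for m in panel.lineage + panel.functional}
        from perilesion.gating import PositivityThresholds

        pos = call_positivity(table, PositivityThresholds(thr))
        for m in list(thr)[:6]:
            expected = table.intensity_for(m).to_numpy() > thr[m]
            np.testing.assert_array_equal(pos[m].to_numpy(), expected)


class TestLevel1:
    def test_ecad_egfr_is_epithelial(self, panel, config):
        pos = positivity_frame(panel, [{"Ecad", "EGFR"}])
        assert classify_level1(pos, config)[0] == "epithelial"

    def test_podoplanin_only_is_endothelial(self, panel, config):
        pos = positivity_frame(panel, [{"Podoplanin"}])
        assert classify_level1(pos, config)[0] == "endothelial"

    def test_all_negative_is_unclassified(self, panel, config):
        pos = positivity_frame(panel, [set()])
        assert classify_level1(pos, config)[0] == "unclassified"

    def test_priority_immune_over_epithelial(self, panel, config):
        pos = positivity_frame(panel, [{"Ecad", "EGFR", "CD4"}])
        assert classify_level1(pos, config)[0] == "immune"

    def test_functional_only_cell(self, panel, config):
        pos = positivity_frame(panel, [{"Ki67"}])
        assert classify_level1(pos, config)[0] == "functional"

    def test_empty_rule_set_rejected(self, panel):
        cfg = GatingConfig(rules=[], level3_markers={}, level4_markers={})
        with pytest.raises(ConfigurationError):
            classify_level1(positivity_frame(panel, [set()]), cfg)

    def test_partition_exactly_one_label(self, panel, config):
        rng = np.random.default_rng(0)
        markers = panel.lineage + panel.functional
        pos = pd.DataFrame(rng.uniform(size=(500, len(markers))) < 0.15, columns=markers)
        labels = classify_level1(pos, config)
        assert len(labels) == 500
        assert all(isinstance(l, str) and l for l in labels)

    def test_permutation_invariance(self, panel, config):
        rng = np.random.default_rng(1)
        markers = panel.lineage + panel.functional
        pos = pd.DataFrame(rng.uniform(size=(100, len(markers))) < 0.2, columns=markers)
        labels = classify_level1(pos, config)
        perm = rng.permutation(100)
        labels_perm = classify_level1(pos.iloc[perm].reset_index(drop=True), config)
        np.testing.assert_array_equal(labels_perm, labels[perm])


class TestLevel2:
    def test_cd68_cd163_is_m2(self, panel, config):
        pos = positivity_frame(panel, [{"CD68", "CD163"}])
        l1 = classify_level1(pos, config)
        assert classify_level2(pos, l1, config)[0] == "M2"

    def test_foxp3_cd4_is_treg(self, panel, config):
        pos = positivity_frame(panel, [{"CD4", "FoxP3"}])
        l1 = classify_level1(pos, config)
        assert classify_level2(pos, l1, config)[0] == "Treg"

    def test_non_immune_gets_no_label(self, panel, config):
        pos = positivity_frame(panel, [{"Ecad", "EGFR"}])
        l1 = classify_level1(pos, config)
        assert classify_level2(pos, l1, config)[0] is None

    def test_unmatched_immune_is_other(self, panel, config):
        pos = positivity_frame(panel, [{"FoxP3"}])  # immune any-list, no subtype rule
        l1 = classify_level1(pos, config)
        assert l1[0] == "immune"
        assert classify_level2(pos, l1, config)[0] == "immune-other"


class TestLevel3:
    def test_immune_with_ecad_infiltrates_epithelium(self, panel, config):
        pos = positivity_frame(panel, [{"CD4", "Ecad"}])
        l1 = classify_level1(pos, config)
        assert classify_level3(pos, l1, config)[0] == "immune-in-epithelial"

    def test_plain_immune_without_coexpression(self, panel, config):
        pos = positivity_frame(panel, [{"CD4"}])
        l1 = classify_level1(pos, config)
        assert classify_level3(pos, l1, config)[0] == "immune"

    def test_precedence_epithelial_over_endothelial(self, panel, config):
        pos = positivity_frame(panel, [{"CD4", "Ecad", "CD31"}])
        l1 = classify_level1(pos, config)
        assert classify_level3(pos, l1, config)[0] == "immune-in-epithelial"

    def test_counts_match_boolean_conjunction_oracle(self, panel, config):
        rng = np.random.default_rng(9)
        markers = panel.lineage + panel.functional
        pos = pd.DataFrame(rng.uniform(size=(400, len(markers))) < 0.12, columns=markers)
        l1 = classify_level1(pos, config)
        l3 = classify_level3(pos, l1, config)
        immune = l1 == "immune"
        epi = pos[["Ecad", "EGFR", "PanCK"]].to_numpy().any(axis=1)
        expected = int((immune & epi).sum())
        assert (pd.Series(l3) == "immune-in-epithelial").sum() == expected


class TestLevel4:
    def test_ki67_only_is_proliferation(self, panel, config):
        pos = positivity_frame(panel, [{"Ki67"}])
        assert classify_level4(pos, config)[0] == frozenset({"proliferation"})

    def test_bnip3_caveolin_multi_flag(self, panel, config):
        pos = positivity_frame(panel, [{"BNIP3", "Caveolin"}])
        assert classify_level4(pos, config)[0] == frozenset({"apoptosis", "autophagy"})

    def test_all_negative_is_non_functional(self, panel, config):
        pos = positivity_frame(panel, [set()])
        flags = classify_level4(pos, config)[0]
        assert level4_to_string(flags) == "non-functional"

    def test_dominant_state_fixed_order(self):
        assert dominant_state(frozenset({"autophagy", "proliferation"})) == "proliferation"
        assert dominant_state(frozenset()) == "non-functional"


class TestRecovery:
    def test_noise_free_levels_1_and_2_perfect(self):
        design = CohortDesign(
            width_um=400, height_um=400, pixel_size=2.0, band_depth_um=120,
            n_vessels=1, vessel_radius_um=30, total_density=2e-3,
            rois_min=1, rois_max=2, noise_free=True,
        )
        cells, _, truth = generate_cohort(design, seed=11)
        table = preprocess_table(cells)
        labeled, _ = classify_table(table)
        m = labeled.data.merge(truth.labels, on="cell_id")
        assert (m["level1"] == m["true_level1"]).all()
        imm = m[m["true_level1"] == "immune"]
        assert (imm["level2"] == imm["true_level2"]).all()

    def test_noisy_accuracy_and_unclassified_recovery(self, small_cohort_arcsinh):
        table, _, truth = small_cohort_arcsinh
        labeled, _ = classify_table(table)
        m = labeled.data.merge(truth.labels, on="cell_id")
        assert (m["level1"] == m["true_level1"]).mean() >= 0.95
        imm = m[m["true_level1"] == "immune"]
        assert (imm["level2"] == imm["true_level2"]).mean() >= 0.95
        planted = (truth.labels["true_type"] == "unclassified").mean()
        recovered = (labeled.data["level1"] == "unclassified").mean()
        assert abs(recovered - planted) <= 0.02
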