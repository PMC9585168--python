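"""AHFI scoring: normalization, recovery scores, classification, statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zfcardio import (AHFI_COMPONENTS, AHFIResult, AhfiThresholds,
                      ConfigurationError, compare_groups, compute_ahfi,
                      normalize_to_control, rank_treatments, recovery_score,
                      score_cohort, summarize_groups)
from zfcardio.indicators import INDICATOR_FIELDS


def _table(groups: dict[str, dict[str, list[float]]]) -> pd.DataFrame:
    """Build a per-fish indicator table; unspecified fields default to 1."""
    rows = []
    for group, fields in groups.items():
        n = len(next(iter(fields.values())))
        for i in range(n):
            row = {"fish_id": f"{group}_{i}", "group": group}
            for f in INDICATOR_FIELDS:
                row[f] = fields.get(f, [1.0] * n)[i]
            rows.append(row)
    return pd.DataFrame(rows)


def _panel(b_by_group: dict[str, float]) -> pd.DataFrame:
    """Normalized panel with the same B on all four components per group."""
    return pd.DataFrame({c: b_by_group for c in AHFI_COMPONENTS})


class TestSummarizeGroups:
    def test_mean_and_sample_sd(self):
        table = _table({"control": {"hr_bpm": [100.0, 120.0]},
                        "model": {"hr_bpm": [50.0, 60.0]}})
        out = summarize_groups(table)
        assert out.loc["control", "hr_bpm_mean"] == pytest.approx(110.0)
        assert out.loc["control", "hr_bpm_sd"] == pytest.approx(
            np.sqrt(200.0), rel=1e-9)  # 14.142...

    def test_identical_fish_have_zero_sd(self):
        table = _table({"control": {"hr_bpm": [150.0] * 4},
                        "model": {"hr_bpm": [90.0] * 4}})
        assert summarize_groups(table).loc["control", "hr_bpm_sd"] == 0.0

    def test_one_summary_row_per_group(self):
        table = _table({g: {"hr_bpm": [1.0, 2.0]}
                        for g in ["control", "model", "a", "b", "c"]})
        assert len(summarize_groups(table)) == 5

    def test_missing_model_group_is_configuration_error(self):
        table = _table({"control": {"hr_bpm": [1.0]}})
        with pytest.raises(ConfigurationError, match="model"):
            summarize_groups(table)


class TestNormalization:
    def test_control_normalizes_to_one(self):
        table = _table({"control": {"hr_bpm": [150.0, 150.0]},
                        "model": {"hr_bpm": [90.0, 90.0]}})
        panel = normalize_to_control(summarize_groups(table))
        assert panel.loc["control"].tolist() == pytest.approx([1.0] * 4)

    def test_depressed_rate_normalizes_to_ratio(self):
        table = _table({"control": {"hr_bpm": [150.0, 150.0]},
                        "model": {"hr_bpm": [90.0, 90.0]}})
        panel = normalize_to_control(summarize_groups(table))
        assert panel.loc["model", "hr_bpm"] == pytest.approx(0.6, rel=1e-12)


class TestRecoveryScore:
    @pytest.mark.parametrize("b_treat, b_model, expected", [
        (1.0, 0.5, 1.0),    # full recovery
        (0.6, 0.6, 0.0),    # no recovery
        (0.8, 0.6, 0.5),    # halfway
    ])
    def test_hand_values(self, b_treat, b_model, expected):
        value, ok = recovery_score(b_treat, b_model)
        assert ok
        assert value == pytest.approx(expected, rel=1e-9)

    def test_degenerate_denominator_flagged_invalid(self):
        value, ok = recovery_score(0.9, 1.0 + 1e-9)
        assert not ok and np.isnan(value)

    def test_elevated_indicator_scores_movement_back_toward_control(self):
        # insult raised the indicator (B_model = 1.4); treatment at 1.1
        value, ok = recovery_score(1.1, 1.4)
        assert ok
        assert value == pytest.approx(0.75, rel=1e-9)


class TestComputeAhfi:
    def test_full_recovery_on_all_components_scores_four(self):
        panel = _panel({"model": 0.5, "treat": 1.0})
        res = compute_ahfi(panel, "treat")
        assert res.ahfi == pytest.approx(4.0)
        assert res.activity_class == "excellent"

    def test_component_sum_and_active_class(self):
        # component RCFs 0.2, 0.1, 0.3, 0.1 -> AHFI 0.7, class active
        rcfs = dict(zip(AHFI_COMPONENTS, [0.2, 0.1, 0.3, 0.1]))
        panel = pd.DataFrame({c: {"model": 0.5, "treat": 0.5 + 0.5 * rcfs[c]}
                              for c in AHFI_COMPONENTS})
        res = compute_ahfi(panel, "treat")
        assert res.ahfi == pytest.approx(0.7, rel=1e-9)
        assert res.activity_class == "active"

    def test_no_recovery_is_inactive(self):
        res = compute_ahfi(_panel({"model": 0.5, "treat": 0.5}), "treat")
        assert res.ahfi == pytest.approx(0.0)
        assert res.activity_class == "inactive"

    def test_threshold_rule(self):
        th = AhfiThresholds()
        assert th.classify(1.0) == "excellent"
        assert th.classify(0.99) == "active"
        assert th.classify(0.59) == "inactive"
        assert th.classify(-0.5) == "inactive"
        assert th.classify(-0.51) == "atypical"

    def test_degenerate_component_invalidates_ahfi(self):
        panel = _panel({"model": 0.5, "treat": 0.8})
        panel.loc["model", "fac"] = 1.0  # insult never moved FAC
        res = compute_ahfi(panel, "treat")
        assert not res.valid
        assert res.invalid_components == ("fac",)
        assert np.isnan(res.ahfi)

    @settings(max_examples=40, deadline=None)
    @given(delta=st.floats(min_value=1e-3, max_value=0.5),
           comp=st.sampled_from(AHFI_COMPONENTS))
    def test_strictly_increasing_in_each_treatment_component(self, delta, comp):
        panel = _panel({"model": 0.5, "treat": 0.8})
        bumped = panel.copy()
        bumped.loc["treat", comp] += delta
        assert (compute_ahfi(bumped, "treat").ahfi
                > compute_ahfi(panel, "treat").ahfi)


class TestRanking:
    @staticmethod
    def _result(group, ahfi, ef=0.0):
        cls = AhfiThresholds().classify(ahfi)
        return AHFIResult(group=group, ahfi=ahfi, activity_class=cls,
                          rcf={"ef": ef})

    def test_descending_order_with_classes(self):
        ranked = rank_treatments([self._result("c", -0.6),
                                  self._result("a", 1.2),
                                  self._result("b", 0.7)])
        assert [r.group for r in ranked] == ["a", "b", "c"]
        assert [r.activity_class for r in ranked] == [
            "excellent", "active", "atypical"]

    def test_tie_broken_by_ef_recovery_then_label(self):
        ranked = rank_treatments([self._result("x", 0.8, ef=0.1),
                                  self._result("w", 0.8, ef=0.3),
                                  self._result("v", 0.8, ef=0.3)])
        assert [r.group for r in ranked] == ["v", "w", "x"]

    def test_single_entry(self):
        one = self._result("only", 0.5)
        assert rank_treatments([one]) == [one]


class TestGroupComparison:
    def test_identical_groups_give_p_of_one(self):
        table = _table({"control": {"hr_bpm": [1.0, 2.0, 3.0]},
                        "model": {"hr_bpm": [1.0, 2.0, 3.0]},
                        "treat": {"hr_bpm": [1.0, 2.0, 3.0]}})
        out = compare_groups(table, fields=("hr_bpm",))
        t_row = out[(out["group"] == "treat") & (out["test"] == "t_vs_model")]
        assert t_row["p_value"].iloc[0] == pytest.approx(1.0)
        assert t_row["statistic"].iloc[0] == pytest.approx(0.0)

    def test_large_shift_flagged_at_1pct(self):
        rng = np.random.default_rng(0)
        table = _table({
            "control": {"hr_bpm": list(150 + rng.normal(0, 5, 20))},
            "model": {"hr_bpm": list(90 + rng.normal(0, 5, 20))},
        })
        out = compare_groups(table, reference="model", fields=("hr_bpm",))
        row = out[out["group"] == "control"].iloc[0]
        assert row["p_value"] < 0.01
        assert row["significance"] == "**"

    def test_anova_row_present_per_indicator(self):
        rng = np.random.default_rng(1)
        table = _table({g: {"hr_bpm": list(rng.normal(100, 5, 5))}
                        for g in ["control", "model", "treat"]})
        out = compare_groups(table, fields=("hr_bpm",))
        assert (out["test"] == "anova").sum() == 1


class TestScoreCohort:
    def test_treatment_identical_to_control_scores_four(self):
        table = _table({
            "control": {"hr_bpm": [150.0, 150.0], "ef": [0.6, 0.6],
                        "co_um3_min": [2e6, 2e6], "fac": [0.4, 0.4]},
            "model": {"hr_bpm": [90.0, 90.0], "ef": [0.3, 0.3],
                      "co_um3_min": [8e5, 8e5], "fac": [0.15, 0.15]},
            "treat": {"hr_bpm": [150.0, 150.0], "ef": [0.6, 0.6],
                      "co_um3_min": [2e6, 2e6], "fac": [0.4, 0.4]},
        })
        results = score_cohort(table)
        assert len(results) == 1
        assert results[0].ahfi == pytest.approx(4.0, abs=1e-12)
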