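"""Differential calling, zero policies, transition classes and scaling."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from phoswave.dynamics import (
    AnalysisConfig,
    Comparison,
    average_replicates,
    call_differential,
    classify_transition,
    replicate_fold_change,
    scale_profiles,
    strain_comparisons,
    summarize_calls,
    timecourse_comparisons,
    welch_t,
)
from _oracles import welch_p_reference
from test_filter_qc import timecourse_design


class TestWelchT:
    def test_closed_form_df2_example(self):
        t, df, p = welch_t([4, 6], [9, 11])
        assert t == pytest.approx(-3.5355339, abs=1e-6)
        assert df == pytest.approx(2.0)
        # F(t) = 1/2 + t / (2 sqrt(2) sqrt(1 + t^2/2)) at df = 2
        closed = 2 * (0.5 + (-abs(t)) / (2 * np.sqrt(2)
                                         * np.sqrt(1 + t * t / 2)))
        assert p == pytest.approx(closed, abs=1e-12)
        assert p == pytest.approx(0.0715, abs=1e-4)

    def test_identical_groups(self):
        t, _, p = welch_t([3.0, 5.0], [3.0, 5.0])
        assert (t, p) == (0.0, 1.0)

    def test_constant_equal_groups_p_one(self):
        _, _, p = welch_t([1, 1], [1, 1])
        assert p == 1.0

    def test_constant_unequal_groups_p_zero(self):
        _, _, p = welch_t([1, 1], [2, 2])
        assert p == 0.0

    def test_matches_reference_on_random_samples(self, rng):
        for _ in range(300):
            a = rng.normal(0, 1, rng.integers(2, 6))
            b = rng.normal(0.5, 2, rng.integers(2, 6))
            _, _, p = welch_t(a, b)
            assert p == pytest.approx(welch_p_reference(a, b), abs=1e-9)

    def test_needs_two_values_per_group(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [2.0, 3.0])


class TestReplicateFoldChange:
    def test_plain_ratio(self):
        fc, imputed = replicate_fold_change([10, 10], [30, 30], 1.0)
        assert fc == pytest.approx(3.0)
        assert not imputed

    def test_zero_substitution(self):
        fc, imputed = replicate_fold_change([0, 10], [20, 20], 5.0)
        # ratios become (4, 2) -> median 3
        assert fc == pytest.approx(3.0)
        assert imputed

    def test_decrease_qualifies(self):
        fc, _ = replicate_fold_change([10, 10], [5, 5], 1.0)
        assert fc == pytest.approx(0.5)
        assert fc < 1 / 1.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            replicate_fold_change([], [], 1.0)


def two_group_matrix(rows: dict[str, tuple[list, list]]):
    data = {f: list(a) + list(b) for f, (a, b) in rows.items()}
    return pd.DataFrame.from_dict(
        data, orient="index", columns=["r1_ref", "r2_ref", "r1_test",
                                       "r2_test"])


COMP = Comparison("c", ("r1_ref", "r2_ref"), ("r1_test", "r2_test"))
CONFIG = AnalysisConfig()


class TestCallDifferential:
    def test_clear_increase_called(self):
        m = two_group_matrix({"f": ([10, 10], [30, 31])})
        res = call_differential(m, [COMP], CONFIG, dataset_min=1.0)
        assert res.iloc[0]["category"] == "increased"
        assert res.iloc[0]["median_fc"] > 1.5

    def test_subthreshold_fold_change_is_no_change(self):
        m = two_group_matrix({"f": ([10, 10], [14, 14])})
        res = call_differential(m, [COMP], CONFIG, dataset_min=1.0)
        assert res.iloc[0]["category"] == "no_change"

    def test_zero_rescue_requires_significance(self):
        # (0,0) vs (7,9): Welch on the literal values gives p ~ 0.079,
        # so the rescue rule alone does not call the site
        m = two_group_matrix({"f": ([0, 0], [7, 9])})
        res = call_differential(m, [COMP], CONFIG, dataset_min=0.5)
        assert res.iloc[0]["p_value"] == pytest.approx(
            welch_p_reference([0, 0], [7, 9]), abs=1e-12)
        assert res.iloc[0]["p_value"] > 0.05
        assert res.iloc[0]["category"] == "no_change"
        assert res.iloc[0]["imputed"]

    def test_zero_rescue_calls_when_significant(self):
        # four replicates tighten the test below alpha
        comp = Comparison("c", ("a1", "a2", "a3", "a4"),
                          ("b1", "b2", "b3", "b4"))
        m = pd.DataFrame([[0, 0, 0, 0, 7, 9, 8, 8.5]],
                         index=["f"],
                         columns=list(comp.ref_channels)
                         + list(comp.test_channels))
        res = call_differential(m, [comp], CONFIG, dataset_min=0.5)
        assert res.iloc[0]["p_value"] < 0.05
        assert res.iloc[0]["zero_rescue"]
        assert res.iloc[0]["category"] == "increased"

    def test_imputed_fold_change_uses_dataset_minimum(self):
        m = two_group_matrix({"f": ([0, 10], [20, 20])})
        res = call_differential(m, [COMP], CONFIG, dataset_min=5.0)
        assert res.iloc[0]["median_fc"] == pytest.approx(3.0)

    def test_scale_invariance_of_categories(self, rng):
        values = rng.lognormal(2, 1, size=(50, 4))
        m = pd.DataFrame(values, columns=COMP.ref_channels
                         + COMP.test_channels,
                         index=[f"f{i}" for i in range(50)])
        res1 = call_differential(m, [COMP], CONFIG, dataset_min=1e-3)
        res2 = call_differential(m * 37.5, [COMP], CONFIG,
                                 dataset_min=37.5e-3)
        assert (res1["category"] == res2["category"]).all()

    def test_swap_inverts_fold_change_and_category(self, rng):
        comp = Comparison("c", ("a1", "a2", "a3"), ("b1", "b2", "b3"))
        swapped = Comparison("c", comp.test_channels, comp.ref_channels)
        values = rng.lognormal(2, 1, size=(60, 6))
        m = pd.DataFrame(values, columns=comp.ref_channels
                         + comp.test_channels,
                         index=[f"f{i}" for i in range(60)])
        res = call_differential(m, [comp], CONFIG, dataset_min=1e-3)
        inv = call_differential(m, [swapped], CONFIG, dataset_min=1e-3)
        # with an odd replicate count the median fold change inverts exactly
        assert np.allclose(res["median_fc"], 1.0 / inv["median_fc"])
        flip = {"increased": "decreased", "decreased": "increased",
                "no_change": "no_change"}
        assert (res["category"].map(flip) == inv["category"]).all()

    def test_unknown_channel_rejected(self):
        m = two_group_matrix({"f": ([1, 2], [3, 4])})
        bad = Comparison("c", ("nope", "r2_ref"), ("r1_test", "r2_test"))
        with pytest.raises(ValueError, match="unknown"):
            call_differential(m, [bad], CONFIG, dataset_min=1.0)

    def test_rescue_superset_of_min_substituted_calls(self, rng):
        """Replacing zeros by the dataset minimum up front can only lose
        calls relative to the rescue rule."""
        values = rng.lognormal(2, 1, size=(80, 4))
        zero_mask = rng.random(values.shape) < 0.3
        values[zero_mask] = 0.0
        m = pd.DataFrame(values, columns=COMP.ref_channels
                         + COMP.test_channels,
                         index=[f"f{i}" for i in range(80)])
        dmin = 1e-2
        with_rescue = call_differential(m, [COMP], CONFIG, dataset_min=dmin)
        pre = m.where(m > 0, dmin)
        without = call_differential(pre, [COMP], CONFIG, dataset_min=dmin)
        called_with = set(with_rescue.loc[
            with_rescue["category"] != "no_change", "feature"])
        called_without = set(without.loc[
            without["category"] != "no_change", "feature"])
        assert called_without <= called_with


class TestSummarizeAndComparisons:
    def test_one_significant_comparison_flags_dynamic(self):
        design = timecourse_design(tps=(0, 45, 60))
        comps = timecourse_comparisons(design, "wild_type", "PE")
        assert [c.label for c in comps] == [
            "wild_type:t0-vs-t45", "wild_type:t0-vs-t60"]
        cols = design.channels(enrichment="PE")
        tp_of = dict(zip(design.subset("PE")["channel_label"],
                         design.subset("PE")["timepoint_min"]))
        vals = [30.0 if tp_of[c] == 60 else 10.0 + 0.01 * i
                for i, c in enumerate(cols)]
        m = pd.DataFrame([vals], index=["f"], columns=cols)
        res = call_differential(m, comps, CONFIG, dataset_min=1.0)
        summary = summarize_calls(res)
        assert summary.loc["f", "dynamic"]
        assert summary.loc["f", "direction"] == "increased"
        assert summary.loc["f", "n_significant"] == 1

    def test_strain_comparisons_are_matched_by_timepoint(self):
        design = timecourse_design(tps=(0, 45),
                                   strains=("wild_type", "mutant"))
        comps = strain_comparisons(design, "wild_type", "mutant", "PE")
        assert len(comps) == 2
        for comp in comps:
            assert all("wi" in c or "wt" in c for c in comp.ref_channels)

    def test_unknown_reference_timepoint_rejected(self):
        design = timecourse_design(tps=(0, 45, 60))
        with pytest.raises(ValueError):
            timecourse_comparisons(design, "wild_type", "PE",
                                   reference_tp=99)


class TestClassifyTransition:
    def test_rise_after_metaphase_one(self):
        design = timecourse_design(tps=(0, 45, 60, 75, 90, 105, 120, 135,
                                        150, 165))
        cols = design.channels(enrichment="PE")
        tp_of = dict(zip(design.subset("PE")["channel_label"],
                         design.subset("PE")["timepoint_min"]))
        vals = [20.0 if tp_of[c] >= 90 else 10.0 + 0.01 * i
                for i, c in enumerate(cols)]
        m = pd.DataFrame([vals], index=["f"], columns=cols)
        out = classify_transition(m, design, "wild_type", "PE", 75,
                                  AnalysisConfig())
        assert out.loc["f"] == "increased"

    def test_flat_profile_is_no_change(self):
        design = timecourse_design(tps=(0, 45, 60, 75, 90, 105, 120, 135,
                                        150, 165))
        cols = design.channels(enrichment="PE")
        m = pd.DataFrame([[10.0 + 0.01 * i for i in range(len(cols))]],
                         index=["f"], columns=cols)
        out = classify_transition(m, design, "wild_type", "PE", 75,
                                  AnalysisConfig())
        assert out.loc["f"] == "no_change"

    def test_metaphase_two_anchor_validated(self):
        config = AnalysisConfig()
        assert config.metaphase_II == 120
        with pytest.raises(ValueError, match="anchor"):
            AnalysisConfig(metaphase_II=47)


class TestProfileTransforms:
    def test_average_replicates_halves_single_zero(self):
        out = average_replicates([10.0], [0.0])
        assert out.tolist() == [5.0]

    def test_average_identical_replicates_unchanged(self):
        out = average_replicates([3.0, 4.0], [3.0, 4.0])
        assert out.tolist() == [3.0, 4.0]

    def test_average_both_zero(self):
        assert average_replicates([0.0], [0.0]).tolist() == [0.0]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            average_replicates([1.0, 2.0], [1.0])

    def test_mean_scaling_gives_unit_mean(self, rng):
        m = pd.DataFrame(rng.lognormal(2, 1, size=(20, 10)))
        scaled, excluded = scale_profiles(m, mode="mean")
        assert len(excluded) == 0
        assert np.allclose(scaled.mean(axis=1), 1.0)

    def test_zeros_enter_mean_and_stay_zero(self):
        m = pd.DataFrame([[0.0, 2.0, 4.0]], index=["f"])
        scaled, _ = scale_profiles(m, mode="mean")
        assert scaled.loc["f"].tolist() == [0.0, 1.0, 2.0]

    def test_combined_scope_preserves_strain_ratio(self):
        wt = np.array([2.0, 4.0, 6.0])
        mut = wt / 2.0
        m = pd.DataFrame([np.concatenate([wt, mut])], index=["f"])
        scaled, _ = scale_profiles(m, mode="mean")
        row = scaled.loc["f"].to_numpy()
        assert np.allclose(row[:3], 2.0 * row[3:])

    def test_reference_mode_sets_anchor_to_one(self):
        m = pd.DataFrame([[2.0, 4.0, 8.0]], index=["f"], columns=[0, 75, 120])
        scaled, _ = scale_profiles(m, mode="reference_tp", reference_col=75)
        assert scaled.loc["f", 75] == 1.0

    def test_zero_mean_feature_excluded(self):
        m = pd.DataFrame([[0.0, 0.0], [1.0, 3.0]], index=["z", "f"])
        scaled, excluded = scale_profiles(m, mode="mean")
        assert list(excluded) == ["z"]
        assert list(scaled.index) == ["f"]
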