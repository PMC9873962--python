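"""Test selection, fold change, the strict significance rule, top tables."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cardiomir.diffscreen import (DiffResult, ScreenParams, fold_change,
                                  od_summary, run_test, screen, select_test,
                                  top_table, volcano_points, welch_anova)
from cardiomir.synthetic import ODTimeSeries, SimConfig, generate_expression
from cardiomir.preprocess import preprocess


def _result(fc, p, mirna="m", significant=None, params=None):
    params = params or ScreenParams()
    if significant is None:
        significant = (fc > params.fc_threshold or fc < 1 / params.fc_threshold) \
            and p < params.alpha
    return DiffResult(mirna=mirna, comparison=("NHF", "AMHF"), fold_change=fc,
                      p_value=p, neg_log10_p=-math.log10(max(p, 1e-300)),
                      test_used="student-t",
                      direction="up" if fc > 1 else ("down" if fc < 1 else "none"),
                      significant=significant)


class TestSelectTest:
    def test_two_normal_equal_variance_groups_get_student_t(self, rng):
        picks = [
            select_test([rng.normal(0, 1, 10), rng.normal(0, 1, 10)])
            for _ in range(50)
        ]
        # both checks pass with high probability under the null
        assert picks.count("student-t") > 35

    def test_grossly_unequal_variances_get_welch_t(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(0, 10, 20)
        assert stats.levene(a, b).pvalue < 0.05  # oracle: variances differ
        assert select_test([a, b]) == "welch-t"

    def test_four_normal_equal_variance_groups_get_anova(self, rng):
        groups = [rng.normal(5, 1, 12) for _ in range(4)]
        if select_test(groups) == "anova":
            assert run_test(groups)[0] == "anova"

    def test_non_normal_multigroup_gets_welch_anova(self, rng):
        groups = [rng.lognormal(0, 2, 15) for _ in range(3)]
        groups[0] = groups[0] * 50
        assert select_test(groups) == "welch-anova"

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            select_test([np.ones(2), np.ones(5)])


class TestWelchPaths:
    def test_student_and_welch_agree_for_equal_n_equal_variance(self, rng):
        """With equal n and equal sample variances the two t statistics coincide."""
        a = rng.normal(0, 1, 15)
        b = rng.normal(0.5, 1, 15)
        b = (b - b.mean()) / b.std(ddof=1) * a.std(ddof=1) + b.mean()
        p_s = stats.ttest_ind(a, b, equal_var=True).pvalue
        p_w = stats.ttest_ind(a, b, equal_var=False).pvalue
        assert p_s == pytest.approx(p_w, rel=1e-10)

    def test_welch_anova_matches_pingouin(self, rng):
        import pingouin as pg

        groups = [rng.normal(i, 1 + i, 12 + 2 * i) for i in range(3)]
        f, p = welch_anova(groups)
        df = pd.DataFrame({
            "y": np.concatenate(groups),
            "g": np.repeat(list("abc"), [len(g) for g in groups]),
        })
        ref = pg.welch_anova(dv="y", between="g", data=df)
        assert f == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert p == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-9)


class TestFoldChange:
    def test_identical_groups_give_unity(self):
        x = np.array([5.0, 6.0, 7.0])
        assert fold_change(x, x) == 1.0

    def test_direct_ratio(self):
        assert fold_change(np.full(3, 100.0), np.full(3, 76.5)) == pytest.approx(0.765)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fold_change(np.array([0.0, 0.0, 0.0]), np.array([1.0, 2.0, 3.0]))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.1, 1e4), min_size=3, max_size=10),
           st.lists(st.floats(0.1, 1e4), min_size=3, max_size=10))
    def test_antisymmetry(self, a, b):
        a, b = np.array(a), np.array(b)
        assert fold_change(a, b) * fold_change(b, a) == pytest.approx(1.0)


class TestSignificanceRule:
    def test_fc_exactly_at_threshold_is_not_significant(self):
        # "more than 1.5 times" is strict: FC = 1.5 fails even at p = .01
        assert not _result(1.5, 0.01).significant
        assert not _result(1 / 1.5, 0.01).significant

    def test_p_exactly_at_alpha_is_not_significant(self):
        assert not _result(2.0, 0.05).significant

    def test_strictly_inside_both_bounds_is_significant(self):
        assert _result(1.5000001, 0.0499).significant
        assert _result(0.5, 0.01).significant

    def test_null_simulation_false_positive_rate_below_alpha(self):
        """No planted effects: the compound rule fires less often than alpha."""
        n_sig = n_tot = 0
        for seed in range(10):
            cfg = SimConfig(de_table=[], n_background_mirnas=80,
                            below_floor_fraction=0.0, seed=seed)
            m, design, _ = generate_expression(cfg)
            res = screen(preprocess(m), design, ("NHF", "AMNHF"))
            n_sig += sum(r.significant for r in res)
            n_tot += len(res)
        assert n_sig / n_tot < 0.05


class TestScreenAndTopTable:
    def test_screen_rejects_unknown_group(self, zero_noise_cohort):
        matrix, design, _ = zero_noise_cohort
        with pytest.raises(ValueError, match="not present"):
            screen(matrix, design, ("NHF", "XYZ"))

    def test_planted_down_list_headed_by_mir320_then_mir204(self, zero_noise_screens):
        _, down = top_table(zero_noise_screens["AMNHF"])
        assert [r.mirna for r in down[:2]] == ["hsa-miR-320", "hsa-miR-204"]

    def test_planted_up_lists_match_published_order(self, zero_noise_screens):
        expected_first = {"AMNHF": "hsa-miR-409-3p", "OMHF": "hsa-miR-3941",
                          "AMHF": "hsa-miR-3667-5p"}
        for case, results in zero_noise_screens.items():
            up, _ = top_table(results)
            assert up[0].mirna == expected_first[case]
            fcs = [r.fold_change for r in up]
            assert fcs == sorted(fcs, reverse=True)

    def test_no_significant_results_give_empty_lists(self):
        results = [_result(1.1, 0.9, f"m{i}") for i in range(10)]
        up, down = top_table(results)
        assert up == [] and down == []

    def test_k_larger_than_result_count_returns_full_lists(self):
        results = [_result(3.0, 0.001, "up1"), _result(0.3, 0.001, "dn1")]
        up, down = top_table(results, ScreenParams(top_k=10))
        assert [r.mirna for r in up] == ["up1"]
        assert [r.mirna for r in down] == ["dn1"]

    def test_strict_gate_excludes_inside_band_hits(self):
        results = [_result(0.765, 0.001, "near"), _result(0.4, 0.001, "far")]
        _, down = top_table(results, require_fc_threshold=True)
        assert [r.mirna for r in down] == ["far"]


class TestVolcano:
    def test_coordinates(self):
        pts = volcano_points([_result(2.0, 1.0), _result(2.0, 0.05)])
        assert pts[0][1] == pytest.approx(0.0)
        assert pts[1][1] == pytest.approx(1.30103, abs=1e-5)

    def test_p_zero_capped_not_infinite(self):
        pts = volcano_points([_result(2.0, 0.0)])
        assert math.isfinite(pts[0][1]) and pts[0][1] >= 300

    def test_flags_mirror_screen_flags(self, zero_noise_screens):
        res = zero_noise_screens["AMHF"]
        pts = volcano_points(res)
        assert [p[2] for p in pts] == [r.significant for r in res]

    def test_ordinate_strictly_decreasing_in_p(self):
        ps = [0.001, 0.01, 0.05, 0.5, 1.0]
        ys = [volcano_points([_result(2.0, p)])[0][1] for p in ps]
        assert all(a > b for a, b in zip(ys, ys[1:]))


class TestODSummary:
    def test_day_mean(self):
        out = od_summary([ODTimeSeries(day=5, well_ods=[1.7, 1.8])])
        assert out.loc[0, "mean_od"] == pytest.approx(1.75)
        assert out.loc[0, "sd_od"] == pytest.approx(np.std([1.7, 1.8], ddof=1))

    def test_single_well_sd_zero_and_flagged(self):
        with pytest.warns(UserWarning, match="single well"):
            out = od_summary([ODTimeSeries(day=1, well_ods=[2.0])])
        assert out.loc[0, "sd_od"] == 0.0
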