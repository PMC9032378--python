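"""Tests of hearing-loss endpoints and cohort statistics against
closed-form and brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from ecochg.outcomes import (
    AUDIOGRAM_FREQS_HZ,
    Audiogram,
    CohortOutcomeModel,
    analysis_report,
    compare_groups,
    compare_two,
    correlate,
    dunn_posthoc,
    hearing_loss,
)
from ecochg.synthetic import CohortConfig, make_audiogram_pair


def audio(values, timepoint="pre"):
    return Audiogram(thresholds_db=tuple(values), timepoint=timepoint)


class TestHearingLoss:
    def test_identical_audiograms_give_zero_loss(self):
        pre = audio([30, 35, 40, 50, 60, 65, 70])
        post = audio([30, 35, 40, 50, 60, 65, 70], "post4w")
        result = hearing_loss(pre, post)
        assert result.lf_pta_hl == 0.0
        assert all(v == 0.0 for v in result.per_frequency_hl)

    def test_uniform_20db_shift(self):
        pre = audio([30, 35, 40, 50, 60, 65, 70])
        post = audio([50, 55, 60, 70, 80, 65, 70], "post4w")
        assert hearing_loss(pre, post).lf_pta_hl == pytest.approx(20.0)

    def test_postoperative_improvement_is_negative_loss(self):
        pre = audio([30, 35, 40, 50, 60, 65, 70])
        post = audio([25, 35, 40, 50, 60, 65, 70], "post4w")
        result = hearing_loss(pre, post)
        assert result.per_frequency_hl[0] == -5.0
        assert result.lf_pta_hl == pytest.approx(-1.0)

    def test_timepoint_mismatch_rejected(self):
        pre = audio([30, 35, 40, 50, 60, 65, 70])
        with pytest.raises(ValueError, match="pair"):
            hearing_loss(pre, pre)

    def test_missing_frequency_skipped_with_warning(self):
        pre = audio([30, np.nan, 40, 50, 60, 65, 70])
        post = audio([40, np.nan, 50, 60, 70, 65, 70], "post4w")
        with pytest.warns(UserWarning, match="250"):
            result = hearing_loss(pre, post)
        assert result.lf_pta_hl == pytest.approx(10.0)

    @given(st.permutations(list(range(len(AUDIOGRAM_FREQS_HZ)))))
    def test_lf_pta_invariant_to_input_frequency_order(self, order):
        values = [30.0, 35.0, 40.0, 50.0, 60.0, 65.0, 70.0]
        mapping = {AUDIOGRAM_FREQS_HZ[i]: values[i] for i in order}
        assert Audiogram.from_mapping(mapping).lf_pta() == pytest.approx(np.mean(values[:5]))


class TestCompareGroups:
    def test_kruskal_matches_brute_force_ranks(self):
        values = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        labels = ["a", "a", "a", "b", "b", "b"]
        comp = compare_groups(values, labels)
        # brute force: H = 12/(N(N+1)) * sum n_i Rbar_i^2 - 3(N+1), no ties
        h = 12.0 / (6 * 7) * (3 * 2.0**2 + 3 * 5.0**2) - 3 * 7
        assert comp.statistic == pytest.approx(h, abs=1e-9)
        assert comp.omnibus_p == pytest.approx(stats.chi2.sf(h, 1), abs=1e-9)

    def test_degenerate_identical_values(self):
        comp = compare_groups([5.0] * 6, ["a", "a", "b", "b", "c", "c"])
        assert comp.statistic == 0.0
        assert comp.omnibus_p == 1.0

    def test_dunn_z_matches_hand_formula(self):
        groups = {"a": np.array([1.0, 2, 3]), "b": np.array([4.0, 5, 6]), "c": np.array([7.0, 8, 9])}
        mat = dunn_posthoc(groups, adjust="holm")
        # mean ranks 2, 5, 8 over N=9; var = 9*10/12 = 7.5 (no ties)
        z_ab = 3.0 / math.sqrt(7.5 * (2 / 3))
        p_ab_raw = 2 * stats.norm.sf(z_ab)
        z_ac = 6.0 / math.sqrt(7.5 * (2 / 3))
        p_ac_raw = 2 * stats.norm.sf(z_ac)
        # Holm over the three pairs: [ab, ac, bc] raw = [p_ab, p_ac, p_ab]
        assert mat.loc["a", "c"] == pytest.approx(3 * p_ac_raw, abs=1e-9)
        assert mat.loc["a", "b"] == pytest.approx(min(2 * p_ab_raw, 1.0), abs=1e-9)
        assert np.array_equal(mat.values, mat.values.T)

    def test_small_group_excluded_with_warning(self):
        values = [1.0, 2, 3, 4, 5, 6, 99]
        labels = ["a", "a", "a", "b", "b", "b", "c"]
        with pytest.warns(UserWarning, match="n < 2"):
            comp = compare_groups(values, labels)
        assert set(comp.group_labels) == {"a", "b", "c"}
        assert set(comp.pairwise_p.index) == {"a", "b"}

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], ["a", "a"])


class TestCompareTwo:
    def test_identical_groups(self):
        t, p = compare_two([1.0, 2, 3, 1, 2, 3], ["a", "a", "a", "b", "b", "b"])
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_welch_matches_closed_form(self):
        a = np.array([3.1, 4.5, 2.2, 5.0])
        b = np.array([7.3, 6.1, 8.0, 9.2, 5.5])
        t, p = compare_two(
            np.concatenate([a, b]), ["a"] * 4 + ["b"] * 5
        )
        want_t = (a.mean() - b.mean()) / math.sqrt(a.var(ddof=1) / 4 + b.var(ddof=1) / 5)
        assert t == pytest.approx(want_t, abs=1e-9)
        nu_num = (a.var(ddof=1) / 4 + b.var(ddof=1) / 5) ** 2
        nu_den = (a.var(ddof=1) / 4) ** 2 / 3 + (b.var(ddof=1) / 5) ** 2 / 4
        want_p = 2 * stats.t.sf(abs(want_t), nu_num / nu_den)
        assert p == pytest.approx(want_p, abs=1e-9)

    def test_degenerate_zero_variance(self):
        assert compare_two([1.0, 1, 1, 1], ["a", "a", "b", "b"]) == (0.0, 1.0)
        t, p = compare_two([1.0, 1, 2, 2], ["a", "a", "b", "b"])
        assert t == math.inf and p == 0.0

    def test_three_groups_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            compare_two([1.0, 2, 3], ["a", "b", "c"])


class TestCorrelate:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        result = correlate(x, 2 * x + 1)
        assert result.r == pytest.approx(1.0, abs=1e-12)
        assert result.n == 10

    def test_matches_closed_form_on_fixed_points(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 7.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 8.0])
        result = correlate(x, y)
        want = np.sum((x - x.mean()) * (y - y.mean())) / math.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert result.r == pytest.approx(want, abs=1e-12)

    def test_independent_variables_near_zero(self):
        rng = np.random.default_rng(0)
        result = correlate(rng.normal(size=2000), rng.normal(size=2000))
        assert abs(result.r) < 0.08

    def test_nan_pairs_dropped_listwise(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [1.0, 2.0, 3.0, 4.0, np.nan]
        with pytest.warns(UserWarning, match="dropped 2"):
            result = correlate(x, y)
        assert result.n == 3

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def simulated_cohort_table(type_means, seed, n_per_type=15, hl_sd=8.0):
    """Per-subject LF HL table via the audiogram generator."""
    config = CohortConfig(type_hl_means=type_means, hl_sd=hl_sd)
    rng = np.random.default_rng(seed)
    rows = []
    for rtype in ("I", "II", "III"):
        for _ in range(n_per_type):
            pre, post = make_audiogram_pair(rtype, config, int(rng.integers(2**31 - 1)))
            rows.append(
                {
                    "response_type": rtype,
                    "lf_hl": hearing_loss(pre, post).lf_pta_hl,
                    "preop_lf_pta_db": pre.lf_pta(),
                    "preop_500_db": pre.as_array()[2],
                    "a_max_uv": float(rng.uniform(20, 150)),
                    "a_min_uv": float(rng.uniform(5, 20)),
                    "a_end_uv": float(rng.uniform(5, 100)),
                }
            )
    return pd.DataFrame(rows)


class TestCohortModel:
    def test_effect_cohort_flags_type_three_only(self):
        table = simulated_cohort_table({"I": 10.0, "II": 10.0, "III": 25.0}, seed=1)
        results = CohortOutcomeModel.from_dataframe(table).fit()
        pairwise = results.by_type.pairwise_p
        assert pairwise.loc["I", "III"] < 0.05
        assert pairwise.loc["II", "III"] < 0.05
        assert pairwise.loc["I", "II"] > 0.05

    def test_null_cohort_shows_no_differences(self):
        table = simulated_cohort_table({"I": 15.0, "II": 15.0, "III": 15.0}, seed=2)
        results = CohortOutcomeModel.from_dataframe(table).fit()
        assert results.by_type.omnibus_p > 0.05

    def test_unclassifiable_subjects_excluded(self):
        table = simulated_cohort_table({"I": 10.0, "II": 10.0, "III": 25.0}, seed=3)
        extra = table.iloc[:2].copy()
        extra["response_type"] = "unclassifiable"
        full = pd.concat([table, extra], ignore_index=True)
        results = CohortOutcomeModel.from_dataframe(full).fit()
        assert results.n_subjects == len(full)
        assert results.n_analyzed == len(table)

    def test_report_and_summary_cover_all_sections(self):
        table = simulated_cohort_table({"I": 10.0, "II": 10.0, "III": 25.0}, seed=4)
        report = analysis_report(table)
        assert set(report["lf_hl_by_type"]["groups"]) == {"I", "II", "III"}
        assert "pairwise_p" in report["lf_hl_by_type"]
        assert any(c["var1"] == "A_min/A_max" for c in report["correlations"])
        assert "I vs III" in report["baseline_preop_t_tests"]
        text = CohortOutcomeModel.from_dataframe(table).fit().summary()
        assert "Kruskal-Wallis" in text and "Pearson" in text and "Welch" in text

    def test_missing_lf_hl_column_rejected(self):
        with pytest.raises(ValueError, match="lf_hl"):
            CohortOutcomeModel(pd.DataFrame({"a": [1.0]}))
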