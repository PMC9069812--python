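"""Panel positivity rule and diagnostic statistics against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

from nodulediag.cohort import MARKERS
from nodulediag.panel import (
    MissingDataError,
    call_panel,
    chi_square_2x2,
    clopper_pearson,
    diagnostic_performance,
    mann_whitney_u,
    marker_count_score,
    roc_curve,
    subgroup_report,
)

UNIT_CUTOFFS = {m: 1.0 for m in MARKERS}


def _cohort_from_conc(rows):
    df = pd.DataFrame(rows, columns=list(MARKERS))
    df["label"] = "malignant"
    return df


class TestCallPanel:
    def test_all_zero_concentrations_negative(self):
        calls = call_panel(_cohort_from_conc([[0.0] * 7]), UNIT_CUTOFFS)
        assert not calls["panel_positive"].iloc[0]

    def test_single_marker_above_cutoff_positive(self):
        row = [0.5] * 7
        row[3] = 1.5
        calls = call_panel(_cohort_from_conc([row]), UNIT_CUTOFFS)
        assert calls["panel_positive"].iloc[0]
        assert calls[f"pos_{MARKERS[3]}"].iloc[0]

    def test_exactly_at_cutoff_is_negative(self):
        # boundary convention: strictly above the cutoff
        calls = call_panel(_cohort_from_conc([[1.0] * 7]), UNIT_CUTOFFS)
        assert not calls["panel_positive"].iloc[0]

    def test_combined_is_disjunction(self, nodule_cohort, default_cutoffs):
        calls = call_panel(nodule_cohort, default_cutoffs)
        per_marker = calls[[f"pos_{m}" for m in MARKERS]].to_numpy()
        assert (calls["panel_positive"].to_numpy() == per_marker.any(axis=1)).all()

    def test_missing_concentration_raises(self):
        df = _cohort_from_conc([[2.0] * 7])
        df.loc[0, "SOX2"] = np.nan
        with pytest.raises(MissingDataError):
            call_panel(df, UNIT_CUTOFFS)

    def test_raising_one_cutoff_is_monotone(self, nodule_cohort, default_cutoffs):
        # raising any single cutoff never gains sensitivity or loses specificity
        labels = nodule_cohort["label"].to_numpy()
        base = diagnostic_performance(
            labels, call_panel(nodule_cohort, default_cutoffs)["panel_positive"])
        for m in MARKERS:
            raised = dict(default_cutoffs)
            raised[m] *= 1.5
            perf = diagnostic_performance(
                labels, call_panel(nodule_cohort, raised)["panel_positive"])
            assert perf.sensitivity <= base.sensitivity
            assert perf.specificity >= base.specificity


def cp_brute_force(k, n, level=0.95):
    """Independent oracle: invert the binomial tail probabilities by root
    finding on binom.sf/cdf (no Beta quantiles involved)."""
    alpha = 1 - level
    if k == 0:
        low = 0.0
    else:
        low = optimize.brentq(
            lambda p: stats.binom.sf(k - 1, n, p) - alpha / 2, 1e-15, 1 - 1e-15,
            xtol=1e-12)
    if k == n:
        high = 1.0
    else:
        high = optimize.brentq(
            lambda p: stats.binom.cdf(k, n, p) - alpha / 2, 1e-15, 1 - 1e-15,
            xtol=1e-12)
    return low, high


class TestClopperPearson:
    @pytest.mark.parametrize("k,n", [(0, 10), (10, 10), (5, 10), (1, 17),
                                     (116, 571), (347, 571), (295, 362)])
    def test_matches_tail_inversion_oracle(self, k, n):
        low, high = clopper_pearson(k, n)
        blow, bhigh = cp_brute_force(k, n)
        assert low == pytest.approx(blow, abs=1e-6)
        assert high == pytest.approx(bhigh, abs=1e-6)

    def test_zero_successes_closed_form(self):
        low, high = clopper_pearson(0, 10)
        assert low == 0.0
        assert high == pytest.approx(1 - 0.025 ** (1 / 10), abs=1e-12)

    def test_mirror_symmetry(self):
        l0, h0 = clopper_pearson(0, 10)
        ln, hn = clopper_pearson(10, 10)
        assert ln == pytest.approx(1 - h0, abs=1e-12)
        assert hn == pytest.approx(1 - l0, abs=1e-12)

    def test_half_successes_symmetric_about_half(self):
        low, high = clopper_pearson(5, 10)
        assert low < 0.5 < high
        assert low == pytest.approx(1 - high, abs=1e-12)

    def test_k_above_n_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson(11, 10)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(1, 60), st.data())
    def test_point_estimate_inside_interval(self, n, data):
        k = data.draw(st.integers(0, n))
        low, high = clopper_pearson(k, n)
        assert low <= k / n <= high


class TestDiagnosticPerformance:
    def test_published_contingency_counts(self):
        # 347 positive of 571 malignant, 295 negative of 362 benign
        labels = np.r_[np.ones(571, bool), np.zeros(362, bool)]
        calls = np.r_[np.ones(347, bool), np.zeros(224, bool),
                      np.ones(67, bool), np.zeros(295, bool)]
        perf = diagnostic_performance(labels, calls)
        assert perf.sensitivity * 100 == pytest.approx(60.7, abs=0.1)
        assert perf.specificity * 100 == pytest.approx(81.5, abs=0.1)
        assert perf.sensitivity_ci[0] < perf.sensitivity < perf.sensitivity_ci[1]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            diagnostic_performance([True, True], [True, False])


def mw_permutation_oracle(x, y):
    """Two-sided permutation p for the U statistic by brute enumeration of
    all orderings (only feasible for tiny samples); U computed directly from
    pairwise comparisons, not ranks."""
    def u_stat(a, b):
        return sum(1.0 if ai > bi else (0.5 if ai == bi else 0.0)
                   for ai in a for bi in b)

    pooled = list(x) + list(y)
    n1 = len(x)
    mu = n1 * len(y) / 2.0
    obs = abs(u_stat(x, y) - mu)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        rest = [pooled[i] for i in range(len(pooled)) if i not in combo]
        grp = [pooled[i] for i in combo]
        total += 1
        if abs(u_stat(grp, rest) - mu) >= obs - 1e-12:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_identical_groups_give_central_u(self):
        u, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert u == 4.5
        assert p == 1.0

    def test_fully_separated_small_groups(self):
        # all 20 rank assignments enumerated: only the two extremes are as
        # extreme as the observed U=0, so p = 2/20
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    @pytest.mark.parametrize("case", [
        ([1, 5, 2, 8], [3, 3, 9]),
        ([0.5, 0.5, 2.0], [0.5, 1.0, 3.0, 3.0]),
        ([7, 1, 4], [2, 2]),
    ])
    def test_exact_p_matches_permutation_oracle(self, case):
        x, y = case
        _, p = mann_whitney_u(x, y)
        assert p == pytest.approx(mw_permutation_oracle(x, y), abs=1e-12)

    def test_large_sample_matches_reference(self, rng):
        x = rng.lognormal(1.0, 1.0, size=60)
        y = rng.lognormal(0.5, 1.0, size=45)
        u, p = mann_whitney_u(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        assert u == pytest.approx(ref.statistic, abs=1e-9)
        assert p == pytest.approx(ref.pvalue, abs=1e-6)

    def test_all_values_identical_p_one(self):
        _, p = mann_whitney_u([2.0] * 20, [2.0] * 15)
        assert p == 1.0

    def test_marker_separation_on_synthetic_cohort(self, nodule_cohort):
        mal = nodule_cohort[nodule_cohort["label"] == "malignant"]
        ben = nodule_cohort[nodule_cohort["label"] == "benign"]
        for m in MARKERS:
            _, p = mann_whitney_u(mal[m], ben[m])
            assert p < 0.001  # class laws are well separated


class TestChiSquare:
    def test_proportional_table_is_null(self):
        stat, p = chi_square_2x2([[20, 30], [40, 60]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_diagonal_table_hand_value(self):
        stat, _ = chi_square_2x2([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0, abs=1e-12)

    def test_published_panel_table_significant(self):
        # combined-test positives vs class, both published benign variants
        for ben_pos, ben_neg in [(67, 295), (71, 291)]:
            _, p = chi_square_2x2([[347, 224], [ben_pos, ben_neg]])
            assert p < 0.001

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [5, 5]])

    def test_matches_reference_implementation(self, rng):
        t = rng.integers(1, 50, size=(2, 2))
        stat, p = chi_square_2x2(t)
        ref = stats.chi2_contingency(t, correction=False)
        assert stat == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_yates_correction_shrinks_statistic(self):
        plain, _ = chi_square_2x2([[12, 5], [6, 14]])
        corrected, _ = chi_square_2x2([[12, 5], [6, 14]], yates=True)
        assert corrected < plain


def auc_concordance_oracle(scores, labels):
    """O(n^2) pairwise concordance with ties counted 1/2."""
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocCurve:
    def test_perfect_separation_auc_one(self):
        labels = np.array([True, True, False, False])
        _, auc = roc_curve(np.array([4.0, 3.0, 2.0, 1.0]), labels)
        assert auc == pytest.approx(1.0, abs=1e-12)

    def test_label_independent_scores_auc_half(self, rng):
        labels = rng.random(4000) < 0.5
        scores = rng.random(4000)
        _, auc = roc_curve(scores, labels)
        assert abs(auc - 0.5) < 0.03

    def test_curve_endpoints(self, rng):
        labels = rng.random(50) < 0.4
        points, _ = roc_curve(rng.random(50), labels)
        assert tuple(points[0]) == (0.0, 0.0)
        assert tuple(points[-1]) == (1.0, 1.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 10**6))
    def test_auc_equals_concordance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 200))
        labels = np.zeros(n, dtype=bool)
        labels[: max(1, n // 3)] = True
        rng.shuffle(labels)
        # coarse grid forces plenty of tied scores
        scores = rng.integers(0, 6, size=n).astype(float)
        _, auc = roc_curve(scores, labels)
        assert auc == pytest.approx(auc_concordance_oracle(scores, labels),
                                    abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1.0, 2.0], [True, True])

    def test_auc_matches_reference_implementation(self, rng):
        from sklearn.metrics import roc_auc_score

        labels = rng.random(500) < 0.4
        scores = rng.standard_normal(500) + labels
        _, auc = roc_curve(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


class TestSubgroupReport:
    def test_composition_strata_partition_cohort(self, nodule_cohort, default_cutoffs):
        calls = call_panel(nodule_cohort, default_cutoffs)
        report, _ = subgroup_report(nodule_cohort, calls, "composition")
        assert len(report) == 4
        assert (report["n_malignant"] + report["n_benign"]).sum() == len(nodule_cohort)

    def test_single_stratum_equals_pooled(self, nodule_cohort, default_cutoffs):
        df = nodule_cohort.copy()
        df["composition"] = "solid"
        calls = call_panel(df, default_cutoffs)
        report, _ = subgroup_report(df, calls, "composition")
        pooled = diagnostic_performance(df["label"].to_numpy(),
                                        calls["panel_positive"].to_numpy())
        row = report.loc["solid"]
        assert row["sensitivity"] == pytest.approx(pooled.sensitivity)
        assert row["specificity"] == pytest.approx(pooled.specificity)
        assert report.loc["GGO", "n_malignant"] == 0  # empty, reported not dropped

    def test_injected_monotone_stage_positivity_recovered(self, rng):
        # generator-independent check: build calls whose positivity rises
        # with stage and confirm the report recovers the monotone ordering
        stages = ["AIS", "I", "II", "III", "IV"]
        n_per = 300
        rows, pos = [], []
        rates = {"AIS": 0.2, "I": 0.35, "II": 0.5, "III": 0.65, "IV": 0.8}
        for s in stages:
            for _ in range(n_per):
                rows.append({"label": "malignant", "stage": s,
                             "size_bin": "8-20", "composition": "solid"})
                pos.append(rng.random() < rates[s])
        df = pd.DataFrame(rows)
        calls = pd.DataFrame({"panel_positive": pos})
        report, pairwise = subgroup_report(df, calls, "stage")
        sens = report["sensitivity"].to_list()
        assert sens == sorted(sens)
        extremes = pairwise[(pairwise["stratum_a"] == "AIS")
                            & (pairwise["stratum_b"] == "IV")]
        assert (extremes["p_value"] < 0.001).all()


class TestMarkerCountScore:
    def test_counts_bounded_and_consistent(self, nodule_cohort, default_cutoffs):
        calls = call_panel(nodule_cohort, default_cutoffs)
        score = marker_count_score(calls)
        assert score.between(0, 7).all()
        assert ((score > 0) == calls["panel_positive"]).all()
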