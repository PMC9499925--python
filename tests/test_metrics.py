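import numpy as np
import pytest
from scipy import stats

from gravinet import (
    auroc,
    compare_groups,
    confusion_at,
    delong_test,
    paired_repeat_ttest,
    relative_improvement,
    youden_threshold,
)
from gravinet.metrics import EvalReport, roc_table

from conftest import make_cohort


def concordance_auroc(scores, labels):
    """O(n^2) count of concordant case-control pairs (ties one half)."""
    pos = scores[labels == 1]
    neg = scores[labels == -1]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([3, 4, 1, 2], [1, 1, -1, -1]) == 1.0

    def test_all_ties_is_half(self):
        assert auroc([5, 5, 5, 5], [1, -1, 1, -1]) == 0.5

    def test_matches_pairwise_concordance(self):
        rng = np.random.default_rng(0)
        scores = np.round(rng.normal(size=50), 1)
        labels = rng.choice([-1, 1], size=50)
        assert abs(auroc(scores, labels) - concordance_auroc(scores, labels)) < 1e-12

    def test_antisymmetry_under_score_negation(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=40)
        labels = rng.choice([-1, 1], size=40)
        assert auroc(-scores, labels) == pytest.approx(1 - auroc(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([1, 2], [1, 1])


class TestConfusionAt:
    def test_published_style_guideline_counts(self):
        # 14/33 cases and 188/1314 controls flagged high-risk
        scores = np.concatenate([np.ones(14), np.zeros(19), np.ones(188), np.zeros(1126)])
        labels = np.concatenate([np.ones(33), -np.ones(1314)]).astype(int)
        sens, spec, ppv, npv = confusion_at(scores, labels, 0.5)
        assert sens == pytest.approx(14 / 33)
        assert spec == pytest.approx(1126 / 1314)
        assert ppv == pytest.approx(14 / 202)
        assert npv == pytest.approx(1126 / 1145)

    def test_threshold_below_all_scores(self):
        with pytest.warns(UserWarning, match="NPV undefined"):
            sens, spec, _, _ = confusion_at([1.0, 2.0], [1, -1], -10.0)
        assert (sens, spec) == (1.0, 0.0)

    def test_threshold_above_all_scores(self):
        with pytest.warns(UserWarning, match="PPV undefined"):
            sens, spec, ppv, _ = confusion_at([1.0, 2.0], [1, -1], 10.0)
        assert (sens, spec) == (0.0, 1.0)
        assert np.isnan(ppv)

    def test_youden_threshold_attains_maximal_j(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=60)
        labels = rng.choice([-1, 1], size=60)
        thr = youden_threshold(scores, labels)
        sens, spec, _, _ = confusion_at(scores, labels, thr)
        j_star = sens + spec - 1
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", UserWarning)  # extreme cuts: PPV undefined
            for t in np.unique(scores):
                s, p, _, _ = confusion_at(scores, labels, t)
                assert s + p - 1 <= j_star + 1e-12


class TestDelong:
    def test_identical_scores_give_p_one(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=50)
        labels = rng.choice([-1, 1], size=50)
        a, b, z, p = delong_test(s, s, labels)
        assert a == b and z == 0.0 and p == 1.0

    def test_monotone_transform_is_rank_invariant(self):
        rng = np.random.default_rng(4)
        s = rng.normal(size=50)
        labels = rng.choice([-1, 1], size=50)
        a, b, z, p = delong_test(s, np.exp(s), labels)
        assert a == pytest.approx(b) and p == 1.0

    def test_z_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(5)
        s1, s2 = rng.normal(size=(2, 80))
        labels = rng.choice([-1, 1], size=80)
        _, _, z, _ = delong_test(s1, s2, labels)
        _, _, z2, _ = delong_test(5 * s1 - 3, s2, labels)
        assert z == pytest.approx(z2)

    def test_standard_error_agrees_with_stratified_bootstrap(self):
        rng = np.random.default_rng(6)
        n1, n0 = 40, 160
        labels = np.concatenate([np.ones(n1), -np.ones(n0)]).astype(int)
        base = np.concatenate([rng.normal(1.0, 1, n1), rng.normal(0, 1, n0)])
        other = 0.6 * base + 0.8 * rng.normal(size=n1 + n0)
        a, b, z, p = delong_test(base, other, labels)
        se_delong = abs(a - b) / abs(z)
        pos_idx = np.flatnonzero(labels == 1)
        neg_idx = np.flatnonzero(labels == -1)
        deltas = []
        for _ in range(2000):
            idx = np.concatenate(
                [rng.choice(pos_idx, n1), rng.choice(neg_idx, n0)]
            )
            deltas.append(auroc(base[idx], labels[idx]) - auroc(other[idx], labels[idx]))
        se_boot = np.std(deltas, ddof=1)
        assert se_delong == pytest.approx(se_boot, rel=0.2)
        p_boot = 2 * stats.norm.sf(abs(a - b) / se_boot)
        assert p == pytest.approx(p_boot, abs=0.05)


class TestScalarComparisons:
    def test_relative_improvement_reference_values(self):
        assert relative_improvement(0.5, 0.5) == 0.0
        assert relative_improvement(0.9, 0.45) == pytest.approx(100.0)
        # (0.885 - 0.710) / 0.710 * 100 = 24.648...
        assert round(relative_improvement(0.885, 0.710), 1) == 24.6

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_improvement(0.9, 0.0)

    def test_paired_ttest_identical_vectors(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            t, p = paired_repeat_ttest([0.8, 0.82, 0.81], [0.8, 0.82, 0.81])
        assert (t, p) == (0.0, 1.0)

    def test_paired_ttest_constant_shift_with_jitter(self):
        rng = np.random.default_rng(7)
        a = 0.85 + 1e-4 * rng.normal(size=20)
        b = a - 0.05 + 1e-4 * rng.normal(size=20)
        t, p = paired_repeat_ttest(a, b)
        assert p < 1e-6 and t > 0

    def test_paired_ttest_matches_hand_formula(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            a, b = rng.normal(size=(2, 12))
            t, p = paired_repeat_ttest(a, b)
            d = a - b
            t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
            assert t == pytest.approx(t_hand)
            assert p == pytest.approx(2 * stats.t.sf(abs(t_hand), len(d) - 1))

    def test_too_few_repeats_rejected(self):
        with pytest.raises(ValueError):
            paired_repeat_ttest([0.8], [0.7])


class TestCompareGroups:
    def _binary_cohort(self, ctrl_pos, ctrl_n, case_pos, case_n):
        from gravinet.cohort import VariableSpec

        x = np.concatenate(
            [
                np.ones(ctrl_pos), np.zeros(ctrl_n - ctrl_pos),
                np.ones(case_pos), np.zeros(case_n - case_pos),
            ]
        ).reshape(-1, 1)
        y = np.concatenate([-np.ones(ctrl_n), np.ones(case_n)]).astype(int)
        spec = (VariableSpec("history_preeclampsia", "binary", "flag"),)
        return make_cohort(x, y, variables=spec)

    def test_rare_factor_uses_fisher_and_is_significant(self):
        # 8/1314 controls vs 4/33 cases with a history of preeclampsia
        cohort = self._binary_cohort(8, 1314, 4, 33)
        stat, p, test = compare_groups(cohort, "history_preeclampsia")
        assert test == "fisher_exact"
        assert p < 0.001

    def test_symmetric_two_by_two_is_p_one(self):
        cohort = self._binary_cohort(1, 2, 1, 2)
        _, p, test = compare_groups(cohort, "history_preeclampsia")
        assert test == "fisher_exact" and p == 1.0

    def test_common_factor_uses_chi2(self):
        cohort = self._binary_cohort(300, 600, 200, 600)
        _, _, test = compare_groups(cohort, "history_preeclampsia")
        assert test == "chi2"

    def test_identical_continuous_groups(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=100)
        x = np.concatenate([base, base]).reshape(-1, 1)
        y = np.concatenate([-np.ones(100), np.ones(100)]).astype(int)
        _, p, test = compare_groups(make_cohort(x, y), "diastolic_bp_early")
        assert test == "welch_t" and p > 0.99

    def test_welch_t_on_generated_groups(self, small_cohort):
        cohort, _, _ = small_cohort
        stat, p, test = compare_groups(cohort, "systolic_bp_early")
        assert test == "welch_t"
        assert p < 0.01  # strong designed group separation


class TestEvalReport:
    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            EvalReport("m", "b", auroc=1.2, sensitivity=0.5, specificity=0.5,
                       ppv=0.1, npv=0.9)

    def test_roc_table_has_monotone_axes(self):
        rng = np.random.default_rng(10)
        t = roc_table(rng.normal(size=30), rng.choice([-1, 1], size=30))
        assert t["fpr"].is_monotonic_increasing
        assert t["tpr"].is_monotonic_increasing
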