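import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from oracles import auc_pairwise_oracle, mw_exact_oracle, threshold_scan_oracle
from epiallele.stats import (
    Contrast,
    bonferroni_adjust,
    compare_all,
    delong_auc_ci,
    estimate_cutoff,
    exact_mann_whitney,
    filter_report,
    forward_select,
    loocv_logistic,
    make_contrasts,
    separation_metrics,
)
from epiallele.variables import VariableMatrix, parse_variable


def matrix_from_values(columns: dict, groups: list, denominator: int = 10_000) -> VariableMatrix:
    """Minimal VariableMatrix over one locus for statistics tests.

    Column names must parse (e.g. "G.C1"); values are snapped to exact
    count/denominator rationals.
    """
    samples = [f"s{i}" for i in range(len(groups))]
    counts = {k: [round(v * denominator) for v in vals] for k, vals in columns.items()}
    values = pd.DataFrame({k: [c / denominator for c in v] for k, v in counts.items()}, index=samples)
    counts = pd.DataFrame(counts, index=samples)
    loci = sorted({parse_variable(k).locus for k in columns})
    denominators = pd.DataFrame({l: denominator for l in loci}, index=samples)
    specs = [parse_variable(k) for k in columns]
    return VariableMatrix(values, counts, denominators, pd.Series(groups, index=samples), specs)


class TestExactMannWhitney:
    def test_worked_example(self):
        assert exact_mann_whitney([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_identical_samples_give_p_one(self):
        assert exact_mann_whitney([1, 2, 3], [1, 2, 3]) == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_full_enumeration_with_and_without_ties(self, seed):
        rng = np.random.default_rng(seed)
        n1 = int(rng.integers(1, 7))
        n2 = int(rng.integers(1, 13 - n1))
        if seed % 2:
            x = rng.integers(0, 4, n1).astype(float)  # heavy ties
            y = rng.integers(0, 4, n2).astype(float)
        else:
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
        assert exact_mann_whitney(x, y) == pytest.approx(mw_exact_oracle(x, y), abs=1e-12)

    def test_p_never_zero(self):
        p = exact_mann_whitney(np.arange(10), np.arange(100, 110))
        assert 0.0 < p <= 1.0


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    st.lists(st.integers(0, 5), min_size=1, max_size=6),
    st.lists(st.integers(0, 5), min_size=1, max_size=6),
)
def test_exact_mann_whitney_property_equals_enumeration(x, y):
    """For any small integer samples (arbitrary tie structure) the exact
    p equals full enumeration over all label assignments."""
    assert exact_mann_whitney(x, y) == pytest.approx(mw_exact_oracle(x, y), abs=1e-12)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 6), st.booleans()), min_size=2, max_size=14))
def test_separation_property_equals_threshold_scan(pairs):
    values = [float(v) for v, _ in pairs]
    labels = [l for _, l in pairs]
    assume(any(labels) and not all(labels))
    o_sens, o_spec, o_complete, _, _ = threshold_scan_oracle(values, labels)
    assert separation_metrics(values, labels) == (o_sens, o_spec, o_complete)


class TestBonferroni:
    def test_worked_example(self):
        assert bonferroni_adjust(1e-6, 3501) == pytest.approx(0.003501)

    def test_cap_at_one(self):
        assert bonferroni_adjust(0.5) == 1.0

    def test_exact_boundary(self):
        assert bonferroni_adjust(0.05 / 3501, 3501) == pytest.approx(0.05)

    def test_monotone(self):
        ps = [bonferroni_adjust(p) for p in (1e-9, 1e-6, 1e-4, 0.01, 1.0)]
        assert ps == sorted(ps) and all(p <= 1 for p in ps)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_adjust(0.5, 0)
        with pytest.raises(ValueError):
            bonferroni_adjust(0.0)


class TestSeparationMetrics:
    def test_disjoint_groups_fully_separate(self):
        sens, spec, complete = separation_metrics(
            [5, 6, 7, 8, 1, 2, 3, 4], [True] * 4 + [False] * 4
        )
        assert (sens, spec, complete) == (100.0, 100.0, True)

    def test_partial_overlap_worked_example(self):
        values = [2, 3, 8, 9, 1, 4, 5, 6]
        labels = [True] * 4 + [False] * 4
        sens, spec, complete = separation_metrics(values, labels)
        assert sens == 50.0 and not complete

    def test_all_identical_values(self):
        assert separation_metrics([1, 1, 1, 1], [True, True, False, False]) == (0.0, 0.0, False)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_threshold_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 16))
        values = rng.integers(0, 6, n).astype(float)
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        o_sens, o_spec, o_complete, _, _ = threshold_scan_oracle(values, labels)
        sens, spec, complete = separation_metrics(values, labels)
        assert (sens, spec, complete) == (o_sens, o_spec, o_complete)


class TestEstimateCutoff:
    def test_geometric_mean_and_ratio(self):
        values = [0.01, 0.02, 0.04, 0.09, 0.12, 0.30]
        labels = [False, False, False, True, True, True]
        cutoff, ratio = estimate_cutoff(values, labels)
        assert cutoff == pytest.approx(0.06)
        assert ratio == pytest.approx(2.25)

    def test_zero_boundary_uses_arithmetic_mean_without_ratio(self):
        cutoff, ratio = estimate_cutoff([0.0, 0.0, 0.1, 0.2], [False, False, True, True])
        assert cutoff == pytest.approx(0.05)
        assert ratio is None

    @pytest.mark.parametrize("seed", range(6))
    def test_overlapping_classes_match_youden_scan(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(6, 20))
        values = rng.integers(0, 8, n).astype(float)
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        _, _, complete, o_thresh, o_score = threshold_scan_oracle(values, labels)
        if complete:
            pytest.skip("fixture happens to separate; covered elsewhere")
        cutoff, ratio = estimate_cutoff(values, labels)
        assert ratio is None
        # the returned threshold must attain the oracle's best sens+spec
        pos = values[labels]
        neg = values[~labels]
        best = max(
            np.mean(pos >= cutoff) + np.mean(neg < cutoff),
            np.mean(pos <= cutoff) + np.mean(neg > cutoff),
        )
        assert best == pytest.approx(o_score, abs=1e-12)


class TestDeLong:
    def test_perfect_predictions_have_unit_auc_and_no_ci(self):
        auc, ci = delong_auc_ci([0, 0, 1, 1], [False, False, True, True])
        assert auc == 1.0 and ci is None

    def test_constant_predictions_give_half(self):
        auc, ci = delong_auc_ci([0.5] * 6, [True, False] * 3)
        assert auc == 0.5

    def test_small_instance_matches_pairwise_counting(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.7, 0.2, 0.4]
        labels = [False, False, True, True, True, False, True]
        auc, ci = delong_auc_ci(scores, labels)
        assert auc == pytest.approx(auc_pairwise_oracle(scores, labels))
        assert ci is not None and 0 <= ci[0] < auc < ci[1] <= 1

    def test_variance_matches_structural_components_by_hand(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.7, 0.2, 0.4])
        labels = np.array([False, False, True, True, True, False, True])
        x, y = scores[labels], scores[~labels]
        psi = np.array([[1.0 if a > b else 0.5 if a == b else 0.0 for b in y] for a in x])
        var = psi.mean(axis=1).var(ddof=1) / len(x) + psi.mean(axis=0).var(ddof=1) / len(y)
        auc, ci = delong_auc_ci(scores, labels)
        half = 1.959963984540054 * np.sqrt(var)
        assert ci == pytest.approx((max(0.0, auc - half), min(1.0, auc + half)), abs=1e-12)

    def test_auc_against_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(2)
        scores = rng.random(40)
        labels = rng.random(40) < 0.4
        labels[0] = True
        labels[1] = False
        auc, _ = delong_auc_ci(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels, scores))

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.random(30)
        labels = rng.random(30) < 0.5
        labels[:2] = [True, False]
        base, _ = delong_auc_ci(scores, labels)
        for f in (np.exp, lambda s: s**3 + 5, lambda s: np.log(s + 1)):
            auc, _ = delong_auc_ci(f(scores), labels)
            assert auc == base


class TestLoocvLogistic:
    def test_completely_separated_predictor_reports_100_without_fitting(self):
        m = matrix_from_values(
            {"G.C1": [0.5, 0.6, 0.7, 0.1, 0.2, 0.3]},
            ["PCa"] * 3 + ["HD"] * 3,
        )
        res = loocv_logistic(m, Contrast("PCa"), ["G.C1"])
        assert (res.accuracy, res.sensitivity, res.specificity, res.auc) == (100, 100, 100, 100)
        assert res.auc_ci is None and res.separated

    def test_uninformative_predictor_near_chance(self):
        rng = np.random.default_rng(0)
        n = 60
        m = matrix_from_values({"G.C1": rng.random(n) * 0.5}, ["PCa", "HD"] * (n // 2))
        res = loocv_logistic(m, Contrast("PCa"), ["G.C1"])
        assert 30 <= res.accuracy <= 70

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(5)
        vals = list(rng.random(12) * 0.2)
        groups = ["PCa"] * 5 + ["HD"] * 7
        m1 = matrix_from_values({"G.C1": vals}, groups)
        perm = rng.permutation(12)
        m2 = matrix_from_values({"G.C1": [vals[i] for i in perm]}, [groups[i] for i in perm])
        r1 = loocv_logistic(m1, Contrast("PCa"), ["G.C1"])
        r2 = loocv_logistic(m2, Contrast("PCa"), ["G.C1"])
        assert r1.accuracy == r2.accuracy and r1.auc == pytest.approx(r2.auc)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(6)
        vals = rng.random(14) * 0.3
        groups = ["PCa"] * 6 + ["HD"] * 8
        m1 = matrix_from_values({"G.C1": vals}, groups)
        r1 = loocv_logistic(m1, Contrast("PCa"), ["G.C1"])
        m2 = matrix_from_values({"G.C1": vals}, groups)
        m2.covariates = pd.DataFrame({"PSA": m1.values["G.C1"] * 37.0 + 4.0})
        r2 = loocv_logistic(m2, Contrast("PCa"), ["PSA"])
        np.testing.assert_allclose(r1.predictions, r2.predictions, atol=1e-6)

    def test_matches_statsmodels_fold_by_fold(self):
        """Dual-route check: held-out probabilities equal a statsmodels GLM
        fit with the same balancing weights in every fold."""
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        n = 18
        groups = ["PCa"] * 8 + ["HD"] * 10
        y = np.array([g == "PCa" for g in groups])
        vals = rng.random(n) * 0.4 + y * 0.1  # weak signal, no separation
        m = matrix_from_values({"G.C1": list(vals)}, groups)
        res = loocv_logistic(m, Contrast("PCa"), ["G.C1"])
        assert not res.separated
        x = m.values["G.C1"].to_numpy()
        for f in range(n):
            tr = np.arange(n) != f
            xtr, ytr = x[tr], y[tr].astype(float)
            mean, sd = xtr.mean(), xtr.std()
            ztr = (xtr - mean) / sd
            npos = ytr.sum()
            w = np.where(ytr > 0.5, len(ytr) / (2 * npos), len(ytr) / (2 * (len(ytr) - npos)))
            glm = sm.GLM(ytr, sm.add_constant(ztr), family=sm.families.Binomial(), var_weights=w)
            fit = glm.fit()
            prob = fit.predict([1.0, (x[f] - mean) / sd])[0]
            assert res.predictions[f] == pytest.approx(prob, abs=1e-5)


class TestForwardSelection:
    def test_stops_after_single_separating_variable(self):
        rng = np.random.default_rng(1)
        cols = {"G.C1": [0.5, 0.6, 0.7, 0.1, 0.2, 0.3], "G.C2": list(rng.random(6))}
        m = matrix_from_values(cols, ["PCa"] * 3 + ["HD"] * 3)
        history = forward_select(m, Contrast("PCa"))
        assert len(history) == 1
        assert history[0]["predictors"] == ("G.C1",)
        assert history[0]["cv_accuracy"] == 100.0

    def test_null_matrix_stays_near_chance(self):
        rng = np.random.default_rng(2)
        n = 40
        cols = {f"G.C{i+1}": list(rng.random(n) * 0.2) for i in range(12)}
        m = matrix_from_values(cols, ["PCa", "HD"] * (n // 2))
        history = forward_select(m, Contrast("PCa"), max_predictors=2)
        if history:  # selection maximizes CV accuracy, so allow optimism
            assert history[-1]["cv_accuracy"] <= 80.0


@pytest.fixture(scope="module")
def small_report(loci, scheme):
    from epiallele.simulate import default_calibrated_model, simulate_pattern_tables
    from epiallele.variables import build_variable_matrix

    model = default_calibrated_model(loci, scheme, seed=11)
    truth = simulate_pattern_tables(model, loci, scheme, reads_per_sample=500)
    matrix = build_variable_matrix(truth.pattern_table, loci, scheme)
    rng = np.random.default_rng(0)
    psa = pd.Series(rng.lognormal(1.5, 0.8, len(matrix.samples)), index=matrix.samples)
    matrix.covariates = pd.DataFrame({"PSA": psa})
    return compare_all(matrix, cv=False), matrix


class TestCompareAll:
    def test_row_count_covers_variables_and_covariates(self, small_report):
        report, matrix = small_report
        assert len(report) == 3 * (1167 + 1)
        assert set(report.contrast) == {"PCa_vs_rest", "HD_vs_rest", "BPH_vs_rest"}

    def test_adjusted_p_uses_fixed_family_and_caps(self, small_report):
        report, _ = small_report
        ok = np.isclose(report.p_adj, np.minimum(1.0, report.p_raw * 3501))
        assert ok.all()

    def test_identical_variable_in_both_groups(self):
        m = matrix_from_values({"G.C1": [0.2] * 8}, ["PCa"] * 4 + ["HD"] * 4)
        report = compare_all(m, contrasts=[Contrast("PCa")], cv=False)
        row = report.iloc[0]
        assert row.p_raw == 1.0 and row.sens_at_100_spec == 0.0

    def test_report_filters(self, small_report):
        report, _ = small_report
        t5 = filter_report(report, "table5")
        assert (t5.complete_separation).all() and (t5.p_adj < 1e-10).all()
        assert len(filter_report(report, "none")) == len(report)
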