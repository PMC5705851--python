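import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcellmon import (
    CohortParams,
    ContingencyTable2x2,
    fisher_exact_2x2,
    logistic_model,
    mann_whitney_u,
    run_paper_analysis,
    simulate_cohort,
    summarize_response,
    threshold_metrics,
)
from bcellmon.simulate import sample_depletion_covariates
from bcellmon.stats import (
    CollinearityError,
    SeparationError,
    median_iqr,
)

from .oracles import fisher_p_enumeration, mann_whitney_p_enumeration


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected_p",
        [
            ((41, 20, 2, 7), 0.023),   # concomitant-IS association
            ((8, 90, 7, 66), 0.789),   # serious infections by depletion
            ((5, 0, 0, 5), 2 / 252),
        ],
    )
    def test_reference_p_values(self, table, expected_p):
        res = fisher_exact_2x2(ContingencyTable2x2(*table))
        assert res.p_two_sided == pytest.approx(expected_p, abs=5e-4)

    def test_odds_ratio_is_cross_product(self):
        res = fisher_exact_2x2(ContingencyTable2x2(41, 20, 2, 7))
        assert res.odds_ratio == pytest.approx(41 * 7 / (20 * 2))

    def test_zero_margin_odds_ratio(self):
        assert fisher_exact_2x2(ContingencyTable2x2(5, 0, 0, 5)).odds_ratio == float(
            "inf"
        )
        assert np.isnan(fisher_exact_2x2(ContingencyTable2x2(0, 0, 0, 5)).odds_ratio)

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)

    @given(
        a=st.integers(0, 15),
        b=st.integers(0, 15),
        c=st.integers(0, 15),
        d=st.integers(0, 15),
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_enumeration_oracle(self, a, b, c, d):
        if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
            return  # degenerate margins: p = 1 by convention, skip
        res = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
        assert res.p_two_sided == pytest.approx(
            fisher_p_enumeration(a, b, c, d), rel=1e-7, abs=1e-12
        )


class TestMannWhitney:
    def test_separated_samples(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0 and p == pytest.approx(0.1)

    def test_identical_samples(self):
        _, p = mann_whitney_u([5.0, 5.0, 5.0], [5.0, 5.0])
        assert p == 1.0

    def test_single_observations(self):
        u, p = mann_whitney_u([1], [2])
        assert u == 0 and p == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1, 2])

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 30)
        y = rng.normal(1, 1, 30)
        _, p = mann_whitney_u(x, y)
        assert 0 < p < 0.05

    @given(
        x=st.lists(st.integers(0, 6), min_size=1, max_size=5),
        y=st.lists(st.integers(0, 6), min_size=1, max_size=5),
    )
    @settings(max_examples=150, deadline=None)
    def test_exact_mode_matches_full_enumeration(self, x, y):
        """Mid-rank exact permutation p equals the pairwise-count oracle,
        ties included, whenever n + m <= 10."""
        _, p = mann_whitney_u(x, y)
        assert p == pytest.approx(mann_whitney_p_enumeration(x, y), abs=1e-12)


class TestThresholdMetrics:
    def test_confusion_matrix_arithmetic(self):
        # 8 true positives, 3 false negatives, 9 true negatives, 1 false positive
        values = [1.0] * 8 + [0.0] * 3 + [0.0] * 9 + [1.0] * 1
        labels = [True] * 11 + [False] * 10
        m = threshold_metrics(values, labels, threshold=0.5)
        assert (m.tp, m.fn, m.tn, m.fp) == (8, 3, 9, 1)
        assert m.sensitivity == pytest.approx(0.727, abs=5e-4)
        assert m.specificity == pytest.approx(0.900, abs=5e-4)

    def test_single_class_metric_is_missing_not_zero(self):
        m = threshold_metrics([1.0, 2.0], [True, True], threshold=0.5)
        assert m.specificity is None and m.sensitivity == 1.0

    def test_perfect_two_point_separation(self):
        m = threshold_metrics(
            [0.2, 0.8], [False, True], threshold=0.5, compute_auc=True
        )
        assert m.sensitivity == 1.0 and m.specificity == 1.0 and m.auc == 1.0

    @given(
        values=st.lists(
            st.floats(0, 1, allow_nan=False), min_size=4, max_size=30
        ),
        data=st.data(),
    )
    @settings(max_examples=200, deadline=None)
    def test_threshold_monotonicity(self, values, data):
        """Raising the threshold never increases sensitivity nor decreases
        specificity."""
        labels = data.draw(
            st.lists(
                st.booleans(), min_size=len(values), max_size=len(values)
            )
        )
        if not (any(labels) and not all(labels)):
            return
        t1 = data.draw(st.floats(0, 1, allow_nan=False))
        t2 = data.draw(st.floats(0, 1, allow_nan=False))
        lo, hi = sorted([t1, t2])
        m_lo = threshold_metrics(values, labels, lo)
        m_hi = threshold_metrics(values, labels, hi)
        assert m_hi.sensitivity <= m_lo.sensitivity
        assert m_hi.specificity >= m_lo.specificity


class TestLogisticModel:
    def test_separation_raises(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 200)
        y = (x > 0).astype(int)
        with pytest.raises(SeparationError):
            logistic_model(y, pd.DataFrame({"x": x}))

    def test_collinear_covariates_raise(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 500)
        X = pd.DataFrame({"x": x, "x_copy": x + rng.normal(0, 0.01, 500)})
        y = (rng.random(500) < 0.5).astype(int)
        with pytest.raises(CollinearityError, match="x"):
            logistic_model(y, X)

    def test_constant_covariate_rejected(self):
        y = np.array([0, 1] * 50)
        with pytest.raises(ValueError, match="constant"):
            logistic_model(y, pd.DataFrame({"x": np.ones(100)}))

    def test_null_covariate_ci_covers_unity(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 2000)
        y = (rng.random(2000) < 0.4).astype(int)
        (est,) = logistic_model(y, pd.DataFrame({"x": x}))
        assert est.ci_low < 1.0 < est.ci_high

    def test_recovers_known_effect(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 4000)
        logit = -0.5 + 0.8 * x
        y = (rng.random(4000) < 1 / (1 + np.exp(-logit))).astype(int)
        (est,) = logistic_model(y, pd.DataFrame({"x": x}))
        assert est.ci_low < np.exp(0.8) < est.ci_high

    def test_complete_case_drops_missing_rows(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 500)
        y = (rng.random(500) < 0.5).astype(int)
        X = pd.DataFrame({"x": x})
        X.loc[:49, "x"] = np.nan
        (est,) = logistic_model(y, X, complete_case=True)
        assert np.isfinite(est.odds_ratio)


class TestDepletionParameterRecovery:
    def test_simulated_coefficients_recovered(self):
        """The generative depletion odds ratios sit inside the fitted 95%
        CIs in the vast majority of replicates."""
        params = CohortParams(n_patients=0, seed=0)
        true_or = {
            "complement_low": params.depletion_or_complement_low,
            "plasmablast_scaled": params.depletion_or_plasmablast_scaled,
        }
        rng = np.random.default_rng(2024)
        covered = {k: 0 for k in true_or}
        n_rep = 100
        for _ in range(n_rep):
            comp, pbs, complete = sample_depletion_covariates(params, 5000, rng)
            X = pd.DataFrame(
                {"complement_low": comp.astype(float), "plasmablast_scaled": pbs}
            )
            for est in logistic_model(complete.astype(int), X):
                if est.ci_low <= true_or[est.covariate] <= est.ci_high:
                    covered[est.covariate] += 1
        for name, k in covered.items():
            assert k >= 0.90 * n_rep, f"{name}: covered in {k}/{n_rep}"


class TestAggregation:
    def test_summarize_response_worked_numbers(self):
        from bcellmon import ResponseCategory as RC

        cats = [RC.MAJOR] * 58 + [RC.PARTIAL] * 38 + [RC.NON_RESPONSE] * 21
        s = summarize_response(cats)
        assert s["n"] == 117
        assert s["responder_pct"] == pytest.approx(100 * 96 / 117)
        assert s["major_pct"] == pytest.approx(100 * 58 / 117)

    def test_median_iqr_lower_interpolation(self):
        s = median_iqr([1, 2, 3, 4, 5, 6, 7, 8])
        assert (s["q1"], s["median"], s["q3"]) == (2.0, 4.0, 6.0)
        assert median_iqr([])["median"] is None

    def test_report_is_deterministic(self):
        cohort = simulate_cohort(CohortParams(n_patients=25, seed=13))
        r1 = run_paper_analysis(cohort).to_json()
        r2 = run_paper_analysis(cohort).to_json()
        assert r1 == r2

    def test_tiny_cohort_flags_insufficient_data(self):
        cohort = simulate_cohort(CohortParams(n_patients=1, seed=2))
        report = run_paper_analysis(cohort)
        assert report.n_patients == 1
        assert (
            report.relapse_prediction.get("insufficient_data")
            or report.relapse_prediction["n"] <= 1
        )
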