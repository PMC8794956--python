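"""Inertia statistics tests: ensemble evaluation, bootstrap CIs, null
comparisons, method comparison, early/late collapse, and the pipeline-level
type-I and specificity properties on miniaturized but complete runs."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neuroinertia.classifiers import (
    LABEL_EMERGENCE,
    LABEL_INDUCTION,
    ClassifierEnsemble,
    TrainedClassifier,
)
from neuroinertia.inertia_analysis import (
    bootstrap_median_ci,
    compare_methods,
    compare_to_null,
    early_late_comparison,
    evaluate_ensemble,
    friedman_test,
)
from neuroinertia.pipeline import analyze_individual
from neuroinertia.synthetic_data import generate_cohort

from conftest import MINI_PARAMS, mini_cohort_config


def _test_meta(n_per_arm=300):
    frames = []
    for source in ("induction", "emergence"):
        step_t = 1800.0 + 4.0 * np.arange(n_per_arm)
        frames.append(pd.DataFrame({
            "source": source, "time_s": step_t, "step_time_s": step_t}))
    # an extra source that must be ignored by evaluation
    frames.append(pd.DataFrame({
        "source": "emergence_induction_arm",
        "time_s": [600.0], "step_time_s": [600.0]}))
    return pd.concat(frames, ignore_index=True)


def _linear_ensemble(weights_biases, method="lda"):
    members = [
        TrainedClassifier(method=method, model=None,
                          weights=np.asarray(w, dtype=float), bias=float(b))
        for w, b in weights_biases
    ]
    return ClassifierEnsemble(members=members, method=method, base_seed=0)


class TestEvaluateEnsemble:
    def test_oracle_classifier_perfect_everywhere(self):
        meta = _test_meta()
        # score dimension 0 encodes the true arm
        X = np.where((meta["source"] == "emergence").to_numpy()[:, None],
                     1.0, -1.0) * np.ones((len(meta), 3))
        ens = _linear_ensemble([(np.array([1.0, 0, 0]), 0.0)] * 5)
        trace = evaluate_ensemble(ens, X, meta,
                                  periods_min=((30.0, 40.0), (40.0, 50.0)))
        assert np.allclose(trace.table["accuracy"], 1.0)
        assert set(trace.table["period"]) == {"30-40", "40-50"}

    def test_coin_flip_near_chance(self, rng):
        meta = _test_meta(n_per_arm=1500)
        X = rng.normal(size=(len(meta), 3))
        ens = _linear_ensemble([(rng.normal(size=3), 0.0) for _ in range(20)])
        trace = evaluate_ensemble(ens, X, meta, periods_min=((30.0, 130.0),))
        accs = trace.accuracies("30-130")
        assert np.abs(np.median(accs) - 0.5) < 0.05

    def test_window_counts_bounded_by_period(self):
        meta = _test_meta(n_per_arm=1500)  # fills minutes 30-130 exactly
        X = np.zeros((len(meta), 1))
        ens = _linear_ensemble([(np.array([1.0]), 1.0)])
        trace = evaluate_ensemble(ens, X, meta, periods_min=((30.0, 130.0),))
        row = trace.table.iloc[0]
        assert row["i_total"] <= 1500 and row["e_total"] <= 1500
        assert row["i_total"] + row["e_total"] == 3000

    def test_empty_period_omitted_with_warning(self):
        meta = _test_meta(n_per_arm=10)
        X = np.zeros((len(meta), 1))
        ens = _linear_ensemble([(np.array([1.0]), 0.0)])
        with pytest.warns(UserWarning, match="empty class"):
            trace = evaluate_ensemble(
                ens, X, meta, periods_min=((30.0, 31.0), (120.0, 130.0)))
        assert set(trace.table["period"]) == {"30-31"}


class TestBootstrapMedianCi:
    def test_constant_values(self):
        med, lo, hi = bootstrap_median_ci(np.full(50, 0.7), seed=1)
        assert (med, lo, hi) == (0.7, 0.7, 0.7)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_median_ci(np.arange(5))

    def test_deterministic_per_seed(self, rng):
        vals = rng.normal(0.5, 0.1, 100)
        assert bootstrap_median_ci(vals, seed=3) == bootstrap_median_ci(vals, seed=3)

    def test_coverage(self):
        """~95% of bootstrap CIs cover the true median over 1000 Gaussian
        replicates."""
        rng = np.random.default_rng(7)
        covered = 0
        n_rep = 1000
        for i in range(n_rep):
            vals = rng.normal(0.0, 1.0, 40)
            _, lo, hi = bootstrap_median_ci(vals, n_boot=800, seed=i)
            covered += lo <= 0.0 <= hi
        assert 0.91 <= covered / n_rep <= 0.985


class TestCompareToNull:
    def test_identical_samples_no_call(self):
        res = compare_to_null(np.full(50, 0.7), np.full(50, 0.7))
        assert res.p_value == 1.0
        assert not res.extra["inertia_call"]

    def test_separated_samples_called(self, rng):
        real = 0.8 + 0.01 * rng.standard_normal(100)
        null = 0.5 + 0.01 * rng.standard_normal(100)
        res = compare_to_null(real, null)
        assert res.p_value < 1e-4
        assert res.extra["inertia_call"]

    def test_type_one_error_rate(self):
        """~5% false calls when both traces come from the same null."""
        rng = np.random.default_rng(11)
        calls = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = 0.5 + 0.02 * rng.standard_normal(80)
            b = 0.5 + 0.02 * rng.standard_normal(80)
            res = compare_to_null(a, b)
            calls += res.extra["inertia_call"]
        # calls require median ordering AND p < 0.05: rate ~ 2.5%
        assert calls / n_rep <= 0.05


class TestFriedman:
    def test_identical_treatments(self):
        X = np.tile(np.arange(6.0)[:, None], (1, 3))
        res = friedman_test(X)
        assert res.p_value == 1.0

    def test_consistent_shift_detected(self, rng):
        base = rng.normal(0.7, 0.05, 6)
        X = np.column_stack([base, base + 0.2])
        res = friedman_test(X)
        assert res.p_value < 0.05

    def test_matches_scipy_for_three_treatments(self, rng):
        X = rng.normal(size=(12, 3))
        ours = friedman_test(X)
        stat, p = stats.friedmanchisquare(*(X[:, j] for j in range(3)))
        assert ours.statistic == pytest.approx(stat, rel=1e-9)
        assert ours.p_value == pytest.approx(p, rel=1e-9)

    def test_compare_methods_bookkeeping(self, rng):
        table = pd.DataFrame({"lda": rng.normal(0.7, 0.1, 6),
                              "svm": rng.normal(0.7, 0.1, 6)},
                             index=[f"m{i}" for i in range(6)])
        res = compare_methods(table)
        assert res.extra["n_blocks"] == 6
        assert res.extra["methods"] == ["lda", "svm"]

    def test_too_few_blocks_rejected(self):
        with pytest.raises(ValueError):
            friedman_test(np.zeros((2, 2)))


class TestEarlyLate:
    def _pairs(self, early, late, individual=1):
        n = len(early)
        return pd.DataFrame({
            "individual": individual, "classifier": np.arange(n),
            "early": early, "late": late,
        })

    def test_identical_periods_tie_branch(self):
        pairs = self._pairs(np.full(30, 0.8), np.full(30, 0.8))
        res = early_late_comparison(pairs)
        assert res.wilcoxon.p_value == 1.0
        assert res.per_individual[0]["direction"] == "none"

    def test_clear_decrease_detected(self, rng):
        frames = [
            self._pairs(0.8 + 0.02 * rng.standard_normal(50),
                        0.55 + 0.02 * rng.standard_normal(50), individual=i)
            for i in range(1, 4)
        ]
        res = early_late_comparison(pd.concat(frames, ignore_index=True))
        assert res.wilcoxon.p_value < 1e-4
        assert res.wilcoxon.extra["decrease"]
        assert all(pi["direction"] == "decrease" and pi["significant"]
                   for pi in res.per_individual)
        assert "C(period)" in res.anova

    def test_sidak_correction_multiplicity(self, rng):
        # a single individual's raw p survives less after correction
        frames = [
            self._pairs(rng.normal(0.7, 0.05, 40),
                        rng.normal(0.7, 0.05, 40), individual=i)
            for i in range(1, 7)
        ]
        res = early_late_comparison(pd.concat(frames, ignore_index=True))
        for pi in res.per_individual:
            assert pi["p_sidak"] >= pi["p_raw"] - 1e-12

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError):
            early_late_comparison(pd.DataFrame({"early": [1.0]}))


class TestEndToEndDynamics:
    def test_collapsing_inertia_late_below_early(self, analyzed_default):
        """On the default collapsing-inertia individual, late-period median
        accuracy falls below the early-period median."""
        res, params = analyzed_default
        trace = res.traces[("lda", False)]
        early = np.median(trace.accuracies("30-50"))
        late = np.median(trace.accuracies("110-130"))
        assert early > 0.6
        assert late < early - 0.1

    def test_real_beats_null_in_early_period(self, analyzed_default):
        res, params = analyzed_default
        real = res.traces[("lda", False)].accuracies("30-50")
        null = res.traces[("lda", True)].accuracies("30-50")
        cmp_res = compare_to_null(real, null)
        assert cmp_res.extra["inertia_call"]

    def test_static_inertia_shows_no_decrease(self):
        """With relaxation far beyond the recording, accuracy does not
        decrease from early to late (5 replicates, miniaturized cohort)."""
        no_decrease = 0
        n_rep = 5
        for rep in range(n_rep):
            cfg = mini_cohort_config(
                relaxation_target_min=1e5, noise_amplitude=0.03)
            cohort = generate_cohort(config=cfg, seed=300 + rep)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = analyze_individual(cohort.individuals[0], MINI_PARAMS,
                                         seed=rep)
            trace = res.traces[("lda", False)]
            t = trace.table.pivot(index="classifier", columns="period",
                                  values="accuracy")
            early, late = t["30-35"], t["35-40"]
            d = late.to_numpy() - early.to_numpy()
            if np.all(d == 0):
                significant_drop = False
            else:
                _, p = stats.wilcoxon(early, late, zero_method="wilcox")
                significant_drop = p < 0.05 and np.median(d) < 0
            no_decrease += not significant_drop
        assert no_decrease >= n_rep - 1

    def test_pipeline_type_one_error_on_null_cohorts(self):
        """Full (miniaturized) pipeline on arm-exchangeable, fast-mixing
        (zero-memory) cohorts makes inertia calls in <= ~5% of 100
        replicates."""
        from neuroinertia.pipeline import AnalysisParams

        spans = {
            "induction": ((0.0, 240.0), (2400.0, 6000.0)),
            "emergence": ((0.0, 240.0), (2400.0, 3600.0), (7800.0, 11400.0)),
        }
        params = AnalysisParams(
            n_classifiers=25, n_per_class=40,
            full_period_min=(30.0, 70.0),
            early_period_min=(30.0, 50.0), late_period_min=(50.0, 70.0),
            test_window_s=(1800.0, 4200.0), bootstrap_samples=500,
        )
        calls = 0
        n_rep = 100
        for rep in range(n_rep):
            cfg = mini_cohort_config(exchangeable=True, spans=spans,
                                     noise_amplitude=0.2)
            cohort = generate_cohort(config=cfg, seed=1000 + rep)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = analyze_individual(cohort.individuals[0], params,
                                         seed=rep)
            real = res.traces[("lda", False)].accuracies("30-70")
            null = res.traces[("lda", True)].accuracies("30-70")
            calls += compare_to_null(real, null).extra["inertia_call"]
        # binomial slack on a true rate <= 5% over 100 replicates
        assert calls <= 8
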