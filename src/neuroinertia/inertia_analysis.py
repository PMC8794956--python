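"""Neural-inertia statistics: ensemble evaluation on the steady-state test
period, chance calibration against shuffled-label nulls, method
comparisons, and the early-vs-late test of inertia collapse.

Neural inertia is operationalized as above-chance balanced accuracy of
induction-vs-emergence classifiers on test windows from minutes 30-130
after the final 0.6% step: if the two arms' spectra were exchangeable the
accuracy would sit at 0.5.  An individual is called inertial when the real
ensemble's accuracies exceed the matched null ensemble's (Kruskal-Wallis,
two-sided, alpha = 0.05) with a higher median.  The two-well model predicts
that this memory decays, so per-classifier mean accuracy over minutes 30-50
is compared with minutes 110-130: pooled across individuals with a Wilcoxon
matched-pairs signed-rank test, and per individual with a two-way ANOVA
(period x individual) followed by Sidak-corrected contrasts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .classifiers import (
    LABEL_EMERGENCE,
    LABEL_INDUCTION,
    ClassifierEnsemble,
    PredictionSummary,
    balanced_accuracy,
)

__all__ = [
    "TEST_WINDOW_S",
    "EARLY_PERIOD_MIN",
    "LATE_PERIOD_MIN",
    "AccuracyTrace",
    "StatResult",
    "EarlyLateResult",
    "InertiaReport",
    "evaluate_ensemble",
    "bootstrap_median_ci",
    "compare_to_null",
    "friedman_test",
    "compare_methods",
    "early_late_comparison",
]

#: test windows span minutes 30-130 of the final 0.6% step
TEST_WINDOW_S = (1800.0, 7800.0)
EARLY_PERIOD_MIN = (30.0, 50.0)
LATE_PERIOD_MIN = (110.0, 130.0)


@dataclass
class AccuracyTrace:
    """Per-classifier balanced accuracy per evaluation period.

    ``table`` columns: classifier, period (label "lo-hi" in minutes),
    accuracy, i_correct/i_total/e_correct/e_total.
    """

    table: pd.DataFrame
    periods_min: tuple
    individual: object = None
    method: str = "lda"
    null: bool = False

    def accuracies(self, period: str | None = None) -> np.ndarray:
        t = self.table
        if period is not None:
            t = t[t["period"] == period]
        return t["accuracy"].to_numpy()

    def period_label(self, period_min) -> str:
        return f"{period_min[0]:g}-{period_min[1]:g}"


def evaluate_ensemble(
    ensemble: ClassifierEnsemble,
    scores: np.ndarray,
    meta: pd.DataFrame,
    periods_min=((30.0, 130.0),),
    test_window_s=TEST_WINDOW_S,
) -> AccuracyTrace:
    """Evaluate every ensemble member on the steady-state test windows.

    ``meta`` rows (aligned with ``scores``) need ``source`` and
    ``step_time_s``; induction-class test windows come from the induction
    recording, emergence-class from the final 0.6% step of the emergence
    recording, both restricted to ``test_window_s``.  Accuracy per period
    pools window counts into one PredictionSummary per classifier (one
    accuracy value per classifier per period, from totals, not an average
    of sub-period accuracies).  Periods with an empty class are omitted
    with a warning.
    """
    meta = meta.reset_index(drop=True)
    lo, hi = test_window_s
    in_test = (meta["step_time_s"] >= lo) & (meta["step_time_s"] < hi)
    is_ind = (meta["source"] == "induction") & in_test
    is_em = (meta["source"] == "emergence") & in_test
    test_idx = np.flatnonzero(is_ind | is_em)
    y_true = np.where(is_em.to_numpy()[test_idx], LABEL_EMERGENCE, LABEL_INDUCTION)
    step_t = meta["step_time_s"].to_numpy()[test_idx]
    preds = ensemble.predict_matrix(scores[test_idx])

    rows = []
    kept_periods = []
    for p in periods_min:
        p_lo, p_hi = 60.0 * p[0], 60.0 * p[1]
        sel = (step_t >= p_lo) & (step_t < p_hi)
        n_i = int(((y_true == LABEL_INDUCTION) & sel).sum())
        n_e = int(((y_true == LABEL_EMERGENCE) & sel).sum())
        if n_i == 0 or n_e == 0:
            warnings.warn(f"period {p} has an empty class; omitted")
            continue
        kept_periods.append(tuple(p))
        label = f"{p[0]:g}-{p[1]:g}"
        yt = y_true[sel]
        for ci in range(ensemble.size):
            summ = _summary(yt, preds[ci][sel])
            rows.append({
                "classifier": ci, "period": label,
                "accuracy": balanced_accuracy(summ),
                "i_correct": summ.i_correct, "i_total": summ.i_total,
                "e_correct": summ.e_correct, "e_total": summ.e_total,
            })
    return AccuracyTrace(
        table=pd.DataFrame(rows), periods_min=tuple(kept_periods),
        method=ensemble.method, null=ensemble.null,
    )


def _summary(y_true, y_pred) -> PredictionSummary:
    is_ind = y_true == LABEL_INDUCTION
    return PredictionSummary(
        i_correct=int((is_ind & (y_pred == LABEL_INDUCTION)).sum()),
        i_total=int(is_ind.sum()),
        e_correct=int((~is_ind & (y_pred == LABEL_EMERGENCE)).sum()),
        e_total=int((~is_ind).sum()),
    )


def bootstrap_median_ci(
    values,
    level: float = 95.0,
    n_boot: int = 10_000,
    seed: int = 0,
):
    """Percentile bootstrap CI of the median; returns (median, lo, hi)."""
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise ValueError("need at least 10 values for a bootstrap CI")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    medians = np.median(values[idx], axis=1)
    alpha = (100.0 - level) / 2.0
    lo, hi = np.percentile(medians, [alpha, 100.0 - alpha])
    return float(np.median(values)), float(lo), float(hi)


@dataclass
class StatResult:
    test: str
    statistic: float
    p_value: float
    n: tuple
    extra: dict = field(default_factory=dict)


def compare_to_null(real_acc, null_acc, alpha: float = 0.05) -> StatResult:
    """Kruskal-Wallis comparison of real vs shuffled-label accuracies.

    The inertia call requires both a higher real median and p < alpha.
    Identical samples short-circuit to p = 1 (the rank test is undefined
    when every value ties).
    """
    real_acc = np.asarray(real_acc, dtype=float)
    null_acc = np.asarray(null_acc, dtype=float)
    pooled = np.concatenate([real_acc, null_acc])
    if np.ptp(pooled) == 0:
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.kruskal(real_acc, null_acc)
    call = bool(np.median(real_acc) > np.median(null_acc) and p < alpha)
    return StatResult(
        test="kruskal-wallis", statistic=float(stat), p_value=float(p),
        n=(real_acc.size, null_acc.size),
        extra={
            "median_real": float(np.median(real_acc)),
            "median_null": float(np.median(null_acc)),
            "inertia_call": call,
        },
    )


def friedman_test(matrix: np.ndarray) -> StatResult:
    """Friedman rank test over blocks x treatments (tie-corrected).

    Implemented directly (rather than via scipy) because the two-treatment
    case — LDA vs SVM across individuals — is legitimate for the statistic
    but rejected by ``scipy.stats.friedmanchisquare``; agreement with scipy
    for k >= 3 is covered by the test-suite.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("Friedman test needs >= 3 blocks and >= 2 treatments")
    n, k = X.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, X)
    rank_sums = ranks.sum(axis=0)
    chi2 = (12.0 / (n * k * (k + 1))) * np.sum(rank_sums ** 2) - 3.0 * n * (k + 1)
    # tie correction
    tie_term = 0.0
    for row in X:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts ** 3 - counts))
    correction = 1.0 - tie_term / (n * (k ** 3 - k))
    if correction <= 0:
        stat, p = 0.0, 1.0
    else:
        stat = chi2 / correction
        p = float(stats.chi2.sf(stat, df=k - 1))
    return StatResult(test="friedman", statistic=float(stat), p_value=float(p),
                      n=(n, k))


def compare_methods(per_individual_accuracy: pd.DataFrame) -> StatResult:
    """Friedman comparison of classifier methods, blocked by individual.

    Input: DataFrame indexed by individual with one column per method
    (e.g. the per-individual median balanced accuracy for LDA and SVM).
    """
    res = friedman_test(per_individual_accuracy.to_numpy())
    res.extra["methods"] = list(per_individual_accuracy.columns)
    res.extra["n_blocks"] = int(per_individual_accuracy.shape[0])
    return res


@dataclass
class EarlyLateResult:
    wilcoxon: StatResult
    anova: dict
    per_individual: list        # dicts: individual, mean_change, p, p_sidak, ...
    early_period_min: tuple = EARLY_PERIOD_MIN
    late_period_min: tuple = LATE_PERIOD_MIN


def early_late_comparison(
    pairs: pd.DataFrame,
    alpha: float = 0.05,
) -> EarlyLateResult:
    """Test whether classifier accuracy decreases from early to late.

    ``pairs`` must have columns individual, classifier, early, late — one
    row per classifier with its mean balanced accuracy over minutes 30-50
    (early) and 110-130 (late).  Pooled inference: two-sided Wilcoxon
    matched-pairs signed-rank over all classifiers.  Per-individual
    inference: two-way ANOVA (period x individual) with Sidak-corrected
    paired contrasts per individual; each contrast reports the direction of
    change.  All-tied pairs yield the documented p = 1 branch.
    """
    for col in ("individual", "classifier", "early", "late"):
        if col not in pairs.columns:
            raise ValueError(f"pairs missing column {col!r}")
    early = pairs["early"].to_numpy(dtype=float)
    late = pairs["late"].to_numpy(dtype=float)
    diffs = late - early
    if np.all(diffs == 0):
        wil = StatResult(test="wilcoxon", statistic=0.0, p_value=1.0,
                         n=(len(diffs),), extra={"note": "all pairs tied"})
    else:
        stat, p = stats.wilcoxon(early, late, alternative="two-sided",
                                 zero_method="wilcox")
        wil = StatResult(test="wilcoxon", statistic=float(stat),
                         p_value=float(p), n=(len(diffs),))
    wil.extra.update({
        "median_early": float(np.median(early)),
        "median_late": float(np.median(late)),
        "decrease": bool(np.median(late) < np.median(early)),
    })

    anova = _two_way_anova(pairs)
    per_ind = _sidak_contrasts(pairs, alpha)
    return EarlyLateResult(wilcoxon=wil, anova=anova, per_individual=per_ind)


def _two_way_anova(pairs: pd.DataFrame) -> dict:
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    long = pd.melt(
        pairs, id_vars=["individual", "classifier"],
        value_vars=["early", "late"], var_name="period", value_name="accuracy",
    )
    if long["individual"].nunique() < 2:
        model = ols("accuracy ~ C(period)", data=long).fit()
    else:
        model = ols("accuracy ~ C(period) * C(individual)", data=long).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return {
        str(idx): {"F": float(row["F"]), "p": float(row["PR(>F)"]),
                   "df": float(row["df"])}
        for idx, row in table.iterrows()
        if np.isfinite(row["F"])
    }


def _sidak_contrasts(pairs: pd.DataFrame, alpha: float) -> list:
    individuals = sorted(pairs["individual"].unique())
    m = len(individuals)
    out = []
    for ind in individuals:
        sub = pairs[pairs["individual"] == ind]
        d = sub["late"].to_numpy(dtype=float) - sub["early"].to_numpy(dtype=float)
        if np.all(d == 0) or d.size < 2:
            p = 1.0
            stat = 0.0
        else:
            stat, p = stats.ttest_rel(sub["late"], sub["early"])
        p_sidak = float(1.0 - (1.0 - min(p, 1.0)) ** m)
        out.append({
            "individual": ind,
            "mean_change": float(np.mean(d)),
            "direction": "decrease" if np.mean(d) < 0 else
                         ("increase" if np.mean(d) > 0 else "none"),
            "statistic": float(stat),
            "p_raw": float(p),
            "p_sidak": p_sidak,
            "significant": bool(p_sidak < alpha),
        })
    return out


@dataclass
class InertiaReport:
    """Machine-readable summary of a cohort analysis."""

    per_individual: list        # dicts with medians, CIs, null comparisons
    method_comparison: dict | None
    early_late: dict | None
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_individual": self.per_individual,
            "method_comparison": self.method_comparison,
            "early_late": self.early_late,
            "config": self.config,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True,
                          default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (StatResult,)):
        return asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
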