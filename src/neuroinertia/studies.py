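"""Headline study conditions, packaged as one-call experiments.

Each function regenerates its synthetic condition from scratch, runs the
relevant pipeline stages and returns the summary quantities: chance
calibration of shuffled-label ensembles on arm-exchangeable data, the
explained-variance calibration of the 50-PC feature space, and the pooled
early-vs-late test of inertia collapse on the default collapsing cohort.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import classifiers as clf
from . import inertia_analysis as ia
from .pipeline import (
    AnalysisParams,
    PipelineConfig,
    analyze_individual,
    features_for_individual,
)
from .synthetic_data import CohortConfig, generate_cohort

__all__ = [
    "null_calibration_study",
    "variance_calibration_study",
    "inertia_collapse_study",
]


def null_calibration_study(
    seed: int = 0,
    n_classifiers: int = 250,
    n_boot: int = 10_000,
) -> dict:
    """Chance calibration: shuffled-label LDA ensemble on exchangeable arms.

    One synthetic individual is generated with symmetric wells (no
    concentration coupling) and randomized initial states, so induction-
    and emergence-labelled recordings are statistically exchangeable and no
    classifier should beat chance.  A shuffled-label LDA ensemble is
    evaluated on the minutes 30-130 test windows; returns the median
    balanced accuracy and its 95% percentile-bootstrap CI.
    """
    # fast mixing (short dwell times) is the zero-memory condition: any
    # residual structure in a recording averages out over the test period
    cohort = generate_cohort(
        n_individuals=1, seed=seed, config=CohortConfig(
            n_individuals=1, exchangeable=True, noise_amplitude=0.15),
    )
    feature_set, _, _ = features_for_individual(cohort.individuals[0])
    ens = clf.train_ensemble(
        feature_set.scores, feature_set.meta, n_members=n_classifiers,
        method="lda", base_seed=seed + 10_000, null=True,
    )
    trace = ia.evaluate_ensemble(
        ens, feature_set.scores, feature_set.meta,
        periods_min=((30.0, 130.0),),
    )
    acc = trace.accuracies("30-130")
    median, lo, hi = ia.bootstrap_median_ci(acc, n_boot=n_boot, seed=seed + 1)
    return {
        "median_accuracy": median, "ci_lo": lo, "ci_hi": hi,
        "n_classifiers": int(acc.size), "chance_in_ci": bool(lo <= 0.5 <= hi),
    }


def variance_calibration_study(seed: int = 0) -> dict:
    """Explained variance of the first 50 PCs for a default individual.

    Builds the 482-dim centered feature matrix over all three recording
    sources of one default-configuration synthetic individual and reports
    the cumulative explained-variance percentage of the first 50 principal
    components (the generator is calibrated to the 70-78% band).
    """
    cohort = generate_cohort(n_individuals=1, seed=seed)
    feature_set, windows, _ = features_for_individual(cohort.individuals[0])
    ev = float(feature_set.explained_variance_ratio.sum())
    return {
        "explained_variance_percent": 100.0 * ev,
        "n_windows": int(windows.n_windows),
        "n_components": int(feature_set.n_components),
    }


def inertia_collapse_study(
    seed: int = 0,
    n_individuals: int = 6,
    n_classifiers: int = 250,
) -> dict:
    """Early-vs-late inertia collapse on the default collapsing cohort.

    Runs the full pipeline on the 6-individual cohort (relaxation target
    40 min), computes each LDA classifier's mean balanced accuracy for
    minutes 30-50 and 110-130 of the test period, pools classifier pairs
    across individuals and returns the two-sided Wilcoxon matched-pairs
    signed-rank p-value along with the period medians.
    """
    config = PipelineConfig(
        cohort=CohortConfig(n_individuals=n_individuals),
        analysis=AnalysisParams(n_classifiers=n_classifiers,
                                include_null=False, bootstrap_samples=2000),
        seed=seed,
    )
    from .pipeline import run_pipeline

    report, _, pairs_table = run_pipeline(config)
    pairs = pairs_table["lda"]
    el = ia.early_late_comparison(pairs)
    return {
        "wilcoxon_p": el.wilcoxon.p_value,
        "n_pairs": int(el.wilcoxon.n[0]),
        "median_early": el.wilcoxon.extra["median_early"],
        "median_late": el.wilcoxon.extra["median_late"],
        "decrease": el.wilcoxon.extra["decrease"],
        "per_individual": el.per_individual,
    }
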