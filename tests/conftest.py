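"""Shared fixtures: small synthetic cohorts and analyzed individuals.

Expensive fixtures are session-scoped so the generator runs once; the mini
spans restrict synthesis to short stretches while keeping the absolute
timing conventions (baseline, 10-30 min training windows, a slice of the
test period) intact.
"""

import numpy as np
import pytest

from neuroinertia.pipeline import AnalysisParams, analyze_individual
from neuroinertia.synthetic_data import CohortConfig, generate_cohort

# short spans that still contain baseline, training and a 10-min test slice
MINI_SPANS = {
    "induction": ((0.0, 240.0), (2400.0, 3600.0), (3600.0, 4200.0)),
    "emergence": ((0.0, 240.0), (2400.0, 3600.0),
                  (7800.0, 9000.0), (9000.0, 9600.0)),
}
MINI_PARAMS = AnalysisParams(
    n_classifiers=25,
    n_per_class=100,
    full_period_min=(30.0, 40.0),
    early_period_min=(30.0, 35.0),
    late_period_min=(35.0, 40.0),
    test_window_s=(1800.0, 2400.0),
    bootstrap_samples=500,
)


def mini_cohort_config(**overrides) -> CohortConfig:
    defaults = dict(n_individuals=1, spans=MINI_SPANS, n_aux_channels=0)
    defaults.update(overrides)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def default_individual():
    """One default-configuration individual (analysis spans)."""
    return generate_cohort(n_individuals=1, seed=42).individuals[0]


@pytest.fixture(scope="session")
def analyzed_default(default_individual):
    """Full per-individual analysis with a reduced (50-member) ensemble."""
    params = AnalysisParams(n_classifiers=50)
    return analyze_individual(default_individual, params, seed=7), params


@pytest.fixture(scope="session")
def mini_pair():
    """One individual on the mini spans (fast pipeline plumbing tests)."""
    cfg = mini_cohort_config(artifact_rate_per_min=0.5)
    return generate_cohort(config=cfg, seed=11).individuals[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
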