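import numpy as np
import pytest

from roifuse import SynthCohortConfig, Effect, cohort_features, generate_cohort, zscore_normalize


@pytest.fixture(scope="session")
def null_cohort():
    """Small two-group cohort with no injected effects."""
    cfg = SynthCohortConfig(n_per_group=20, n_roi=6, n_timepoints=80, seed=11)
    cohort, truth = generate_cohort(cfg)
    return cohort, truth


@pytest.fixture(scope="session")
def effect_cohort():
    """Cohort with a GM shift and an FC delta at ROI 2."""
    cfg = SynthCohortConfig(
        n_per_group=30,
        n_roi=6,
        n_timepoints=100,
        seed=7,
        effects=[
            Effect(roi=2, modality="gm", size=1.2),
            Effect(roi=2, modality="fc", size=0.4, partner=4),
        ],
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_features(null_cohort):
    cohort, _ = null_cohort
    return zscore_normalize(cohort_features(cohort)), cohort.labels
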