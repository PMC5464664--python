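import numpy as np
import pytest

from wqsses import simulate_study
from wqsses.experiments import REDUCED_PREVALENCES, small_spec


@pytest.fixture(scope="session")
def small_study():
    """A compact known-truth study: 4 components, gender-only covariate variation."""
    return simulate_study(
        seed=7,
        n_individuals=1200,
        n_tracts=50,
        bgs_per_tract=3,
        spec=small_spec(4),
        true_weights=np.array([0.4, 0.3, 0.2, 0.1]),
        true_beta1=0.5,
        covariate_prevalences=REDUCED_PREVALENCES,
    )


@pytest.fixture(scope="session")
def full_covariate_study():
    """A study exercising every covariate level (prevalences >= 5% each)."""
    prevalences = {
        "age_band": {"50-54": 0.2, "55-59": 0.2, "60-64": 0.2, "65-69": 0.2, "70-74": 0.2},
        "gender": {"female": 0.5, "male": 0.5},
        "race": {"white": 0.5, "black": 0.1, "asian": 0.1, "american_indian": 0.1,
                 "native_hawaiian": 0.1, "null": 0.1},
        "ethnicity": {"non_hispanic": 0.8, "hispanic": 0.1, "null": 0.1},
        "tobacco": {"never": 0.4, "quit": 0.2, "passive": 0.1, "yes": 0.2, "null": 0.1},
    }
    return simulate_study(
        seed=11,
        n_individuals=1500,
        n_tracts=40,
        bgs_per_tract=3,
        spec=small_spec(3),
        true_weights=np.array([0.5, 0.3, 0.2]),
        true_beta1=0.4,
        covariate_prevalences=prevalences,
    )
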