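import numpy as np
import pandas as pd
import pytest

from ltmatch.episodes import build_episodes
from ltmatch.registry import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort_small():
    """Default-parameter cohort, small n: shared read-only fixture."""
    return generate_cohort(GeneratorConfig(n_candidates=1500, seed=7))


@pytest.fixture(scope="session")
def dataset_small(cohort_small):
    return build_episodes(cohort_small, sampling_seed=7)


@pytest.fixture(scope="session")
def cohort_2k():
    return generate_cohort(GeneratorConfig(n_candidates=2000, seed=13))


def make_toy_registry():
    """Hand-sized registry: 5 candidates, one per outcome plus one
    two-step graft failure, and a 3-donor stream. Used for exact metric
    and reward checks."""
    candidates = pd.DataFrame(
        {
            "candidate_id": [0, 1, 2, 3, 4],
            "blood_type": ["A", "A", "O", "B", "A"],
            "listing_date": [10, 10, 12, 15, 20],
            "age_years": [50.0, 60.0, 45.0, 55.0, 65.0],
            "sex": [0, 1, 0, 1, 0],
            "weight_kg": [80.0, 70.0, 90.0, 75.0, 85.0],
            "height_cm": [170.0, 160.0, 180.0, 165.0, 175.0],
            "on_dialysis": [False, True, False, False, True],
            "on_ventilator": [False] * 5,
            "portal_vein_thrombosis": [False] * 5,
            "bacterial_peritonitis": [False] * 5,
            "encephalopathy_grade": [0, 2, 1, 0, 3],
            "latent_severity": [0.0, 1.0, -0.5, 0.2, 1.5],
            "outcome": [
                "GRAFT_FAILURE",
                "WAITLIST_DEATH",
                "TRANSPLANT_SUCCESS",
                "DELIST_RECOVERED",
                "CENSORED",
            ],
            "outcome_date": [12, 10, 14, 17, 22],
            "donor_id": [0.0, np.nan, 1.0, np.nan, np.nan],
        }
    )
    meld_observations = pd.DataFrame(
        {
            "candidate_id": [0, 0, 1, 2, 2, 3, 3, 4, 4],
            "obs_date": [10, 12, 10, 12, 14, 15, 17, 20, 22],
            "meld": [20, 30, 35, 18, 22, 15, 12, 25, 26],
        }
    )
    donors = pd.DataFrame(
        {
            "donor_id": [0, 1, 2],
            "blood_type": ["A", "O", "A"],
            "recovery_date": [12, 14, 20],
            "age_years": [40.0, 30.0, 60.0],
            "weight_kg": [75.0, 80.0, 70.0],
            "height_cm": [175.0, 180.0, 165.0],
            "dcd": [False, False, True],
            "ph": [7.3, 7.4, 7.1],
            "sodium_meq_l": [140.0, 142.0, 133.0],
            "transaminase_u_l": [40.0, 30.0, 90.0],
            "bilirubin_mg_dl": [0.8, 0.6, 1.5],
            "creatinine_mg_dl": [1.0, 0.9, 1.8],
            "infection": [False, False, True],
            "latent_quality": [-0.5, 1.0, -1.5],
            "disposition": ["USED", "USED", "DISCARDED"],
            "caused_graft_failure": [True, False, False],
        }
    )
    from ltmatch.registry import RegistryTables

    return RegistryTables(candidates, meld_observations, donors, None)


@pytest.fixture()
def toy_registry():
    return make_toy_registry()
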