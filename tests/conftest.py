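import numpy as np
import pandas as pd
import pytest

from petbias.synthetic import CohortTruth, GeneratorConfig, PhantomSpec, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(n_patients=5, n_with_lesions=4, total_lesions=10, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


def make_truth(
    organ_values: dict | None = None,
    lesions: list[dict] | None = None,
    patient_id: str = "P0001",
) -> CohortTruth:
    """Hand-built single-patient truth for phantom/VOI tests.

    ``organ_values`` maps organ -> dict with any of suv_max_ac/suv_max_ce/
    mu_ac/mu_ce overrides; ``lesions`` is a list of dicts with
    suv_max_ac/suv_max_ce.
    """
    defaults = {
        "aorta": dict(suv_max_ac=2.21, suv_max_ce=2.41, mu_ac=0.0992, mu_ce=0.1091),
        "liver": dict(suv_max_ac=2.87, suv_max_ce=3.07, mu_ac=0.0998, mu_ce=0.1044),
        "muscle": dict(suv_max_ac=0.65, suv_max_ce=0.67, mu_ac=0.0981, mu_ce=0.0988),
        "vertebra_L5": dict(suv_max_ac=1.70, suv_max_ce=1.77, mu_ac=0.1215, mu_ce=0.1264),
    }
    organ_rows = []
    for organ, vals in defaults.items():
        vals = {**vals, **(organ_values or {}).get(organ, {})}
        organ_rows.append(
            {
                "patient_id": patient_id,
                "organ": organ,
                "suv_max_ac": vals["suv_max_ac"],
                "suv_max_ce": vals["suv_max_ce"],
                "suv_mean_ac": vals["suv_max_ac"] * 0.8,
                "suv_mean_ce": vals["suv_max_ce"] * 0.8,
                "suv_factor": vals["suv_max_ce"] / vals["suv_max_ac"],
                "mu_ac": vals["mu_ac"],
                "mu_ce": vals["mu_ce"],
                "mu_factor": vals["mu_ce"] / vals["mu_ac"],
                "volume_ccm": 10.0,
            }
        )
    lesion_rows = []
    for k, les in enumerate(lesions or []):
        lesion_rows.append(
            {
                "patient_id": patient_id,
                "lesion_id": f"{patient_id}:lesion{k + 1}",
                "suv_max_ac": les["suv_max_ac"],
                "suv_max_ce": les["suv_max_ce"],
                "suv_mean_ac": les["suv_max_ac"] * 0.65,
                "suv_mean_ce": les["suv_max_ce"] * 0.65,
                "suv_factor": les["suv_max_ce"] / les["suv_max_ac"],
                "suvr_aorta_ratio": np.nan,
                "volume_ccm": 2.0,
            }
        )
    lesion_cols = [
        "patient_id",
        "lesion_id",
        "suv_max_ac",
        "suv_max_ce",
        "suv_mean_ac",
        "suv_mean_ce",
        "suv_factor",
        "suvr_aorta_ratio",
        "volume_ccm",
    ]
    patients = pd.DataFrame(
        {
            "patient_id": [patient_id],
            "weight_kg": [70.0],
            "injected_activity_mbq": [210.0],
            "has_lesions": [bool(lesions)],
            "n_lesions": [len(lesions or [])],
        }
    )
    return CohortTruth(
        config=GeneratorConfig(),
        patients=patients,
        organs=pd.DataFrame(organ_rows),
        lesions=pd.DataFrame(lesion_rows, columns=lesion_cols),
    )


@pytest.fixture(scope="session")
def single_patient_truth():
    return make_truth(lesions=[dict(suv_max_ac=5.68, suv_max_ce=5.97)])


@pytest.fixture(scope="session")
def single_patient_phantom(single_patient_truth):
    from petbias.synthetic import generate_phantom

    return generate_phantom(single_patient_truth, "P0001", PhantomSpec())
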