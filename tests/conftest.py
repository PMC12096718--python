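import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from firstdose import (
    CohortConfig,
    DosingRegimen,
    InfusionEvent,
    PatientCovariates,
    StructuralParameters,
    default_model_path,
    generate_cohort,
    load_population_model,
)


@pytest.fixture(scope="session")
def meropenem_model():
    return load_population_model(default_model_path("meropenem"))


@pytest.fixture(scope="session")
def piperacillin_model():
    return load_population_model(default_model_path("piperacillin"))


@pytest.fixture(scope="session")
def models(meropenem_model, piperacillin_model):
    return {"meropenem": meropenem_model, "piperacillin": piperacillin_model}


@pytest.fixture
def two_cpt_params():
    return StructuralParameters(CL=10.0, V1=10.0, Q=5.0, V2=20.0)


@pytest.fixture
def meropenem_regimen():
    """1 g over 0.5 h then 1 g q8h extended infusions."""
    return DosingRegimen(
        drug="meropenem", loading=InfusionEvent(0.0, 0.5, 1000.0), maintenance_amount=1000.0, tau=8.0
    )


@pytest.fixture
def piperacillin_regimen():
    """4 g over 0.5 h then 4 g q6h extended infusions."""
    return DosingRegimen(
        drug="piperacillin", loading=InfusionEvent(0.0, 0.5, 4000.0), maintenance_amount=4000.0, tau=6.0
    )


@pytest.fixture
def typical_patient():
    return PatientCovariates(
        patient_id="P1", age=58.0, sex="male", weight=83.0, height=178.0,
        serum_creatinine=58.0, sofa=8, trauma_admission=False,
    )


def random_parameters(rng: np.random.Generator) -> StructuralParameters:
    """Physiologically plausible random parameter draw for property tests."""
    return StructuralParameters(
        CL=rng.uniform(3.0, 25.0),
        V1=rng.uniform(8.0, 30.0),
        Q=rng.uniform(2.0, 25.0),
        V2=rng.uniform(5.0, 30.0),
    )


def random_regimen(rng: np.random.Generator, drug: str = "meropenem") -> DosingRegimen:
    return DosingRegimen(
        drug=drug,
        loading=InfusionEvent(0.0, 0.5, float(rng.uniform(500, 4000))),
        maintenance_amount=float(rng.uniform(500, 4000)),
        tau=float(rng.choice([6.0, 8.0, 12.0])),
    )


@pytest.fixture(scope="session")
def small_cohort(models):
    """Deterministic 16-patient mixed cohort used by several suites."""
    cfg = CohortConfig(n_meropenem=8, n_piperacillin=8, seed=42)
    return generate_cohort(cfg, models)
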