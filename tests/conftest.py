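import numpy as np
import pytest

from ihsim import (
    GeneratorConfig,
    build_patient_model,
    load_registry,
    sample_cohort,
    simulate_patient,
)


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def small_cohort(registry):
    """A small deterministic synthetic cohort with models and simulations."""
    records = sample_cohort(config=GeneratorConfig(n_patients=12, seed=42))
    models = [build_patient_model(r, registry) for r in records]
    results = [simulate_patient(m) for m in models]
    return records, models, results
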