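import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import ktxclaims as k

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def code_config():
    return k.default_config()


@pytest.fixture(scope="session")
def sim800():
    """A midsize zero-noise synthetic cohort shared across module tests."""
    bundle, truth = k.generate(k.SimConfig(n_patients=800, seed=7))
    return bundle, truth


@pytest.fixture(scope="session")
def pipeline800(sim800):
    """Cohort, exposure and outcomes computed once for the shared cohort."""
    bundle, truth = sim800
    index_events, retransplants = k.find_index(bundle)
    cohort, report = k.apply_eligibility(index_events, bundle)
    exposure = k.compute_exposure(bundle, cohort)
    outcomes = k.compute_outcomes(bundle, cohort, exposure.timelines, retransplants)
    return {
        "bundle": bundle,
        "truth": truth,
        "index_events": index_events,
        "retransplants": retransplants,
        "cohort": cohort,
        "eligibility": report,
        "exposure": exposure,
        "outcomes": outcomes,
    }


def make_bundle(patients=None, stays=None, deliveries=None, dialysis=None,
                code_config=None):
    """Assemble a small bundle from row dicts, filling schema defaults."""
    from ktxclaims.model import (_coerce_dtypes, PATIENT_COLUMNS, STAY_COLUMNS,
                                 DELIVERY_COLUMNS, DIALYSIS_COLUMNS)

    def frame(rows, cols, defaults):
        if not rows:
            return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
        filled = [{**defaults, **r} for r in rows]
        return pd.DataFrame(filled)[cols]

    b = k.ClaimsBundle(
        patients=_coerce_dtypes("patients", frame(
            patients, PATIENT_COLUMNS,
            {"birth_date": "1970-01-01", "sex": "male", "death_date": None})),
        stays=_coerce_dtypes("stays", frame(
            stays, STAY_COLUMNS,
            {"procedure_codes": "", "principal_diagnosis": "",
             "associated_diagnoses": "", "is_chemo_delivery": 0})),
        deliveries=_coerce_dtypes("deliveries", frame(
            deliveries, DELIVERY_COLUMNS, {"presentation_id": ""})),
        dialysis=_coerce_dtypes("dialysis", frame(dialysis, DIALYSIS_COLUMNS, {})),
        code_config=code_config or k.default_config(),
    )
    return b


@pytest.fixture
def bundle_factory():
    return make_bundle
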