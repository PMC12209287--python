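import pytest

from ordercast import (
    GeneratorConfig,
    JudgmentRecord,
    TreatmentOrderModel,
    generate_labeled_dataset,
)


@pytest.fixture
def case1_record():
    """Severe schizophrenia diagnosis, documented non-compliance, long
    requested duration (5 years -> normalized 1 under the trace
    scalers), legal aid, no substance use, middle-aged male."""
    return JudgmentRecord(
        represented=True, legal_aid=True, age_years=54, sex="male",
        main_diagnosis="paranoid schizophrenia",
        other_diagnoses=[],
        symptoms_text="refused all medication; documented non-compliance",
        substance_use_reported=False, substances=[],
        request_type="treatment",
        treatment_requested="antipsychotic medication",
        accessory_requests=[],
        time_requested_years=5.0, decision="accepted",
        time_granted_years=5.0, acceptance_extent="entire",
    )


@pytest.fixture
def case2_record():
    """Compliant mood-disorder patient, short requested duration
    (0.5 years -> normalized 0), legal aid, no substance use."""
    return JudgmentRecord(
        represented=True, legal_aid=True, age_years=54, sex="male",
        main_diagnosis="major depressive disorder",
        other_diagnoses=[],
        symptoms_text="cooperative and adherent to treatment",
        substance_use_reported=False, substances=[],
        request_type="treatment",
        treatment_requested="antidepressant with follow-up",
        accessory_requests=[],
        time_requested_years=0.5, decision="accepted",
        time_granted_years=0.25, acceptance_extent="partial",
    )


def recovery_config(seed: int = 11) -> GeneratorConfig:
    """Strong-burden-effect generating process for parameter-recovery
    checks: a steep logistic in the burden composite (threshold at
    burden 0.585, between atoms of the burden distribution) with 5%
    label noise, so labels are a noisy deterministic function of the
    features the pipeline reconstructs."""
    return GeneratorConfig(n=1000, seed=seed, beta1=1000.0,
                           beta0=-1000.0 * 0.585, beta2=0.0,
                           label_noise=0.05, denied_prob=0.0)


@pytest.fixture(scope="session")
def recovery_fit():
    """Hybrid pipeline fitted once on the strong-effect synthetic data
    (shared across tests for speed)."""
    ds = generate_labeled_dataset(recovery_config())
    results = TreatmentOrderModel(ds.records).fit(seed=11)
    return ds, results
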