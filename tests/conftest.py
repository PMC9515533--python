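import pytest

import siropk as sp


@pytest.fixture(scope="session")
def final_model() -> sp.PopulationModel:
    """The published sirolimus model used as simulation truth and fixture."""
    return sp.sirolimus_final_model()


@pytest.fixture(scope="session")
def typical_20kg(final_model) -> sp.StructuralParams:
    """Typical structural parameters of a 20 kg child without posaconazole."""
    return sp.typical_params(final_model, 20.0)


@pytest.fixture(scope="session")
def study_dataset(final_model) -> sp.Dataset:
    """Study-sized (n=24) synthetic dataset simulated from the final model
    without the posaconazole effect (the covariate-null base truth)."""
    base_truth = final_model.replace(effects=())
    cohort = sp.generate_cohort(sp.CohortSpec(), seed=7)
    return sp.simulate_observations(cohort, base_truth, seed=8)
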