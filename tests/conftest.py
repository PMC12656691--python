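import pytest

from dermabs import (
    DermalAbsorptionLMM,
    DermalRecord,
    SyntheticTruth,
    generate_logit_dataset,
)

#: Generating values used across recovery checks: the published posterior
#: means for the BfR2024 dataset (residual variance is a generator choice).
TRUE_PARAMS = {
    "alpha": -2.34,
    "beta_concentrate": -2.37,
    "beta_other": -0.24,
    "beta_solid": -0.94,
    "beta_water_based": -0.67,
    "var_substance_dilution": 0.64,
    "var_substance_concentrate": 0.52,
    "var_study": 0.67,
    "var_within": 0.59,
    "rho_substance": 0.20,
}


def make_record(**overrides) -> DermalRecord:
    """A valid replicate record with small compartment fractions."""
    base = dict(
        study_id="study1",
        substance="subA",
        formulation_type="EC",
        target_concentration=100.0,
        is_undiluted_product=True,
        exposure_hours=8.0,
        replicate_id="r1",
        receptor_fluid_fraction=0.02,
        chamber_wash_fraction=0.005,
        skin_fraction=0.01,
        tape_strip_fractions=(0.004, 0.003, 0.005, 0.002, 0.001),
        mean_recovery_percent=100.0,
        absorbed_at_half_duration_percent=40.0,
    )
    base.update(overrides)
    return DermalRecord(**base)


@pytest.fixture(scope="session")
def balanced_cell_weights():
    return {cell: 1.0 for cell in SyntheticTruth().cell_weights}


@pytest.fixture(scope="session")
def small_fit(balanced_cell_weights):
    """One modest fitted model shared by prediction/diagnostic tests."""
    truth = SyntheticTruth.reduced(
        n_substances=25, seed=7, cell_weights=balanced_cell_weights
    )
    prepared, effects = generate_logit_dataset(truth)
    results = DermalAbsorptionLMM(prepared).fit(draws=600, burnin=250, seed=42)
    return truth, prepared, effects, results
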