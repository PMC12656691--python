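"""Synthetic-data generator: ground-truth fidelity and preprocessing round trips."""

import numpy as np
import pandas as pd
import pytest

from dermabs import (
    ConcentrateDefinition,
    ModelParams,
    RawScenario,
    SyntheticTruth,
    generate_logit_dataset,
    generate_raw_records,
    prepare_dataset,
    recovery_filter,
)

from conftest import TRUE_PARAMS


def test_zero_variance_truth_gives_identical_fractions_per_cell():
    degen = ModelParams(
        **{**TRUE_PARAMS, "var_substance_dilution": 0.0,
           "var_substance_concentrate": 0.0, "rho_substance": 0.0,
           "var_study": 0.0, "var_within": 0.0},
        var_resid=0.0,
    )
    truth = SyntheticTruth.reduced(n_substances=10, seed=1, params=degen)
    prepared, _ = generate_logit_dataset(truth)
    per_cell = prepared.table.groupby(["formulation_category", "status"])[
        "fraction_absorbed"
    ].nunique()
    assert (per_cell == 1).all()
    ref = prepared.table.query(
        "formulation_category == 'organic_solvent' and status == 'dilution'"
    )["fraction_absorbed"]
    if len(ref):
        from dermabs import inv_logit

        assert ref.iloc[0] == pytest.approx(inv_logit(TRUE_PARAMS["alpha"]))


def test_substance_effect_sample_covariance_matches_G():
    truth = SyntheticTruth(n_substances=155, seed=4)
    _, effects = generate_logit_dataset(truth)
    B = effects.substance_effects.to_numpy()
    sample_G = np.cov(B.T)
    G = truth.params.G
    assert np.linalg.norm(sample_G - G) / np.linalg.norm(G) < 0.20


def test_high_correlation_truth_yields_correlated_effects():
    params = ModelParams(**{**TRUE_PARAMS, "rho_substance": 0.99})
    truth = SyntheticTruth(n_substances=120, seed=6, params=params)
    _, effects = generate_logit_dataset(truth)
    B = effects.substance_effects.to_numpy()
    assert np.corrcoef(B.T)[0, 1] > 0.9


def test_seed_determinism_and_distinct_seeds():
    t = SyntheticTruth.reduced(n_substances=8, seed=42)
    a, _ = generate_logit_dataset(t)
    b, _ = generate_logit_dataset(SyntheticTruth.reduced(n_substances=8, seed=42))
    pd.testing.assert_frame_equal(a.table, b.table)
    c, _ = generate_logit_dataset(SyntheticTruth.reduced(n_substances=8, seed=43))
    assert not a.table.equals(c.table)


def test_default_scale_mimics_reference_dataset_shape():
    truth = SyntheticTruth(seed=0)
    prepared, _ = generate_logit_dataset(truth)
    t = prepared.table
    assert 0.7 * 6340 < len(t) < 1.3 * 6340
    assert 0.7 * 356 < t["study_id"].nunique() < 1.3 * 356
    assert t["substance"].nunique() == 155
    # both statuses and all four categories represented
    assert t.groupby(["formulation_category", "status"]).ngroups == 8


class TestRawRecords:
    def test_planted_recovery_violations_are_exactly_the_filtered_ones(self):
        truth = SyntheticTruth.reduced(n_substances=12, seed=9)
        scenario = RawScenario(frac_recovery_low=0.2, frac_recovery_high=0.1)
        records, _, _ = generate_raw_records(truth, scenario)
        retained, excluded = recovery_filter(records)
        assert all(90 <= r.mean_recovery_percent <= 110 for r in retained)
        assert all(
            r.mean_recovery_percent < 90 or r.mean_recovery_percent > 110
            for r in excluded
        )
        assert excluded  # scenario actually planted violations

    def test_round_trip_recovers_planted_fractions(self):
        """generate -> preprocess reproduces the generated fractions to 1e-12
        under both tape-strip branches."""
        truth = SyntheticTruth.reduced(n_substances=12, seed=9)
        scenario = RawScenario(frac_complete_absorption=0.5)
        records, planted, _ = generate_raw_records(truth, scenario)
        prepared = prepare_dataset(records, ConcentrateDefinition("commercial"))

        by_gid = {
            gid: grp["fraction_absorbed"].to_numpy()
            for gid, grp in planted.table.groupby("group_id")
        }
        expected = np.array(
            [
                by_gid[rec.replicate_id.rsplit("-r", 1)[0]][
                    int(rec.replicate_id.rsplit("-r", 1)[1]) - 1
                ]
                for rec in records
                if 90 <= rec.mean_recovery_percent <= 110
            ]
        )
        assert len(prepared) == len(expected) > 0
        np.testing.assert_allclose(
            prepared.table["fraction_absorbed"].to_numpy(), expected, rtol=1e-12
        )

    def test_complete_absorption_branch_excludes_all_strip_mass(self):
        """An experiment planted above the 75% half-duration threshold keeps
        none of its tape-strip mass in the absorbed fraction."""
        truth = SyntheticTruth.reduced(n_substances=6, seed=14)
        scenario = RawScenario(
            frac_complete_absorption=1.0, excluded_strip_mass=0.01
        )
        records, planted, _ = generate_raw_records(truth, scenario)
        rec = records[0]
        assert rec.absorbed_at_half_duration_percent >= 75
        direct = (
            rec.receptor_fluid_fraction
            + rec.chamber_wash_fraction
            + rec.skin_fraction
        )
        from dermabs import potential_absorption, select_tape_strips

        assert select_tape_strips(rec) == frozenset()
        assert potential_absorption(rec, select_tape_strips(rec)) == pytest.approx(
            direct
        )
        assert sum(rec.tape_strip_fractions) > 0  # strip mass exists but is excluded


def test_end_to_end_records_to_predictions_runs(balanced_cell_weights):
    truth = SyntheticTruth.reduced(
        n_substances=10, seed=3, cell_weights=balanced_cell_weights
    )
    records, _, _ = generate_raw_records(truth)
    from dermabs import DermalAbsorptionLMM, prediction_table

    prepared = prepare_dataset(records, ConcentrateDefinition("commercial"))
    res = DermalAbsorptionLMM(prepared).fit(draws=100, burnin=50, seed=1)
    table = prediction_table(res.posterior)
    assert len(table) == 24
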