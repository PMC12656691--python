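"""Recovery filter, tape-strip rule, potential absorption and the logit scale."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dermabs import (
    ConcentrateDefinition,
    inv_logit,
    logit,
    potential_absorption,
    prepare_dataset,
    recovery_filter,
    select_tape_strips,
)

from conftest import make_record


class TestRecoveryFilter:
    @pytest.mark.parametrize("recovery,kept", [
        (89.9, False),
        (90.0, True),  # bounds are inclusive: only strictly outside is dropped
        (100.0, True),
        (110.0, True),
        (110.1, False),
        (None, False),  # missing recovery is never silently kept
    ])
    def test_boundaries(self, recovery, kept):
        retained, excluded = recovery_filter([make_record(mean_recovery_percent=recovery)])
        assert (len(retained) == 1) is kept
        assert len(retained) + len(excluded) == 1

    def test_idempotent(self):
        recs = [
            make_record(replicate_id=str(i), mean_recovery_percent=r)
            for i, r in enumerate([85.0, 95.0, 105.0, 115.0])
        ]
        once, _ = recovery_filter(recs)
        twice, dropped = recovery_filter(once)
        assert twice == once and not dropped


class TestTapeStripRule:
    def test_complete_absorption_excludes_all_strips(self):
        rec = make_record(absorbed_at_half_duration_percent=80.0)
        assert select_tape_strips(rec) == frozenset()

    def test_boundary_75_counts_as_complete(self):
        rec = make_record(absorbed_at_half_duration_percent=75.0)
        assert select_tape_strips(rec) == frozenset()

    def test_incomplete_keeps_strips_three_onward(self):
        rec = make_record(absorbed_at_half_duration_percent=74.9)
        assert select_tape_strips(rec) == frozenset({3, 4, 5})

    def test_missing_value_defaults_to_conservative_branch(self):
        rec = make_record(absorbed_at_half_duration_percent=None)
        assert select_tape_strips(rec) == frozenset({3, 4, 5})
        assert select_tape_strips(rec, missing_half_duration_complete=True) == frozenset()


class TestPotentialAbsorption:
    def test_sums_compartments_and_included_strips(self):
        rec = make_record(
            receptor_fluid_fraction=0.02,
            chamber_wash_fraction=0.005,
            skin_fraction=0.01,
            tape_strip_fractions=(0.1, 0.1, 0.005),
        )
        assert potential_absorption(rec, {3}) == pytest.approx(0.04)

    def test_tiny_fraction_is_preserved(self):
        rec = make_record(
            receptor_fluid_fraction=0.0,
            chamber_wash_fraction=0.0,
            skin_fraction=9e-6,
            tape_strip_fractions=(),
        )
        assert potential_absorption(rec, set()) == pytest.approx(9e-6)

    def test_sum_of_one_is_rejected_not_clamped(self):
        rec = make_record(
            replicate_id="bad",
            receptor_fluid_fraction=0.5,
            chamber_wash_fraction=0.2,
            skin_fraction=0.3,
            tape_strip_fractions=(),
        )
        with pytest.raises(ValueError, match="bad"):
            potential_absorption(rec, set())

    @given(st.floats(0.0, 0.2), st.floats(0.0, 0.2), st.floats(1e-9, 0.2))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_each_compartment(self, rf, cw, skin):
        base = make_record(
            receptor_fluid_fraction=rf,
            chamber_wash_fraction=cw,
            skin_fraction=skin,
            tape_strip_fractions=(),
        )
        bumped = make_record(
            receptor_fluid_fraction=rf + 0.01,
            chamber_wash_fraction=cw,
            skin_fraction=skin,
            tape_strip_fractions=(),
        )
        assert potential_absorption(bumped, set()) >= potential_absorption(base, set())


class TestLogit:
    def test_half_maps_to_zero(self):
        assert logit(0.5) == 0.0

    def test_published_intercept_back_transform(self):
        # -2.34 on the logit scale is 8.8% absorption to one decimal
        assert round(inv_logit(-2.34) * 100, 1) == 8.8

    @pytest.mark.parametrize("f", [0.0, 1.0, -0.1, 1.1])
    def test_boundaries_rejected(self, f):
        with pytest.raises(ValueError):
            logit(f)

    @given(st.floats(1e-6, 1 - 1e-6))
    @settings(max_examples=200, deadline=None)
    def test_round_trip_to_machine_precision(self, f):
        assert inv_logit(logit(f)) == pytest.approx(f, rel=1e-12)

    def test_round_trip_grid(self):
        grid = np.logspace(-6, math.log10(1 - 1e-6), 500)
        back = np.array([inv_logit(logit(f)) for f in grid])
        np.testing.assert_allclose(back, grid, rtol=1e-12)


def test_prepare_dataset_builds_group_keys_and_report():
    recs = []
    for study, conc in [("s1", 10.0), ("s1", 100.0), ("s2", 10.0)]:
        for i in range(3):
            recs.append(
                make_record(
                    study_id=study,
                    target_concentration=conc,
                    is_undiluted_product=conc > 50,
                    replicate_id=f"{study}-{conc}-{i}",
                )
            )
    recs.append(make_record(replicate_id="dropped", mean_recovery_percent=80.0))
    prepared = prepare_dataset(recs, ConcentrateDefinition("commercial"))
    assert prepared.report.n_input == 10
    assert prepared.report.n_excluded_recovery == 1
    assert prepared.report.n_retained == 9
    # one group per (study, substance, formulation, concentration)
    assert prepared.table.group_id.nunique() == 3
    grp = prepared.table.groupby("group_id")["target_concentration"].nunique()
    assert (grp == 1).all()
    np.testing.assert_allclose(
        prepared.table["y"],
        [logit(f) for f in prepared.table["fraction_absorbed"]],
    )
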