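"""Fortification (add-then-shrink) and additive (shrink-then-add) scenarios."""

import numpy as np
import pandas as pd
import pytest

from usualintake import (
    FixedAdditionSpec,
    FortificationSpec,
    SupplementProgramSpec,
    SyntheticSpec,
    TransformSpec,
    add_fixed_amounts,
    add_supplement_program,
    apply_fortification,
    estimate_usual_intake,
    generate_population,
)
from usualintake.errors import DataError, DomainError
from usualintake.intervention import parse_intervention, split_interventions

from conftest import make_pseudo


class TestFortification:
    def _dataset(self):
        df = pd.DataFrame({
            "person_id": ["a", "a", "b", "b"],
            "recall_index": [1, 2, 1, 2],
            "intake": [100.0, 120.0, 80.0, 90.0],
            "vehicle_oil": [10.0, 5.0, 0.0, 0.0],
            "weight": 1.0,
        })
        from usualintake import RecallDataset
        return RecallDataset.from_long(df)

    def test_adds_level_times_consumption(self):
        # 100 ug + 10 g oil x 12 ug/g = 220 ug
        out = apply_fortification(self._dataset(), FortificationSpec("oil", 12.0))
        assert out.recalls["intake"].tolist() == [220.0, 180.0, 80.0, 90.0]

    def test_non_consumers_and_zero_level_unchanged(self):
        ds = self._dataset()
        out = apply_fortification(ds, FortificationSpec("oil", 12.0))
        assert out.recalls["intake"].iloc[2:].tolist() == [80.0, 90.0]
        zero = apply_fortification(ds, FortificationSpec("oil", 0.0))
        pd.testing.assert_frame_equal(zero.recalls, ds.recalls)

    def test_original_dataset_untouched(self):
        ds = self._dataset()
        before = ds.recalls["intake"].copy()
        apply_fortification(ds, FortificationSpec("oil", 12.0))
        pd.testing.assert_series_equal(ds.recalls["intake"], before)

    def test_missing_vehicle_and_negative_level_rejected(self):
        with pytest.raises(DataError, match="vehicle_salt"):
            apply_fortification(self._dataset(), FortificationSpec("salt", 1.0))
        with pytest.raises(DomainError):
            FortificationSpec("oil", -1.0)

    def test_constant_vehicle_identity_scale_shifts_usual_intake_exactly(self):
        # with lam=1, constant per-person vehicle consumption v, and v in
        # the prediction function, the add-then-shrink pipeline shifts each
        # person's usual intake by exactly v x level (the fortification
        # addition is absorbed into the vehicle coefficient)
        spec = SyntheticSpec(n_persons=150, n_recalls=2, lam=1.0, seed=31,
                             vehicle_name="oil", vehicle_constant_within_person=True,
                             vehicle_consumer_share=0.6)
        ds, _ = generate_population(spec)
        ds.persons["oil_grams"] = ds.recalls.groupby("person_id")["vehicle_oil"].first()
        level = 0.5
        _, base, _ = estimate_usual_intake(ds, covariates=["oil_grams"],
                                           transform=TransformSpec(1.0),
                                           m=10, seed=4, return_parts=True)
        fortified = apply_fortification(ds, FortificationSpec("oil", level))
        _, after, _ = estimate_usual_intake(fortified, covariates=["oil_grams"],
                                            transform=TransformSpec(1.0),
                                            m=10, seed=4, return_parts=True)
        v = ds.persons["oil_grams"]
        shift = (after.frame.groupby("source_person_id")["usual_food_intake"].mean()
                 - base.frame.groupby("source_person_id")["usual_food_intake"].mean())
        np.testing.assert_allclose(shift.to_numpy(), level * v.to_numpy(), atol=1e-6)


class TestSupplementProgram:
    def test_mean_contribution_converges_to_dose_times_coverage(self):
        pseudo = make_pseudo(np.full(10_000, 100.0))
        out = add_supplement_program(pseudo, SupplementProgramSpec(dose=167.0, coverage=0.9),
                                     seed=1)
        mean = out.frame["supplement_contribution"].mean()
        # Bernoulli sampling error: sd = 167*sqrt(.9*.1/10000) ~ 0.5
        assert mean == pytest.approx(150.3, abs=2.0)

    def test_zero_and_full_coverage(self):
        pseudo = make_pseudo([10.0, 20.0, 30.0])
        none = add_supplement_program(pseudo, SupplementProgramSpec(167.0, 0.0), seed=0)
        assert (none.frame["supplement_contribution"] == 0).all()
        pd.testing.assert_series_equal(none.frame["total_intake"],
                                       pseudo.frame["total_intake"])
        full = add_supplement_program(pseudo, SupplementProgramSpec(167.0, 1.0), seed=0)
        np.testing.assert_allclose(full.frame["total_intake"],
                                   pseudo.frame["total_intake"] + 167.0)

    def test_eligibility_restricts_recipients(self):
        pseudo = make_pseudo([1.0] * 6, child=[True, True, True, False, False, False])
        out = add_supplement_program(
            pseudo, SupplementProgramSpec(30.0, 1.0, eligibility="child"), seed=0)
        assert out.frame["supplement_contribution"].tolist() == [30.0] * 3 + [0.0] * 3

    def test_invalid_coverage_rejected(self):
        with pytest.raises(DomainError):
            SupplementProgramSpec(dose=10.0, coverage=1.5)

    def test_label_derived_stream_is_stable_under_added_scenarios(self):
        pseudo = make_pseudo(np.arange(100, dtype=float))
        spec_a = SupplementProgramSpec(10.0, 0.5, label="prog_a")
        only_a = add_supplement_program(pseudo, spec_a, seed=3)
        b_then_a = add_supplement_program(
            add_supplement_program(pseudo, SupplementProgramSpec(5.0, 0.5, label="prog_b"),
                                   seed=3), spec_a, seed=3)
        got_a_alone = only_a.frame["supplement_contribution"] > 0
        got_a_stacked = (b_then_a.frame["supplement_contribution"]
                         - add_supplement_program(pseudo, SupplementProgramSpec(
                             5.0, 0.5, label="prog_b"), seed=3).frame["supplement_contribution"]) > 0
        pd.testing.assert_series_equal(got_a_alone, got_a_stacked,
                                       check_names=False)


class TestFixedAmounts:
    def test_group_level_breast_milk_amounts(self):
        # regional breast-milk vitamin A contributions for breastfed children
        amounts = {"North": 550.6, "South": 232.2, "Cities": 473.2}
        pseudo = make_pseudo([100.0] * 4,
                             stratum=["North", "South", "Cities", "North"],
                             breastfed=[True, True, True, False])
        out = add_fixed_amounts(pseudo, FixedAdditionSpec(
            amounts, key_column="stratum", eligibility="breastfed"))
        assert out.frame["supplement_contribution"].tolist() == [550.6, 232.2, 473.2, 0.0]
        assert out.frame["total_intake"].tolist() == [650.6, 332.2, 573.2, 100.0]

    def test_individual_level_map(self):
        pseudo = make_pseudo([5.0, 5.0])
        out = add_fixed_amounts(pseudo, FixedAdditionSpec(
            {"p0": 30.0, "p1": 0.0}, key_column="source_person_id"))
        assert out.frame["total_intake"].tolist() == [35.0, 5.0]

    def test_unmapped_eligible_key_is_named(self):
        pseudo = make_pseudo([1.0], stratum=["West"])
        with pytest.raises(DataError, match="West"):
            add_fixed_amounts(pseudo, FixedAdditionSpec({"North": 1.0},
                                                        key_column="stratum"))

    def test_negative_amounts_rejected(self):
        with pytest.raises(DomainError):
            FixedAdditionSpec({"North": -5.0})


class TestComposition:
    def test_conservation_after_any_chain(self):
        pseudo = make_pseudo(np.linspace(50, 150, 200),
                             stratum=["N"] * 100 + ["S"] * 100)
        out = add_supplement_program(pseudo, SupplementProgramSpec(167.0, 0.9), seed=2)
        out = add_fixed_amounts(out, FixedAdditionSpec({"N": 550.6, "S": 232.2},
                                                       key_column="stratum"))
        f = out.frame
        np.testing.assert_array_equal(
            f["total_intake"].to_numpy(),
            f["usual_food_intake"].to_numpy() + f["supplement_contribution"].to_numpy())

    def test_shrink_then_add_steps_commute(self):
        pseudo = make_pseudo(np.linspace(10, 20, 50), stratum=["N"] * 50)
        supp = SupplementProgramSpec(30.0, 0.5, label="x")
        fixed = FixedAdditionSpec({"N": 5.0}, key_column="stratum")
        a = add_fixed_amounts(add_supplement_program(pseudo, supp, seed=9), fixed)
        b = add_supplement_program(add_fixed_amounts(pseudo, fixed), supp, seed=9)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_prevalence_monotone_in_dose_coverage_and_level(self):
        rng = np.random.default_rng(12)
        intakes = rng.normal(100, 30, 4000).clip(1)
        cutoff = 110.0

        def prev(pop):
            f = pop.frame
            w = f["weight_share"].to_numpy()
            return w[f["total_intake"].to_numpy() < cutoff].sum() / w.sum()

        pseudo = make_pseudo(intakes)
        for doses in ([0, 10, 20, 40],):
            prevs = [prev(add_supplement_program(
                pseudo, SupplementProgramSpec(d, 0.9, label="d"), seed=5)) for d in doses]
            assert np.all(np.diff(prevs) <= 1e-12)
        coverages = [0.0, 0.3, 0.6, 1.0]
        prevs = [prev(add_supplement_program(
            pseudo, SupplementProgramSpec(20.0, c, label="c"), seed=5)) for c in coverages]
        assert np.all(np.diff(prevs) <= 1e-12)

    def test_stage_split_is_structural_not_positional(self):
        fort = parse_intervention({"kind": "fortification", "vehicle": "oil", "level": 1.0})
        supp = parse_intervention({"kind": "supplement_program", "dose": 1.0, "coverage": 0.5})
        pre, post = split_interventions([supp, fort])
        assert pre == [fort] and post == [supp]

    def test_unknown_kind_rejected(self):
        with pytest.raises(DataError):
            parse_intervention({"kind": "mystery"})
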