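"""Core model: per-source salt, iodine conversion, scenarios, references."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import saltiodine as si

PARAMS = si.IodizationParams(iodine_mg_per_kg=22.5, retention=0.7)
REFS = si.ReferenceValues(ear_ug=95, rni_ug=150, ul_ug=600)
CURRENT = si.Scenario("current", mode="current", salt_scale=1.0)
POTENTIAL = si.Scenario("potential", mode="potential", salt_scale=1.0)

FOODS = (
    si.FoodProduct("bread", 0.01, 1.0),
    si.FoodProduct("dried_fish", 0.16, 0.0),
    si.FoodProduct("biscuits", 0.014, 1.0),
)


def make_profile(salt=8.5, coverage=0.78, bread=32.0, fish=10.0, bisc=7.0,
                 name="region"):
    return si.RegionProfile(
        name=name,
        household_salt=si.HouseholdSaltSource(salt, coverage),
        consumption={"bread": bread, "dried_fish": fish, "biscuits": bisc})


def brute_force_iodine(profile, foods, params, scenario):
    """Independent recomputation, written directly from the intake equations:
    sum over sources of grams x salt fraction x scale x conc x retention x a."""
    total = 0.0
    a_hh = 1.0 if scenario.mode == "potential" else profile.household_salt.coverage
    total += (profile.household_salt.intake_g_per_day * scenario.salt_scale
              * params.iodine_mg_per_kg * params.retention * a_hh)
    for f in foods:
        if f.name not in profile.consumption:
            continue
        a = 1.0 if scenario.mode == "potential" else f.iodized_fraction
        total += (profile.consumption[f.name] * f.salt_fraction
                  * scenario.salt_scale
                  * params.iodine_mg_per_kg * params.retention * a)
    return total


class TestSaltIntake:
    @pytest.mark.parametrize("grams, fraction, expected", [
        (32.0, 0.01, 0.32),     # bread: displays as 0.3 g
        (10.0, 0.16, 1.6),      # dried fish
        (7.0, 0.014, 0.098),    # biscuits
        (123.4, 0.0, 0.0),      # zero salt content
    ])
    def test_examples(self, grams, fraction, expected):
        assert si.salt_intake(grams, fraction) == pytest.approx(expected)

    @pytest.mark.parametrize("grams, fraction", [(-1, 0.1), (10, -0.1), (10, 1.5)])
    def test_rejects_out_of_range(self, grams, fraction):
        with pytest.raises(si.ValidationError):
            si.salt_intake(grams, fraction)


class TestIodineFromSalt:
    @pytest.mark.parametrize("salt_g, fraction, expected", [
        (8.5, 1.0, 133.875),    # household salt, all iodized -> displays 134
        (8.5, 0.78, 104.4225),  # 78% coverage -> displays 104
        (1.6, 0.0, 0.0),        # non-iodized dried-fish salt
    ])
    def test_examples(self, salt_g, fraction, expected):
        got = si.iodine_from_salt(salt_g, PARAMS, fraction)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_unit_sanity(self):
        # 1 g salt at 22.5 mg/kg, full retention -> exactly 22.5 ug
        p = si.IodizationParams(iodine_mg_per_kg=22.5, retention=1.0)
        assert si.iodine_from_salt(1.0, p, 1.0) == 22.5

    def test_rejects_bad_fraction(self):
        with pytest.raises(si.ValidationError):
            si.iodine_from_salt(1.0, PARAMS, 1.2)

    @settings(derandomize=True, max_examples=200)
    @given(salt=st.floats(0, 100), a=st.floats(0, 1), k=st.floats(0, 10))
    def test_linearity(self, salt, a, k):
        base = si.iodine_from_salt(salt, PARAMS, a)
        assert si.iodine_from_salt(k * salt, PARAMS, a) == pytest.approx(
            k * base, rel=1e-12, abs=1e-12)
        if a * 0.5 <= 1:
            assert si.iodine_from_salt(salt, PARAMS, 0.5 * a) == pytest.approx(
                0.5 * base, rel=1e-12, abs=1e-12)


class TestCompareToReferences:
    @pytest.mark.parametrize("total, which, expected", [
        (165.66, "ear", 174),   # potential vs EAR 95
        (110.98, "rni", 74),    # current vs RNI 150
        (95.0, "ear", 100),     # identity
    ])
    def test_examples(self, total, which, expected):
        pct = dict(zip(("ear", "rni", "ul"),
                       si.compare_to_references(total, REFS)))
        assert si.round_half_up(pct[which]) == expected

    def test_rejects_nonpositive_reference(self):
        with pytest.raises(si.ValidationError):
            si.ReferenceValues(ear_ug=0, rni_ug=150, ul_ug=600)


class TestAssessRegion:
    def test_western_province(self):
        profile = make_profile(salt=7.1, coverage=0.78, bread=45.0,
                               name="Western")
        cur = si.assess_region(profile, FOODS, PARAMS, REFS, CURRENT)
        pot = si.assess_region(profile, FOODS, PARAMS, REFS, POTENTIAL)
        assert si.round_half_up(cur.total_salt_g, 1) == 9.2
        assert si.round_half_up(pot.total_iodine_ug) == 146
        assert si.round_half_up(cur.total_iodine_ug) == 96

    def test_national(self):
        profile = make_profile(name="Sri Lanka")
        cur = si.assess_region(profile, FOODS, PARAMS, REFS, CURRENT)
        pot = si.assess_region(profile, FOODS, PARAMS, REFS, POTENTIAL)
        assert si.round_half_up(cur.total_salt_g, 1) == 10.5
        assert si.round_half_up(pot.total_iodine_ug) == 166
        assert si.round_half_up(cur.total_iodine_ug) == 111

    def test_mode_equivalence_when_all_fractions_one(self):
        foods = tuple(si.FoodProduct(f.name, f.salt_fraction, 1.0) for f in FOODS)
        profile = make_profile(coverage=1.0)
        cur = si.assess_region(profile, foods, PARAMS, REFS, CURRENT)
        pot = si.assess_region(profile, foods, PARAMS, REFS, POTENTIAL)
        assert cur.total_iodine_ug == pot.total_iodine_ug
        assert cur.per_source_iodine_ug == pot.per_source_iodine_ug

    def test_unknown_food_is_configuration_error(self):
        profile = si.RegionProfile(
            "X", si.HouseholdSaltSource(5, 0.5), {"cheese": 3.0})
        with pytest.raises(si.ConfigurationError, match="cheese"):
            si.assess_region(profile, FOODS, PARAMS, REFS, CURRENT)

    # randomized brute-force oracle equivalence on small instances
    @settings(derandomize=True, max_examples=100)
    @given(data=st.data())
    def test_oracle_equivalence(self, data):
        n_foods = data.draw(st.integers(0, 5))
        foods = tuple(
            si.FoodProduct(f"food{i}",
                           data.draw(st.floats(0, 1)),
                           data.draw(st.floats(0, 1)))
            for i in range(n_foods))
        profile = si.RegionProfile(
            "R",
            si.HouseholdSaltSource(data.draw(st.floats(0, 20)),
                                   data.draw(st.floats(0, 1))),
            {f.name: data.draw(st.floats(0, 100)) for f in foods})
        scen = si.Scenario(
            "s", mode=data.draw(st.sampled_from(["potential", "current"])),
            salt_scale=data.draw(st.floats(0.1, 1.0)))
        got = si.assess_region(profile, foods, PARAMS, REFS, scen)
        want = brute_force_iodine(profile, foods, PARAMS, scen)
        assert got.total_iodine_ug == pytest.approx(want, rel=1e-9, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(salt=st.floats(0, 20), cov=st.floats(0, 1),
           bread=st.floats(0, 100), fish=st.floats(0, 50))
    def test_potential_dominates_current(self, salt, cov, bread, fish):
        profile = make_profile(salt=salt, coverage=cov, bread=bread, fish=fish)
        cur = si.assess_region(profile, FOODS, PARAMS, REFS, CURRENT)
        pot = si.assess_region(profile, FOODS, PARAMS, REFS, POTENTIAL)
        assert pot.total_iodine_ug >= cur.total_iodine_ug - 1e-12

    def test_conservation(self, results):
        for r in results:
            assert r.total_salt_g == pytest.approx(
                sum(r.per_source_salt_g.values()), rel=1e-9)
            assert r.total_iodine_ug == pytest.approx(
                sum(r.per_source_iodine_ug.values()), rel=1e-9)


class TestApplyReduction:
    @pytest.mark.parametrize("salt, coverage, bread, expected", [
        (8.5, 0.78, 32.0, 78),   # national
        (7.7, 0.70, 24.0, 63),   # provincial minimum
        (9.6, 0.91, 36.0, 101),  # provincial maximum
    ])
    def test_thirty_percent_reduction(self, salt, coverage, bread, expected):
        profile = make_profile(salt=salt, coverage=coverage, bread=bread)
        red = si.apply_reduction(profile, FOODS, PARAMS, REFS, 0.7)
        assert si.round_half_up(red.total_iodine_ug) == expected

    def test_factor_one_is_identity(self):
        profile = make_profile()
        base = si.assess_region(profile, FOODS, PARAMS, REFS, CURRENT)
        red = si.apply_reduction(profile, FOODS, PARAMS, REFS, 1.0)
        assert red.total_iodine_ug == base.total_iodine_ug
        assert red.total_salt_g == base.total_salt_g

    @pytest.mark.parametrize("factor", [0.0, -0.5, 1.5])
    def test_rejects_bad_factor(self, factor):
        with pytest.raises(si.ValidationError):
            si.apply_reduction(make_profile(), FOODS, PARAMS, REFS, factor)

    @settings(derandomize=True, max_examples=50)
    @given(f=st.floats(0.01, 1.0), salt=st.floats(0, 20),
           bread=st.floats(0, 100))
    def test_scaling_identity(self, f, salt, bread):
        """Every salt and iodine field of the reduced result is f x the
        unreduced field, to machine precision."""
        profile = make_profile(salt=salt, bread=bread)
        base = si.assess_region(profile, FOODS, PARAMS, REFS, CURRENT)
        red = si.apply_reduction(profile, FOODS, PARAMS, REFS, f)
        for src in base.per_source_salt_g:
            assert red.per_source_salt_g[src] == pytest.approx(
                f * base.per_source_salt_g[src], rel=1e-12, abs=1e-15)
            assert red.per_source_iodine_ug[src] == pytest.approx(
                f * base.per_source_iodine_ug[src], rel=1e-12, abs=1e-15)
        assert red.total_iodine_ug == pytest.approx(
            f * base.total_iodine_ug, rel=1e-12, abs=1e-15)


class TestAssembleAssessment:
    def test_total_salt_column(self, results):
        cur = [r for r in results if r.scenario == "current"]
        totals = [si.round_half_up(r.total_salt_g, 1) for r in cur]
        assert totals == [9.2, 10.3, 9.2, 11.4, 11.7, 9.6, 10.3, 9.2, 9.2, 10.5]

    def test_national_is_last_and_own_inputs(self, results, national):
        cur = [r for r in results if r.scenario == "current"]
        assert cur[-1].region == "Sri Lanka"
        # national row is computed from its own inputs, not a province average
        assert national["current"].per_source_salt_g["bread"] == pytest.approx(0.32)

    def test_provincial_current_extremes(self, results):
        cur = {r.region: r for r in results
               if r.scenario == "current" and r.region != "Sri Lanka"}
        rounded = {k: si.round_half_up(v.total_iodine_ug) for k, v in cur.items()}
        assert min(rounded, key=rounded.get) == "North Western"
        assert max(rounded, key=rounded.get) == "Eastern"
        assert rounded["North Western"] == 90
        assert rounded["Eastern"] == 145

    def test_single_region_equals_assess_region(self):
        profile = make_profile(name="Only")
        inputs = si.AssessmentInputs(
            foods=FOODS, regions=(profile,), params=PARAMS, refs=REFS,
            national="Only", scenarios=(CURRENT,))
        [row] = si.assemble_assessment(inputs)
        direct = si.assess_region(profile, FOODS, PARAMS, REFS, CURRENT)
        assert row == direct

    def test_duplicate_regions_rejected(self):
        p = make_profile(name="A")
        inputs_kwargs = dict(foods=FOODS, params=PARAMS, refs=REFS,
                             national="A", scenarios=(CURRENT,))
        with pytest.raises(si.ConfigurationError, match="duplicate"):
            si.assemble_assessment(
                si.AssessmentInputs(regions=(p, p), **inputs_kwargs))

    def test_missing_national_rejected(self):
        p = make_profile(name="A")
        with pytest.raises(si.ConfigurationError, match="national"):
            si.assemble_assessment(si.AssessmentInputs(
                foods=FOODS, regions=(p,), params=PARAMS, refs=REFS,
                national="B", scenarios=(CURRENT,)))


class TestScreening:
    def test_keeps_foods_above_threshold(self):
        foods = FOODS + (si.FoodProduct("cheese", 0.02, 1.0),)
        consumption = {"bread": 32.0, "dried_fish": 10.0, "biscuits": 7.0,
                       "cheese": 1.0}  # cheese: 0.02 g salt -> 0.315 ug
        kept = si.screen_foods(consumption, foods, PARAMS, threshold_ug=1.5)
        assert set(kept) == {"bread", "dried_fish", "biscuits"}
        assert kept["dried_fish"] == pytest.approx(25.2)


class TestDomainValidation:
    @pytest.mark.parametrize("ctor", [
        lambda: si.FoodProduct("", 0.1, 1.0),
        lambda: si.FoodProduct("x", 1.2, 1.0),
        lambda: si.FoodProduct("x", 0.1, -0.2),
        lambda: si.HouseholdSaltSource(-1, 0.5),
        lambda: si.HouseholdSaltSource(5, 1.5),
        lambda: si.IodizationParams(-1, 0.7),
        lambda: si.ReferenceValues(200, 150, 600),
        lambda: si.Scenario("s", mode="other"),
        lambda: si.Scenario("s", salt_scale=0.0),
        lambda: si.RegionProfile("r", si.HouseholdSaltSource(1, 1),
                                 {"bread": -2.0}),
        lambda: si.HouseholdSaltSource(float("nan"), 0.5),
    ])
    def test_invariants_rejected(self, ctor):
        with pytest.raises(si.ValidationError):
            ctor()
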