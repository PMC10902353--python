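import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from livech4 import (
    AnimalTraits,
    Category,
    EnergyBreakdown,
    Subclass,
    ValidationError,
    build_enteric_ef_table,
    ef_dairy,
    ef_enteric_tier1,
    ef_enteric_tier2,
    gross_energy,
    net_energy_components,
    reg,
    rem,
)
from livech4.types import SUBCLASSES, TIER1_CATEGORIES, TIER2_CATEGORIES
from livech4.enteric import METHANE_ENERGY_MJ_PER_KG


def rem_oracle(de):
    return 1.123 - 0.004092 * de + 1.126e-5 * de**2 - 25.4 / de


def reg_oracle(de):
    return 1.164 - 0.00516 * de + 1.308e-5 * de**2 - 37.4 / de


class TestRemReg:
    def test_rem_65(self):
        assert rem(65) == pytest.approx(0.5138, abs=1e-4)

    def test_rem_50_hand_arithmetic(self):
        # 1.123 - 0.2046 + 0.02815 - 0.508
        assert rem(50) == pytest.approx(0.43855, abs=1e-4)

    def test_reg_65_hand_arithmetic(self):
        # 1.164 - 0.3354 + 0.05527 - 0.57538
        assert reg(65) == pytest.approx(0.30849, abs=1e-4)

    def test_reg_45_positive(self):
        assert reg(45) > 0

    @pytest.mark.parametrize("bad", [44.9, 85.1, 0, -10, 200])
    def test_domain_errors(self, bad):
        with pytest.raises(ValidationError):
            rem(bad)
        with pytest.raises(ValidationError):
            reg(bad)

    def test_rem_monotone_grid(self):
        grid = np.linspace(45.0, 85.0, 401)
        vals = [rem(d) for d in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert all(0 < v < 1 for v in vals)

    def test_reg_below_rem_grid(self):
        for de in np.linspace(45.0, 85.0, 401):
            assert 0 < reg(de) < rem(de) < 1

    @given(st.floats(min_value=45, max_value=85))
    def test_matches_oracle(self, de):
        assert rem(de) == pytest.approx(rem_oracle(de), rel=1e-12)
        assert reg(de) == pytest.approx(reg_oracle(de), rel=1e-12)


class TestNetEnergyComponents:
    def test_maintenance_hand_value(self, params):
        # cf=0.322, W=400 -> 0.322 * 400^0.75 = 28.80
        traits = AnimalTraits(body_weight=400, DE=60, Ym=6.5,
                              feeding_situation="stall")
        comps = net_energy_components(
            traits, Subclass.OTHER, params, Category.NONDAIRY_CATTLE
        )
        assert comps.ne_m == pytest.approx(28.80, abs=0.05)
        assert comps.ne_a == 0.0  # stall

    def test_other_subclass_no_repro_energy(self, params):
        traits = params.traits_for(Category.NONDAIRY_CATTLE, Subclass.OTHER)
        comps = net_energy_components(
            traits, Subclass.OTHER, params, Category.NONDAIRY_CATTLE
        )
        assert comps.ne_l == comps.ne_p == comps.ne_g == 0.0

    def test_lactation_hand_value(self, params):
        # 10 kg/day, 3.5% fat -> 10 * (1.47 + 0.40*3.5) = 28.7
        traits = AnimalTraits(
            body_weight=550, DE=65, Ym=6.5, milk_yield=3650.0, milk_fat=3.5,
        )
        comps = net_energy_components(
            traits, Subclass.MATURE_FEMALE, params, Category.DAIRY_CATTLE
        )
        assert comps.ne_l == pytest.approx(28.7, abs=1e-9)

    def test_work_always_zero(self, params):
        for sub in SUBCLASSES[Category.NONDAIRY_CATTLE]:
            traits = params.traits_for(Category.NONDAIRY_CATTLE, sub)
            comps = net_energy_components(
                traits, sub, params, Category.NONDAIRY_CATTLE
            )
            assert comps.ne_work == 0.0

    def test_growth_only_for_young(self, params):
        young = params.traits_for(Category.NONDAIRY_CATTLE, Subclass.YOUNG)
        comps = net_energy_components(
            young, Subclass.YOUNG, params, Category.NONDAIRY_CATTLE
        )
        assert comps.ne_g > 0

    def test_growth_oracle(self, params):
        coeff = params.coefficients
        traits = AnimalTraits(
            body_weight=180, DE=60, Ym=5.5, weight_gain=0.4, mature_weight=400,
        )
        comps = net_energy_components(
            traits, Subclass.YOUNG, params, Category.NONDAIRY_CATTLE
        )
        expected = 22.02 * (180 / (coeff.growth_c * 400)) ** 0.75 * 0.4**1.097
        assert comps.ne_g == pytest.approx(expected, rel=1e-12)

    def test_wool_energy(self, params):
        traits = params.traits_for(Category.SHEEP, Subclass.MATURE_FEMALE)
        comps = net_energy_components(traits, Subclass.MATURE_FEMALE, params,
                                      Category.SHEEP)
        assert comps.ne_wool == pytest.approx(
            params.coefficients.ev_wool * traits.wool_yield / 365.0, rel=1e-12
        )


class TestGrossEnergy:
    def test_maintenance_only_hand_value(self):
        comps = EnergyBreakdown(ne_m=28.8)
        assert gross_energy(comps, 65) == pytest.approx(86.24, abs=0.1)

    def test_all_zero(self):
        assert gross_energy(EnergyBreakdown(), 65) == 0.0

    def test_decreasing_in_de(self):
        comps = EnergyBreakdown(ne_m=30.0, ne_g=5.0)
        vals = [gross_energy(comps, de) for de in np.arange(45, 85.01, 0.5)]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_oracle_identity(self):
        comps = EnergyBreakdown(ne_m=20, ne_a=3, ne_l=10, ne_p=1, ne_g=4, ne_wool=0.1)
        de = 62.0
        expected = ((20 + 3 + 10 + 1) / rem(de) + (4 + 0.1) / reg(de)) / (de / 100)
        assert gross_energy(comps, de) == pytest.approx(expected, rel=1e-12)


class TestEfTier2:
    def test_hand_value(self):
        assert ef_enteric_tier2(250, 6.5) == pytest.approx(106.58, abs=0.01)

    def test_zero_ym(self):
        assert ef_enteric_tier2(250, 0) == 0.0

    def test_homogeneity(self):
        assert ef_enteric_tier2(500, 6.5) == pytest.approx(
            2 * ef_enteric_tier2(250, 6.5), rel=1e-12
        )

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            ef_enteric_tier2(-1, 6.5)
        with pytest.raises(ValidationError):
            ef_enteric_tier2(250, 16)


class TestEfDairy:
    def test_6000(self):
        # 30.8 * 6000^0.2 - 53.6, oracle-evaluated
        assert ef_dairy(6000) == pytest.approx(30.8 * 6000**0.2 - 53.6, rel=1e-12)
        assert ef_dairy(6000) == pytest.approx(121.86, abs=0.05)

    def test_4000(self):
        assert ef_dairy(4000) == pytest.approx(30.8 * 4000**0.2 - 53.6, rel=1e-12)
        assert ef_dairy(4000) == pytest.approx(108.19, abs=0.05)

    def test_increasing_and_concave(self):
        grid = np.linspace(1000, 12000, 200)
        vals = np.array([ef_dairy(m) for m in grid])
        d1 = np.diff(vals)
        assert (d1 > 0).all()
        assert (np.diff(d1) < 0).all()

    def test_daily_units_rejected(self):
        with pytest.raises(ValidationError, match="annual"):
            ef_dairy(15)  # ~daily-scale milk -> negative EF

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            ef_dairy(0)


class TestEfTier1:
    def test_horse_lookup(self, params):
        assert ef_enteric_tier1(Category.HORSE, params) == \
            params.tier1_efs[Category.HORSE].enteric

    def test_swine_is_tier2(self, params):
        with pytest.raises(ValidationError):
            ef_enteric_tier1(Category.SWINE, params)

    def test_unknown_category(self, params):
        with pytest.raises((ValidationError, ValueError)):
            ef_enteric_tier1("dragon", params)


class TestBuildTable:
    def test_table_size(self, params):
        regions, years = ["r1", "r2"], [2010, 2011, 2012]
        table = build_enteric_ef_table(params, regions, years)
        n_tier2_subclasses = sum(len(SUBCLASSES[c]) for c in TIER2_CATEGORIES)
        expected = len(regions) * len(years) * (
            n_tier2_subclasses + len(TIER1_CATEGORIES)
        )
        assert len(table) == expected

    def test_all_positive(self, params):
        table = build_enteric_ef_table(params, ["r1"], [2010])
        assert (table["ef"] > 0).all()

    def test_heavier_region_larger_cattle_ef(self, params):
        traits = pd.DataFrame(
            [
                {"region_id": "north", "year": 2010, "category": "nondairy_cattle",
                 "subclass": "mature_female", "body_weight": 400.0},
                {"region_id": "south", "year": 2010, "category": "nondairy_cattle",
                 "subclass": "mature_female", "body_weight": 300.0},
            ]
        )
        table = build_enteric_ef_table(params, ["north", "south"], [2010], traits)
        sel = table[
            (table["category"] == "nondairy_cattle")
            & (table["subclass"] == "mature_female")
        ].set_index("region_id")["ef"]
        assert sel["north"] > sel["south"]

    def test_dairy_ef_ignores_body_weight(self, params):
        traits = pd.DataFrame(
            [
                {"region_id": "a", "year": 2010, "category": "dairy_cattle",
                 "subclass": "mature_female", "body_weight": 700.0,
                 "milk_yield": np.nan},
                {"region_id": "b", "year": 2010, "category": "dairy_cattle",
                 "subclass": "mature_female", "body_weight": 400.0,
                 "milk_yield": np.nan},
            ]
        )
        table = build_enteric_ef_table(params, ["a", "b"], [2010], traits)
        sel = table[
            (table["category"] == "dairy_cattle")
            & (table["subclass"] == "mature_female")
        ].set_index("region_id")["ef"]
        assert sel["a"] == sel["b"]

    def test_tier1_constant_across_regions_years(self, params):
        table = build_enteric_ef_table(params, ["r1", "r2"], [2010, 2015])
        horse = table[table["category"] == "horse"]["ef"]
        assert horse.nunique() == 1


class TestMonotonicityEnvelope:
    def _ef(self, params, **overrides):
        base = dict(body_weight=400.0, DE=60.0, Ym=6.5,
                    feeding_situation="pasture")
        base.update(overrides)
        traits = AnimalTraits(**base)
        comps = net_energy_components(
            traits, Subclass.OTHER, params, Category.NONDAIRY_CATTLE
        )
        return ef_enteric_tier2(gross_energy(comps, traits.DE), traits.Ym)

    def test_increasing_in_body_weight(self, params):
        efs = [self._ef(params, body_weight=w) for w in np.arange(250, 601, 25)]
        assert all(b > a for a, b in zip(efs, efs[1:]))

    def test_increasing_in_ym(self, params):
        efs = [self._ef(params, Ym=y) for y in np.arange(4.0, 8.01, 0.5)]
        assert all(b > a for a, b in zip(efs, efs[1:]))

    def test_decreasing_in_de(self, params):
        efs = [self._ef(params, DE=d) for d in np.arange(45, 85.01, 2.5)]
        assert all(b < a for a, b in zip(efs, efs[1:]))

    def test_dairy_increasing_in_milk(self):
        efs = [ef_dairy(m) for m in np.arange(3000, 9001, 500)]
        assert all(b > a for a, b in zip(efs, efs[1:]))

    def test_sanity_envelopes(self, params, small_pipeline):
        table = small_pipeline.enteric_ef
        nondairy = table[table["category"] == "nondairy_cattle"]["ef"]
        assert nondairy.between(30, 120).all()
        dairy = table[table["category"] == "dairy_cattle"]["ef"]
        assert dairy.between(60, 180).all()


def test_ef_oracle_1000_draws(params):
    """Tier 2 EFs match a one-line recomputation to 1e-9 relative."""
    rng = np.random.default_rng(123)
    for _ in range(1000):
        ne = rng.uniform(0, 40, size=6)
        de = rng.uniform(45, 85)
        ym = rng.uniform(2, 9)
        comps = EnergyBreakdown(
            ne_m=ne[0], ne_a=ne[1], ne_l=ne[2], ne_p=ne[3], ne_g=ne[4],
            ne_wool=ne[5],
        )
        got = ef_enteric_tier2(gross_energy(comps, de), ym)
        expected = (
            (((ne[0] + ne[1] + ne[2] + ne[3]) / rem_oracle(de)
              + (ne[4] + ne[5]) / reg_oracle(de)) / (de / 100))
            * (ym / 100) * 365 / METHANE_ENERGY_MJ_PER_KG
        )
        assert got == pytest.approx(expected, rel=1e-9)
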