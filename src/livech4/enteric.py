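"""Enteric-fermentation emission factors.

Tier 2 categories get region/year-specific EFs from the gross-energy intake
model; dairy cattle use the milk-production regression instead (their body
weight is not tracked in the activity statistics); minor species fall back
to fixed Tier 1 lookup EFs.

All EFs are kg CH4 head-1 yr-1.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .params import ParameterSet
from .types import (
    SUBCLASSES,
    TIER1_CATEGORIES,
    TIER2_CATEGORIES,
    AnimalTraits,
    Category,
    EnergyBreakdown,
    Subclass,
    ValidationError,
)

#: Energy content of methane, MJ per kg.
METHANE_ENERGY_MJ_PER_KG = 55.65

_DE_LO, _DE_HI = 45.0, 85.0


def _check_de(DE: float) -> None:
    if not (_DE_LO <= DE <= _DE_HI):
        raise ValidationError(f"DE must be in [{_DE_LO}, {_DE_HI}] %, got {DE}")


def rem(DE: float) -> float:
    """Fraction of digestible energy available for maintenance-type uses.

    DE is feed digestibility in percent, valid on [45, 85].
    """
    _check_de(DE)
    return 1.123 - 4.092e-3 * DE + 1.126e-5 * DE**2 - 25.4 / DE


def reg(DE: float) -> float:
    """Fraction of digestible energy available for growth-type uses."""
    _check_de(DE)
    return 1.164 - 5.16e-3 * DE + 1.308e-5 * DE**2 - 37.4 / DE


def net_energy_components(
    traits: AnimalTraits, subclass: Subclass, params: ParameterSet, category: Category
) -> EnergyBreakdown:
    """Daily net-energy components (MJ day-1) for one animal class.

    Lactation and pregnancy energy accrue only to mature females, growth
    energy only to young animals, and work energy is always zero (draft
    animals are excluded from the inventory).  Sheep/goat "other" animals
    can optionally accrue growth energy via ``params.sheep_other_growth``.
    """
    coeff = params.coefficients
    cf = coeff.cf_maintenance.get(category)
    if cf is None:
        raise ValidationError(f"missing cf_maintenance coefficient for {category.value}")
    ca = coeff.ca_activity.get(traits.feeding_situation)
    if ca is None:
        raise ValidationError(
            f"missing ca_activity coefficient for {traits.feeding_situation.value}"
        )

    ne_m = cf * traits.body_weight**0.75
    ne_a = ca * ne_m
    ne_l = ne_p = ne_g = 0.0
    if subclass is Subclass.MATURE_FEMALE:
        milk_daily = traits.milk_yield / 365.0
        ne_l = milk_daily * (1.47 + 0.40 * traits.milk_fat)
        ne_p = coeff.cp_pregnancy * ne_m * traits.pregnancy_fraction
    grows = subclass is Subclass.YOUNG or (
        params.sheep_other_growth
        and subclass is Subclass.OTHER
        and category in (Category.SHEEP, Category.GOAT)
    )
    if grows and traits.weight_gain > 0:
        mature = traits.mature_weight
        if mature is None:
            mf = params.traits.get((category, Subclass.MATURE_FEMALE))
            mature = mf.body_weight if mf is not None else traits.body_weight
        ne_g = (
            22.02
            * (traits.body_weight / (coeff.growth_c * mature)) ** 0.75
            * traits.weight_gain**1.097
        )
    ne_wool = coeff.ev_wool * traits.wool_yield / 365.0
    return EnergyBreakdown(
        ne_m=ne_m,
        ne_a=ne_a,
        ne_l=ne_l,
        ne_work=0.0,
        ne_p=ne_p,
        ne_g=ne_g,
        ne_wool=ne_wool,
        rem=rem(traits.DE),
        reg=reg(traits.DE),
    )


def gross_energy(components: EnergyBreakdown, DE: float) -> float:
    """Gross energy intake (MJ day-1) from net-energy components.

    Maintenance-type components are scaled by REM, growth-type by REG, and
    the sum is divided by digestibility expressed as a fraction (DE/100).
    """
    _check_de(DE)
    r_m, r_g = rem(DE), reg(DE)
    if r_m <= 0 or r_g <= 0:
        raise ValidationError(f"REM/REG non-positive at DE={DE}")
    return (components.maintenance_pool / r_m + components.growth_pool / r_g) / (
        DE / 100.0
    )


def ef_enteric_tier2(GE: float, Ym: float) -> float:
    """Annual enteric EF from gross energy and the methane conversion factor.

    EF = GE * (Ym/100) * 365 / 55.65, in kg CH4 head-1 yr-1.
    """
    if GE < 0:
        raise ValidationError(f"GE must be >= 0, got {GE}")
    if not (0 <= Ym <= 15):
        raise ValidationError(f"Ym must be in [0, 15] %, got {Ym}")
    return GE * (Ym / 100.0) * 365.0 / METHANE_ENERGY_MJ_PER_KG


def ef_dairy(milk_production: float) -> float:
    """Dairy-cattle enteric EF from annual milk production per head.

    EF = 30.8 * production^0.2 - 53.6 with production in kg head-1 yr-1.
    Production so low that the EF would be non-positive almost certainly
    signals a unit mistake (e.g. daily instead of annual milk).
    """
    if milk_production <= 0:
        raise ValidationError(
            f"milk_production must be > 0 kg head-1 yr-1, got {milk_production}"
        )
    ef = 30.8 * milk_production**0.2 - 53.6
    if ef <= 0:
        raise ValidationError(
            f"milk production {milk_production} kg head-1 yr-1 yields EF {ef:.3g} "
            "<= 0; check that production is annual, not daily"
        )
    return ef


def ef_enteric_tier1(category: Category, params: ParameterSet) -> float:
    """Fixed enteric EF for a Tier 1 category (constant over regions/years)."""
    if category in TIER2_CATEGORIES:
        raise ValidationError(
            f"{category.value} is a Tier 2 category; use the gross-energy pathway"
        )
    if category not in TIER1_CATEGORIES:
        raise ValidationError(f"unknown category {category!r}")
    return params.tier1_efs[category].enteric


def ef_for(
    params: ParameterSet,
    category: Category,
    subclass: Subclass,
    traits: AnimalTraits | None = None,
) -> float:
    """Single enteric EF for one (category, subclass), routing by tier."""
    if category in TIER1_CATEGORIES:
        return ef_enteric_tier1(category, params)
    traits = traits if traits is not None else params.traits_for(category, subclass)
    if category is Category.DAIRY_CATTLE:
        milk = traits.milk_yield
        if milk <= 0:
            milk = params.traits_for(category, Subclass.MATURE_FEMALE).milk_yield
        return ef_dairy(milk)
    comps = net_energy_components(traits, subclass, params, category)
    return ef_enteric_tier2(gross_energy(comps, traits.DE), traits.Ym)


def build_enteric_ef_table(
    params: ParameterSet,
    regions: Iterable[str],
    years: Iterable[int],
    trait_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """EF table with one row per (region, year, category, subclass).

    ``trait_table`` optionally overrides default traits per region-year; it
    needs columns region_id, year, category, subclass plus any trait fields
    to override (body_weight, milk_yield, DE, Ym, ...).
    """
    overrides: dict[tuple, dict] = {}
    if trait_table is not None:
        trait_cols = [
            c
            for c in trait_table.columns
            if c not in ("region_id", "year", "category", "subclass")
        ]
        for row in trait_table.itertuples(index=False):
            d = row._asdict()
            key = (d["region_id"], int(d["year"]), d["category"], d["subclass"])
            overrides[key] = {
                c: d[c] for c in trait_cols if pd.notna(d[c])
            }

    rows = []
    regions = list(regions)
    years = list(years)
    for region in regions:
        for year in years:
            for cat in Category:
                for sub in SUBCLASSES[cat]:
                    if cat in TIER1_CATEGORIES:
                        ef = ef_enteric_tier1(cat, params)
                    else:
                        base = params.traits_for(cat, sub)
                        over = overrides.get((region, year, cat.value, sub.value))
                        traits = (
                            base
                            if not over
                            else AnimalTraits(
                                **{
                                    **{
                                        f: getattr(base, f)
                                        for f in (
                                            "body_weight",
                                            "DE",
                                            "Ym",
                                            "feeding_situation",
                                            "weight_gain",
                                            "milk_yield",
                                            "milk_fat",
                                            "wool_yield",
                                            "pregnancy_fraction",
                                            "mature_weight",
                                        )
                                    },
                                    **over,
                                }
                            )
                        )
                        ef = ef_for(params, cat, sub, traits)
                    rows.append(
                        {
                            "region_id": region,
                            "year": year,
                            "category": cat.value,
                            "subclass": sub.value,
                            "pathway": "enteric",
                            "ef": ef,
                        }
                    )
    return pd.DataFrame(rows)
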