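"""Manure-management emission factors and emissions.

Per-head manure EFs combine daily volatile-solids excretion, the manure's
maximum methane-producing capacity (B0), and management-system fractions
weighted by climate-dependent methane conversion factors.  Annualisation is
applied exactly once (daily VS x 365); methane volume converts to mass via
the configured density (0.67 kg m-3 by default).
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .params import ParameterSet
from .types import (
    SUBCLASSES,
    TIER1_CATEGORIES,
    Category,
    ClimateClass,
    ManureProfile,
    ValidationError,
)


def vs_daily(vs_rate: float, animal_mass: float) -> float:
    """Volatile solids excreted per head per day (kg VS head-1 day-1).

    vs_rate is kg VS per 1000 kg animal mass per day; animal_mass is kg.
    """
    if vs_rate <= 0:
        raise ValidationError(f"vs_rate must be > 0, got {vs_rate}")
    if animal_mass <= 0:
        raise ValidationError(f"animal_mass must be > 0, got {animal_mass}")
    return vs_rate * animal_mass / 1000.0


def ef_manure(
    vs_per_day: float,
    b0: float,
    profile: ManureProfile,
    climate: ClimateClass,
    methane_density: float = 0.67,
) -> float:
    """Annual manure EF (kg CH4 head-1 yr-1) for one animal class.

    EF = 365 * VS_daily * B0 * density * sum_S( MCF[S, climate]/100 * frac_S ).
    """
    if vs_per_day < 0:
        raise ValidationError(f"vs_per_day must be >= 0, got {vs_per_day}")
    weighted_mcf = 0.0
    for system, frac in profile.system_fractions.items():
        if frac == 0:
            continue
        try:
            mcf = profile.mcf[(system, climate)]
        except KeyError:
            raise ValidationError(
                f"missing MCF for ({system.value}, {climate.value})"
            ) from None
        weighted_mcf += mcf / 100.0 * frac
    return 365.0 * vs_per_day * b0 * methane_density * weighted_mcf


def build_manure_ef_table(
    params: ParameterSet,
    regions: Iterable[str],
    years: Iterable[int],
    trait_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Manure EF table, one row per (region, year, category, subclass, climate).

    Tier 2 categories use the VS pathway with the subclass body weight as
    animal mass (overridable per region-year via ``trait_table``); Tier 1
    categories carry their fixed EF replicated across climate classes so the
    downstream join is uniform.
    """
    weight_over: dict[tuple, float] = {}
    if trait_table is not None and "body_weight" in trait_table.columns:
        for row in trait_table.itertuples(index=False):
            if pd.notna(row.body_weight):
                weight_over[
                    (row.region_id, int(row.year), row.category, row.subclass)
                ] = float(row.body_weight)

    rows = []
    for region in regions:
        for year in years:
            for cat in Category:
                for sub in SUBCLASSES[cat]:
                    for climate in ClimateClass:
                        if cat in TIER1_CATEGORIES:
                            ef = params.tier1_efs[cat].manure
                        else:
                            profile = params.manure[cat]
                            mass = weight_over.get(
                                (region, year, cat.value, sub.value),
                                params.traits_for(cat, sub).body_weight,
                            )
                            ef = ef_manure(
                                vs_daily(profile.vs_rate, mass),
                                profile.b0,
                                profile,
                                climate,
                                params.methane_density,
                            )
                        rows.append(
                            {
                                "region_id": region,
                                "year": year,
                                "category": cat.value,
                                "subclass": sub.value,
                                "climate_class": climate.value,
                                "pathway": "manure",
                                "ef": ef,
                            }
                        )
    return pd.DataFrame(rows)


def manure_emissions(
    panel: pd.DataFrame,
    manure_ef_table: pd.DataFrame,
    params: ParameterSet,
    climate: pd.DataFrame,
) -> pd.DataFrame:
    """Manure-pathway emissions per city-year-category, in Gg CH4.

    Convenience wrapper around the full inventory computation restricted to
    the manure pathway; see :func:`livech4.inventory.compute_emissions`.
    """
    from .inventory import _pathway_emissions

    return _pathway_emissions(panel, manure_ef_table, params, climate, "manure")
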