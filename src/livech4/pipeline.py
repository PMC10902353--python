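"""End-to-end convenience wrapper: synthesise, gap-fill, build EFs, compute."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .enteric import build_enteric_ef_table
from .gapfill import GapfillReport, fill_panel
from .inventory import InventoryCube, compute_emissions
from .manure import build_manure_ef_table
from .params import ParameterSet, load_parameter_set
from .synthetic import (
    SyntheticSpec,
    generate_activity_panel,
    generate_trait_and_climate_tables,
)


@dataclass
class PipelineResult:
    panel: pd.DataFrame
    meat: pd.DataFrame
    traits: pd.DataFrame
    climate: pd.DataFrame
    enteric_ef: pd.DataFrame
    manure_ef: pd.DataFrame
    cube: InventoryCube
    gapfill_report: GapfillReport
    params: ParameterSet


def run_synthetic_pipeline(
    spec: SyntheticSpec, params: ParameterSet | None = None
) -> PipelineResult:
    """Generate a synthetic panel and run the full inventory on it."""
    params = params if params is not None else load_parameter_set()
    synth = generate_activity_panel(spec, params)
    traits, climate = generate_trait_and_climate_tables(spec, params)
    filled, report = fill_panel(synth.panel, synth.meat, params)
    regions = sorted(filled["province_id"].unique())
    years = spec.year_list
    enteric_ef = build_enteric_ef_table(params, regions, years, traits)
    manure_ef = build_manure_ef_table(params, regions, years, traits)
    cube = compute_emissions(filled, enteric_ef, manure_ef, params, climate)
    return PipelineResult(
        panel=filled,
        meat=synth.meat,
        traits=traits,
        climate=climate,
        enteric_ef=enteric_ef,
        manure_ef=manure_ef,
        cube=cube,
        gapfill_report=report,
        params=params,
    )
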