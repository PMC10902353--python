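"""Emission assembly, hierarchical aggregation and dataset export.

Emissions are accumulated per city-year-category-pathway with average
lifespan weighting: both the year-end stock and the animals slaughtered
during the year emit, each for its own number of months.  Output unit is
Gg CH4 per year throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .params import ParameterSet, expand_subclasses
from .types import RUMINANTS, Category, ValidationError

#: Files written by :func:`export_dataset`, in order.
EXPORT_FILES = (
    "city_total_emissions",
    "city_enteric_emissions",
    "city_manure_emissions",
    "city_ruminant_split",
    "national_provincial_emissions",
    "category_national_series",
)


def _lifespan_frame(params: ParameterSet) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "category": cat.value,
                "als_stock": ls.stock,
                "als_slaughtered": ls.slaughtered,
            }
            for cat, ls in params.lifespans.items()
        ]
    )


def _pathway_emissions(
    panel: pd.DataFrame,
    ef_table: pd.DataFrame,
    params: ParameterSet,
    climate: pd.DataFrame | None,
    pathway: str,
) -> pd.DataFrame:
    """Per city-year-category emissions (Gg) for one pathway."""
    df = panel.copy()
    df = df.merge(_lifespan_frame(params), on="category", how="left", validate="m:1")
    if df["als_stock"].isna().any():
        missing = sorted(df.loc[df["als_stock"].isna(), "category"].unique())
        raise ValidationError([f"missing lifespan for {c}" for c in missing])
    df["weighted_heads"] = (
        df["stock_head"] * df["als_stock"]
        + df["slaughtered_head"] * df["als_slaughtered"]
    ) / 12.0

    ef_keys = ["region_id", "year", "category", "subclass"]
    if pathway == "manure":
        if climate is None:
            raise ValidationError("manure pathway requires climate records")
        clim = climate[["city_id", "year", "climate_class"]]
        df = df.merge(clim, on=["city_id", "year"], how="left", validate="m:1")
        if df["climate_class"].isna().any():
            missing = df.loc[
                df["climate_class"].isna(), ["city_id", "year"]
            ].drop_duplicates()
            raise ValidationError(
                [
                    f"missing climate record for ({r.city_id}, {r.year})"
                    for r in missing.itertuples(index=False)
                ][:20]
            )
        ef_keys = ef_keys + ["climate_class"]
    ef = ef_table.rename(columns={"ef": "ef_value"})[
        [c for c in ef_keys if c != "region_id"] + ["region_id", "ef_value"]
    ]
    df = df.merge(
        ef,
        left_on=["province_id"] + [k for k in ef_keys if k != "region_id"],
        right_on=["region_id"] + [k for k in ef_keys if k != "region_id"],
        how="left",
        validate="m:1",
    )
    if df["ef_value"].isna().any():
        missing = df.loc[
            df["ef_value"].isna(), ["province_id", "year", "category", "subclass"]
        ].drop_duplicates()
        raise ValidationError(
            [
                f"no {pathway} EF for {tuple(r)}"
                for r in missing.itertuples(index=False)
            ][:20]
        )
    df["emissions_gg"] = df["weighted_heads"] * df["ef_value"] / 1e6
    out = (
        df.groupby(["city_id", "province_id", "year", "category"], as_index=False)[
            "emissions_gg"
        ]
        .sum()
        .assign(pathway=pathway)
    )
    return out


@dataclass
class InventoryCube:
    """Emissions indexed by (city, province, year, category, pathway)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"city_id", "province_id", "year", "category", "pathway", "emissions_gg"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValidationError(f"cube missing columns {sorted(missing)}")
        if len(self.records) and (self.records["emissions_gg"] < 0).any():
            raise ValidationError("negative emissions in cube")

    def city_totals(self) -> pd.DataFrame:
        """Total (enteric + manure) emissions per city-year."""
        return (
            self.records.groupby(["city_id", "province_id", "year"], as_index=False)[
                "emissions_gg"
            ]
            .sum()
            .sort_values(["city_id", "year"], kind="stable")
            .reset_index(drop=True)
        )

    def city_pathway(self, pathway: str) -> pd.DataFrame:
        sub = self.records[self.records["pathway"] == pathway]
        return (
            sub.groupby(["city_id", "province_id", "year"], as_index=False)[
                "emissions_gg"
            ]
            .sum()
            .sort_values(["city_id", "year"], kind="stable")
            .reset_index(drop=True)
        )

    def aggregate(self, level: str) -> pd.DataFrame:
        """Exact sums at ``city``, ``province`` or ``national`` level,
        keeping the pathway split."""
        if level == "city":
            keys = ["city_id", "province_id", "year", "pathway"]
        elif level == "province":
            keys = ["province_id", "year", "pathway"]
        elif level == "national":
            keys = ["year", "pathway"]
        else:
            raise ValidationError(f"unknown aggregation level {level!r}")
        return (
            self.records.groupby(keys, as_index=False)["emissions_gg"]
            .sum()
            .sort_values(keys, kind="stable")
            .reset_index(drop=True)
        )

    def split_ruminant(self) -> pd.DataFrame:
        """Per city-year emissions of ruminant vs nonruminant animals.

        Always emits both class rows per city-year (zero-filled), so a full
        panel yields exactly two records per city-year cell.
        """
        ruminant_codes = {c.value for c in RUMINANTS}
        df = self.records.assign(
            animal_class=self.records["category"]
            .isin(ruminant_codes)
            .map({True: "ruminant", False: "nonruminant"})
        )
        grouped = df.groupby(
            ["city_id", "province_id", "year", "animal_class"], as_index=False
        )["emissions_gg"].sum()
        cells = df[["city_id", "province_id", "year"]].drop_duplicates()
        full = cells.merge(
            pd.DataFrame({"animal_class": ["ruminant", "nonruminant"]}), how="cross"
        )
        out = full.merge(
            grouped, on=["city_id", "province_id", "year", "animal_class"], how="left"
        ).fillna({"emissions_gg": 0.0})
        return out.sort_values(
            ["city_id", "year", "animal_class"], kind="stable"
        ).reset_index(drop=True)

    def category_national(self) -> pd.DataFrame:
        return (
            self.records.groupby(["year", "category"], as_index=False)["emissions_gg"]
            .sum()
            .sort_values(["year", "category"], kind="stable")
            .reset_index(drop=True)
        )


def compute_emissions(
    panel: pd.DataFrame,
    enteric_ef_table: pd.DataFrame,
    manure_ef_table: pd.DataFrame,
    params: ParameterSet,
    climate: pd.DataFrame,
    expand: bool = True,
) -> InventoryCube:
    """Run the full emission accounting and return an :class:`InventoryCube`.

    ``panel`` rows with missing head counts are excluded (they represent
    unfilled activity gaps); whole-herd rows of multi-subclass categories
    are split with the configured default shares unless ``expand=False``.
    """
    if panel.empty:
        return InventoryCube(
            pd.DataFrame(
                columns=[
                    "city_id",
                    "province_id",
                    "year",
                    "category",
                    "pathway",
                    "emissions_gg",
                ]
            )
        )
    work = panel.dropna(subset=["stock_head", "slaughtered_head"])
    if expand:
        work = expand_subclasses(work, params)
    enteric = _pathway_emissions(work, enteric_ef_table, params, None, "enteric")
    manure = _pathway_emissions(work, manure_ef_table, params, climate, "manure")
    records = pd.concat([enteric, manure], ignore_index=True).sort_values(
        ["city_id", "year", "category", "pathway"], kind="stable"
    )
    return InventoryCube(records.reset_index(drop=True))


def _round_sig(df: pd.DataFrame, col: str = "emissions_gg", sig: int = 6) -> pd.DataFrame:
    out = df.copy()
    out[col] = out[col].map(lambda x: float(f"{x:.{sig}g}"))
    return out


def export_dataset(
    cube: InventoryCube, out_dir: str | Path, fmt: str = "csv"
) -> dict[str, Path]:
    """Write the six dataset files; returns a name -> path map.

    City-level files carry one row per city-year (totals, enteric, manure)
    or two rows per city-year (ruminant/nonruminant split); the remaining
    files hold national+provincial pathway structure and per-category
    national series.  Values are rounded to 6 significant digits.
    """
    if fmt not in ("csv", "xlsx"):
        raise ValidationError(f"unknown export format {fmt!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    prov = cube.aggregate("province").pivot_table(
        index=["province_id", "year"],
        columns="pathway",
        values="emissions_gg",
        aggfunc="sum",
        fill_value=0.0,
    ).reset_index()
    prov.columns.name = None
    prov = prov.rename(columns={"enteric": "enteric_gg", "manure": "manure_gg"})
    prov["total_gg"] = prov.get("enteric_gg", 0.0) + prov.get("manure_gg", 0.0)
    nat = cube.aggregate("national").pivot_table(
        index=["year"], columns="pathway", values="emissions_gg", aggfunc="sum",
        fill_value=0.0,
    ).reset_index()
    nat.columns.name = None
    nat = nat.rename(columns={"enteric": "enteric_gg", "manure": "manure_gg"})
    nat["total_gg"] = nat.get("enteric_gg", 0.0) + nat.get("manure_gg", 0.0)
    nat.insert(0, "province_id", "NATIONAL")
    nat_prov = pd.concat([nat, prov], ignore_index=True)
    for col in ("enteric_gg", "manure_gg", "total_gg"):
        nat_prov[col] = nat_prov[col].map(lambda x: float(f"{x:.6g}"))

    tables = {
        "city_total_emissions": _round_sig(cube.city_totals()),
        "city_enteric_emissions": _round_sig(cube.city_pathway("enteric")),
        "city_manure_emissions": _round_sig(cube.city_pathway("manure")),
        "city_ruminant_split": _round_sig(cube.split_ruminant()),
        "national_provincial_emissions": nat_prov,
        "category_national_series": _round_sig(cube.category_national()),
    }
    paths: dict[str, Path] = {}
    for name, df in tables.items():
        path = out_dir / f"{name}.{fmt}"
        if fmt == "csv":
            df.to_csv(path, index=False)
        else:
            df.to_excel(path, index=False)
        paths[name] = path
    return paths
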