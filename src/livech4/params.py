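"""Parameter registry, climate classification and activity-panel validation.

The parameter registry is loaded from a YAML config (see
``livech4/data/default_params.yaml`` for the shipped defaults and the unit
conventions).  Activity panels are pandas DataFrames with the schema

    city_id, province_id, year, category, subclass,
    stock_head, slaughtered_head, source_flag

where ``category``/``subclass`` hold the enum string codes and
``source_flag`` is ``observed`` or ``gapfilled``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .types import (
    SUBCLASSES,
    TIER1_CATEGORIES,
    TIER2_CATEGORIES,
    AnimalTraits,
    Category,
    ClimateClass,
    EnergyCoefficients,
    FeedingSituation,
    Lifespan,
    ManureProfile,
    ManureSystem,
    Subclass,
    TierOneEF,
    ValidationError,
)

PANEL_COLUMNS = [
    "city_id",
    "province_id",
    "year",
    "category",
    "subclass",
    "stock_head",
    "slaughtered_head",
    "source_flag",
]

#: Trait fields required per subclass, beyond body_weight/DE/Ym.
_EXTRA_REQUIRED: dict[Subclass, tuple[str, ...]] = {
    Subclass.MATURE_FEMALE: ("pregnancy_fraction",),
    Subclass.YOUNG: ("weight_gain",),
    Subclass.OTHER: (),
    Subclass.WHOLE_HERD: (),
}

# Cool/temperate and temperate/warm breakpoints [deg C annual mean].
CLIMATE_BREAKPOINTS = (15.0, 25.0)


def classify_climate(mean_temp: float) -> ClimateClass:
    """Assign an annual-mean temperature to a climate class.

    Half-open bins with boundaries assigned upward: cool below 15 degC,
    temperate in [15, 25), warm at or above 25 degC.

    Raises
    ------
    ValidationError
        If ``mean_temp`` is not finite or outside [-30, 40] degC.
    """
    if not isinstance(mean_temp, (int, float)) or not math.isfinite(mean_temp):
        raise ValidationError(f"mean_temp must be finite, got {mean_temp!r}")
    if not (-30.0 <= mean_temp <= 40.0):
        raise ValidationError(f"mean_temp {mean_temp} outside plausible [-30, 40]")
    if mean_temp < CLIMATE_BREAKPOINTS[0]:
        return ClimateClass.COOL
    if mean_temp < CLIMATE_BREAKPOINTS[1]:
        return ClimateClass.TEMPERATE
    return ClimateClass.WARM


@dataclass
class ParameterSet:
    """Validated bundle of every table the inventory pipeline needs."""

    regions: list[str]
    coefficients: EnergyCoefficients
    traits: dict[tuple[Category, Subclass], AnimalTraits]
    manure: dict[Category, ManureProfile]
    mcf: dict[tuple[ManureSystem, ClimateClass], float]
    tier1_efs: dict[Category, TierOneEF]
    lifespans: dict[Category, Lifespan]
    cvs: dict[Category, dict[str, float]]
    subclass_shares: dict[Category, dict[Subclass, float]]
    carcass_weights: dict[Category, float]
    methane_density: float = 0.67
    sheep_other_growth: bool = False
    raw: dict = field(default_factory=dict, repr=False)

    def traits_for(self, category: Category, subclass: Subclass) -> AnimalTraits:
        try:
            return self.traits[(category, subclass)]
        except KeyError:
            raise ValidationError(
                f"no traits for {category.value}.{subclass.value}"
            ) from None

    def lifespan_for(self, category: Category) -> Lifespan:
        return self.lifespans[category]

    def carcass_weights_by_code(self) -> dict[str, float]:
        """Carcass weights keyed by category string code."""
        return {c.value: w for c, w in self.carcass_weights.items()}

    def to_config(self) -> dict:
        """Serialise back to the config mapping layout (round-trippable)."""
        cfg: dict = {
            "regions": list(self.regions),
            "coefficients": {
                "cf_maintenance": {
                    c.value: v for c, v in self.coefficients.cf_maintenance.items()
                },
                "ca_activity": {
                    f.value: v for f, v in self.coefficients.ca_activity.items()
                },
                "cp_pregnancy": self.coefficients.cp_pregnancy,
                "growth_c": self.coefficients.growth_c,
                "ev_wool": self.coefficients.ev_wool,
                "methane_energy_mj_per_kg": self.coefficients.methane_energy_mj_per_kg,
            },
            "sheep_other_growth": self.sheep_other_growth,
            "manure_constants": {"methane_density_kg_per_m3": self.methane_density},
            "traits": {},
            "manure": {},
            "mcf": {},
            "tier1_efs": {
                c.value: {"enteric": ef.enteric, "manure": ef.manure}
                for c, ef in self.tier1_efs.items()
            },
            "lifespans": {
                c.value: {"stock": ls.stock, "slaughtered": ls.slaughtered}
                for c, ls in self.lifespans.items()
            },
            "cvs": {c.value: dict(v) for c, v in self.cvs.items()},
            "subclass_shares": {
                c.value: {s.value: w for s, w in shares.items()}
                for c, shares in self.subclass_shares.items()
            },
            "carcass_weights": {c.value: w for c, w in self.carcass_weights.items()},
        }
        for (cat, sub), tr in self.traits.items():
            block = cfg["traits"].setdefault(cat.value, {})
            entry = {
                "body_weight": tr.body_weight,
                "DE": tr.DE,
                "Ym": tr.Ym,
                "feeding_situation": tr.feeding_situation.value,
            }
            for opt in (
                "weight_gain",
                "milk_yield",
                "milk_fat",
                "wool_yield",
                "pregnancy_fraction",
            ):
                val = getattr(tr, opt)
                if val:
                    entry[opt] = val
            if tr.mature_weight is not None:
                entry["mature_weight"] = tr.mature_weight
            block[sub.value] = entry
        for cat, prof in self.manure.items():
            cfg["manure"][cat.value] = {
                "vs_rate": prof.vs_rate,
                "b0": prof.b0,
                "system_fractions": {
                    s.value: f for s, f in prof.system_fractions.items()
                },
            }
        mcf_by_system: dict[str, dict[str, float]] = {}
        for (system, climate), val in self.mcf.items():
            mcf_by_system.setdefault(system.value, {})[climate.value] = val
        cfg["mcf"] = mcf_by_system
        return cfg

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_config(), sort_keys=True))


def default_config_path() -> Path:
    return Path(resources.files("livech4").joinpath("data/default_params.yaml"))


def _parse_traits(cfg: Mapping, errors: list[str]) -> dict:
    traits: dict[tuple[Category, Subclass], AnimalTraits] = {}
    raw = cfg.get("traits", {})
    for cat in sorted(TIER2_CATEGORIES, key=lambda c: c.value):
        block = raw.get(cat.value)
        if block is None:
            errors.append(f"traits missing for category {cat.value}")
            continue
        for sub in SUBCLASSES[cat]:
            entry = block.get(sub.value)
            if entry is None:
                errors.append(f"traits missing for {cat.value}.{sub.value}")
                continue
            missing = [
                f for f in ("body_weight", "DE", "Ym") if entry.get(f) is None
            ]
            missing += [
                f
                for f in _EXTRA_REQUIRED[sub]
                if entry.get(f) is None
            ]
            if cat is Category.DAIRY_CATTLE and sub is Subclass.MATURE_FEMALE:
                for f in ("milk_yield", "milk_fat"):
                    if entry.get(f) is None:
                        missing.append(f)
            if missing:
                errors.extend(
                    f"missing parameter {cat.value}.{f}"
                    if sub is Subclass.MATURE_FEMALE
                    else f"missing parameter {cat.value}.{sub.value}.{f}"
                    for f in missing
                )
                continue
            try:
                traits[(cat, sub)] = AnimalTraits(
                    body_weight=float(entry["body_weight"]),
                    DE=float(entry["DE"]),
                    Ym=float(entry["Ym"]),
                    feeding_situation=FeedingSituation(
                        entry.get("feeding_situation", "stall")
                    ),
                    weight_gain=float(entry.get("weight_gain", 0.0)),
                    milk_yield=float(entry.get("milk_yield", 0.0)),
                    milk_fat=float(entry.get("milk_fat", 0.0)),
                    wool_yield=float(entry.get("wool_yield", 0.0)),
                    pregnancy_fraction=float(entry.get("pregnancy_fraction", 0.0)),
                    mature_weight=(
                        float(entry["mature_weight"])
                        if entry.get("mature_weight") is not None
                        else None
                    ),
                )
            except (ValidationError, ValueError) as exc:
                errors.append(f"invalid traits for {cat.value}.{sub.value}: {exc}")
    return traits


def _parse_mcf(cfg: Mapping, errors: list[str]) -> dict:
    mcf: dict[tuple[ManureSystem, ClimateClass], float] = {}
    for sys_name, by_climate in cfg.get("mcf", {}).items():
        try:
            system = ManureSystem(sys_name)
        except ValueError:
            errors.append(f"unknown manure system in mcf table: {sys_name}")
            continue
        for climate_name, value in by_climate.items():
            try:
                climate = ClimateClass(climate_name)
            except ValueError:
                errors.append(f"unknown climate class in mcf table: {climate_name}")
                continue
            value = float(value)
            if not (0 < value <= 100):
                errors.append(
                    f"MCF({sys_name}, {climate_name}) must be in (0, 100], got {value}"
                )
                continue
            mcf[(system, climate)] = value
    return mcf


def _parse_manure(cfg: Mapping, mcf: Mapping, traits: Mapping, errors: list[str]) -> dict:
    manure: dict[Category, ManureProfile] = {}
    raw = cfg.get("manure", {})
    for cat in sorted(TIER2_CATEGORIES, key=lambda c: c.value):
        block = raw.get(cat.value)
        if block is None:
            errors.append(f"manure parameters missing for category {cat.value}")
            continue
        fracs: dict[ManureSystem, float] = {}
        for sys_name, frac in (block.get("system_fractions") or {}).items():
            try:
                fracs[ManureSystem(sys_name)] = float(frac)
            except ValueError:
                errors.append(f"unknown manure system for {cat.value}: {sys_name}")
        total = sum(fracs.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            errors.append(
                f"{cat.value} system_fractions sum to {total:.6g}, expected 1"
            )
            continue
        for system in fracs:
            for climate in ClimateClass:
                if (system, climate) not in mcf:
                    errors.append(
                        f"missing MCF({system.value}, {climate.value}) "
                        f"required by {cat.value}"
                    )
        # reference animal mass: mature-female (or whole-herd) body weight
        ref_sub = SUBCLASSES[cat][0]
        tr = traits.get((cat, ref_sub))
        am = tr.body_weight if tr is not None else float("nan")
        try:
            manure[cat] = ManureProfile(
                vs_rate=float(block.get("vs_rate", 0.0)),
                animal_mass=am,
                b0=float(block.get("b0", 0.0)),
                system_fractions=fracs,
                mcf={
                    (s, k): mcf[(s, k)]
                    for s in fracs
                    for k in ClimateClass
                    if (s, k) in mcf
                },
            )
        except ValidationError as exc:
            errors.append(f"invalid manure profile for {cat.value}: {exc}")
    return manure


def load_parameter_set(config_path: str | Path | None = None) -> ParameterSet:
    """Load and validate the full parameter registry from a YAML config.

    Validation is eager and exhaustive: all missing or inconsistent entries
    are collected and raised together in one :class:`ValidationError`.
    """
    path = Path(config_path) if config_path is not None else default_config_path()
    if not path.exists():
        raise FileNotFoundError(path)
    cfg = yaml.safe_load(path.read_text())
    if not isinstance(cfg, dict):
        raise ValidationError(f"config {path} did not parse to a mapping")
    errors: list[str] = []

    coeff_raw = cfg.get("coefficients", {})
    coefficients = EnergyCoefficients(
        cf_maintenance={
            Category(c): float(v)
            for c, v in (coeff_raw.get("cf_maintenance") or {}).items()
        },
        ca_activity={
            FeedingSituation(f): float(v)
            for f, v in (coeff_raw.get("ca_activity") or {}).items()
        },
        cp_pregnancy=float(coeff_raw.get("cp_pregnancy", 0.10)),
        growth_c=float(coeff_raw.get("growth_c", 0.8)),
        ev_wool=float(coeff_raw.get("ev_wool", 24.0)),
        methane_energy_mj_per_kg=float(
            coeff_raw.get("methane_energy_mj_per_kg", 55.65)
        ),
    )
    for cat in sorted(TIER2_CATEGORIES, key=lambda c: c.value):
        if cat not in coefficients.cf_maintenance:
            errors.append(f"missing coefficient cf_maintenance.{cat.value}")
    for feeding in FeedingSituation:
        if feeding not in coefficients.ca_activity:
            errors.append(f"missing coefficient ca_activity.{feeding.value}")

    traits = _parse_traits(cfg, errors)
    mcf = _parse_mcf(cfg, errors)
    manure = _parse_manure(cfg, mcf, traits, errors)

    tier1: dict[Category, TierOneEF] = {}
    t1_raw = cfg.get("tier1_efs", {})
    for cat in sorted(TIER1_CATEGORIES, key=lambda c: c.value):
        entry = t1_raw.get(cat.value)
        if entry is None or entry.get("enteric") is None or entry.get("manure") is None:
            errors.append(f"missing tier1 EF pair for {cat.value}")
            continue
        tier1[cat] = TierOneEF(float(entry["enteric"]), float(entry["manure"]))

    lifespans: dict[Category, Lifespan] = {}
    for cat in Category:
        entry = (cfg.get("lifespans") or {}).get(cat.value)
        if entry is None:
            errors.append(f"missing lifespan for {cat.value}")
            continue
        try:
            lifespans[cat] = Lifespan(
                float(entry["stock"]), float(entry["slaughtered"])
            )
        except (KeyError, ValidationError) as exc:
            errors.append(f"invalid lifespan for {cat.value}: {exc}")

    cvs: dict[Category, dict[str, float]] = {}
    for cat in Category:
        entry = (cfg.get("cvs") or {}).get(cat.value)
        if entry is None:
            errors.append(f"missing CVs for {cat.value}")
            continue
        cvs[cat] = {"ef": float(entry["ef"]), "activity": float(entry["activity"])}

    shares: dict[Category, dict[Subclass, float]] = {}
    for cat in sorted(TIER2_CATEGORIES, key=lambda c: c.value):
        entry = (cfg.get("subclass_shares") or {}).get(cat.value)
        if entry is None:
            errors.append(f"missing subclass_shares for {cat.value}")
            continue
        parsed = {Subclass(s): float(w) for s, w in entry.items()}
        if not math.isclose(sum(parsed.values()), 1.0, abs_tol=1e-9):
            errors.append(f"subclass_shares for {cat.value} do not sum to 1")
            continue
        shares[cat] = parsed

    carcass = {
        Category(c): float(w)
        for c, w in (cfg.get("carcass_weights") or {}).items()
    }

    if errors:
        raise ValidationError(errors)

    return ParameterSet(
        regions=[str(r) for r in cfg.get("regions", ["default"])],
        coefficients=coefficients,
        traits=traits,
        manure=manure,
        mcf=mcf,
        tier1_efs=tier1,
        lifespans=lifespans,
        cvs=cvs,
        subclass_shares=shares,
        carcass_weights=carcass,
        methane_density=float(
            (cfg.get("manure_constants") or {}).get("methane_density_kg_per_m3", 0.67)
        ),
        sheep_other_growth=bool(cfg.get("sheep_other_growth", False)),
        raw=cfg,
    )


@dataclass(frozen=True)
class PanelReport:
    """Structural validation report for an activity panel (report-only)."""

    n_records: int
    n_cells: int
    duplicate_keys: tuple
    negative_rows: int
    incomplete_rows: int
    missing_city_years: tuple
    gapfilled_fraction: float

    @property
    def ok(self) -> bool:
        return (
            not self.duplicate_keys
            and self.negative_rows == 0
            and not self.missing_city_years
        )


def validate_activity_panel(
    panel: pd.DataFrame,
    cities: Iterable[str] | None = None,
    years: Iterable[int] | None = None,
) -> PanelReport:
    """Validate an activity panel without mutating it.

    ``cities``/``years`` declare the expected coverage; when omitted they are
    inferred from the panel itself (so only duplicates/negatives can fail).
    """
    key = ["city_id", "year", "category", "subclass"]
    if panel.empty:
        expected = {
            (c, y) for c in (cities or []) for y in (years or [])
        }
        return PanelReport(0, 0, (), 0, 0, tuple(sorted(expected)), 0.0)
    dup_mask = panel.duplicated(subset=key, keep=False)
    duplicates = tuple(
        sorted(set(map(tuple, panel.loc[dup_mask, key].itertuples(index=False))))
    )
    counts = panel[["stock_head", "slaughtered_head"]]
    negative = int(((counts < 0).any(axis=1)).sum())
    incomplete = int(counts.isna().any(axis=1).sum())
    have_cells = set(map(tuple, panel[["city_id", "year"]].drop_duplicates().itertuples(index=False)))
    cities = set(cities) if cities is not None else {c for c, _ in have_cells}
    years = set(years) if years is not None else {y for _, y in have_cells}
    missing = tuple(sorted({(c, y) for c in cities for y in years} - have_cells))
    gapfilled = float((panel["source_flag"] == "gapfilled").mean())
    return PanelReport(
        n_records=len(panel),
        n_cells=len(have_cells),
        duplicate_keys=duplicates,
        negative_rows=negative,
        incomplete_rows=incomplete,
        missing_city_years=missing,
        gapfilled_fraction=gapfilled,
    )


def expand_subclasses(panel: pd.DataFrame, params: ParameterSet) -> pd.DataFrame:
    """Split whole-herd rows of Tier 2 multi-subclass categories using the
    configured default shares.  Rows already at subclass resolution and
    genuinely whole-herd categories pass through unchanged."""
    multi = {
        c.value
        for c in TIER2_CATEGORIES
        if SUBCLASSES[c] != (Subclass.WHOLE_HERD,)
    }
    mask = (panel["subclass"] == Subclass.WHOLE_HERD.value) & panel[
        "category"
    ].isin(multi)
    passthrough = panel.loc[~mask]
    to_split = panel.loc[mask]
    if to_split.empty:
        return panel.copy().reset_index(drop=True)
    shares = pd.DataFrame(
        [
            {"category": c.value, "split_subclass": s.value, "share": w}
            for c, by_sub in params.subclass_shares.items()
            for s, w in by_sub.items()
        ]
    )
    split = to_split.merge(shares, on="category", how="left")
    split["subclass"] = split.pop("split_subclass")
    split["stock_head"] = split["stock_head"] * split["share"]
    split["slaughtered_head"] = split["slaughtered_head"] * split["share"]
    split = split.drop(columns=["share"])
    return (
        pd.concat([passthrough, split], ignore_index=True)
        .sort_values(["city_id", "year", "category", "subclass"], kind="stable")
        .reset_index(drop=True)
    )
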