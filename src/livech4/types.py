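"""Core domain types for the livestock methane inventory.

Panels and tables are handled as :class:`pandas.DataFrame` objects with the
column schemas documented in :mod:`livech4.params`; the dataclasses here give
typed single-record views and hold validated parameter bundles.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field


class Category(str, enum.Enum):
    """Livestock category codes."""

    DAIRY_CATTLE = "dairy_cattle"
    NONDAIRY_CATTLE = "nondairy_cattle"
    BUFFALO = "buffalo"
    SHEEP = "sheep"
    GOAT = "goat"
    CAMEL = "camel"
    SWINE = "swine"
    HORSE = "horse"
    DONKEY = "donkey"
    MULE = "mule"
    POULTRY = "poultry"
    RABBIT = "rabbit"


#: Categories whose emission factors are built from the gross-energy /
#: volatile-solids pathway (region- and year-specific parameters).
TIER2_CATEGORIES: frozenset[Category] = frozenset(
    {
        Category.DAIRY_CATTLE,
        Category.NONDAIRY_CATTLE,
        Category.BUFFALO,
        Category.SHEEP,
        Category.GOAT,
        Category.SWINE,
    }
)

#: Categories with fixed lookup emission factors (provincial-guideline style).
TIER1_CATEGORIES: frozenset[Category] = frozenset(
    {
        Category.HORSE,
        Category.DONKEY,
        Category.MULE,
        Category.POULTRY,
        Category.RABBIT,
        Category.CAMEL,
    }
)

#: Ruminant digestive physiology (enteric methane dominant pathway).
RUMINANTS: frozenset[Category] = frozenset(
    {
        Category.DAIRY_CATTLE,
        Category.NONDAIRY_CATTLE,
        Category.BUFFALO,
        Category.SHEEP,
        Category.GOAT,
        Category.CAMEL,
    }
)


class Subclass(str, enum.Enum):
    MATURE_FEMALE = "mature_female"
    YOUNG = "young"
    OTHER = "other"
    WHOLE_HERD = "whole_herd"


#: Admissible subclasses per category.
SUBCLASSES: dict[Category, tuple[Subclass, ...]] = {
    Category.DAIRY_CATTLE: (Subclass.MATURE_FEMALE, Subclass.YOUNG, Subclass.OTHER),
    Category.NONDAIRY_CATTLE: (Subclass.MATURE_FEMALE, Subclass.YOUNG, Subclass.OTHER),
    Category.BUFFALO: (Subclass.MATURE_FEMALE, Subclass.YOUNG, Subclass.OTHER),
    Category.SHEEP: (Subclass.MATURE_FEMALE, Subclass.OTHER),
    Category.GOAT: (Subclass.MATURE_FEMALE, Subclass.OTHER),
    Category.CAMEL: (Subclass.WHOLE_HERD,),
    Category.SWINE: (Subclass.WHOLE_HERD,),
    Category.HORSE: (Subclass.WHOLE_HERD,),
    Category.DONKEY: (Subclass.WHOLE_HERD,),
    Category.MULE: (Subclass.WHOLE_HERD,),
    Category.POULTRY: (Subclass.WHOLE_HERD,),
    Category.RABBIT: (Subclass.WHOLE_HERD,),
}


class Pathway(str, enum.Enum):
    ENTERIC = "enteric"
    MANURE = "manure"


class ClimateClass(str, enum.Enum):
    COOL = "cool"
    TEMPERATE = "temperate"
    WARM = "warm"


class FeedingSituation(str, enum.Enum):
    STALL = "stall"
    PASTURE = "pasture"
    GRAZING_LARGE_AREA = "grazing_large_area"


class ManureSystem(str, enum.Enum):
    PASTURE = "pasture"
    DAILY_SPREAD = "daily_spread"
    SOLID_STORAGE = "solid_storage"
    DRY_LOT = "dry_lot"
    LIQUID_SLURRY = "liquid_slurry"
    ANAEROBIC_DIGESTER = "anaerobic_digester"
    LAGOON = "lagoon"
    OTHER = "other"


class ValidationError(ValueError):
    """A parameter or input table failed a structural invariant."""

    def __init__(self, errors: list[str] | str):
        if isinstance(errors, str):
            errors = [errors]
        self.errors = errors
        super().__init__("; ".join(errors))


class GapfillError(RuntimeError):
    """A missing activity cell could not be reconstructed."""


def is_tier2(category: Category) -> bool:
    return category in TIER2_CATEGORIES


def is_ruminant(category: Category) -> bool:
    return category in RUMINANTS


@dataclass(frozen=True)
class AnimalTraits:
    """Biological and management parameters feeding gross-energy intake.

    Units: body_weight kg; weight_gain kg day-1; milk_yield kg head-1 yr-1;
    milk_fat percent by mass; wool_yield kg head-1 yr-1; DE and Ym percent.
    """

    body_weight: float
    DE: float
    Ym: float
    feeding_situation: FeedingSituation = FeedingSituation.STALL
    weight_gain: float = 0.0
    milk_yield: float = 0.0
    milk_fat: float = 0.0
    wool_yield: float = 0.0
    pregnancy_fraction: float = 0.0
    mature_weight: float | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.feeding_situation, FeedingSituation):
            object.__setattr__(
                self, "feeding_situation", FeedingSituation(self.feeding_situation)
            )
        errs = []
        if not (self.body_weight > 0):
            errs.append(f"body_weight must be > 0, got {self.body_weight}")
        if not (0 < self.DE <= 100):
            errs.append(f"DE must be in (0, 100], got {self.DE}")
        if not (0 <= self.Ym <= 15):
            errs.append(f"Ym must be in [0, 15], got {self.Ym}")
        if not (0 <= self.pregnancy_fraction <= 1):
            errs.append(
                f"pregnancy_fraction must be in [0, 1], got {self.pregnancy_fraction}"
            )
        if errs:
            raise ValidationError(errs)


@dataclass(frozen=True)
class EnergyBreakdown:
    """Daily net-energy components (MJ day-1) and the resulting gross energy.

    ``ne_work`` is retained for completeness but is always zero: draft-animal
    energy is excluded from the inventory.
    """

    ne_m: float = 0.0
    ne_a: float = 0.0
    ne_l: float = 0.0
    ne_work: float = 0.0
    ne_p: float = 0.0
    ne_g: float = 0.0
    ne_wool: float = 0.0
    rem: float = float("nan")
    reg: float = float("nan")
    ge: float = float("nan")

    @property
    def maintenance_pool(self) -> float:
        """Components routed through REM."""
        return self.ne_m + self.ne_a + self.ne_l + self.ne_work + self.ne_p

    @property
    def growth_pool(self) -> float:
        """Components routed through REG."""
        return self.ne_g + self.ne_wool


@dataclass(frozen=True)
class ManureProfile:
    """Volatile-solids and management-system parameters for one category.

    vs_rate: kg VS per 1000 kg animal mass per day; animal_mass: kg;
    b0: m3 CH4 per kg VS; system_fractions must sum to 1;
    mcf values are percent of B0 realised per (system, climate class).
    """

    vs_rate: float
    animal_mass: float
    b0: float
    system_fractions: dict[ManureSystem, float]
    mcf: dict[tuple[ManureSystem, ClimateClass], float]

    def __post_init__(self) -> None:
        errs = []
        if not (self.vs_rate > 0):
            errs.append(f"vs_rate must be > 0, got {self.vs_rate}")
        if not (self.b0 > 0):
            errs.append(f"b0 must be > 0, got {self.b0}")
        total = sum(self.system_fractions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            errs.append(f"system_fractions sum to {total}, expected 1")
        for key, val in self.mcf.items():
            if not (0 < val <= 100):
                errs.append(f"MCF{key} must be in (0, 100], got {val}")
        if errs:
            raise ValidationError(errs)


@dataclass(frozen=True)
class TierOneEF:
    """Fixed per-head EFs (kg CH4 head-1 yr-1) for minor species."""

    enteric: float
    manure: float


@dataclass(frozen=True)
class Lifespan:
    """Months per calendar year a category emits, by population type."""

    stock: float
    slaughtered: float

    def __post_init__(self) -> None:
        errs = []
        if not (0 < self.stock <= 12):
            errs.append(f"stock lifespan must be in (0, 12], got {self.stock}")
        if not (0 < self.slaughtered <= 12):
            errs.append(
                f"slaughtered lifespan must be in (0, 12], got {self.slaughtered}"
            )
        if self.slaughtered > self.stock:
            errs.append(
                f"slaughtered lifespan {self.slaughtered} exceeds stock {self.stock}"
            )
        if errs:
            raise ValidationError(errs)


@dataclass(frozen=True)
class EnergyCoefficients:
    """Coefficients of the net-energy component equations."""

    cf_maintenance: dict[Category, float] = field(default_factory=dict)
    ca_activity: dict[FeedingSituation, float] = field(default_factory=dict)
    cp_pregnancy: float = 0.10
    growth_c: float = 0.8
    ev_wool: float = 24.0
    methane_energy_mj_per_kg: float = 55.65
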