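"""Synthetic activity panels, trait tables, climates and dataset variants.

The generator emulates the statistical structure of a multi-city,
multi-year livestock activity panel: heavy-tailed municipal herd sizes,
smooth year-over-year dynamics, a north-south body-weight gradient, a small
fraction of cities with no breeding records (but meat production retained,
so gap-filling is always exercisable), and three discrepant copies of the
panel for activity-data CV estimation.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import PANEL_COLUMNS, ParameterSet, classify_climate, load_parameter_set
from .types import Category, Subclass, ValidationError

#: median stock head count and lognormal sigma per category
DEFAULT_ABUNDANCE: dict[Category, tuple[float, float]] = {
    Category.DAIRY_CATTLE: (20_000, 0.8),
    Category.NONDAIRY_CATTLE: (60_000, 0.8),
    Category.BUFFALO: (8_000, 1.0),
    Category.SHEEP: (300_000, 1.0),
    Category.GOAT: (200_000, 1.0),
    Category.CAMEL: (500, 1.2),
    Category.SWINE: (800_000, 0.8),
    Category.HORSE: (10_000, 1.0),
    Category.DONKEY: (8_000, 1.0),
    Category.MULE: (3_000, 1.0),
    Category.POULTRY: (8_000_000, 0.8),
    Category.RABBIT: (100_000, 1.0),
}

#: slaughtered/stock ratio per category (annual turnover)
DEFAULT_SLAUGHTER_RATE: dict[Category, float] = {
    Category.DAIRY_CATTLE: 0.15,
    Category.NONDAIRY_CATTLE: 0.35,
    Category.BUFFALO: 0.25,
    Category.SHEEP: 0.8,
    Category.GOAT: 0.8,
    Category.CAMEL: 0.1,
    Category.SWINE: 1.5,
    Category.HORSE: 0.1,
    Category.DONKEY: 0.15,
    Category.MULE: 0.1,
    Category.POULTRY: 3.0,
    Category.RABBIT: 1.5,
}

_MAX_LOG_STEP = 0.3  # |log year-over-year ratio| bound for head counts
_MAX_WEIGHT_STEP = 0.05  # body weight year-over-year ratio within [0.95, 1.05]


@dataclass(frozen=True)
class SyntheticSpec:
    """Configuration of the synthetic panel generator."""

    n_cities: int = 347
    n_provinces: int = 31
    years: tuple[int, int] = (2010, 2020)
    seed: int = 0
    missing_city_fraction: float = 0.05
    category_abundance: dict = field(default_factory=lambda: dict(DEFAULT_ABUNDANCE))
    north_south_weight_gradient: float = 1.15
    dataset_discrepancy_cv: float = 0.1

    def __post_init__(self) -> None:
        errs = []
        if not (0 <= self.missing_city_fraction < 0.1):
            errs.append(
                f"missing_city_fraction must be in [0, 0.1), got "
                f"{self.missing_city_fraction}"
            )
        if self.n_provinces > self.n_cities:
            errs.append("n_provinces must not exceed n_cities")
        y0, y1 = self.years
        if y0 > y1 or y0 < 2000 or y1 > 2030:
            errs.append(f"years {self.years} must lie within 2000-2030")
        if errs:
            raise ValidationError(errs)

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    def city_ids(self) -> list[str]:
        return [f"C{i:04d}" for i in range(1, self.n_cities + 1)]

    def province_of(self) -> dict[str, str]:
        """Round-robin city -> province assignment (contiguous blocks)."""
        cities = self.city_ids()
        per = int(np.ceil(self.n_cities / self.n_provinces))
        return {
            c: f"P{min(i // per, self.n_provinces - 1) + 1:02d}"
            for i, c in enumerate(cities)
        }

    def northern_provinces(self) -> set[str]:
        """First half of the province list plays the northern latitude band."""
        return {f"P{i:02d}" for i in range(1, self.n_provinces // 2 + 1)}


@dataclass
class SyntheticPanel:
    """Generator output: observed panel, meat side table, and ground truth."""

    panel: pd.DataFrame
    meat: pd.DataFrame
    truth: pd.DataFrame
    missing_cities: list[str]


def generate_activity_panel(
    spec: SyntheticSpec, params: ParameterSet | None = None
) -> SyntheticPanel:
    """Generate a city-year-category activity panel plus its meat side table.

    Head counts are lognormal per category and follow a bounded
    multiplicative random walk over years.  A ``missing_city_fraction``
    share of cities has stock/slaughter blanked (NaN) in every category
    while meat-production rows are retained, so the gap-fill path sees the
    same inputs the compiled yearbook panel would offer.
    """
    params = params if params is not None else load_parameter_set()
    rng = np.random.default_rng(spec.seed)
    cities = spec.city_ids()
    province = spec.province_of()
    years = spec.year_list
    n_years = len(years)

    n_missing = int(np.floor(spec.missing_city_fraction * spec.n_cities))
    missing_cities = sorted(rng.choice(cities, size=n_missing, replace=False).tolist())
    missing_set = set(missing_cities)

    frames = []
    for cat in Category:
        median, sigma = spec.category_abundance[cat]
        base = np.exp(rng.normal(np.log(median), sigma, size=spec.n_cities))
        steps = np.clip(
            rng.normal(0.0, 0.08, size=(spec.n_cities, n_years - 1)),
            -_MAX_LOG_STEP,
            _MAX_LOG_STEP,
        )
        log_path = np.cumsum(np.concatenate(
            [np.zeros((spec.n_cities, 1)), steps], axis=1), axis=1)
        stock = np.round(base[:, None] * np.exp(log_path))
        rate = DEFAULT_SLAUGHTER_RATE[cat] * np.exp(
            rng.normal(0.0, 0.1, size=spec.n_cities)
        )
        slaughtered = np.round(stock * rate[:, None])
        frames.append(
            pd.DataFrame(
                {
                    "city_id": np.repeat(cities, n_years),
                    "province_id": np.repeat(
                        [province[c] for c in cities], n_years
                    ),
                    "year": np.tile(years, spec.n_cities),
                    "category": cat.value,
                    "subclass": Subclass.WHOLE_HERD.value,
                    "stock_head": stock.ravel(),
                    "slaughtered_head": slaughtered.ravel(),
                    "source_flag": "observed",
                }
            )
        )
    truth = pd.concat(frames, ignore_index=True)[PANEL_COLUMNS]

    meat_cats = {c.value for c in params.carcass_weights}
    meat = truth[truth["category"].isin(meat_cats)].copy()
    carcass = {c.value: w for c, w in params.carcass_weights.items()}
    meat["meat_production"] = meat["slaughtered_head"] * meat["category"].map(carcass)
    meat = meat[["city_id", "year", "category", "meat_production"]].reset_index(
        drop=True
    )

    panel = truth.copy()
    blank = panel["city_id"].isin(missing_set)
    panel.loc[blank, ["stock_head", "slaughtered_head"]] = np.nan
    return SyntheticPanel(
        panel=panel, meat=meat, truth=truth, missing_cities=missing_cities
    )


def generate_trait_and_climate_tables(
    spec: SyntheticSpec, params: ParameterSet | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per province-year trait overrides and per city-year climate records.

    Body weights start from the configured defaults, receive the northern
    weight-gradient multiplier, and drift smoothly over years (adjacent-year
    ratio within [0.95, 1.05]).  Milk yields stay within 3000-9000 kg
    head-1 yr-1.  City temperatures span all three climate classes once the
    panel has a few dozen cities.
    """
    params = params if params is not None else load_parameter_set()
    rng = np.random.default_rng((spec.seed, 1))
    years = spec.year_list
    n_years = len(years)
    provinces = sorted(set(spec.province_of().values()))
    north = spec.northern_provinces()

    rows = []
    for prov in provinces:
        gradient = spec.north_south_weight_gradient if prov in north else 1.0
        for (cat, sub), tr in sorted(
            params.traits.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
        ):
            w0 = tr.body_weight * gradient * np.exp(rng.normal(0.0, 0.05))
            steps = np.clip(
                rng.normal(0.0, 0.02, size=n_years - 1),
                np.log(1 - _MAX_WEIGHT_STEP),
                np.log(1 + _MAX_WEIGHT_STEP),
            )
            weights = w0 * np.exp(
                np.concatenate([[0.0], np.cumsum(steps)])
            )
            milk = np.full(n_years, np.nan)
            if tr.milk_yield > 0:
                m0 = float(
                    np.clip(
                        tr.milk_yield * np.exp(rng.normal(0.0, 0.15)), 3300, 8200
                    )
                )
                msteps = np.clip(
                    rng.normal(0.01, 0.02, size=n_years - 1), -0.04, 0.04
                )
                milk = np.clip(
                    m0 * np.exp(np.concatenate([[0.0], np.cumsum(msteps)])),
                    3000,
                    9000,
                )
            for k, year in enumerate(years):
                rows.append(
                    {
                        "region_id": prov,
                        "year": year,
                        "category": cat.value,
                        "subclass": sub.value,
                        "body_weight": weights[k],
                        "milk_yield": milk[k],
                    }
                )
    traits = pd.DataFrame(rows)

    cities = spec.city_ids()
    base_temp = np.linspace(3.0, 28.0, spec.n_cities)
    crows = []
    for i, city in enumerate(cities):
        temps = base_temp[i] + rng.normal(0.0, 0.8, size=n_years)
        temps = np.clip(temps, -29.0, 39.0)
        for k, year in enumerate(years):
            t = float(temps[k])
            crows.append(
                {
                    "city_id": city,
                    "year": year,
                    "mean_temp": t,
                    "climate_class": classify_climate(t).value,
                }
            )
    climate = pd.DataFrame(crows)
    return traits, climate


def generate_dataset_variants(
    panel: pd.DataFrame, spec: SyntheticSpec
) -> list[pd.DataFrame]:
    """Three discrepant copies of an activity panel.

    Variant 1 is the base panel itself; variants 2 and 3 carry independent
    multiplicative lognormal noise with CV ``spec.dataset_discrepancy_cv``
    on both head-count columns (mimicking city-compiled vs national vs
    international statistics).
    """
    if panel.empty:
        raise ValidationError("panel must be nonempty")
    cv = spec.dataset_discrepancy_cv
    sigma = float(np.sqrt(np.log1p(cv**2)))
    rng = np.random.default_rng((spec.seed, 2))
    variants = [panel.copy()]
    for _ in range(2):
        var = panel.copy()
        for col in ("stock_head", "slaughtered_head"):
            noise = rng.lognormal(-(sigma**2) / 2.0, sigma, size=len(var))
            var[col] = var[col] * noise
        variants.append(var)
    return variants
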