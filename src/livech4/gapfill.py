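"""Reconstruction of missing activity records and trait years.

Missing city head counts are extrapolated from meat production via carcass
weights, then converted to stock via a slaughter rate resolved with a fixed
priority: the same city's other years first, then same-province cities, then
the province-wide mean.  Body-weight series with missing years are extended
geometrically with the mean observed year-over-year change rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ParameterSet
from .types import Category, GapfillError, ValidationError


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def estimate_slaughtered_from_meat(
    meat_production: float, carcass_weight: float
) -> int:
    """Slaughtered head count from annual meat production (kg carcass).

    Head = meat / carcass weight, rounded half-up to an integer.
    """
    if carcass_weight <= 0:
        raise ValidationError(f"carcass_weight must be > 0, got {carcass_weight}")
    if meat_production < 0:
        raise ValidationError(f"meat_production must be >= 0, got {meat_production}")
    return _round_half_up(meat_production / carcass_weight)


def estimate_stock_from_slaughter(slaughtered_head: float, slaughter_rate: float) -> int:
    """Stock head count from the slaughtered count and a slaughtered/stock rate."""
    if slaughter_rate <= 0:
        raise ValidationError(f"slaughter_rate must be > 0, got {slaughter_rate}")
    if slaughtered_head < 0:
        raise ValidationError(f"slaughtered_head must be >= 0, got {slaughtered_head}")
    return _round_half_up(slaughtered_head / slaughter_rate)


def resolve_slaughter_rate(
    panel: pd.DataFrame, city_id: str, year: int, category: str
) -> float:
    """Resolve a slaughtered/stock rate for one missing cell.

    Priority: mean rate of the same city in other years, then the mean rate
    of other same-province cities ("adjacent" cities), then the
    province-wide mean over all years.  Only observed rows with positive
    stock contribute.
    """
    obs = panel[
        (panel["category"] == category)
        & panel["stock_head"].notna()
        & panel["slaughtered_head"].notna()
        & (panel["stock_head"] > 0)
    ]
    if obs.empty:
        raise GapfillError(
            f"no observed slaughter rates anywhere for category {category}"
        )
    rates = obs["slaughtered_head"] / obs["stock_head"]

    same_city = obs["city_id"] == city_id
    candidates = [
        rates[same_city & (obs["year"] != year)],
    ]
    prov_rows = panel.loc[panel["city_id"] == city_id, "province_id"]
    if not prov_rows.empty:
        province = prov_rows.iloc[0]
        in_prov = (obs["province_id"] == province) & ~same_city
        candidates.append(rates[in_prov & (obs["year"] == year)])
        candidates.append(rates[in_prov])
    for cand in candidates:
        if len(cand) and cand.mean() > 0:
            return float(cand.mean())
    raise GapfillError(
        f"no resolvable slaughter rate for ({city_id}, {year}, {category})"
    )


def fill_body_weight_series(
    series: dict[int, float], years: list[int] | None = None
) -> dict[int, float]:
    """Fill gap years of a body-weight series geometrically.

    The mean year-over-year change rate of the observed years (geometric
    mean of per-year step ratios) extends each missing year from its nearest
    observed neighbour; a single observation is held constant.
    """
    observed = {int(y): float(w) for y, w in series.items() if w is not None and not (
        isinstance(w, float) and math.isnan(w))}
    if not observed:
        raise ValidationError("body-weight series has no observed years")
    if any(w <= 0 for w in observed.values()):
        raise ValidationError("body weights must be positive")
    obs_years = sorted(observed)
    if years is None:
        years = list(range(obs_years[0], obs_years[-1] + 1))
    if len(obs_years) == 1:
        return {y: observed[obs_years[0]] for y in years}
    # mean annual log-rate over consecutive observed spans
    log_rates = [
        (math.log(observed[y2]) - math.log(observed[y1])) / (y2 - y1)
        for y1, y2 in zip(obs_years, obs_years[1:])
    ]
    rate = math.exp(sum(log_rates) / len(log_rates))
    out = {}
    obs_arr = np.array(obs_years)
    for y in years:
        if y in observed:
            out[y] = observed[y]
            continue
        nearest = int(obs_arr[np.argmin(np.abs(obs_arr - y))])
        out[y] = observed[nearest] * rate ** (y - nearest)
    return out


@dataclass(frozen=True)
class GapfillReport:
    n_missing: int
    n_filled: int
    n_unfillable: int
    unfillable: tuple

    @property
    def filled_fraction(self) -> float:
        return self.n_filled / self.n_missing if self.n_missing else 0.0


def fill_panel(
    panel: pd.DataFrame,
    meat: pd.DataFrame,
    params: ParameterSet,
) -> tuple[pd.DataFrame, GapfillReport]:
    """Fill every missing activity cell that has a meat-production record.

    Returns a new panel (input is not mutated) where filled rows carry
    ``source_flag='gapfilled'``; cells without a meat record stay NaN and
    are listed in the report.
    """
    out = panel.copy()
    meat_idx = meat.set_index(["city_id", "year", "category"])["meat_production"]
    carcass = {c.value: w for c, w in params.carcass_weights.items()}

    missing_mask = out["stock_head"].isna() | out["slaughtered_head"].isna()
    unfillable = []
    n_filled = 0
    rate_cache: dict[tuple, float] = {}
    for idx in out.index[missing_mask]:
        row = out.loc[idx]
        key = (row["city_id"], int(row["year"]), row["category"])
        if key not in meat_idx.index or row["category"] not in carcass:
            unfillable.append(key)
            continue
        slaughtered = estimate_slaughtered_from_meat(
            float(meat_idx.loc[key]), carcass[row["category"]]
        )
        if slaughtered == 0:
            stock = 0
        else:
            cache_key = (row["city_id"], int(row["year"]), row["category"])
            try:
                if cache_key not in rate_cache:
                    rate_cache[cache_key] = resolve_slaughter_rate(
                        panel, *cache_key
                    )
                stock = estimate_stock_from_slaughter(
                    slaughtered, rate_cache[cache_key]
                )
            except GapfillError:
                unfillable.append(key)
                continue
        out.loc[idx, "stock_head"] = float(stock)
        out.loc[idx, "slaughtered_head"] = float(slaughtered)
        out.loc[idx, "source_flag"] = "gapfilled"
        n_filled += 1
    return out, GapfillReport(
        n_missing=int(missing_mask.sum()),
        n_filled=n_filled,
        n_unfillable=len(unfillable),
        unfillable=tuple(unfillable),
    )
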