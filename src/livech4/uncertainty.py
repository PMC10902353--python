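"""Monte Carlo uncertainty propagation for the inventory.

Activity data are perturbed with uniform multipliers (half-width
sqrt(3)*CV, so the draw's true CV equals the stated CV) and emission
factors with normal multipliers truncated at zero.  Perturbations are drawn
per category and shared across cities within a simulation — they model
systematic statistical bias, not independent municipal noise.  Because the
emission accounting is linear in both head counts and EFs, each simulation
is an exact re-evaluation of the pipeline on the perturbed inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inventory import compute_emissions
from .params import ParameterSet
from .types import Category, ValidationError

_SQRT3 = np.sqrt(3.0)


def _cv(table: dict, category: str) -> float:
    """CV lookup accepting either Category or string keys."""
    if category in table:
        return float(table[category])
    return float(table.get(Category(category), 0.0))


@dataclass(frozen=True)
class UncertaintySpec:
    """Monte Carlo configuration."""

    n_sims: int = 10_000
    seed: int = 0
    ef_cv: dict = field(default_factory=dict)
    activity_cv: dict = field(default_factory=dict)
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        errs = []
        if self.n_sims < 100:
            errs.append(f"n_sims must be >= 100, got {self.n_sims}")
        if not (0 < self.ci_level < 1):
            errs.append(f"ci_level must be in (0, 1), got {self.ci_level}")
        bad = [
            f"{k}: {v}"
            for d in (self.ef_cv, self.activity_cv)
            for k, v in d.items()
            if v < 0
        ]
        if bad:
            errs.append(f"negative CVs: {bad}")
        if errs:
            raise ValidationError(errs)

    @classmethod
    def from_params(
        cls, params: ParameterSet, n_sims: int = 10_000, seed: int = 0,
        ci_level: float = 0.95,
    ) -> "UncertaintySpec":
        return cls(
            n_sims=n_sims,
            seed=seed,
            ef_cv={c: v["ef"] for c, v in params.cvs.items()},
            activity_cv={c: v["activity"] for c, v in params.cvs.items()},
            ci_level=ci_level,
        )


def activity_cv(
    variants: list[pd.DataFrame], method: str = "mean_abs_dev"
) -> dict[str, float]:
    """Per-category activity-data CV from three discrepant panel variants.

    Per cell, CV = mean(|x_d - mean(x)|) / mean(x) over the three datasets
    (``method='pairwise'`` uses the mean absolute pairwise difference
    instead).  The category CV is the head-count-weighted mean over cells;
    zero-mean cells are skipped with a warning.
    """
    if len(variants) != 3:
        raise ValidationError(f"expected exactly 3 variants, got {len(variants)}")
    if method not in ("mean_abs_dev", "pairwise"):
        raise ValidationError(f"unknown method {method!r}")
    key = ["city_id", "year", "category", "subclass"]
    stacks = []
    for i, var in enumerate(variants):
        v = var[key + ["stock_head"]].rename(columns={"stock_head": f"x{i}"})
        stacks.append(v.set_index(key))
    wide = pd.concat(stacks, axis=1).dropna()
    x = wide[["x0", "x1", "x2"]].to_numpy(float)
    mean = x.mean(axis=1)
    zero = mean <= 0
    if zero.any():
        warnings.warn(f"skipping {int(zero.sum())} zero-mean cells", stacklevel=2)
    x, mean = x[~zero], mean[~zero]
    cats = wide.index.get_level_values("category").to_numpy()[~zero]
    if method == "mean_abs_dev":
        cell_cv = np.abs(x - mean[:, None]).mean(axis=1) / mean
    else:
        diffs = (
            np.abs(x[:, 0] - x[:, 1])
            + np.abs(x[:, 0] - x[:, 2])
            + np.abs(x[:, 1] - x[:, 2])
        ) / 3.0
        cell_cv = diffs / mean
    out: dict[str, float] = {}
    for cat in np.unique(cats):
        sel = cats == cat
        out[str(cat)] = float(np.average(cell_cv[sel], weights=mean[sel]))
    return out


def _uniform_multipliers(rng: np.random.Generator, cv: np.ndarray, size: int) -> np.ndarray:
    """Uniform draws with mean 1 and sd equal to cv (per column)."""
    half = _SQRT3 * cv
    lo, hi = 1.0 - half, 1.0 + half
    if (lo < 0).any():
        warnings.warn("uniform lower bound < 0 clipped at 0", stacklevel=2)
        lo = np.clip(lo, 0.0, None)
    return rng.uniform(lo, hi, size=(size, len(cv)))


def _normal_multipliers(rng: np.random.Generator, cv: np.ndarray, size: int) -> np.ndarray:
    """Normal draws with mean 1, sd cv, truncated at 0 by resampling."""
    draws = rng.normal(1.0, cv, size=(size, len(cv)))
    for _ in range(100):
        neg = draws <= 0
        if not neg.any():
            break
        draws[neg] = rng.normal(1.0, np.broadcast_to(cv, draws.shape)[neg])
    return np.clip(draws, 1e-12, None)


def sample_inputs(
    panel: pd.DataFrame,
    ef_tables: dict[str, pd.DataFrame],
    spec: UncertaintySpec,
    sim_index: int,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """One simulation's perturbed copies of the panel and EF tables.

    Deterministic given ``(spec.seed, sim_index)``.  Multipliers are drawn
    per category: uniform for activity, truncated normal for EFs (drawn
    independently per pathway).
    """
    rng = np.random.default_rng((spec.seed, sim_index))
    cats = sorted({c.value for c in Category})
    act_cv = np.array([_cv(spec.activity_cv, c) for c in cats])
    ef_cv = np.array([_cv(spec.ef_cv, c) for c in cats])
    act = dict(zip(cats, _uniform_multipliers(rng, act_cv, 1)[0]))
    ent = dict(zip(cats, _normal_multipliers(rng, ef_cv, 1)[0]))
    man = dict(zip(cats, _normal_multipliers(rng, ef_cv, 1)[0]))

    new_panel = panel.copy()
    mult = new_panel["category"].map(act)
    new_panel["stock_head"] = new_panel["stock_head"] * mult
    new_panel["slaughtered_head"] = new_panel["slaughtered_head"] * mult
    new_tables = {}
    for name, table in ef_tables.items():
        t = table.copy()
        t["ef"] = t["ef"] * t["category"].map(ent if name == "enteric" else man)
        new_tables[name] = t
    return new_panel, new_tables


def run_monte_carlo(
    panel: pd.DataFrame,
    enteric_ef_table: pd.DataFrame,
    manure_ef_table: pd.DataFrame,
    params: ParameterSet,
    climate: pd.DataFrame,
    spec: UncertaintySpec,
) -> pd.DataFrame:
    """Per-year uncertainty of national total emissions.

    Computes the unperturbed point estimate, then re-evaluates the
    (category-linear) emission totals under ``spec.n_sims`` draws of the
    category-level multipliers, and reports the empirical central CI.

    Returns a DataFrame with columns: year, point_gg, ci_low_gg, ci_high_gg,
    rel_low_pct, rel_high_pct, sim_mean_gg, sim_std_gg.
    """
    cube = compute_emissions(panel, enteric_ef_table, manure_ef_table, params, climate)
    if cube.records.empty:
        raise ValidationError("empty emission cube; nothing to simulate")
    base = (
        cube.records.groupby(["year", "category", "pathway"])["emissions_gg"]
        .sum()
        .unstack("pathway", fill_value=0.0)
    )
    years = sorted(base.index.get_level_values("year").unique())
    cats = sorted(base.index.get_level_values("category").unique())
    b_ent = np.zeros((len(years), len(cats)))
    b_man = np.zeros((len(years), len(cats)))
    for (year, cat), row in base.iterrows():
        i, j = years.index(year), cats.index(cat)
        b_ent[i, j] = row.get("enteric", 0.0)
        b_man[i, j] = row.get("manure", 0.0)

    act_cv = np.array([_cv(spec.activity_cv, c) for c in cats])
    ef_cv = np.array([_cv(spec.ef_cv, c) for c in cats])
    rng = np.random.default_rng(spec.seed)
    act = _uniform_multipliers(rng, act_cv, spec.n_sims)
    ent = _normal_multipliers(rng, ef_cv, spec.n_sims)
    man = _normal_multipliers(rng, ef_cv, spec.n_sims)

    # totals[s, y] = sum_c act[s,c] * (ent[s,c]*B_ent[y,c] + man[s,c]*B_man[y,c])
    totals = (act * ent) @ b_ent.T + (act * man) @ b_man.T

    alpha = (1.0 - spec.ci_level) / 2.0
    lo = np.quantile(totals, alpha, axis=0)
    hi = np.quantile(totals, 1.0 - alpha, axis=0)
    point = b_ent.sum(axis=1) + b_man.sum(axis=1)
    return pd.DataFrame(
        {
            "year": years,
            "point_gg": point,
            "ci_low_gg": lo,
            "ci_high_gg": hi,
            "rel_low_pct": (lo - point) / point * 100.0,
            "rel_high_pct": (hi - point) / point * 100.0,
            "sim_mean_gg": totals.mean(axis=0),
            "sim_std_gg": totals.std(axis=0, ddof=1),
        }
    )
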