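"""Per-participant dietary exposures from 24-hour recalls (and FFQ).

The daily glycemic load is GL = sum over foods of CHO_food (g) * GI_food /
100; the participant's dietary GI is 100 * GL / total CHO, i.e. the
CHO-weighted mean GI of everything consumed. Foods assigned GI 0 by the
zero rule contribute carbohydrate but no load, so they dilute the dietary
GI — exactly the behaviour wanted for mainly-fat/protein foods.

Nutrient exposures are energy-adjusted by the residual method: within each
sex, the nutrient is regressed on total energy intake by ordinary least
squares and the residual replaces the raw value. Residual tertiles are the
exposure categories used throughout the association models.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import LookupFoodError, UndefinedGIError
from .fooddb import FoodTable

#: Inclusive plausible daily-energy bounds (kcal/d) by sex; recall summaries
#: outside these are excluded from analysis.
ENERGY_BOUNDS_KCAL = {"male": (800.0, 4200.0), "female": (500.0, 3500.0)}

RECALL_COLUMNS = ("participant_id", "day_index", "food_id", "grams")


def _food_lookup(records: pd.DataFrame, db: FoodTable) -> pd.DataFrame:
    comp = db.composition_frame()
    unknown = set(records["food_id"]) - set(comp.index)
    if unknown:
        raise LookupFoodError(f"unresolved food_id(s): {sorted(unknown)}")
    merged = records.merge(comp, left_on="food_id", right_index=True, how="left")
    scale = merged["grams"] / 100.0
    merged["cho_g"] = scale * merged["cho_per_100g"]
    merged["gl_g"] = merged["cho_g"] * merged["gi"] / 100.0
    merged["fiber_g"] = scale * merged["fiber_per_100g"]
    merged["cereal_fiber_g"] = merged["fiber_g"].where(merged["is_cereal"], 0.0)
    merged["energy_kcal"] = scale * merged["energy_kcal_per_100g"]
    merged["protein_g"] = scale * merged["protein_per_100g"]
    merged["fat_g"] = scale * merged["fat_per_100g"]
    return merged


def daily_gl_gi(records: pd.DataFrame, db: FoodTable) -> tuple[float, float | None, float]:
    """(GL grams, dietary GI, CHO grams) for one day of recall records.

    ``records`` needs ``food_id`` and ``grams`` columns. The GI is returned
    as None when the day contains no carbohydrate at all.
    """
    merged = _food_lookup(records, db)
    cho = float(merged["cho_g"].sum())
    gl = float(merged["gl_g"].sum())
    if cho <= 0:
        return gl, None, cho
    return gl, 100.0 * gl / cho, cho


def summarize_cohort(recalls: pd.DataFrame, db: FoodTable) -> pd.DataFrame:
    """Diet summary per participant: unweighted mean over available recall days.

    Returns one row per participant with n_recalls, energy_kcal_d, cho_g_d,
    gl_g_d, gi, fiber_g_d, cereal_fiber_g_d, protein_pct_e, fat_pct_e and
    cho_pct_e. Dietary GI is computed from the day-mean GL and CHO (the
    ratio of means, identical to the CHO-weighted mean over the whole
    recall period).
    """
    missing = [c for c in RECALL_COLUMNS if c not in recalls.columns]
    if missing:
        raise KeyError(f"recall table missing column(s): {missing}")
    merged = _food_lookup(recalls, db)
    per_day = merged.groupby(["participant_id", "day_index"], sort=False)[
        ["energy_kcal", "cho_g", "gl_g", "fiber_g", "cereal_fiber_g", "protein_g", "fat_g"]
    ].sum()
    per_pid = per_day.groupby(level="participant_id", sort=False).mean()
    n_recalls = per_day.groupby(level="participant_id", sort=False).size()

    out = pd.DataFrame(index=per_pid.index)
    out["n_recalls"] = n_recalls
    out["energy_kcal_d"] = per_pid["energy_kcal"]
    out["cho_g_d"] = per_pid["cho_g"]
    out["gl_g_d"] = per_pid["gl_g"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["gi"] = np.where(
            per_pid["cho_g"] > 0, 100.0 * per_pid["gl_g"] / per_pid["cho_g"], np.nan
        )
    out["fiber_g_d"] = per_pid["fiber_g"]
    out["cereal_fiber_g_d"] = per_pid["cereal_fiber_g"]
    energy = per_pid["energy_kcal"].replace(0.0, np.nan)
    out["protein_pct_e"] = 100.0 * 4.0 * per_pid["protein_g"] / energy
    out["fat_pct_e"] = 100.0 * 9.0 * per_pid["fat_g"] / energy
    out["cho_pct_e"] = 100.0 * 4.0 * per_pid["cho_g"] / energy
    out.index.name = "participant_id"
    return out


def summarize_participant(records: pd.DataFrame, db: FoodTable) -> pd.Series:
    """Diet summary for a single participant's recall records."""
    if records.empty:
        raise ValueError("participant has no recall records")
    return summarize_cohort(records, db).iloc[0]


def cereal_fiber(recalls: pd.DataFrame, db: FoodTable) -> pd.Series:
    """Mean daily cereal fiber (g/d) per participant.

    Sum of fiber from foods flagged as cereal (rice, millet, noodles,
    cereals, bread, cookies, crackers), averaged over recall days.
    """
    return summarize_cohort(recalls, db)["cereal_fiber_g_d"]


def plausibility_filter(
    summaries: pd.DataFrame, sex: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split participants into retained and excluded on daily energy.

    Retention bounds are inclusive at both ends: men 800-4200 kcal/d, women
    500-3500 kcal/d. Returns (retained summaries, exclusion log with an
    ``exclusion_reason`` column).
    """
    sex = sex.reindex(summaries.index)
    unknown = sex.isna() | ~sex.isin(ENERGY_BOUNDS_KCAL)
    if unknown.any():
        raise ValueError(
            f"unknown sex for participant(s): {list(summaries.index[unknown])}"
        )
    lo = sex.map({k: v[0] for k, v in ENERGY_BOUNDS_KCAL.items()})
    hi = sex.map({k: v[1] for k, v in ENERGY_BOUNDS_KCAL.items()})
    energy = summaries["energy_kcal_d"]
    keep = (energy >= lo) & (energy <= hi)
    excluded = summaries.loc[~keep].copy()
    excluded["exclusion_reason"] = np.where(
        energy.loc[~keep] < lo.loc[~keep],
        "energy below plausible bound",
        "energy above plausible bound",
    )
    return summaries.loc[keep].copy(), excluded


def energy_residuals(
    values: pd.Series, energy: pd.Series, sex: pd.Series
) -> pd.Series:
    """Sex-specific energy-adjusted residuals of a dietary variable.

    Within each sex stratum the variable is regressed on energy intake
    (ordinary least squares with intercept); the residual observed - fitted
    is returned. Residuals are orthogonal to energy within stratum. A
    stratum with no energy variance falls back to mean-centering, with a
    warning.
    """
    values, energy, sex = values.align(energy)[0], energy, sex.reindex(values.index)
    out = pd.Series(np.nan, index=values.index, name=f"{values.name}_resid")
    for stratum, idx in values.groupby(sex).groups.items():
        v = values.loc[idx].to_numpy(dtype=float)
        e = energy.loc[idx].to_numpy(dtype=float)
        if len(idx) < 3:
            raise ValueError(f"stratum {stratum!r} has fewer than 3 participants")
        if np.ptp(e) == 0:
            warnings.warn(
                f"stratum {stratum!r}: zero energy variance; residuals are "
                "mean-centered values",
                stacklevel=2,
            )
            out.loc[idx] = v - v.mean()
            continue
        slope, intercept = np.polyfit(e, v, 1)
        out.loc[idx] = v - (intercept + slope * e)
    return out


def assign_tertiles(values: pd.Series | Iterable[float]) -> pd.Series:
    """Tertile labels 1-3 with cuts at the 33.33rd/66.67th percentiles.

    Values exactly at a cut point go to the lower tertile (deterministic,
    order-independent tie-breaking). If all values are equal everything is
    tertile 1 and a warning is raised.
    """
    values = pd.Series(values)
    if len(values) < 3:
        raise ValueError("need at least 3 values to form tertiles")
    arr = values.to_numpy(dtype=float)
    q1, q2 = np.quantile(arr, [1.0 / 3.0, 2.0 / 3.0])
    if q1 == q2 and np.ptp(arr) == 0:
        warnings.warn("all values equal; every observation in tertile 1", stacklevel=2)
    labels = 1 + (arr > q1).astype(int) + (arr > q2).astype(int)
    return pd.Series(labels, index=values.index, name="tertile")


def ffq_gi_gl(items: Iterable[tuple[float, float, float]]) -> tuple[float, float]:
    """Dietary (GI, GL) from food-frequency items.

    ``items`` is an iterable of (servings per day, CHO grams per serving,
    GI). GL = sum(servings * cho * gi / 100); GI = 100 * GL / total CHO.
    """
    triples = [(float(s), float(c), float(g)) for s, c, g in items]
    total_cho = sum(s * c for s, c, _ in triples)
    if total_cho <= 0:
        raise UndefinedGIError("FFQ items have zero total carbohydrate; GI undefined")
    gl = sum(s * c * g for s, c, g in triples) / 100.0
    return 100.0 * gl / total_cho, gl
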