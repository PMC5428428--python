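"""Glucose-homeostasis indices, anthropometric indices and pre-diabetes.

HOMA indices come from the closed-form homeostasis-model equations
(IR = glucose * insulin / 22.5, beta = 20 * insulin / (glucose - 3.5), with
glucose in mmol/L and insulin in uIU/mL). The iterative HOMA2 computer model
is not available in closed form; the ``homa2_approx`` variant multiplies the
closed-form values by configurable recalibration constants (defaults 1.0) so
users who have fitted such constants can plug them in. Analyses in this
package therefore interpret HOMA contrasts on the closed-form scale.

Pre-diabetes follows the definition: fasting plasma glucose in
[5.5, 7.0) mmol/L or HbA1c in [5.7, 6.4] %. The FPG upper bound is exclusive
(7.0 is the diabetes threshold); the HbA1c bounds are inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

FPG_PREDIABETES_RANGE = (5.5, 7.0)   # mmol/L, [low, high)
HBA1C_PREDIABETES_RANGE = (5.7, 6.4)  # %, [low, high]

BF_PCT_BOUNDS = (3.0, 60.0)

#: Default body-fat-percentage coefficients (intercept, per BMI, per WC cm,
#: per male indicator). Synthetic surrogate constants chosen to put median
#: BF% of a typical adult cohort in the low-to-mid twenties; the canonical
#: published coefficients can be supplied instead.
DEFAULT_BF_COEFFICIENTS = (-22.9, 1.20, 0.23, -5.0)


@dataclass(frozen=True)
class HomaRecalibration:
    """Multiplicative recalibration constants for the homa2_approx variant."""

    ir_scale: float = 1.0
    beta_scale: float = 1.0


def homa_indices(
    fpg_mmol_l,
    insulin_uiu_ml,
    variant: str = "homa1",
    recalibration: HomaRecalibration = HomaRecalibration(),
):
    """(HOMA-IR, HOMA-beta %) from fasting glucose and insulin.

    Accepts scalars or aligned arrays/Series. HOMA-beta requires glucose
    above 3.5 mmol/L; at or below that it is returned as NaN with a warning.
    """
    if variant not in {"homa1", "homa2_approx"}:
        raise ValueError(f"unknown HOMA variant {variant!r}")
    fpg = np.asarray(fpg_mmol_l, dtype=float)
    ins = np.asarray(insulin_uiu_ml, dtype=float)
    if np.any(fpg <= 0) or np.any(ins <= 0):
        raise ValueError("glucose and insulin must be positive")
    ir = fpg * ins / 22.5
    denom = fpg - 3.5
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(denom > 0, 20.0 * ins / np.where(denom > 0, denom, np.nan), np.nan)
    if np.any(denom <= 0):
        warnings.warn(
            "HOMA-beta undefined for glucose <= 3.5 mmol/L; returned as missing",
            stacklevel=2,
        )
    if variant == "homa2_approx":
        ir = ir * recalibration.ir_scale
        beta = beta * recalibration.beta_scale
    if np.isscalar(fpg_mmol_l) and np.isscalar(insulin_uiu_ml):
        return float(ir), (float(beta) if np.isfinite(beta) else float("nan"))
    return ir, beta


def classify_prediabetes(fpg_mmol_l, hba1c_pct):
    """Pre-diabetes: FPG in [5.5, 7.0) mmol/L or HbA1c in [5.7, 6.4] %.

    Scalars or aligned arrays. Missing inputs yield a missing (pandas NA)
    classification.
    """
    fpg = np.asarray(fpg_mmol_l, dtype=float)
    h = np.asarray(hba1c_pct, dtype=float)
    f_lo, f_hi = FPG_PREDIABETES_RANGE
    h_lo, h_hi = HBA1C_PREDIABETES_RANGE
    flag = ((fpg >= f_lo) & (fpg < f_hi)) | ((h >= h_lo) & (h <= h_hi))
    missing = np.isnan(fpg) | np.isnan(h)
    if np.isscalar(fpg_mmol_l) and np.isscalar(hba1c_pct):
        return None if missing else bool(flag)
    out = pd.array(flag, dtype="boolean")
    out[missing] = pd.NA
    return out


def bmi_kg_m2(weight_kg, height_m):
    """Body-mass index, weight / height^2."""
    return np.asarray(weight_kg, dtype=float) / np.asarray(height_m, dtype=float) ** 2


def body_fat_pct(bmi, wc_cm, male, coefficients=DEFAULT_BF_COEFFICIENTS):
    """Percent body fat from BMI and waist circumference.

    Linear form a + b*BMI + c*WC + d*male_indicator, clipped to [3, 60] %.
    ``coefficients`` is pluggable; the default is a synthetic surrogate for
    the published BMI/WC equations (see module docstring).
    """
    a, b, c, d = coefficients
    bmi = np.asarray(bmi, dtype=float)
    wc = np.asarray(wc_cm, dtype=float)
    m = np.asarray(male, dtype=float)
    raw = a + b * bmi + c * wc + d * m
    return np.clip(raw, *BF_PCT_BOUNDS)


def derive_panel(participants: pd.DataFrame, variant: str = "homa1") -> pd.DataFrame:
    """Append derived biomarker and anthropometric columns.

    Expects fpg_mmol_l, insulin_uiu_ml, hba1c_pct, and (if present)
    weight_kg/height_m/wc_cm/sex. Derived columns (homa_ir, homa_beta_pct,
    prediabetes, bmi_kg_m2, bf_pct, overweight) are appended, never
    overwritten if already present.
    """
    out = participants.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ir, beta = homa_indices(out["fpg_mmol_l"], out["insulin_uiu_ml"], variant=variant)
    if "homa_ir" not in out:
        out["homa_ir"] = ir
    if "homa_beta_pct" not in out:
        out["homa_beta_pct"] = beta
    if "prediabetes" not in out:
        out["prediabetes"] = np.asarray(
            classify_prediabetes(out["fpg_mmol_l"], out["hba1c_pct"]), dtype=float
        )
    if {"weight_kg", "height_m"} <= set(out.columns) and "bmi_kg_m2" not in out:
        out["bmi_kg_m2"] = bmi_kg_m2(out["weight_kg"], out["height_m"])
    if {"bmi_kg_m2", "wc_cm", "sex"} <= set(out.columns):
        male = (out["sex"] == "male").astype(float)
        if "bf_pct" not in out:
            out["bf_pct"] = body_fat_pct(out["bmi_kg_m2"], out["wc_cm"], male)
        if "overweight" not in out:
            out["overweight"] = (out["bmi_kg_m2"] >= 25.0).astype(float)
    return out
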