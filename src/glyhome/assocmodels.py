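"""Covariate-adjusted association models for glucose homeostasis.

Continuous outcomes (fasting glucose, HbA1c, insulin, HOMA indices) are
log-transformed and fitted by ordinary least squares on exposure-tertile
indicators plus nested covariate tiers; reported group means are
least-squares means — the model prediction for each tertile with every other
covariate held at its sample mean (binary covariates at their observed
proportion) — back-transformed by exponentiation, with Wald 95% confidence
intervals formed on the model scale. Trend tests replace the tertile factor
by the continuous energy-adjusted residual in the same model. Pre-diabetes
is modelled by maximum-likelihood logistic regression with tertile 1 as the
reference. Interactions enter as a continuous exposure-residual x modifier
product term and are judged against a 0.1 significance threshold; joint
exposure/modifier effects are displayed by 3x3 cross-classification with a
single reference cell.

Adjustment tiers are nested:

    1: age, sex
    2: + smoking, physical activity, education
    3: + cereal-fiber residual, protein residual
    4: + body fatness

and, mirroring the source tables, models adjust for the weighted genetic
risk score by default ("adjusting for GRS only, i.e. without interaction
terms"); the interaction p-value comes from a separate fit that adds the
product term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConsistencyError, DegenerateModifierError, GlyhomeError

INTERACTION_ALPHA = 0.1
MAIN_ALPHA = 0.05

TIER_COVARIATES: dict[int, list[str]] = {
    0: [],  # unadjusted
    1: ["age_y", "female"],
    2: ["age_y", "female", "current_smoker", "activity_met_h_wk", "high_education"],
    3: [
        "age_y",
        "female",
        "current_smoker",
        "activity_met_h_wk",
        "high_education",
        "cereal_fiber_resid",
        "protein_resid",
    ],
    4: [
        "age_y",
        "female",
        "current_smoker",
        "activity_met_h_wk",
        "high_education",
        "cereal_fiber_resid",
        "protein_resid",
        "bf_pct",
    ],
}


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: outcome, exposure, adjustment tier, optional interaction.

    ``exposure`` is a column prefix: the cohort table must carry
    ``{exposure}_resid`` (energy-adjusted residual) and ``{exposure}_tertile``
    (labels 1-3). ``interaction_with`` names a continuous modifier column
    (e.g. ``grs_weighted`` or ``cereal_fiber_resid``).
    """

    outcome: str
    exposure: str = "gi"
    tier: int = 3
    log_transform: bool = True
    adjust_grs: bool = True
    interaction_with: str | None = None

    def covariates(self) -> list[str]:
        if self.tier not in TIER_COVARIATES:
            raise ValueError(f"unknown adjustment tier {self.tier}")
        covs = list(TIER_COVARIATES[self.tier])
        if self.adjust_grs and "grs_weighted" not in covs:
            covs.append("grs_weighted")
        return covs


@dataclass
class ModelResult:
    """Adjusted (back-transformed) tertile means with CIs and trend test."""

    outcome: str
    exposure: str
    tier: int
    estimates: pd.DataFrame  # index tertile 1..3; columns mean, ci_low, ci_high, n
    p_trend: float
    trend_slope: float
    p_interaction: float | None = None
    interaction_alpha: float = INTERACTION_ALPHA


@dataclass
class ORResult:
    """Per-tertile odds ratios for a binary outcome, tertile 1 = reference."""

    outcome: str
    exposure: str
    tier: int
    estimates: pd.DataFrame  # index tertile; columns odds_ratio, ci_low, ci_high, n, n_cases
    p_trend: float
    p_interaction: float | None = None
    interaction_alpha: float = INTERACTION_ALPHA


@dataclass
class CrossClassResult:
    """3x3 joint classification: cell sizes and adjusted estimates.

    ``estimate`` holds adjusted means for continuous outcomes or odds ratios
    (reference cell exactly 1) for binary outcomes; grids are indexed by
    exposure tertile (rows) x modifier tertile (columns).
    """

    outcome: str
    kind: str  # "means" or "odds_ratio"
    reference: tuple[int, int]
    n: pd.DataFrame
    estimate: pd.DataFrame
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        _, r = np.linalg.qr(arr)
        diag = np.abs(np.diag(r))
        bad = [X.columns[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise GlyhomeError(f"rank-deficient design; collinear column(s): {bad}")


def _design(df: pd.DataFrame, spec: ModelSpec, continuous_exposure: bool) -> pd.DataFrame:
    cols = {}
    cols["const"] = np.ones(len(df))
    if continuous_exposure:
        cols[f"{spec.exposure}_resid"] = df[f"{spec.exposure}_resid"].to_numpy(dtype=float)
    else:
        tert = df[f"{spec.exposure}_tertile"].to_numpy()
        cols["tertile_2"] = (tert == 2).astype(float)
        cols["tertile_3"] = (tert == 3).astype(float)
    for cov in spec.covariates():
        cols[cov] = df[cov].to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=df.index)
    _check_rank(X)
    return X


def _outcome_vector(df: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    y = df[spec.outcome].to_numpy(dtype=float)
    if spec.log_transform:
        if np.any(y <= 0):
            raise ValueError(f"{spec.outcome}: non-positive values cannot be log-transformed")
        y = np.log(y)
    return y


def _lsmean_rows(X: pd.DataFrame) -> dict[int, np.ndarray]:
    """Design rows evaluating each tertile at sample-mean covariates."""
    base = X.mean(axis=0).to_numpy()
    names = list(X.columns)
    i2, i3 = names.index("tertile_2"), names.index("tertile_3")
    rows = {}
    for t in (1, 2, 3):
        row = base.copy()
        row[i2] = 1.0 if t == 2 else 0.0
        row[i3] = 1.0 if t == 3 else 0.0
        rows[t] = row
    return rows


def fit_adjusted_means(df: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """OLS fit of the (log) outcome on exposure tertiles + covariates.

    Returns back-transformed least-squares means per tertile with 95% Wald
    CIs, the continuous-residual trend test, and (when requested) the
    interaction p-value from a separate fit including the product term.
    """
    y = _outcome_vector(df, spec)
    X = _design(df, spec, continuous_exposure=False)
    fit = sm.OLS(y, X).fit()
    rows = _lsmean_rows(X)
    cov = fit.cov_params().to_numpy()
    params = fit.params.to_numpy()
    records = []
    tert = df[f"{spec.exposure}_tertile"]
    for t in (1, 2, 3):
        x = rows[t]
        est = float(x @ params)
        se = float(np.sqrt(x @ cov @ x))
        lo, hi = est - 1.96 * se, est + 1.96 * se
        if spec.log_transform:
            est, lo, hi = np.exp(est), np.exp(lo), np.exp(hi)
        records.append(
            {"tertile": t, "mean": est, "ci_low": lo, "ci_high": hi, "n": int((tert == t).sum())}
        )
    trend = trend_test(df, spec)
    p_inter = None
    if spec.interaction_with is not None:
        p_inter = interaction_scan(df, spec, spec.interaction_with).p_value
    return ModelResult(
        outcome=spec.outcome,
        exposure=spec.exposure,
        tier=spec.tier,
        estimates=pd.DataFrame(records).set_index("tertile"),
        p_trend=trend.p_value,
        trend_slope=trend.slope,
        p_interaction=p_inter,
    )


@dataclass(frozen=True)
class TrendResult:
    slope: float
    se: float
    p_value: float


def trend_test(df: pd.DataFrame, spec: ModelSpec) -> TrendResult:
    """Trend test: the continuous residual replaces the tertile factor."""
    y = _outcome_vector(df, spec)
    X = _design(df, spec, continuous_exposure=True)
    binary = not spec.log_transform and set(np.unique(y)) <= {0.0, 1.0}
    fit = _fit_logit(y, X) if binary else sm.OLS(y, X).fit()
    name = f"{spec.exposure}_resid"
    slope = float(fit.params[name])
    p = float(fit.pvalues[name])
    if np.isnan(p):  # zero residual variance (e.g. constant outcome)
        p = 1.0 if abs(slope) < 1e-12 else 0.0
    return TrendResult(slope=slope, se=float(fit.bse[name]), p_value=p)


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    import warnings as _warnings

    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if not fit.mle_retvals.get("converged", True):
                # Newton can stall on ill-scaled designs; BFGS is slower but sturdier
                fit = sm.Logit(y, X).fit(disp=0, method="bfgs", maxiter=1000)
    except Exception as exc:  # statsmodels raises several separation/convergence types
        raise GlyhomeError(
            "logistic fit failed (possible separation; penalized estimation is "
            f"out of scope): {exc}"
        ) from exc
    if not fit.mle_retvals.get("converged", True):
        raise GlyhomeError("logistic fit did not converge (possible separation)")
    return fit


def fit_prediabetes_or(df: pd.DataFrame, spec: ModelSpec) -> ORResult:
    """Logistic regression of a binary outcome on exposure tertiles.

    Tertile 1 is the reference (odds ratio exactly 1); the trend p-value
    comes from the logistic model with the continuous residual.
    """
    spec = ModelSpec(
        outcome=spec.outcome,
        exposure=spec.exposure,
        tier=spec.tier,
        log_transform=False,
        adjust_grs=spec.adjust_grs,
        interaction_with=spec.interaction_with,
    )
    y = df[spec.outcome].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError(f"{spec.outcome} is not binary 0/1")
    X = _design(df, spec, continuous_exposure=False)
    fit = _fit_logit(y, X)
    conf = fit.conf_int()
    tert = df[f"{spec.exposure}_tertile"]
    records = [
        {
            "tertile": 1,
            "odds_ratio": 1.0,
            "ci_low": 1.0,
            "ci_high": 1.0,
            "n": int((tert == 1).sum()),
            "n_cases": int(y[tert == 1].sum()),
        }
    ]
    for t in (2, 3):
        name = f"tertile_{t}"
        records.append(
            {
                "tertile": t,
                "odds_ratio": float(np.exp(fit.params[name])),
                "ci_low": float(np.exp(conf.loc[name, 0])),
                "ci_high": float(np.exp(conf.loc[name, 1])),
                "n": int((tert == t).sum()),
                "n_cases": int(y[tert == t].sum()),
            }
        )
    trend = trend_test(df, spec)
    p_inter = None
    if spec.interaction_with is not None:
        p_inter = interaction_scan(df, spec, spec.interaction_with).p_value
    return ORResult(
        outcome=spec.outcome,
        exposure=spec.exposure,
        tier=spec.tier,
        estimates=pd.DataFrame(records).set_index("tertile"),
        p_trend=trend.p_value,
        p_interaction=p_inter,
    )


@dataclass(frozen=True)
class InteractionResult:
    coefficient: float
    se: float
    p_value: float
    alpha: float = INTERACTION_ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def interaction_scan(df: pd.DataFrame, spec: ModelSpec, modifier: str) -> InteractionResult:
    """Wald test of the continuous exposure-residual x modifier product term.

    The modifier (weighted GRS or a nutrient residual) enters as a continuous
    covariate alongside the product term; significance threshold 0.1.
    """
    mod = df[modifier].to_numpy(dtype=float)
    if np.ptp(mod) == 0:
        raise DegenerateModifierError(f"modifier {modifier!r} is constant")
    y_spec_binary = spec.outcome == "prediabetes" or not spec.log_transform
    y = (
        df[spec.outcome].to_numpy(dtype=float)
        if y_spec_binary
        else _outcome_vector(df, spec)
    )
    X = _design(df, spec, continuous_exposure=True)
    if modifier not in X.columns:
        X = X.assign(**{modifier: mod})
    X = X.assign(interaction=df[f"{spec.exposure}_resid"].to_numpy(dtype=float) * mod)
    _check_rank(X)
    binary = set(np.unique(y)) <= {0.0, 1.0}
    fit = _fit_logit(y, X) if binary else sm.OLS(y, X).fit()
    return InteractionResult(
        coefficient=float(fit.params["interaction"]),
        se=float(fit.bse["interaction"]),
        p_value=float(fit.pvalues["interaction"]),
    )


def cross_classify(
    df: pd.DataFrame,
    exposure_tertile: str,
    modifier_tertile: str,
    outcome: str,
    tier: int = 3,
    log_transform: bool = True,
    reference: tuple[int, int] = (1, 1),
    adjust_grs: bool = False,
    exclude_covariates: tuple[str, ...] = (),
) -> CrossClassResult:
    """Joint 3x3 classification by exposure and modifier tertiles.

    Continuous outcomes: adjusted (least-squares) cell means. Binary
    outcomes: odds ratios versus the ``reference`` cell from a logistic
    model with an 8-level cell factor plus the tier covariates.
    ``exclude_covariates`` drops named tier covariates from the adjustment —
    used when the modifier's own continuous version sits in the tier, which
    would otherwise adjust away the very contrast being displayed.
    """
    spec = ModelSpec(outcome=outcome, tier=tier, log_transform=log_transform, adjust_grs=adjust_grs)
    e = df[exposure_tertile].to_numpy()
    m = df[modifier_tertile].to_numpy()
    cells = [(i, j) for i in (1, 2, 3) for j in (1, 2, 3)]
    counts = {c: int(np.sum((e == c[0]) & (m == c[1]))) for c in cells}
    empty = [c for c, k in counts.items() if k == 0]
    if empty:
        raise GlyhomeError(f"empty cross-classification cell(s): {empty}")
    if reference not in cells:
        raise ValueError(f"reference cell {reference} not a tertile pair")

    cols = {"const": np.ones(len(df))}
    for c in cells:
        if c == reference:
            continue
        cols[f"cell_{c[0]}{c[1]}"] = ((e == c[0]) & (m == c[1])).astype(float)
    for cov in spec.covariates():
        if cov in exclude_covariates:
            continue
        cols[cov] = df[cov].to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=df.index)
    _check_rank(X)

    y = df[outcome].to_numpy(dtype=float)
    binary = set(np.unique(y)) <= {0.0, 1.0}

    def grid() -> pd.DataFrame:
        return pd.DataFrame(
            np.zeros((3, 3)),
            index=pd.Index([1, 2, 3], name=f"{exposure_tertile}"),
            columns=pd.Index([1, 2, 3], name=f"{modifier_tertile}"),
        )

    n_grid, est, lo, hi = grid(), grid(), grid(), grid()
    for c, k in counts.items():
        n_grid.loc[c[0], c[1]] = k

    if binary:
        fit = _fit_logit(y, X)
        conf = fit.conf_int()
        for c in cells:
            if c == reference:
                est.loc[c[0], c[1]] = 1.0
                lo.loc[c[0], c[1]] = 1.0
                hi.loc[c[0], c[1]] = 1.0
                continue
            name = f"cell_{c[0]}{c[1]}"
            est.loc[c[0], c[1]] = np.exp(fit.params[name])
            lo.loc[c[0], c[1]] = np.exp(conf.loc[name, 0])
            hi.loc[c[0], c[1]] = np.exp(conf.loc[name, 1])
        kind = "odds_ratio"
    else:
        yv = np.log(y) if log_transform else y
        fit = sm.OLS(yv, X).fit()
        params = fit.params.to_numpy()
        covm = fit.cov_params().to_numpy()
        base = X.mean(axis=0).to_numpy()
        names = list(X.columns)
        cell_idx = {nm: i for i, nm in enumerate(names) if nm.startswith("cell_")}
        for c in cells:
            row = base.copy()
            for nm, i in cell_idx.items():
                row[i] = 0.0
            if c != reference:
                row[cell_idx[f"cell_{c[0]}{c[1]}"]] = 1.0
            e_est = float(row @ params)
            se = float(np.sqrt(row @ covm @ row))
            lo_v, hi_v = e_est - 1.96 * se, e_est + 1.96 * se
            if log_transform:
                e_est, lo_v, hi_v = np.exp(e_est), np.exp(lo_v), np.exp(hi_v)
            est.loc[c[0], c[1]] = e_est
            lo.loc[c[0], c[1]] = lo_v
            hi.loc[c[0], c[1]] = hi_v
        kind = "means"

    return CrossClassResult(
        outcome=outcome, kind=kind, reference=reference,
        n=n_grid, estimate=est, ci_low=lo, ci_high=hi,
    )


def energy_partition_fit(
    df: pd.DataFrame,
    component_cols: list[str],
    total_energy_col: str,
    outcome: str,
    tier: int = 3,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Energy partition model: source-specific energies as separate terms.

    Each named component energy (kcal/d) and the remaining energy
    (total - sum of components) enter the adjusted model as separate
    continuous terms, so each coefficient is the effect of adding energy
    from that source while holding the others fixed. Components exceeding
    total energy raise a consistency error.
    """
    comp = df[component_cols].to_numpy(dtype=float)
    total = df[total_energy_col].to_numpy(dtype=float)
    remaining = total - comp.sum(axis=1)
    if np.any(remaining < -1e-6):
        raise ConsistencyError("component energies exceed total energy for some participants")
    spec = ModelSpec(outcome=outcome, tier=tier, log_transform=log_transform, adjust_grs=False)
    cols = {"const": np.ones(len(df))}
    for c in component_cols:
        cols[c] = df[c].to_numpy(dtype=float)
    cols["remaining_energy"] = remaining
    for cov in spec.covariates():
        cols[cov] = df[cov].to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=df.index)
    _check_rank(X)
    y = df[outcome].to_numpy(dtype=float)
    binary = set(np.unique(y)) <= {0.0, 1.0}
    if binary:
        fit = _fit_logit(y, X)
    else:
        fit = sm.OLS(np.log(y) if log_transform else y, X).fit()
    rows = []
    for c in component_cols + ["remaining_energy"]:
        rows.append(
            {
                "term": c,
                "coefficient": float(fit.params[c]),
                "se": float(fit.bse[c]),
                "p_value": float(fit.pvalues[c]),
            }
        )
    return pd.DataFrame(rows).set_index("term")


def percent_contrast(result: ModelResult, from_tertile: int = 1, to_tertile: int = 3) -> float:
    """Percent difference between two adjusted tertile means."""
    m_from = float(result.estimates.loc[from_tertile, "mean"])
    m_to = float(result.estimates.loc[to_tertile, "mean"])
    if m_from <= 0:
        raise ValueError("percent contrast undefined for non-positive baseline mean")
    return 100.0 * (m_to - m_from) / m_from
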