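"""Synthetic cohort generator calibrated to the study's printed effects.

The generator emulates a south-Chinese adult cohort (default n = 3918,
~53% female, mean dietary GI ~69, energy ~1670 kcal/d) in which white rice
dominates carbohydrate intake. Each participant gets:

1. demographics and lifestyle covariates with realistic margins;
2. a latent diet preference: a target dietary GI drawn around 69 that sets
   the share of staple carbohydrate coming from a high-GI pool (sticky
   rice, steamed bread) versus a lower-GI pool (wheat noodles, mung-bean
   noodles, lower-GI rice, black-rice porridge), plus side dishes; the
   preference is materialised as 1-3 days of 24-hour recall records with
   day-level portion noise;
3. genotypes at 12 risk SNPs drawn in Hardy-Weinberg equilibrium, scored
   into the weighted genetic risk score by the genetics module;
4. log-normal fasting glucose, HbA1c and insulin driven by linear
   predictors in the *scored* energy-adjusted GI residual, the weighted
   GRS, the cereal-fiber residual and their products. The exposures feeding
   the outcome model are computed by the same scoring code the analysis
   pipeline uses, so generator and pipeline agree exactly.

Pre-diabetes is never drawn directly: the pipeline classifies it from the
generated glucose and HbA1c, keeping the classification logic on the test
path. Because the classification is a *window* (FPG in [5.5, 7.0), HbA1c in
[5.7, 6.4]), the odds-ratio structure of the cohort is shaped by both the
location effects and the residual spreads; the default spreads are part of
the calibration (see docs/methods.md) and are deliberately wider than a
narrow metabolic-panel spread so that the classification reproduces the
target prevalence and adjusted odds-ratio pattern alongside the continuous
mean contrasts.

HOMA indices are always derived downstream by the biomarkers module, never
generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import dietmetrics, genetics
from .errors import CalibrationError
from .fooddb import FoodTable, demo_catalog

# --------------------------------------------------------------------------
# diet construction constants (CHO shares within each staple pool; grams of
# side dishes at the reference energy intake)

HIGH_POOL_CHO_SHARES = {"rice_sticky": 0.50, "steamed_bread": 0.40, "rice_high": 0.10}
LOW_POOL_CHO_SHARES = {
    "wheat_noodles": 0.30,
    "mung_noodles": 0.25,
    "black_porridge": 0.15,
    "rice_low": 0.20,
    "rice_low_b": 0.10,
}
SIDE_GRAMS_AT_REFERENCE = {
    "vegetables": 250.0,
    "pork": 110.0,
    "egg": 40.0,
    "tofu": 40.0,
    "oil": 22.0,
    "apple": 50.0,
}
REFERENCE_ENERGY_KCAL = 1670.0
STAPLE_ENERGY_FRACTION = 0.585


@dataclass(frozen=True)
class OutcomeCoefficients:
    """Log-scale linear predictor for one biomarker.

    ``gmean`` is the back-transformed intercept (the geometric mean at mean
    exposure and covariates); slopes are per GI-residual point, per SD of
    the weighted GRS, per SD of the cereal-fiber residual, and per product
    unit for the interactions; ``sigma`` is the residual SD on the log scale.
    """

    gmean: float
    beta_exposure: float
    beta_grs: float = 0.0
    beta_inter_grs: float = 0.0
    beta_cf: float = 0.0
    beta_inter_cf: float = 0.0
    beta_age: float = 0.0
    beta_female: float = 0.0
    sigma: float = 0.1


def default_outcome_models() -> dict[str, OutcomeCoefficients]:
    """Calibrated defaults (see :func:`calibrate` and docs/methods.md)."""
    return {
        "fpg": OutcomeCoefficients(
            gmean=5.4833, beta_exposure=0.0060190, beta_grs=0.0455, beta_inter_grs=0.0016,
            beta_cf=-0.0540, beta_inter_cf=-0.0013, beta_age=0.015, beta_female=-0.010,
            sigma=0.30,
        ),
        "hba1c": OutcomeCoefficients(
            gmean=5.8009, beta_exposure=0.0010874, beta_grs=0.0119, beta_inter_grs=0.0008,
            beta_cf=-0.0118, beta_inter_cf=-0.0006, beta_age=0.010, beta_female=-0.005,
            sigma=0.20,
        ),
        "insulin": OutcomeCoefficients(
            gmean=7.1148, beta_exposure=0.0074600, beta_grs=0.050, beta_inter_grs=0.0020,
            beta_cf=-0.005, beta_inter_cf=-0.0010, beta_age=0.020, beta_female=0.020,
            sigma=0.42,
        ),
    }


@dataclass
class CohortConfig:
    """Everything the generator needs; defaults are the study conditions."""

    n: int = 3918
    female_frac: float = 0.529
    #: probability of having 3 / 2 / 1 recall days
    recall_mix: tuple[float, float, float] = (0.80, 0.16, 0.04)

    age_mean: float = 46.0
    age_sd: float = 14.0
    age_range: tuple[float, float] = (23.0, 69.0)
    urban_frac: float = 0.287
    smoker_frac: float = 0.28
    high_edu_frac: float = 0.112
    activity_mean: float = 14.7
    activity_sd: float = 12.0

    energy_mean_male: float = 1840.0
    energy_mean_female: float = 1520.0
    energy_log_sd: float = 0.27
    #: pre-truncation mean/sd of the target dietary GI; the truncated draw
    #: lands the cohort mean near 69
    gi_target_mean: float = 76.0
    gi_target_sd: float = 11.0
    gi_target_range: tuple[float, float] = (44.0, 79.5)
    staple_share_sd: float = 0.12
    day_noise_sd: float = 0.15
    side_noise_sd: float = 0.20

    #: FFQ measurement model: shrinkage of the diet preference toward the
    #: cohort mean plus extra noise, mimicking frequency-questionnaire error
    ffq_shrink: float = 0.70
    ffq_gi_noise_sd: float = 4.5
    ffq_serving_noise_sd: float = 0.30

    insulin_fpg_rho: float = 0.40
    outcome_models: dict[str, OutcomeCoefficients] = field(default_factory=default_outcome_models)
    #: calibration guard: |log-scale slope| per GI point may not exceed this
    max_exposure_coefficient: float = 0.05

    def validate(self) -> None:
        if self.n < 30:
            raise ValueError("cohort size must be at least 30")
        if not 0 <= self.female_frac <= 1:
            raise ValueError("female_frac must lie in [0, 1]")
        if abs(sum(self.recall_mix) - 1.0) > 1e-9:
            raise ValueError("recall mix must sum to 1")
        for name, m in self.outcome_models.items():
            if m.sigma <= 0:
                raise ValueError(f"{name}: residual SD must be positive")


@dataclass
class GeneratedCohort:
    """Observable tables plus the ground-truth latents behind them."""

    participants: pd.DataFrame
    recalls: pd.DataFrame
    genotypes: genetics.GenotypePanel
    ffq: pd.DataFrame
    ffq_items: pd.DataFrame
    truth: pd.DataFrame
    catalog: FoodTable
    seed: int

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.participants.to_csv(outdir / "participants.tsv", sep="\t", index=False)
        self.recalls.to_csv(outdir / "recalls.tsv", sep="\t", index=False)
        genetics.write_panel(
            self.genotypes, outdir / "genotypes.tsv", outdir / "snp_meta.tsv"
        )
        self.ffq.to_csv(outdir / "ffq.tsv", sep="\t", index=False)
        self.ffq_items.to_csv(outdir / "ffq_items.tsv", sep="\t", index=False)
        self.truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)


def _truncated_normal(rng, mean, sd, lo, hi, size) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, int(bad.sum())) if np.isscalar(mean) else rng.normal(
            np.broadcast_to(mean, out.shape)[bad], sd, int(bad.sum())
        )
    return np.clip(out, lo, hi)


def _pool_stats(catalog: FoodTable) -> dict:
    comp = catalog.composition_frame()

    def pool(shares):
        gi = sum(s * comp.loc[f, "gi"] for f, s in shares.items())
        kcal_per_g_cho = sum(
            s * comp.loc[f, "energy_kcal_per_100g"] / comp.loc[f, "cho_per_100g"]
            for f, s in shares.items()
        )
        return gi, kcal_per_g_cho

    gi_hi, k_hi = pool(HIGH_POOL_CHO_SHARES)
    gi_lo, k_lo = pool(LOW_POOL_CHO_SHARES)
    return {"gi_hi": gi_hi, "gi_lo": gi_lo, "kcal_per_g_cho": 0.5 * (k_hi + k_lo), "comp": comp}


def _base_day_grams(
    energy: np.ndarray,
    gi_target: np.ndarray,
    staple_share: np.ndarray,
    side_noise: np.ndarray,
    catalog: FoodTable,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-participant base (noise-free) grams for one day, all foods.

    Returns (grams frame indexed by participant position, columns food ids)
    and the realized high-pool carbohydrate fraction lambda.
    """
    stats = _pool_stats(catalog)
    comp = stats["comp"]
    n = len(energy)

    staple_energy = STAPLE_ENERGY_FRACTION * energy * staple_share
    side_energy_budget = energy - staple_energy

    side_ids = list(SIDE_GRAMS_AT_REFERENCE)
    side_base = np.array([SIDE_GRAMS_AT_REFERENCE[f] for f in side_ids])
    side_energy_per_g = np.array(
        [comp.loc[f, "energy_kcal_per_100g"] / 100.0 for f in side_ids]
    )
    base_side_energy = float(side_base @ side_energy_per_g)
    side_scale = side_energy_budget / base_side_energy  # (n,)
    side_grams = side_scale[:, None] * side_base[None, :] * side_noise

    side_cho = side_grams @ np.array([comp.loc[f, "cho_per_100g"] / 100.0 for f in side_ids])
    side_gl = side_grams @ np.array(
        [comp.loc[f, "cho_per_100g"] / 100.0 * comp.loc[f, "gi"] / 100.0 for f in side_ids]
    )

    staple_cho = staple_energy / stats["kcal_per_g_cho"]
    total_cho = staple_cho + side_cho
    # solve the high-pool CHO fraction that realizes the target dietary GI
    needed_pool_gi = (gi_target * total_cho - 100.0 * side_gl) / staple_cho
    lam = (needed_pool_gi - stats["gi_lo"]) / (stats["gi_hi"] - stats["gi_lo"])
    lam = np.clip(lam, 0.0, 1.0)

    grams = {}
    for f, share in HIGH_POOL_CHO_SHARES.items():
        grams[f] = staple_cho * lam * share / (comp.loc[f, "cho_per_100g"] / 100.0)
    for f, share in LOW_POOL_CHO_SHARES.items():
        grams[f] = staple_cho * (1 - lam) * share / (comp.loc[f, "cho_per_100g"] / 100.0)
    for j, f in enumerate(side_ids):
        grams[f] = side_grams[:, j]
    return pd.DataFrame(grams), lam


def _recalls_from_base(
    base: pd.DataFrame, pids: np.ndarray, n_recalls: np.ndarray, rng, day_noise_sd: float
) -> pd.DataFrame:
    frames = []
    n_foods = base.shape[1]
    for day in (1, 2, 3):
        has_day = n_recalls >= day
        idx = np.where(has_day)[0]
        noise = np.exp(
            rng.normal(-0.5 * day_noise_sd**2, day_noise_sd, (len(idx), n_foods))
        )
        grams = base.iloc[idx].to_numpy() * noise
        frame = pd.DataFrame(
            {
                "participant_id": np.repeat(pids[idx], n_foods),
                "day_index": day,
                "food_id": np.tile(base.columns.to_numpy(), len(idx)),
                "grams": np.round(grams.ravel(), 1),
            }
        )
        frames.append(frame)
    recalls = pd.concat(frames, ignore_index=True)
    return recalls[recalls["grams"] >= 1.0].reset_index(drop=True)


def generate(config: CohortConfig | None = None, seed: int = 0) -> GeneratedCohort:
    """Draw a full synthetic cohort; bit-identical for a fixed (config, seed).

    One master seed is expanded into named substreams (demographics, diet,
    recall days, genotypes, outcomes, FFQ), so adding draws to one component
    never perturbs the others.
    """
    config = config or CohortConfig()
    config.validate()
    streams = np.random.SeedSequence(seed).spawn(6)
    rng_demo, rng_diet, rng_days, rng_geno, rng_out, rng_ffq = (
        np.random.default_rng(s) for s in streams
    )
    catalog = demo_catalog()
    n = config.n
    pids = np.array([f"p{i + 1:05d}" for i in range(n)])

    # --- demographics -----------------------------------------------------
    female = rng_demo.random(n) < config.female_frac
    age = _truncated_normal(rng_demo, config.age_mean, config.age_sd, *config.age_range, n)
    urban = rng_demo.random(n) < config.urban_frac
    smoker = rng_demo.random(n) < config.smoker_frac
    high_edu = rng_demo.random(n) < config.high_edu_frac
    shape = (config.activity_mean / config.activity_sd) ** 2
    activity = rng_demo.gamma(shape, config.activity_mean / shape, n)

    # --- diet latents and recalls ----------------------------------------
    mean_energy = np.where(female, config.energy_mean_female, config.energy_mean_male)
    bounds_lo = np.where(female, 500.0, 800.0)
    bounds_hi = np.where(female, 3500.0, 4200.0)
    log_e = rng_diet.normal(np.log(mean_energy) - 0.5 * config.energy_log_sd**2,
                            config.energy_log_sd, n)
    energy = np.exp(log_e)
    for _ in range(50):
        bad = (energy < bounds_lo) | (energy > bounds_hi)
        if not bad.any():
            break
        energy[bad] = np.exp(
            rng_diet.normal(
                np.log(mean_energy[bad]) - 0.5 * config.energy_log_sd**2,
                config.energy_log_sd,
            )
        )
    energy = np.clip(energy, bounds_lo, bounds_hi)

    gi_target = _truncated_normal(
        rng_diet, config.gi_target_mean, config.gi_target_sd, *config.gi_target_range, n
    )
    staple_share = _truncated_normal(rng_diet, 1.0, config.staple_share_sd, 0.65, 1.35, n)
    side_ids = list(SIDE_GRAMS_AT_REFERENCE)
    side_noise = np.exp(
        rng_diet.normal(-0.5 * config.side_noise_sd**2, config.side_noise_sd, (n, len(side_ids)))
    )
    base, lam = _base_day_grams(energy, gi_target, staple_share, side_noise, catalog)

    n_recalls = rng_days.choice([3, 2, 1], size=n, p=list(config.recall_mix))
    recalls = _recalls_from_base(base, pids, n_recalls, rng_days, config.day_noise_sd)

    # --- score the diet exactly as the pipeline will ----------------------
    diet = dietmetrics.summarize_cohort(recalls, catalog).reindex(pids)
    sex = pd.Series(np.where(female, "female", "male"), index=pids)
    gi_resid = dietmetrics.energy_residuals(diet["gi"], diet["energy_kcal_d"], sex)
    cf_resid = dietmetrics.energy_residuals(
        diet["cereal_fiber_g_d"], diet["energy_kcal_d"], sex
    )
    z_cf = (cf_resid / cf_resid.std()).to_numpy()
    r = gi_resid.to_numpy()

    # --- genotypes --------------------------------------------------------
    meta = genetics.default_snp_meta()
    dosages = pd.DataFrame(
        {
            snp: rng_geno.binomial(2, meta.loc[snp, "risk_allele_freq"], n)
            for snp in meta.index
        },
        index=pids,
    )
    panel = genetics.GenotypePanel(dosages=dosages, snp_meta=meta)
    grs = genetics.weighted_grs(panel)["grs_weighted"]
    z_grs = ((grs - grs.mean()) / grs.std()).to_numpy()

    # --- outcomes ---------------------------------------------------------
    z_age = (age - config.age_mean) / config.age_sd
    fem = female.astype(float)

    def linear_predictor(m: OutcomeCoefficients) -> np.ndarray:
        return (
            np.log(m.gmean)
            + m.beta_exposure * r
            + m.beta_grs * z_grs
            + m.beta_inter_grs * r * z_grs
            + m.beta_cf * z_cf
            + m.beta_inter_cf * r * z_cf
            + m.beta_age * z_age
            + m.beta_female * fem
        )

    z_f = rng_out.standard_normal(n)
    z_h = rng_out.standard_normal(n)
    z_i_ind = rng_out.standard_normal(n)
    rho = config.insulin_fpg_rho
    z_i = rho * z_f + np.sqrt(1 - rho**2) * z_i_ind

    models = config.outcome_models
    fpg = np.exp(linear_predictor(models["fpg"]) + models["fpg"].sigma * z_f)
    hba1c = np.exp(linear_predictor(models["hba1c"]) + models["hba1c"].sigma * z_h)
    insulin = np.exp(linear_predictor(models["insulin"]) + models["insulin"].sigma * z_i)

    # --- anthropometry ----------------------------------------------------
    height = np.where(
        female,
        rng_out.normal(1.57, 0.055, n),
        rng_out.normal(1.68, 0.060, n),
    )
    bmi = _truncated_normal(rng_out, 23.7, 3.2, 16.0, 38.0, n)
    weight = bmi * height**2
    wc = 2.4 * bmi + 24.0 - 6.0 * fem + rng_out.normal(0, 4.0, n)

    participants = pd.DataFrame(
        {
            "participant_id": pids,
            "sex": np.where(female, "female", "male"),
            "age_y": np.round(age, 1),
            "urban": urban.astype(int),
            "current_smoker": smoker.astype(int),
            "high_education": high_edu.astype(int),
            "activity_met_h_wk": np.round(activity, 2),
            "height_m": np.round(height, 3),
            "weight_kg": np.round(weight, 1),
            "wc_cm": np.round(wc, 1),
            "history_diabetes": 0,
            "history_cvd_cancer": 0,
            "fpg_mmol_l": np.round(fpg, 3),
            "insulin_uiu_ml": np.round(insulin, 3),
            "hba1c_pct": np.round(hba1c, 3),
        }
    )

    # --- FFQ (attenuated view of the same diet) ---------------------------
    gi_ffq_target = (
        config.ffq_shrink * gi_target
        + (1 - config.ffq_shrink) * float(np.mean(gi_target))
        + rng_ffq.normal(0, config.ffq_gi_noise_sd, n)
    )
    gi_ffq_target = np.clip(gi_ffq_target, *config.gi_target_range)
    ffq_base, _ = _base_day_grams(energy, gi_ffq_target, staple_share, side_noise, catalog)
    serving_noise = np.exp(
        rng_ffq.normal(
            -0.5 * config.ffq_serving_noise_sd**2,
            config.ffq_serving_noise_sd,
            ffq_base.shape,
        )
    )
    servings = ffq_base.to_numpy() * serving_noise / 100.0  # 100 g standard servings
    ffq = pd.DataFrame(
        {
            "participant_id": np.repeat(pids, ffq_base.shape[1]),
            "item_id": np.tile(ffq_base.columns.to_numpy(), n),
            "servings_per_day": np.round(servings.ravel(), 3),
        }
    )
    ffq = ffq[ffq["servings_per_day"] > 0.005].reset_index(drop=True)
    comp = catalog.composition_frame()
    ffq_items = pd.DataFrame(
        {
            "item_id": comp.index,
            "cho_per_serving": comp["cho_per_100g"].to_numpy(),
            "gi": comp["gi"].to_numpy(),
        }
    )

    truth = pd.DataFrame(
        {
            "participant_id": pids,
            "gi_target": gi_target,
            "lambda_high_pool": lam,
            "energy_true_kcal": energy,
            "gi_resid_used": r,
            "z_grs": z_grs,
            "z_cereal_fiber": z_cf,
            "lp_fpg": linear_predictor(models["fpg"]),
            "lp_hba1c": linear_predictor(models["hba1c"]),
            "lp_insulin": linear_predictor(models["insulin"]),
        }
    )

    return GeneratedCohort(
        participants=participants,
        recalls=recalls,
        genotypes=panel,
        ffq=ffq,
        ffq_items=ffq_items,
        truth=truth,
        catalog=catalog,
        seed=seed,
    )


# --------------------------------------------------------------------------
# calibration


@dataclass(frozen=True)
class ContrastTarget:
    """One outcome's calibration target: extreme-tertile ratio and top level."""

    ratio: float       # adjusted top/bottom tertile ratio of the outcome
    top_level: float   # adjusted (geometric-mean) level in the top tertile


DEFAULT_TARGETS: dict[str, ContrastTarget] = {
    "fpg": ContrastTarget(ratio=5.67 / 5.19, top_level=5.67),
    "hba1c": ContrastTarget(ratio=1.012, top_level=5.82),
    "insulin": ContrastTarget(ratio=7.53 / 6.73, top_level=7.53),
}


@dataclass
class CalibrationReport:
    delta_residual: float
    tertile_means: dict[int, float]
    coefficients: dict[str, OutcomeCoefficients]


def calibrate(
    targets: dict[str, ContrastTarget] | None = None,
    config: CohortConfig | None = None,
    seed: int = 20170324,
) -> tuple[CohortConfig, CalibrationReport]:
    """Solve outcome coefficients implying the requested tertile contrasts.

    A pilot cohort is drawn to measure the spread of the energy-adjusted GI
    residual; on the log scale the exposure slope is log(target ratio)
    divided by the difference in mean residual between extreme tertiles,
    and the intercept anchors the top-tertile geometric mean at the target
    level. Infeasible targets (slope beyond the configured cap) raise a
    calibration error.
    """
    targets = targets or DEFAULT_TARGETS
    config = config or CohortConfig()
    pilot = generate(config, seed=seed)
    r = pd.Series(pilot.truth["gi_resid_used"].to_numpy())
    tert = dietmetrics.assign_tertiles(r)
    means = {t: float(r[tert == t].mean()) for t in (1, 2, 3)}
    delta = means[3] - means[1]
    if delta <= 0:
        raise CalibrationError("zero or negative exposure spread in pilot cohort")
    new_models = dict(config.outcome_models)
    for name, target in targets.items():
        if name not in new_models:
            raise CalibrationError(f"no outcome model named {name!r}")
        beta = float(np.log(target.ratio)) / delta
        if abs(beta) > config.max_exposure_coefficient:
            raise CalibrationError(
                f"{name}: target ratio {target.ratio:.3f} needs slope {beta:.4f} "
                f"per GI point, beyond the cap {config.max_exposure_coefficient}"
            )
        gmean = target.top_level / float(np.exp(beta * means[3]))
        new_models[name] = replace(new_models[name], beta_exposure=beta, gmean=gmean)
    new_config = replace(config, outcome_models=new_models)
    return new_config, CalibrationReport(
        delta_residual=delta, tertile_means=means, coefficients=new_models
    )
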