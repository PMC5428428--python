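"""End-to-end orchestration: exclusions -> scoring -> residuals -> models.

The run applies the study-sample exclusions (disease history, energy
plausibility, completeness), scores dietary GI/GL/fiber from recalls (or,
in the FFQ sensitivity mode, GI/GL from the food-frequency items), forms
sex-specific energy residuals and tertiles, derives biomarkers and the
weighted GRS, and fits the full model battery: adjusted tertile means for
the log-transformed glucose-homeostasis outcomes, pre-diabetes odds ratios,
trend tests, GRS and cereal-fiber interaction scans, 3x3
cross-classifications, and the rice energy-partition model. Every stage
logs counts so the exclusion flow always sums: input n - excluded = analyzed n.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import assocmodels, biomarkers, dietmetrics, genetics
from .assocmodels import CrossClassResult, ModelSpec, ModelResult, ORResult
from .cohort import GeneratedCohort

CONTINUOUS_OUTCOMES = ("fpg_mmol_l", "hba1c_pct", "insulin_uiu_ml", "homa_ir", "homa_beta_pct")

#: Descriptive-table test choice is declared, not inferred from the data:
#: normal -> ANOVA, skewed -> Kruskal-Wallis, categorical -> chi-square.
DESCRIPTIVE_TYPES = {
    "female": "categorical",
    "urban": "categorical",
    "current_smoker": "categorical",
    "high_education": "categorical",
    "overweight": "categorical",
    "prediabetes": "categorical",
    "age_y": "normal",
    "bmi_kg_m2": "normal",
    "activity_met_h_wk": "normal",
    "energy_kcal_d": "normal",
    "gl_g_d": "normal",
    "cho_pct_e": "normal",
    "grs_weighted": "normal",
    "bf_pct": "skewed",
    "fpg_mmol_l": "skewed",
    "hba1c_pct": "skewed",
    "insulin_uiu_ml": "skewed",
    "homa_ir": "skewed",
    "homa_beta_pct": "skewed",
}


@dataclass
class RunConfig:
    """Pipeline options: exposures, adjustment tiers, sensitivity toggles."""

    exposures: tuple[str, ...] = ("gi", "gl")
    tiers: tuple[int, ...] = (1, 2, 3, 4)
    ffq_mode: bool = False
    three_recall_only: bool = False
    homa_variant: str = "homa1"
    seed: int | None = None

    def validate(self) -> None:
        if not self.exposures:
            raise ValueError("at least one exposure required")
        if not self.tiers:
            raise ValueError("at least one adjustment tier required")
        bad = [e for e in self.exposures if e not in {"gi", "gl"}]
        if bad:
            raise ValueError(f"unknown exposure(s): {bad}")


@dataclass
class PipelineReport:
    """All tables a run produces, plus the exclusion flow and manifest."""

    cohort_table: pd.DataFrame
    descriptives: pd.DataFrame
    adjusted_means: dict[tuple[str, int, str], ModelResult]
    odds_ratios: dict[tuple[str, int], ORResult]
    cross_class: dict[str, CrossClassResult]
    energy_partition: dict[str, pd.DataFrame]
    flow: pd.DataFrame
    manifest: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.descriptives.to_csv(outdir / "table1_descriptives.tsv", sep="\t")
        rows = []
        for (exposure, tier, outcome), res in sorted(self.adjusted_means.items()):
            for t in (1, 2, 3):
                e = res.estimates.loc[t]
                rows.append(
                    {
                        "exposure": exposure, "tier": tier, "outcome": outcome,
                        "tertile": t, "mean": e["mean"], "ci_low": e["ci_low"],
                        "ci_high": e["ci_high"], "n": e["n"],
                        "p_trend": res.p_trend, "p_interaction": res.p_interaction,
                    }
                )
        pd.DataFrame(rows).to_csv(outdir / "table2_3_adjusted_means.tsv", sep="\t", index=False)
        rows = []
        for (exposure, tier), res in sorted(self.odds_ratios.items()):
            for t in (1, 2, 3):
                e = res.estimates.loc[t]
                rows.append(
                    {
                        "exposure": exposure, "tier": tier, "tertile": t,
                        "odds_ratio": e["odds_ratio"], "ci_low": e["ci_low"],
                        "ci_high": e["ci_high"], "n": e["n"], "n_cases": e["n_cases"],
                        "p_trend": res.p_trend, "p_interaction": res.p_interaction,
                    }
                )
        pd.DataFrame(rows).to_csv(outdir / "table4_prediabetes_or.tsv", sep="\t", index=False)
        for name, res in sorted(self.cross_class.items()):
            res.estimate.to_csv(outdir / f"crossclass_{name}_estimate.tsv", sep="\t")
            res.n.to_csv(outdir / f"crossclass_{name}_n.tsv", sep="\t")
        for name, table in sorted(self.energy_partition.items()):
            table.to_csv(outdir / f"energy_partition_{name}.tsv", sep="\t")
        self.flow.to_csv(outdir / "exclusion_flow.tsv", sep="\t", index=False)
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=2, sort_keys=True))


def _config_hash(run_config: RunConfig) -> str:
    payload = json.dumps(
        {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(run_config).items()},
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _ffq_scores(ffq: pd.DataFrame, items: pd.DataFrame) -> pd.DataFrame:
    merged = ffq.merge(items, on="item_id", how="left")
    merged["cho"] = merged["servings_per_day"] * merged["cho_per_serving"]
    merged["gl"] = merged["cho"] * merged["gi"] / 100.0
    agg = merged.groupby("participant_id")[["cho", "gl"]].sum()
    agg["gi_ffq"] = 100.0 * agg["gl"] / agg["cho"]
    return agg.rename(columns={"gl": "gl_ffq"})[["gi_ffq", "gl_ffq"]]


def _descriptive_table(df: pd.DataFrame, tertile_col: str) -> pd.DataFrame:
    rows = []
    groups = [df[df[tertile_col] == t] for t in (1, 2, 3)]
    for var, kind in DESCRIPTIVE_TYPES.items():
        if var not in df.columns:
            continue
        series = [g[var].dropna() for g in groups]
        if any(len(s) == 0 for s in series):
            continue
        if kind == "categorical":
            table = pd.crosstab(df[tertile_col], df[var])
            p = sps.chi2_contingency(table)[1] if table.shape[1] > 1 else np.nan
            cells = [f"{int(s.sum())} ({100 * s.mean():.1f})" for s in series]
        elif kind == "normal":
            p = sps.f_oneway(*series)[1]
            cells = [f"{s.mean():.1f} ({s.std():.1f})" for s in series]
        else:
            p = sps.kruskal(*series)[1]
            cells = [
                f"{s.median():.2f} ({s.quantile(0.25):.2f}, {s.quantile(0.75):.2f})"
                for s in series
            ]
        rows.append(
            {"variable": var, "kind": kind, "tertile_1": cells[0],
             "tertile_2": cells[1], "tertile_3": cells[2], "p_value": p}
        )
    return pd.DataFrame(rows).set_index("variable")


def build_analysis_table(
    cohort: GeneratedCohort, run_config: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclusions + scoring + residuals + tertiles + derived biomarkers.

    Returns (analysis-ready cohort table indexed by participant, exclusion
    flow table).
    """
    flow = []
    part = cohort.participants.set_index("participant_id")
    n0 = len(part)
    flow.append(("input", n0, 0))

    history = (part["history_diabetes"] == 1) | (part["history_cvd_cancer"] == 1)
    part = part[~history]
    flow.append(("history of diabetes/CVD/cancer", len(part), int(history.sum())))

    diet = dietmetrics.summarize_cohort(cohort.recalls, cohort.catalog)
    has_recalls = part.index.isin(diet.index)
    flow.append(("no recall data", int(has_recalls.sum()), int((~has_recalls).sum())))
    part = part[has_recalls]
    diet = diet.reindex(part.index)

    if run_config.three_recall_only:
        keep = diet["n_recalls"] == 3
        flow.append(("fewer than 3 recalls (sensitivity)", int(keep.sum()), int((~keep).sum())))
        part, diet = part[keep], diet[keep]

    retained, excluded = dietmetrics.plausibility_filter(diet, part["sex"])
    flow.append(("implausible energy intake", len(retained), len(excluded)))
    part = part.loc[retained.index]
    diet = retained

    complete = part[["fpg_mmol_l", "insulin_uiu_ml", "hba1c_pct", "age_y"]].notna().all(axis=1)
    flow.append(("incomplete biomarkers/covariates", int(complete.sum()), int((~complete).sum())))
    part, diet = part[complete], diet[complete]

    df = part.join(diet)
    if run_config.ffq_mode:
        ffq_scores = _ffq_scores(cohort.ffq, cohort.ffq_items).reindex(df.index)
        df["gi"] = ffq_scores["gi_ffq"]
        df["gl_g_d"] = ffq_scores["gl_ffq"]

    df["female"] = (df["sex"] == "female").astype(float)
    df = biomarkers.derive_panel(df, variant=run_config.homa_variant)
    df["protein_g_d"] = df["protein_pct_e"] / 100.0 * df["energy_kcal_d"] / 4.0

    sex = df["sex"]
    energy = df["energy_kcal_d"]
    df["gi_resid"] = dietmetrics.energy_residuals(df["gi"], energy, sex)
    df["gl_resid"] = dietmetrics.energy_residuals(df["gl_g_d"], energy, sex)
    df["cereal_fiber_resid"] = dietmetrics.energy_residuals(df["cereal_fiber_g_d"], energy, sex)
    df["protein_resid"] = dietmetrics.energy_residuals(df["protein_g_d"], energy, sex)
    for exposure in ("gi", "gl"):
        df[f"{exposure}_tertile"] = dietmetrics.assign_tertiles(df[f"{exposure}_resid"])
    df["cereal_fiber_tertile"] = dietmetrics.assign_tertiles(df["cereal_fiber_resid"])

    grs = genetics.weighted_grs(cohort.genotypes)
    df["grs_weighted"] = grs["grs_weighted"].reindex(df.index)
    df["grs_tertile"] = dietmetrics.assign_tertiles(df["grs_weighted"])

    flow_df = pd.DataFrame(flow, columns=["stage", "n_after", "n_excluded"])
    return df, flow_df


def _rice_component_energies(cohort: GeneratedCohort, index: pd.Index) -> pd.DataFrame:
    """Mean daily energy (kcal/d) from high-GI (>=70) and lower-GI staple foods."""
    comp = cohort.catalog.composition_frame()
    merged = cohort.recalls.merge(comp, left_on="food_id", right_index=True)
    merged["energy"] = merged["grams"] * merged["energy_kcal_per_100g"] / 100.0
    merged["component"] = np.where(
        ~merged["is_cereal"], "other",
        np.where(merged["gi"] >= 70.0, "high_gi_staple_kcal", "low_gi_staple_kcal"),
    )
    per_day = (
        merged[merged["component"] != "other"]
        .groupby(["participant_id", "day_index", "component"])["energy"]
        .sum()
        .unstack("component", fill_value=0.0)
    )
    days = merged.groupby(["participant_id", "day_index"]).size().groupby("participant_id").size()
    out = per_day.groupby(level="participant_id").sum()
    out = out.div(days, axis=0)
    for col in ("high_gi_staple_kcal", "low_gi_staple_kcal"):
        if col not in out:
            out[col] = 0.0
    return out.reindex(index).fillna(0.0)


def run_pipeline(cohort: GeneratedCohort, run_config: RunConfig | None = None) -> PipelineReport:
    """Run the full analysis on a cohort and return the report bundle."""
    run_config = run_config or RunConfig()
    run_config.validate()
    df, flow = build_analysis_table(cohort, run_config)

    descriptives = _descriptive_table(df, "gi_tertile")

    adjusted: dict[tuple[str, int, str], ModelResult] = {}
    ors: dict[tuple[str, int], ORResult] = {}
    for exposure in run_config.exposures:
        for tier in run_config.tiers:
            for outcome in CONTINUOUS_OUTCOMES:
                sub = df[np.isfinite(df[outcome]) & (df[outcome] > 0)]
                spec = ModelSpec(
                    outcome=outcome, exposure=exposure, tier=tier,
                    interaction_with="grs_weighted",
                )
                adjusted[(exposure, tier, outcome)] = assocmodels.fit_adjusted_means(sub, spec)
            spec = ModelSpec(
                outcome="prediabetes", exposure=exposure, tier=tier,
                log_transform=False, interaction_with="grs_weighted",
            )
            ors[(exposure, tier)] = assocmodels.fit_prediabetes_or(df, spec)

    cross: dict[str, CrossClassResult] = {}
    for exposure in run_config.exposures:
        cross[f"{exposure}_x_grs_prediabetes"] = assocmodels.cross_classify(
            df, f"{exposure}_tertile", "grs_tertile", "prediabetes",
            tier=3, log_transform=False, reference=(1, 1),
        )
        cross[f"{exposure}_x_grs_homa_ir"] = assocmodels.cross_classify(
            df, f"{exposure}_tertile", "grs_tertile", "homa_ir",
            tier=3, log_transform=True, reference=(1, 1),
        )
        cross[f"{exposure}_x_fiber_prediabetes"] = assocmodels.cross_classify(
            df, f"{exposure}_tertile", "cereal_fiber_tertile", "prediabetes",
            tier=3, log_transform=False, reference=(1, 3),
            exclude_covariates=("cereal_fiber_resid",),
        )

    rice = _rice_component_energies(cohort, df.index)
    part_df = df.join(rice)
    partition = {
        "fpg": assocmodels.energy_partition_fit(
            part_df, ["high_gi_staple_kcal", "low_gi_staple_kcal"],
            "energy_kcal_d", "fpg_mmol_l", tier=3, log_transform=True,
        ),
        "prediabetes": assocmodels.energy_partition_fit(
            part_df, ["high_gi_staple_kcal", "low_gi_staple_kcal"],
            "energy_kcal_d", "prediabetes", tier=3, log_transform=False,
        ),
    }

    manifest = {
        "seed": run_config.seed if run_config.seed is not None else cohort.seed,
        "config_hash": _config_hash(run_config),
        "n_input": int(flow.iloc[0]["n_after"]),
        "n_analyzed": int(len(df)),
        "n_excluded": int(flow["n_excluded"].sum()),
        "exposures": list(run_config.exposures),
        "tiers": list(run_config.tiers),
        "ffq_mode": run_config.ffq_mode,
        "three_recall_only": run_config.three_recall_only,
    }
    return PipelineReport(
        cohort_table=df,
        descriptives=descriptives,
        adjusted_means=adjusted,
        odds_ratios=ors,
        cross_class=cross,
        energy_partition=partition,
        flow=flow,
        manifest=manifest,
    )
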