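"""End-to-end orchestration: simulate -> reanalyse -> build panel ->
fit GLM & RF -> evaluate, from one config pair and one seed.

Every stage is deterministic given the seed; the metrics report and
prediction tables written by :func:`run_all` are byte-identical across runs
with the same inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .anthro import add_whz, apply_exclusions, reanalyse
from .config import GeneratorConfig, PipelineConfig
from .exceptions import ShortlistError
from .forest import RfConfig, StratumMonthForest, aggregate_training_table, rf_loocv
from .glm import (
    CandidateModel,
    ChildGLM,
    assemble_training_frame,
    chronological_split,
    enumerate_models,
    family_for,
    loocv,
    select_predictor_form,
    shortlist,
)
from .metrics import build_report, mse, plot_data
from .panel import (
    CLIMATE_WINDOWS,
    LagSpec,
    impute_chained,
    impute_market,
    interpolate_series,
    panel_to_wide,
    per_capita_rate,
    rolling_mean,
    screen_missingness,
    smooth_spline,
    wide_to_panel,
)
from .simulate import (
    RATE_SCALE,
    VARIABLE_META,
    TRUTH_LAGS,
    generate_all_surveys,
    generate_predictor_panel,
    generate_world,
)

log = logging.getLogger("malnowcast")

#: panel variables offered to the models in run_all (rates derived from
#: counts; livelihood static)
DEFAULT_MODEL_VARIABLES = (
    "conflict_death_rate", "measles_rate", "ndvi", "water_price", "livelihood",
)


def engineer_panel(panel: pd.DataFrame, population: pd.DataFrame,
                   pipe: PipelineConfig, seed: int,
                   nearest_market: dict | None = None) -> pd.DataFrame:
    """Raw observed panel -> completed panel with derived variables.

    Stages: missingness screening (30% rule), linear interpolation of
    humanitarian-presence style series, nearest-market 0.7/0.3 imputation of
    price series, chained-equation imputation of whatever remains, count ->
    per-population rates, 3-month trailing rolling means of the time-varying
    variables, and spline smoothing of price variables. Derived variables get
    suffixed names; the originals are retained.
    """
    strata = sorted(panel["stratum_id"].unique())
    months = sorted(panel["month"].unique())
    kept, screen = screen_missingness(panel, 0.30, strata, months)
    log.info("missingness screen kept %d/%d variables", len(kept), screen.shape[0])
    panel = panel[panel["variable"].isin(kept)].copy()

    pieces = [panel[panel["variable"] == v] for v in kept
              if VARIABLE_META.get(v, {}).get("kind") == "static"]
    numeric_vars = [v for v in kept
                    if VARIABLE_META.get(v, {}).get("kind") != "static"]
    pop_wide = population.pivot(index="month", columns="stratum_id",
                                values="population").astype(float)

    if nearest_market is None:
        nearest_market = {s: strata[(i + 1) % len(strata)]
                          for i, s in enumerate(strata)}

    completed = {}
    for var in numeric_vars:
        wide = panel_to_wide(panel, var)
        imputed = wide.isna()
        kind = VARIABLE_META.get(var, {}).get("kind")
        if kind == "continuous":  # humanitarian presence: interpolate
            for s in wide.columns:
                if wide[s].notna().sum() >= 2:
                    wide[s], _ = interpolate_series(wide[s])
        elif kind == "price":  # market imputation then later smoothing
            filled = {}
            for s in wide.columns:
                others = wide.drop(columns=[s])
                near = wide[nearest_market.get(s, s)] if nearest_market.get(s, s) in wide else pd.Series(np.nan, index=wide.index)
                filled[s], _, _ = impute_market(wide[s], near, others)
            wide = pd.DataFrame(filled, index=wide.index)[wide.columns]
        completed[var] = (wide, imputed)

    # chained-equation pass over whatever is still missing
    flat = pd.concat({v: w.stack(future_stack=True) for v, (w, _) in completed.items()}, axis=1)
    if flat.isna().any().any():
        obs_frac = flat.notna().mean()
        can = list(obs_frac[obs_frac >= 0.30].index)
        done = impute_chained(flat[can], pipe.mice_iterations, seed)
        flat[can] = done
    for var in completed:
        wide, imputed = completed[var]
        filled = flat[var].unstack()
        completed[var] = (filled, imputed)

    for var, (wide, imputed) in completed.items():
        pieces.append(wide_to_panel(wide, var, imputed))
        kind = VARIABLE_META.get(var, {}).get("kind")
        if kind == "count":
            rate = {}
            for s in wide.columns:
                rate[s] = per_capita_rate(wide[s], pop_wide[s], RATE_SCALE)
            rate_name = var.replace("_cases", "").replace("_deaths", "_death")
            rate_name = f"{rate_name}_rate" if not rate_name.endswith("rate") else rate_name
            rw = pd.DataFrame(rate, index=wide.index)
            pieces.append(wide_to_panel(rw, rate_name, imputed))
        if kind == "price":
            sw = wide.apply(lambda col: smooth_spline(col, pipe.spline_lam))
            pieces.append(wide_to_panel(sw, f"{var}_smooth", imputed))
        roll = wide.apply(lambda col: rolling_mean(col, 3))
        pieces.append(wide_to_panel(roll, f"{var}_roll3", imputed))

    return pd.concat(pieces, ignore_index=True)


def candidate_lag_specs(variable: str, pipe: PipelineConfig) -> list[LagSpec]:
    climate = VARIABLE_META.get(variable, {}).get("kind") == "climate"
    if climate:
        return [LagSpec(variable, a, b, climate=True) for a, b in CLIMATE_WINDOWS]
    return [LagSpec(variable, a, b) for a, b in pipe.candidate_lags]


def build_model_features(panel: pd.DataFrame, keys, pipe: PipelineConfig,
                         variables=DEFAULT_MODEL_VARIABLES) -> pd.DataFrame:
    """Feature table for all candidate lags of the model variables."""
    specs = []
    static = []
    for var in variables:
        if VARIABLE_META.get(var, {}).get("kind") == "static":
            static.append(var)
            continue
        specs.extend(candidate_lag_specs(var, pipe))
    from .panel import build_features
    return build_features(panel, specs, keys, pipe.forecast_offset, static)


def _glm_track(outcome, children, meta_train, meta_holdout, features, pipe,
               seed, variables):
    family = family_for(outcome)
    frame = assemble_training_frame(children, meta_train, features, outcome)
    specs = []
    for var in variables:
        if VARIABLE_META.get(var, {}).get("kind") == "static":
            levels = tuple(sorted(pd.unique(frame[var].dropna())))
            if len(levels) >= 2:
                from .glm import PredictorSpec
                specs.append(PredictorSpec(var, var, "categorical", levels=levels))
            continue
        lags = candidate_lag_specs(var, pipe)
        try:
            specs.append(select_predictor_form(
                frame, var, lags, family,
                n_breakpoint_levels=pipe.n_breakpoint_levels))
        except Exception as exc:
            log.warning("form selection failed for %s: %s", var, exc)
    subsets = enumerate_models(specs, pipe.max_terms, pipe.enumeration_cap)

    holdout_keys = list(zip(meta_holdout["stratum_id"], meta_holdout["month"]))
    candidates = []
    for sub in subsets:
        cand = CandidateModel(outcome, family, sub)
        try:
            cand.results = ChildGLM(outcome, frame, sub).fit()
            cand.converged = cand.results.converged
        except Exception:
            cand.converged = False
        candidates.append(cand)
    return specs, candidates, holdout_keys


def run_all(gen_config: GeneratorConfig, pipe: PipelineConfig, seed: int,
            outdir) -> dict:
    """Full pipeline on a synthetic world; returns {'glm': .., 'rf': ..}
    reports and writes all artefacts under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gen_config = dataclasses.replace(gen_config, seed=seed)
    world = generate_world(gen_config)
    panel_obs = generate_predictor_panel(world)
    children, meta = generate_all_surveys(world)
    log.info("simulated %d surveys, %d children", len(meta), len(children))

    io.write_children(children, outdir / "children.csv")
    io.write_survey_meta(meta, outdir / "survey_meta.csv")
    io.write_panel(panel_obs, outdir / "panel.csv")
    io.write_population(world.population, outdir / "population.csv")

    children = add_whz(children, world.reference)
    children = apply_exclusions(children)
    observed = reanalyse(children, meta)
    observed.to_csv(outdir / "reanalysis.csv", index=False)

    panel_done = engineer_panel(panel_obs, world.population, pipe, seed)
    keys = [(s, int(m)) for s in world.strata["stratum_id"] for m in world.months]
    features = build_model_features(panel_done, keys, pipe)
    io.write_features(features, outdir / "features.csv")

    meta_train, meta_holdout = chronological_split(meta, pipe.train_fraction)
    train_ids = set(meta_train["survey_id"])
    children_train = children[children["survey_id"].isin(train_ids)]

    all_preds, reports = [], {"glm": {}, "rf": {}}
    for outcome in pipe.outcomes:
        specs, candidates, holdout_keys = _glm_track(
            outcome, children_train, meta_train, meta_holdout, features,
            pipe, seed, DEFAULT_MODEL_VARIABLES)
        obs_out = observed[observed["outcome"] == outcome]
        obs_map = obs_out.set_index(["stratum_id", "month"])["point"]
        for cand in candidates:
            if not cand.converged or cand.results is None:
                continue
            pred = cand.results.predict_stratum_month(
                features, holdout_keys, n_draws=200, seed=seed, source="holdout")
            merged = pred.merge(obs_out, on=["stratum_id", "month"],
                                suffixes=("", "_obs"))
            if len(merged):
                cand.holdout_mse = float(np.mean(
                    (merged["point"] - merged["point_obs"])**2))
        try:
            best = shortlist(candidates, pipe.shortlist_fraction)[0]
        except ShortlistError:
            log.warning("no rankable GLM candidate for %s", outcome)
            continue
        res = best.results
        train_keys = sorted(set(zip(meta_train["stratum_id"], meta_train["month"])))
        preds = [
            res.predict_stratum_month(features, train_keys, pipe.n_draws,
                                      seed, source="train"),
            res.predict_stratum_month(features, holdout_keys, pipe.n_draws,
                                      seed, source="holdout"),
        ]
        if pipe.glm_loocv:
            preds.append(loocv(outcome, children_train, meta_train, features,
                               best.specs, seed, n_draws=pipe.n_draws))
        glm_preds = pd.concat(preds, ignore_index=True)
        glm_preds["track"] = "glm"
        all_preds.append(glm_preds)
        reports["glm"][outcome] = build_report(glm_preds, observed, outcome)

        # RF track on the aggregated training table
        table = aggregate_training_table(
            obs_out[obs_out["survey_id"].isin(train_ids)], features)
        if len(table) >= 10:
            rf_cfg = RfConfig(n_trees=pipe.rf_n_trees,
                              min_node=pipe.rf_min_node, seed=seed)
            rf_res = StratumMonthForest(table, outcome, config=rf_cfg).fit()
            rf_preds = [
                rf_res.predict_ci(features, train_keys, source="train"),
                rf_res.predict_ci(features, holdout_keys, source="holdout"),
            ]
            if pipe.rf_loocv:
                rf_preds.append(rf_loocv(table, outcome, rf_cfg))
            rf_pred = pd.concat(rf_preds, ignore_index=True)
            rf_pred["track"] = "rf"
            all_preds.append(rf_pred)
            reports["rf"][outcome] = build_report(rf_pred, observed, outcome)
            rf_res.importance().to_csv(
                outdir / f"importance_{outcome}.csv", index=False)

    predictions = pd.concat(all_preds, ignore_index=True)
    io.write_predictions(predictions, outdir / "predictions.csv")

    payload = {
        track: {outcome: rep.to_dict() for outcome, rep in block.items()}
        for track, block in reports.items()
    }
    with open(outdir / "metrics.json", "w") as fh:
        fh.write(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    plot_frames = []
    for outcome in pipe.outcomes:
        try:
            plot_frames.append(plot_data(predictions, observed, outcome))
        except Exception:
            pass
    if plot_frames:
        pd.concat(plot_frames, ignore_index=True).to_csv(
            outdir / "plot_data.csv", index=False)
    return reports
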