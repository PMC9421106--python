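"""CSV readers/writers for the pipeline's tabular interchange formats.

All files are one-header-row UTF-8 CSV. Children: one row per measured
child. Survey metadata: one row per survey. Predictor panel: long format
(stratum, month, variable, value). Features: wide, keyed by stratum-month.
"""

from __future__ import annotations

import pandas as pd

CHILD_COLUMNS = [
    "survey_id", "cluster_id", "age_months", "sex", "weight_kg",
    "height_cm", "muac_mm", "oedema", "whz",
]
META_COLUMNS = [
    "survey_id", "stratum_id", "month", "design", "quality_score_raw",
    "quality_rescaled", "sampling_coverage", "analysis_weight",
]
PANEL_COLUMNS = ["stratum_id", "month", "variable", "value", "is_imputed"]


def write_children(children: pd.DataFrame, path) -> None:
    cols = [c for c in CHILD_COLUMNS if c in children.columns]
    children[cols].to_csv(path, index=False)


def read_children(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"survey_id": str, "cluster_id": str, "sex": str})
    if "oedema" in df.columns:
        df["oedema"] = df["oedema"].astype(bool)
    if "whz" not in df.columns:
        df["whz"] = float("nan")
    return df


def write_survey_meta(meta: pd.DataFrame, path) -> None:
    cols = [c for c in META_COLUMNS if c in meta.columns]
    meta[cols].to_csv(path, index=False)


def read_survey_meta(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"survey_id": str, "stratum_id": str})


def write_panel(panel: pd.DataFrame, path) -> None:
    panel[[c for c in PANEL_COLUMNS if c in panel.columns]].to_csv(path, index=False)


def read_panel(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"stratum_id": str, "variable": str})
    # values are numeric except for static categorical variables
    return df


def write_population(population: pd.DataFrame, path) -> None:
    population.to_csv(path, index=False)


def read_population(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"stratum_id": str})


def write_features(features: pd.DataFrame, path) -> None:
    features.reset_index().to_csv(path, index=False)


def read_features(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"stratum_id": str})
    return df.set_index(["stratum_id", "month"]).sort_index()


def write_predictions(predictions: pd.DataFrame, path) -> None:
    predictions.to_csv(path, index=False)


def read_predictions(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"stratum_id": str, "outcome": str, "source": str})
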