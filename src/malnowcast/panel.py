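"""Stratum-month predictor panel engineering.

Turns raw long-format predictor series into the model-ready feature table:
missingness screening, gap interpolation, nearest-market imputation, chained
-equation imputation, per-population rates, rolling means, spline smoothing
and lagged window features. Observed (non-imputed) cells are never altered;
rolling means and spline smoothing produce new derived variables so the
originals survive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .exceptions import ConfigError, ImputationError

__all__ = [
    "LagSpec",
    "CLIMATE_WINDOWS",
    "screen_missingness",
    "interpolate_series",
    "impute_market",
    "impute_chained",
    "per_capita_rate",
    "rolling_mean",
    "smooth_spline",
    "build_features",
    "panel_to_wide",
    "wide_to_panel",
]

#: the only admissible lag windows for climate variables: the two trimesters
#: and the semester prior to the reference month
CLIMATE_WINDOWS = ((1, 3), (4, 6), (1, 6))


@dataclass(frozen=True)
class LagSpec:
    """A lagged-window feature: mean of ``variable`` over months
    ``t - window_end .. t - window_start`` prior to reference month t."""

    variable: str
    window_start: int
    window_end: int
    climate: bool = False

    def __post_init__(self):
        if self.window_start < 1 or self.window_end < self.window_start:
            raise ConfigError(
                "lag window must satisfy 1 <= start <= end "
                f"(got {self.window_start}..{self.window_end})")
        if self.climate and (self.window_start, self.window_end) not in CLIMATE_WINDOWS:
            raise ConfigError(
                f"climate variables only admit windows {CLIMATE_WINDOWS}")

    @property
    def feature_name(self) -> str:
        return f"{self.variable}_lag{self.window_start}_{self.window_end}"


def panel_to_wide(panel: pd.DataFrame, variable: str) -> pd.DataFrame:
    """One variable as a month x stratum wide table."""
    sub = panel[panel["variable"] == variable]
    return (sub.pivot(index="month", columns="stratum_id", values="value")
            .astype(float).sort_index())


def wide_to_panel(wide: pd.DataFrame, variable: str,
                  imputed_mask: pd.DataFrame | None = None) -> pd.DataFrame:
    long = wide.stack(future_stack=True).rename("value").reset_index()
    long.columns = ["month", "stratum_id", "value"]
    long["variable"] = variable
    if imputed_mask is not None:
        im = imputed_mask.stack(future_stack=True).rename("is_imputed").reset_index()
        im.columns = ["month", "stratum_id", "is_imputed"]
        long = long.merge(im, on=["month", "stratum_id"], how="left")
        long["is_imputed"] = long["is_imputed"].astype("boolean").fillna(False).astype(bool)
    else:
        long["is_imputed"] = False
    return long[["stratum_id", "month", "variable", "value", "is_imputed"]]


def screen_missingness(panel: pd.DataFrame, threshold: float = 0.30,
                       strata: list | None = None,
                       months: list | None = None):
    """Exclude variables too incomplete to model.

    A variable is excluded when the fraction of strata with no value in any
    month is >= ``threshold``, or the fraction of months with no value in any
    stratum is >= ``threshold``. Returns ``(kept_variables, report)`` where
    the report carries both fractions and the exclusion reason per variable.
    """
    if len(panel) == 0:
        raise ConfigError("empty panel")
    strata = list(strata) if strata is not None else sorted(panel["stratum_id"].unique())
    months = list(months) if months is not None else sorted(panel["month"].unique())
    rows, kept = [], []
    for var, sub in panel.groupby("variable", sort=True):
        obs = sub[sub["value"].notna()]
        strata_with = set(obs["stratum_id"])
        months_with = set(obs["month"])
        f_strata = sum(1 for s in strata if s not in strata_with) / len(strata)
        f_months = sum(1 for m in months if m not in months_with) / len(months)
        excluded = f_strata >= threshold or f_months >= threshold
        rows.append({
            "variable": var,
            "frac_strata_missing": f_strata,
            "frac_months_missing": f_months,
            "excluded": excluded,
            "reason": (None if not excluded else
                       ("strata" if f_strata >= threshold else "months")),
        })
        if not excluded:
            kept.append(var)
    return kept, pd.DataFrame(rows)


def interpolate_series(series: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Linear interpolation of interior gaps; nearest-value edge fill.

    ``series`` must be indexed by month (time-ordered) with >= 2 observed
    points. Returns ``(filled, imputed_mask)``.
    """
    series = series.sort_index()
    if series.notna().sum() < 2:
        raise ImputationError("interpolation needs >= 2 observed points")
    idx = series.index.to_numpy(float)
    obs = series.notna().to_numpy()
    filled = pd.Series(
        np.interp(idx, idx[obs], series.to_numpy(float)[obs]),
        index=series.index, name=series.name)
    return filled, ~series.notna()


def impute_market(target: pd.Series, nearest: pd.Series,
                  others: pd.DataFrame,
                  weights: tuple[float, float] = (0.7, 0.3)):
    """Fill missing market cells from the nearest market and the market mean.

    missing cell <- w1 * nearest + w2 * mean(other non-missing markets), the
    standard 0.7/0.3 weighting. If the nearest market is also missing, fall
    back to the mean of non-missing markets (flagged); if every market is
    missing the cell is left missing for downstream chained imputation.

    Returns ``(filled, imputed_mask, fallback_mask)`` aligned on the target
    index (months).
    """
    w1, w2 = weights
    target = target.sort_index()
    nearest = nearest.reindex(target.index)
    others = others.reindex(target.index)
    other_mean = others.mean(axis=1, skipna=True)
    miss = target.isna()
    combined = w1 * nearest + w2 * other_mean
    fallback = miss & nearest.isna() & other_mean.notna()
    filled = target.copy()
    use_comb = miss & nearest.notna() & other_mean.notna()
    filled[use_comb] = combined[use_comb]
    filled[fallback] = other_mean[fallback]
    imputed = miss & filled.notna()
    return filled, imputed, fallback


def impute_chained(table: pd.DataFrame, n_iterations: int = 10,
                   seed: int = 0, min_observed: float = 0.30) -> pd.DataFrame:
    """Chained-equations imputation of a numeric stratum-month table.

    ``table`` is wide (rows = stratum-months, columns = variables). Each
    incomplete variable is iteratively regressed on the others with a normal
    linear model and missing cells replaced by draws from the predictive
    distribution (Bayesian ridge, posterior sampling); a single completed
    dataset is returned, deterministic given ``seed``.
    """
    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer

    if table.isna().sum().sum() == 0:
        return table.copy()
    frac_obs = table.notna().mean()
    bad = frac_obs[frac_obs < min_observed]
    if len(bad):
        raise ImputationError(
            f"variables below {min_observed:.0%} observed: {list(bad.index)}")
    imputer = IterativeImputer(
        max_iter=n_iterations, sample_posterior=True,
        random_state=int(seed) % (2**31), keep_empty_features=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        completed = imputer.fit_transform(table.to_numpy(float))
    return pd.DataFrame(completed, index=table.index, columns=table.columns)


def per_capita_rate(counts: pd.Series, population: pd.Series,
                    scale: float = 100_000.0) -> pd.Series:
    """count / population * scale, aligned on the count index.

    Missing population for an observed count yields a missing rate.
    """
    population = population.reindex(counts.index)
    if (population <= 0).any():
        raise ConfigError("populations must be positive")
    return counts / population * scale


def rolling_mean(series: pd.Series, window: int = 3) -> pd.Series:
    """Trailing rolling mean over months t-window+1..t, shrinking at edges.

    Trailing (never centred) so that no future information enters a
    now-casting feature.
    """
    series = series.sort_index()
    return series.rolling(window, min_periods=1).mean()


def smooth_spline(series: pd.Series, lam: float = 5.0) -> pd.Series:
    """Cubic smoothing spline over time, evaluated at every month.

    ``lam`` is the roughness penalty (second-derivative); lam -> 0 approaches
    interpolation, lam -> infinity the least-squares line. Series with fewer
    than 4 observed points are returned unsmoothed with a warning.
    """
    series = series.sort_index()
    obs = series.notna()
    if obs.sum() < 4:
        warnings.warn("too few points to smooth; series returned unsmoothed")
        return series.copy()
    x = series.index.to_numpy(float)[obs]
    y = series.to_numpy(float)[obs]
    spl = make_smoothing_spline(x, y, lam=lam)
    out = pd.Series(spl(series.index.to_numpy(float)),
                    index=series.index, name=series.name)
    out[series.isna()] = np.nan
    return out


def build_features(panel: pd.DataFrame, lag_specs: list[LagSpec],
                   reference_keys, forecast_offset: int = 0,
                   static_variables: list | None = None) -> pd.DataFrame:
    """Lagged-window feature table keyed by (stratum_id, month).

    For each reference stratum-month t and spec, the feature is the mean of
    the variable over months ``t - end - offset .. t - start - offset``; a
    positive ``forecast_offset`` turns now-casting features into forecasting
    features by pushing every window further into the past. Windows reaching
    before the panel start yield missing features. Static variables pass
    through unlagged.
    """
    if forecast_offset < 0:
        raise ConfigError("forecast_offset must be >= 0")
    keys = pd.DataFrame(reference_keys, columns=["stratum_id", "month"])
    out = keys.set_index(["stratum_id", "month"]).sort_index()
    ref_months = [int(m) for _, m in out.index]
    for spec in lag_specs:
        wide = panel_to_wide(panel, spec.variable)
        lo = int(min(wide.index.min(), min(ref_months)))
        hi = int(max(wide.index.max(), max(ref_months)))
        wide = wide.reindex(range(lo, hi + 1))
        start = spec.window_start + forecast_offset
        end = spec.window_end + forecast_offset
        w = end - start + 1
        lagged = wide.rolling(w, min_periods=w).mean().shift(start)
        stacked = lagged.stack(future_stack=True)
        stacked.index = stacked.index.swaplevel()
        out[spec.feature_name] = stacked.reindex(out.index)
    for var in static_variables or []:
        sub = panel[panel["variable"] == var]
        per_stratum = sub.groupby("stratum_id")["value"].first()
        out[var] = per_stratum.reindex(out.index.get_level_values(0)).to_numpy()
    return out
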