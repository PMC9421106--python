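"""Random-forest prediction track on stratum-month aggregated outcomes.

A regression forest (default 1000 trees) is grown on one row per surveyed
stratum-month, with the survey's design-based point estimate as the response
and its analysis weight as a case weight. Prediction intervals use the
infinitesimal jackknife variance estimator computed from the per-tree
bootstrap inclusion counts, with the standard Monte-Carlo bias correction;
variable importance is permutation importance with per-feature random
streams so that rankings do not depend on column order.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.ensemble._forest import (
    _generate_sample_indices,
    _get_n_samples_bootstrap,
)

from .exceptions import ConfigError
from .glm import family_for

__all__ = [
    "RfConfig",
    "StratumMonthForest",
    "ForestResults",
    "aggregate_training_table",
    "infinitesimal_jackknife_variance",
]


@dataclass
class RfConfig:
    """Forest hyper-parameters: 1000 trees, regression-convention mtry
    (ceil(p/3)), and a seed controlling all randomness."""

    n_trees: int = 1000
    mtry: int | None = None
    min_node: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ConfigError("n_trees must be >= 1")
        if self.min_node < 1:
            raise ConfigError("min node size must be >= 1")


def aggregate_training_table(observed: pd.DataFrame,
                             features: pd.DataFrame) -> pd.DataFrame:
    """One row per surveyed stratum-month: observed outcome, features, weight.

    ``observed`` is the reanalysis table restricted to one outcome (columns
    survey_id, stratum_id, month, point, analysis_weight). Surveys whose
    stratum-month lacks a complete feature row are dropped and listed in the
    ``dropped`` attr.
    """
    feat = features.reset_index()
    table = observed.merge(feat, on=["stratum_id", "month"], how="left")
    feat_cols = [c for c in features.columns]
    complete = table[feat_cols].notna().all(axis=1)
    dropped = list(table.loc[~complete, "survey_id"])
    out = table[complete].reset_index(drop=True)
    out.attrs["dropped"] = dropped
    out.attrs["feature_columns"] = feat_cols
    return out


def _one_hot(X: pd.DataFrame) -> pd.DataFrame:
    obj = X.select_dtypes(include=["object", "category"]).columns
    if len(obj) == 0:
        return X.astype(float)
    return pd.get_dummies(X, columns=list(obj), dtype=float)


def infinitesimal_jackknife_variance(inbag: np.ndarray,
                                     tree_preds: np.ndarray) -> np.ndarray:
    """IJ variance of bagged predictions with Monte-Carlo bias correction.

    ``inbag`` is (n_train, B) bootstrap inclusion counts; ``tree_preds``
    (B, m) per-tree predictions at m query points. Returns the corrected
    variance per query point, floored at zero (a floor is applied with a
    warning when the correction overshoots).
    """
    n, b = inbag.shape
    centred_counts = inbag - inbag.mean(axis=1, keepdims=True)
    centred_preds = tree_preds - tree_preds.mean(axis=0, keepdims=True)
    cov = centred_counts @ centred_preds / b  # (n, m)
    v_ij = (cov**2).sum(axis=0)
    boot_var = (centred_preds**2).mean(axis=0)
    v_ij_u = v_ij - (n / b) * boot_var
    if (v_ij_u < 0).any():
        warnings.warn("negative IJ variance after bias correction; floored at 0")
    return np.clip(v_ij_u, 0.0, None)


class StratumMonthForest:
    """Random-forest regression of a stratum-month outcome on features."""

    def __init__(self, table: pd.DataFrame, outcome: str,
                 feature_columns: list | None = None,
                 config: RfConfig | None = None):
        self.outcome = outcome
        self.config = config or RfConfig()
        self.table = table.reset_index(drop=True)
        cols = feature_columns or table.attrs.get("feature_columns")
        if cols is None:
            raise ConfigError("feature_columns must be given or carried by the table")
        self.feature_columns = list(cols)
        self._X = _one_hot(self.table[self.feature_columns])
        self.design_columns = list(self._X.columns)

    def fit(self) -> "ForestResults":
        if len(self.table) < 10:
            raise ConfigError("need >= 10 stratum-month rows to grow a forest")
        y = self.table["point"].to_numpy(float)
        w = self.table["analysis_weight"].to_numpy(float)
        w = np.where(np.isfinite(w) & (w > 0), w, 0.5)
        p = self._X.shape[1]
        mtry = self.config.mtry or int(np.ceil(p / 3))
        rf = RandomForestRegressor(
            n_estimators=self.config.n_trees,
            max_features=min(mtry, p),
            min_samples_leaf=self.config.min_node,
            bootstrap=True, oob_score=True,
            random_state=int(self.config.seed) % (2**31),
            n_jobs=1,
        )
        degenerate = np.allclose(y, y[0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rf.fit(self._X.to_numpy(float), y, sample_weight=w)
        if degenerate:
            warnings.warn("constant response: degenerate forest, importances 0")
        # weighted bootstrap draws: inclusion counts must be recomputed with
        # the same weights the forest used
        n = len(y)
        n_bs = _get_n_samples_bootstrap(n, rf.max_samples, w)
        inbag = np.zeros((n, self.config.n_trees))
        for i, tree in enumerate(rf.estimators_):
            idx = _generate_sample_indices(tree.random_state, n, n_bs, w)
            inbag[:, i] = np.bincount(idx, minlength=n)
        oob = rf.oob_prediction_
        oob_mse = float(np.mean((oob - y) ** 2))
        ss_tot = float(np.mean((y - y.mean()) ** 2))
        oob_r2 = 1.0 - oob_mse / ss_tot if ss_tot > 0 else 0.0
        return ForestResults(self, rf, inbag, oob_mse, oob_r2)


class ForestResults:
    """Fitted forest with IJ intervals and permutation importance."""

    def __init__(self, model: StratumMonthForest, rf, inbag, oob_mse, oob_r2):
        self.model = model
        self.rf = rf
        self.inbag = inbag
        self.oob_mse = oob_mse
        self.oob_r2 = oob_r2
        self._importance = None

    @property
    def outcome(self):
        return self.model.outcome

    def _design(self, features: pd.DataFrame) -> np.ndarray:
        X = _one_hot(features[self.model.feature_columns])
        X = X.reindex(columns=self.model.design_columns, fill_value=0.0)
        return X.to_numpy(float)

    def predict_ci(self, features: pd.DataFrame, keys=None,
                   source: str = "holdout") -> pd.DataFrame:
        """Ensemble-mean prediction with jackknife 95%/80% intervals.

        ``features`` is indexed by (stratum_id, month); rows with any missing
        feature are skipped. Prevalence outcomes are truncated to [0, 1].
        """
        if keys is None:
            keys = list(features.index)
        feat = features.loc[list(keys)]
        ok = feat[self.model.feature_columns].notna().all(axis=1)
        feat = feat[ok]
        X = self._design(feat)
        tree_preds = np.stack([t.predict(X) for t in self.rf.estimators_])
        point = tree_preds.mean(axis=0)
        var = infinitesimal_jackknife_variance(self.inbag, tree_preds)
        se = np.sqrt(var)
        z95, z80 = stats.norm.ppf(0.975), stats.norm.ppf(0.90)
        out = pd.DataFrame({
            "stratum_id": [k[0] for k in feat.index],
            "month": [k[1] for k in feat.index],
            "outcome": self.outcome,
            "source": source,
            "point": point,
            "ci95_low": point - z95 * se,
            "ci95_high": point + z95 * se,
            "ci80_low": point - z80 * se,
            "ci80_high": point + z80 * se,
        })
        if family_for(self.outcome) == "quasibinomial":
            for col in ("point", "ci95_low", "ci95_high", "ci80_low", "ci80_high"):
                out[col] = out[col].clip(0.0, 1.0)
        out.attrs["n_missing"] = int((~ok).sum())
        return out

    def importance(self, n_repeats: int = 10) -> pd.DataFrame:
        """Permutation importance (MSE increase), per original feature.

        Each feature's permutation stream is seeded from the feature *name*,
        so scores do not depend on the order of feature columns; one-hot
        blocks of a categorical feature are permuted jointly.
        """
        if self._importance is not None:
            return self._importance
        table = self.model.table
        y = table["point"].to_numpy(float)
        X0 = self._design(table)
        base = float(np.mean((self.rf.predict(X0) - y) ** 2))
        rows = []
        for feature in self.model.feature_columns:
            block = [j for j, c in enumerate(self.model.design_columns)
                     if c == feature or c.startswith(f"{feature}_")]
            tag = zlib.crc32(feature.encode())
            rng = np.random.default_rng([int(self.model.config.seed) % (2**31), tag])
            incr = []
            for _ in range(n_repeats):
                Xp = X0.copy()
                perm = rng.permutation(len(y))
                Xp[:, block] = Xp[perm][:, block]
                incr.append(np.mean((self.rf.predict(Xp) - y) ** 2) - base)
            rows.append({"variable": feature, "score": float(np.mean(incr))})
        imp = pd.DataFrame(rows).sort_values(
            ["score", "variable"], ascending=[False, True]).reset_index(drop=True)
        imp["rank"] = np.arange(1, len(imp) + 1)
        self._importance = imp
        return imp

    def summary(self) -> pd.DataFrame:
        imp = self.importance()
        out = imp.copy()
        out.attrs["oob_mse"] = self.oob_mse
        out.attrs["oob_r2"] = self.oob_r2
        return out


def rf_loocv(table: pd.DataFrame, outcome: str, config: RfConfig | None = None,
             feature_columns: list | None = None) -> pd.DataFrame:
    """Leave-one-survey-out RF predictions (refits one forest per row)."""
    config = config or RfConfig()
    cols = feature_columns or table.attrs.get("feature_columns")
    preds = []
    for i in range(len(table)):
        sub = table.drop(index=i).reset_index(drop=True)
        sub.attrs["feature_columns"] = cols
        res = StratumMonthForest(sub, outcome, cols, config).fit()
        feat = table.loc[[i], cols]
        feat.index = pd.MultiIndex.from_arrays(
            [table.loc[[i], "stratum_id"], table.loc[[i], "month"]])
        pred = res.predict_ci(feat, source="loocv")
        pred["survey_id"] = table.loc[i, "survey_id"]
        preds.append(pred)
    return pd.concat(preds, ignore_index=True)
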