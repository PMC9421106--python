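"""Child-level GLM prediction track.

Chronological train/holdout split, per-predictor form and lag selection by
univariate test p-value, all-subsets model enumeration, weighted
quasi-binomial / gaussian fitting with cluster-robust (sandwich) standard
errors, stratum-month aggregated prediction with simulation-based intervals,
leave-one-survey-out cross-validation, and best-fraction shortlisting by
holdout mean square error.

The modelling surface follows the statsmodels idiom: :class:`ChildGLM` is
built from data and ``fit()`` returns a :class:`ChildGLMResults` carrying
estimates, robust covariance, dispersion and prediction methods.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from .anthro import BINARY_OUTCOMES, CONTINUOUS_OUTCOMES, MUAC_DEFINITION, WFH_DEFINITION, classify_children
from .exceptions import ConfigError, SelectionError, ShortlistError, SplitError
from .panel import LagSpec

__all__ = [
    "PredictorSpec",
    "CandidateModel",
    "ChildGLM",
    "ChildGLMResults",
    "chronological_split",
    "assemble_training_frame",
    "design_matrix",
    "select_predictor_form",
    "enumerate_models",
    "loocv",
    "shortlist",
    "weighted_quantile_breakpoints",
]


@dataclass(frozen=True)
class PredictorSpec:
    """A predictor's chosen representation in the linear predictor.

    ``column`` names the (already lag-aggregated) feature column; ``form`` is
    'continuous' or 'categorical'. Numeric categoricals carry strictly
    increasing ``breakpoints``; string categoricals carry ``levels`` with the
    reference level first.
    """

    variable: str
    column: str
    form: str
    lag: tuple | None = None
    breakpoints: tuple | None = None
    levels: tuple | None = None
    p_value: float | None = None

    def __post_init__(self):
        if self.form not in ("continuous", "categorical"):
            raise ConfigError(f"unknown form {self.form!r}")
        if self.form == "categorical":
            if self.breakpoints is not None:
                bp = tuple(self.breakpoints)
                if len(bp) < 1 or any(a >= b for a, b in zip(bp, bp[1:])):
                    raise ConfigError("breakpoints must be strictly increasing")
            elif self.levels is not None:
                if len(self.levels) < 2:
                    raise ConfigError("categorical form needs >= 2 levels")
            else:
                raise ConfigError("categorical form needs breakpoints or levels")

    def design_columns(self, values: pd.Series) -> pd.DataFrame:
        """Design sub-matrix for this predictor from raw feature values."""
        if self.form == "continuous":
            return pd.DataFrame({self.column: values.astype(float)})
        if self.breakpoints is not None:
            edges = [-np.inf, *self.breakpoints, np.inf]
            binned = pd.cut(values.astype(float), edges, right=False)
            cats = binned.cat.categories
            out = {}
            for cat in cats[1:]:  # first bin is the reference
                out[f"{self.column}[{cat}]"] = (binned == cat).astype(float)
            df = pd.DataFrame(out, index=values.index)
            df[values.isna()] = np.nan
            return df
        out = {}
        for lev in self.levels[1:]:
            out[f"{self.column}[{lev}]"] = (values == lev).astype(float)
        df = pd.DataFrame(out, index=values.index)
        df[values.isna()] = np.nan
        return df


def weighted_quantile_breakpoints(values: pd.Series, weights: pd.Series,
                                  n_levels: int = 4) -> tuple:
    """Interior weighted quantiles as default categorisation breakpoints."""
    v = values.to_numpy(float)
    w = weights.to_numpy(float)
    ok = np.isfinite(v) & np.isfinite(w)
    v, w = v[ok], w[ok]
    order = np.argsort(v)
    v, w = v[order], w[order]
    cdf = np.cumsum(w) / w.sum()
    qs = np.arange(1, n_levels) / n_levels
    bps = np.interp(qs, cdf, v)
    bps = tuple(sorted(set(np.round(bps, 10))))
    return bps


def chronological_split(meta: pd.DataFrame, train_fraction: float = 0.70):
    """Chronologically first ~70% of surveys to train, rest to holdout.

    Surveys are sorted by month; the first ceil(f*N) go to train, and any
    further surveys sharing the boundary month are kept in train too (whole
    months are never split). Raises :class:`SplitError` when fewer than two
    surveys exist or the holdout would be empty.
    """
    if len(meta) < 2:
        raise SplitError("need >= 2 surveys to split")
    meta = meta.sort_values(["month", "survey_id"], kind="mergesort").reset_index(drop=True)
    n_train = math.ceil(train_fraction * len(meta))
    boundary = meta.loc[n_train - 1, "month"]
    train = meta[meta["month"] <= boundary]
    holdout = meta[meta["month"] > boundary]
    if len(holdout) == 0:
        raise SplitError("holdout empty: all surveys fall in the boundary month")
    return train.reset_index(drop=True), holdout.reset_index(drop=True)


def _endog(children: pd.DataFrame, outcome: str) -> pd.Series:
    if outcome in BINARY_OUTCOMES:
        severity, basis = BINARY_OUTCOMES[outcome]
        definition = WFH_DEFINITION if basis == "wfh" else MUAC_DEFINITION
        cls = classify_children(children, definition)
        y = ((cls["status"] == "SAM") if severity == "sam"
             else cls["gam"].astype("boolean"))
        y = y.astype("float")
        y[cls["status"].isna()] = np.nan
        return y
    if outcome in CONTINUOUS_OUTCOMES:
        return children[CONTINUOUS_OUTCOMES[outcome]].astype(float)
    raise ConfigError(f"unknown outcome {outcome!r}")


def family_for(outcome: str) -> str:
    return "quasibinomial" if outcome in BINARY_OUTCOMES else "gaussian"


def assemble_training_frame(children: pd.DataFrame, meta: pd.DataFrame,
                            features: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """Child-level modelling frame: endog, weight, cluster code, features.

    Joins each non-excluded child to its survey's stratum-month feature row
    and analysis weight. Children that are unclassifiable for the outcome or
    whose survey lacks features are dropped (that is the only filtering).
    """
    kept = children[children["exclusion_reason"].isna()].copy()
    kept["y"] = _endog(kept, outcome)
    kept = kept[kept["y"].notna()]
    mcols = ["survey_id", "stratum_id", "month", "analysis_weight"]
    frame = kept.merge(meta[mcols], on="survey_id", how="left")
    frame["analysis_weight"] = frame["analysis_weight"].fillna(0.5)
    frame = frame[frame["analysis_weight"] > 0]
    feat = features.reset_index()
    frame = frame.merge(feat, on=["stratum_id", "month"], how="left")
    frame["cluster"] = frame["survey_id"].astype(str) + "/" + frame["cluster_id"].astype(str)
    return frame


def design_matrix(frame: pd.DataFrame, specs: tuple) -> pd.DataFrame:
    """Design matrix (with intercept) for a set of predictor specs."""
    parts = [pd.DataFrame({"const": np.ones(len(frame))}, index=frame.index)]
    for spec in specs:
        parts.append(spec.design_columns(frame[spec.column]))
    return pd.concat(parts, axis=1)


def _drop_collinear(X: pd.DataFrame) -> pd.DataFrame:
    arr = X.to_numpy(float)
    q, r = np.linalg.qr(arr)
    diag = np.abs(np.diag(r))
    keep = diag > 1e-8 * max(diag.max(), 1.0)
    if keep.all():
        return X
    dropped = list(X.columns[~keep])
    warnings.warn(f"dropping collinear design columns: {dropped}")
    return X.loc[:, keep]


class ChildGLM:
    """Weighted GLM of a child-level anthropometric outcome on stratum-month
    predictor features.

    Binary outcomes (SAM/GAM by either basis) use a quasi-binomial logit
    model; continuous outcomes (WHZ, MUAC) a gaussian model. Survey analysis
    weights (quality x coverage) enter as variance weights; standard errors
    are sandwich estimates clustered on survey x cluster.
    """

    def __init__(self, outcome: str, frame: pd.DataFrame, specs: tuple):
        self.outcome = outcome
        self.family = family_for(outcome)
        self.specs = tuple(specs)
        need = [s.column for s in self.specs]
        ok = frame[need].notna().all(axis=1) if need else pd.Series(True, index=frame.index)
        self.frame = frame[ok]
        self.n_dropped_missing_features = int((~ok).sum())

    @classmethod
    def from_data(cls, outcome: str, children: pd.DataFrame, meta: pd.DataFrame,
                  features: pd.DataFrame, specs: tuple) -> "ChildGLM":
        frame = assemble_training_frame(children, meta, features, outcome)
        return cls(outcome, frame, specs)

    def fit(self) -> "ChildGLMResults":
        frame = self.frame
        if len(frame) == 0:
            raise SelectionError("no usable observations")
        X = _drop_collinear(design_matrix(frame, self.specs))
        y = frame["y"].to_numpy(float)
        w = frame["analysis_weight"].to_numpy(float)
        groups = pd.Categorical(frame["cluster"]).codes
        fam = (sm.families.Binomial() if self.family == "quasibinomial"
               else sm.families.Gaussian())
        model = sm.GLM(y, X.to_numpy(float), family=fam, var_weights=w)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(cov_type="cluster", cov_kwds={"groups": groups})
        converged = bool(getattr(res, "converged", True)) and np.isfinite(res.params).all()
        dispersion = float(res.pearson_chi2 / res.df_resid) if res.df_resid > 0 else np.nan
        params = pd.Series(res.params, index=X.columns)
        cov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
        return ChildGLMResults(self, params, cov, dispersion, res, converged)


class ChildGLMResults:
    """Fitted child-level GLM: coefficients, cluster-robust covariance,
    Pearson dispersion, and stratum-month prediction machinery."""

    def __init__(self, model: ChildGLM, params: pd.Series, cov: pd.DataFrame,
                 dispersion: float, sm_results, converged: bool):
        self.model = model
        self.params = params
        self.cov_params = cov
        self.dispersion = dispersion
        self.sm_results = sm_results
        self.converged = converged

    @property
    def outcome(self):
        return self.model.outcome

    @property
    def family(self):
        return self.model.family

    def _linear_response(self, eta):
        return expit(eta) if self.family == "quasibinomial" else eta

    def _target_design(self, features: pd.DataFrame, keys) -> pd.DataFrame:
        feat = features.loc[list(keys)]
        X = design_matrix(feat, self.model.specs)
        X = X.loc[:, self.params.index]  # align with (possibly pruned) fit
        return X

    def predict_stratum_month(self, features: pd.DataFrame, keys=None,
                              n_draws: int = 10_000, seed: int = 0,
                              source: str = "train") -> pd.DataFrame:
        """Point prediction and percentile intervals per stratum-month.

        The point is the fitted response at the stratum-month's feature row
        (features are constant within a stratum-month, so the child-mean
        equals the single-row response). Intervals come from parametric
        simulation: coefficient draws from a multivariate normal with the
        cluster-robust covariance, the stratum-month response recomputed per
        draw, and 95% / 80% percentile intervals taken. Deterministic given
        ``seed``. Stratum-months with missing features are skipped and
        reported via the ``n_missing`` attribute on the result.
        """
        if keys is None:
            keys = list(features.index)
        feat = features.loc[list(keys)]
        need = [s.column for s in self.model.specs]
        ok = feat[need].notna().all(axis=1) if need else pd.Series(True, index=feat.index)
        usable = feat.index[ok]
        X = self._target_design(features, usable).to_numpy(float)
        point = self._linear_response(X @ self.params.to_numpy())

        cov = self.cov_params.to_numpy(float)
        cov = (cov + cov.T) / 2.0
        rng = np.random.default_rng(seed)
        if np.allclose(cov, 0.0):
            draws_resp = np.tile(point[:, None], (1, 1))
            qs = {"ci95_low": point, "ci95_high": point,
                  "ci80_low": point, "ci80_high": point}
        else:
            vals, vecs = np.linalg.eigh(cov)
            vals = np.clip(vals, 0.0, None)
            root = vecs * np.sqrt(vals)
            z = rng.standard_normal((n_draws, len(self.params)))
            betas = self.params.to_numpy() + z @ root.T
            eta = X @ betas.T
            draws_resp = self._linear_response(eta)
            q = np.percentile(draws_resp, [2.5, 97.5, 10.0, 90.0], axis=1)
            qs = {"ci95_low": q[0], "ci95_high": q[1],
                  "ci80_low": q[2], "ci80_high": q[3]}

        out = pd.DataFrame({
            "stratum_id": [k[0] for k in usable],
            "month": [k[1] for k in usable],
            "outcome": self.outcome,
            "source": source,
            "point": point,
            **qs,
        })
        for col in ("ci95_low", "ci80_low"):
            out[col] = np.minimum(out[col], out["point"])
        for col in ("ci95_high", "ci80_high"):
            out[col] = np.maximum(out[col], out["point"])
        out.attrs["n_missing"] = int((~ok).sum())
        return out

    def summary(self):
        """Statsmodels-style coefficient table with robust SEs."""
        se = np.sqrt(np.diag(self.cov_params.to_numpy(float)))
        z = self.params.to_numpy() / np.where(se > 0, se, np.nan)
        p = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame({
            "coef": self.params, "robust_se": se, "z": z, "p_value": p,
        })


def _null_pvalue(frame: pd.DataFrame, spec_cols: pd.DataFrame, family: str):
    """p-value of the univariate model against the intercept-only null."""
    ok = spec_cols.notna().all(axis=1)
    y = frame.loc[ok, "y"].to_numpy(float)
    w = frame.loc[ok, "analysis_weight"].to_numpy(float)
    X1 = np.column_stack([np.ones(ok.sum()), spec_cols[ok].to_numpy(float)])
    X1 = X1[:, np.abs(X1).sum(axis=0) > 0]
    if X1.shape[1] < 2 or np.linalg.matrix_rank(X1) < X1.shape[1]:
        return None
    X0 = X1[:, :1]
    fam = sm.families.Binomial() if family == "quasibinomial" else sm.families.Gaussian()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            r1 = sm.GLM(y, X1, family=fam, var_weights=w).fit()
            r0 = sm.GLM(y, X0, family=fam, var_weights=w).fit()
        except Exception:
            return None
    q = X1.shape[1] - 1
    if family == "quasibinomial":
        phi = r1.pearson_chi2 / r1.df_resid if r1.df_resid > 0 else 1.0
        phi = max(phi, 1e-12)
        stat = (r0.deviance - r1.deviance) / phi
        if not np.isfinite(stat) or stat < 0:
            return None
        return float(stats.chi2.sf(stat, q))
    rss1, rss0 = r1.deviance, r0.deviance
    df1 = r1.df_resid
    if df1 <= 0 or rss1 <= 0:
        return None
    f = ((rss0 - rss1) / q) / (rss1 / df1)
    if not np.isfinite(f) or f < 0:
        return None
    return float(stats.f.sf(f, q, df1))


def select_predictor_form(frame: pd.DataFrame, variable: str,
                          candidate_lags: list[LagSpec], family: str,
                          breakpoints: tuple | None = None,
                          n_breakpoint_levels: int = 4,
                          forms: tuple = ("continuous", "categorical")) -> PredictorSpec:
    """Choose the representation of one predictor by univariate p-value.

    Fits a weighted univariate GLM per (form, lag) candidate and tests it
    against the intercept-only null (scaled-deviance chi-square for binary
    outcomes, F-test for continuous ones); returns the spec with the smallest
    p-value. Ties break toward the continuous form, then the shortest lag.
    Unestimable candidates (separation, zero variance) are skipped; if every
    candidate is skipped a :class:`SelectionError` is raised.
    """
    candidates = []
    for lag_spec in candidate_lags:
        col = lag_spec.feature_name
        if col not in frame.columns:
            continue
        values = frame[col]
        if values.notna().sum() == 0:
            continue
        for form in forms:
            if form == "continuous":
                spec = PredictorSpec(variable, col, "continuous",
                                     lag=(lag_spec.window_start, lag_spec.window_end))
            else:
                bps = breakpoints
                if bps is None:
                    bps = weighted_quantile_breakpoints(
                        values, frame["analysis_weight"], n_breakpoint_levels)
                if len(bps) < 1:
                    continue
                spec = PredictorSpec(variable, col, "categorical",
                                     lag=(lag_spec.window_start, lag_spec.window_end),
                                     breakpoints=tuple(bps))
            p = _null_pvalue(frame, spec.design_columns(values), family)
            if p is not None:
                candidates.append((spec, p))
    if not candidates:
        raise SelectionError(f"no estimable candidate for {variable!r}")

    def sort_key(item):
        spec, p = item
        form_rank = 0 if spec.form == "continuous" else 1
        lag = spec.lag or (0, 0)
        return (p, form_rank, lag[1] - lag[0], lag[0])

    best, p = min(candidates, key=sort_key)
    return replace(best, p_value=p)


@dataclass
class CandidateModel:
    """One member of the all-subsets enumeration."""

    outcome: str
    family: str
    specs: tuple
    results: ChildGLMResults | None = None
    holdout_mse: float | None = None
    loocv_mse: float | None = None
    converged: bool = True

    @property
    def n_terms(self) -> int:
        return len(self.specs)

    @property
    def label(self) -> str:
        return " + ".join(s.column for s in self.specs)


def enumerate_models(specs: list, max_terms: int | None = None,
                     cap: int = 4096) -> list[tuple]:
    """All non-empty subsets of the spec list, up to ``max_terms`` terms."""
    if len(specs) == 0:
        raise ConfigError("need >= 1 predictor spec")
    k = len(specs)
    max_terms = max_terms or k
    total = sum(math.comb(k, j) for j in range(1, max_terms + 1))
    if total > cap:
        raise ConfigError(
            f"enumeration would produce {total} candidates (> cap {cap}); "
            "raise the cap or reduce the number of predictors")
    out = []
    for j in range(1, max_terms + 1):
        out.extend(itertools.combinations(specs, j))
    return out


def loocv(outcome: str, children: pd.DataFrame, meta: pd.DataFrame,
          features: pd.DataFrame, specs: tuple, seed: int = 0,
          n_draws: int = 2000) -> pd.DataFrame:
    """Leave-one-survey-out cross-validated stratum-month predictions.

    For each survey the model is refitted on every other survey's children
    and the held-out survey's stratum-month is predicted (its own children
    never enter the fold's fit). Folds whose refit fails are skipped and
    reported via the ``skipped`` attr.
    """
    if len(meta) < 3:
        raise SplitError("LOOCV needs >= 3 surveys")
    frame = assemble_training_frame(children, meta, features, outcome)
    preds, skipped = [], []
    fold_nobs = {}
    for sid in meta["survey_id"]:
        sub = frame[frame["survey_id"] != sid]
        fold_nobs[sid] = len(sub)
        mrow = meta[meta["survey_id"] == sid].iloc[0]
        key = (mrow["stratum_id"], mrow["month"])
        try:
            res = ChildGLM(outcome, sub, specs).fit()
            pred = res.predict_stratum_month(
                features, [key], n_draws=n_draws, seed=seed, source="loocv")
        except Exception as exc:  # refit failure: skip and report
            skipped.append((sid, str(exc)))
            continue
        pred["survey_id"] = sid
        preds.append(pred)
    out = pd.concat(preds, ignore_index=True) if preds else pd.DataFrame()
    out.attrs["skipped"] = skipped
    out.attrs["fold_nobs"] = fold_nobs
    out.attrs["total_nobs"] = len(frame)
    return out


def shortlist(candidates: list[CandidateModel],
              fraction: float = 0.10) -> list[CandidateModel]:
    """Best candidates by holdout MSE: top ceil(fraction * M), ascending.

    Ties break by fewer terms, then lexicographic spec order. Candidates
    without a holdout MSE (failed fits, no holdout overlap) are not ranked;
    if none remain a :class:`ShortlistError` is raised.
    """
    scored = [c for c in candidates
              if c.holdout_mse is not None and np.isfinite(c.holdout_mse)
              and c.converged]
    if not scored:
        raise ShortlistError("no candidate has holdout predictions")
    k = math.ceil(fraction * len(scored))
    ranked = sorted(scored, key=lambda c: (c.holdout_mse, c.n_terms, c.label))
    return ranked[:k]
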