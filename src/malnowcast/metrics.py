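"""Predictive-performance evaluation of stratum-month predictions.

Metrics follow the humanitarian now-casting conventions: mean square error;
relative bias, the mean of (yhat_i - y_i) / y_i over stratum-months;
relative precision, the mean ratio of the one-sided 95% interval half-width
to the point estimate; effective coverage, the proportion of stratum-months
whose predicted point falls inside the observed survey's design-based CI;
and sensitivity/specificity of predicted vs observed classification at the
programmatic prevalence thresholds (SAM 2% and 5%, GAM 15% and 20%).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError, EvaluationError

__all__ = [
    "ThresholdSet",
    "THRESHOLDS",
    "MetricsReport",
    "match_pairs",
    "mse",
    "relative_bias",
    "relative_precision",
    "effective_coverage",
    "threshold_classification",
    "build_report",
    "plot_data",
]


@dataclass(frozen=True)
class ThresholdSet:
    """Programmatic prevalence thresholds for one outcome family."""

    family: str
    lower: float
    upper: float

    def __post_init__(self):
        if not (0.0 < self.lower < self.upper < 1.0):
            raise ConfigError("thresholds must satisfy 0 < lower < upper < 1")


THRESHOLDS = {
    "sam": ThresholdSet("sam", 0.02, 0.05),
    "gam": ThresholdSet("gam", 0.15, 0.20),
}


def thresholds_for(outcome: str) -> ThresholdSet | None:
    if outcome.startswith("sam"):
        return THRESHOLDS["sam"]
    if outcome.startswith("gam"):
        return THRESHOLDS["gam"]
    return None


def match_pairs(predictions: pd.DataFrame, observed: pd.DataFrame) -> pd.DataFrame:
    """Inner join of predictions and observed surveys on
    (stratum_id, month, outcome), keeping the prediction source.

    Unmatched keys from either side are reported via attrs; zero matches
    raise :class:`EvaluationError`.
    """
    keys = ["stratum_id", "month", "outcome"]
    obs = observed.rename(columns={
        "point": "y", "ci95_low": "y_ci95_low", "ci95_high": "y_ci95_high",
        "ci80_low": "y_ci80_low", "ci80_high": "y_ci80_high",
    })
    obs_cols = keys + ["y", "y_ci95_low", "y_ci95_high", "y_ci80_low", "y_ci80_high"]
    obs_cols = [c for c in obs_cols if c in obs.columns]
    pairs = predictions.merge(obs[obs_cols], on=keys, how="inner")
    if len(pairs) == 0:
        raise EvaluationError("no matched prediction-observation pairs")
    pkeys = set(map(tuple, predictions[keys].to_numpy()))
    okeys = set(map(tuple, observed[keys].to_numpy()))
    pairs.attrs["unmatched_predictions"] = sorted(pkeys - okeys)
    pairs.attrs["unmatched_observed"] = sorted(okeys - pkeys)
    return pairs


def mse(pairs: pd.DataFrame) -> float:
    """Mean of squared prediction errors (yhat - y)^2."""
    if len(pairs) == 0:
        raise EvaluationError("no pairs")
    d = pairs["point"].to_numpy(float) - pairs["y"].to_numpy(float)
    return float(np.mean(d**2))


def relative_bias(pairs: pd.DataFrame):
    """Signed mean of (yhat - y)/y; pairs with y = 0 excluded and counted.

    Returns ``(bias, n_used, n_zero_excluded)``; the bias is None when every
    observation is zero (undefined).
    """
    y = pairs["y"].to_numpy(float)
    yhat = pairs["point"].to_numpy(float)
    nz = y != 0
    n_zero = int((~nz).sum())
    if nz.sum() == 0:
        return None, 0, n_zero
    bias = float(np.mean((yhat[nz] - y[nz]) / y[nz]))
    return bias, int(nz.sum()), n_zero


def relative_precision(predictions: pd.DataFrame):
    """Mean ratio of the one-sided 95% CI half-width to the point estimate.

    The one-sided interval is (ci95_high - ci95_low)/2 (half-width reading of
    a "one-sided CI"). Zero point estimates are excluded and counted.
    Returns ``(precision, n_used, n_zero_excluded)``.
    """
    point = predictions["point"].to_numpy(float)
    half = (predictions["ci95_high"].to_numpy(float)
            - predictions["ci95_low"].to_numpy(float)) / 2.0
    nz = point != 0
    n_zero = int((~nz).sum())
    if nz.sum() == 0:
        return None, 0, n_zero
    return float(np.mean(half[nz] / point[nz])), int(nz.sum()), n_zero


def effective_coverage(pairs: pd.DataFrame, level: float = 0.95):
    """Fraction of pairs whose predicted point lies inside the observed
    survey's CI at ``level`` (closed interval). Pairs lacking the observed
    CI are excluded and counted. Returns ``(coverage, n_used, n_excluded)``.
    """
    tag = f"y_ci{int(round(level * 100))}"
    lo_col, hi_col = f"{tag}_low", f"{tag}_high"
    if lo_col not in pairs.columns or hi_col not in pairs.columns:
        raise EvaluationError(f"observed CIs at level {level} not available")
    lo = pairs[lo_col].to_numpy(float)
    hi = pairs[hi_col].to_numpy(float)
    point = pairs["point"].to_numpy(float)
    ok = np.isfinite(lo) & np.isfinite(hi)
    n_excl = int((~ok).sum())
    if ok.sum() == 0:
        return None, 0, n_excl
    inside = (lo[ok] <= point[ok]) & (point[ok] <= hi[ok])
    return float(inside.mean()), int(ok.sum()), n_excl


def threshold_classification(pairs: pd.DataFrame,
                             thresholds: ThresholdSet) -> dict:
    """Sensitivity and specificity at each threshold, observed = gold standard.

    Classes use >= on both axes (observed positive when y >= tau, predicted
    positive when yhat >= tau). Returns, per threshold, sensitivity and
    specificity with their denominators (None when a denominator is zero).
    """
    y = pairs["y"].to_numpy(float)
    yhat = pairs["point"].to_numpy(float)
    out = {}
    for name, tau in (("lower", thresholds.lower), ("upper", thresholds.upper)):
        obs_pos = y >= tau
        pred_pos = yhat >= tau
        n_pos, n_neg = int(obs_pos.sum()), int((~obs_pos).sum())
        sens = float((pred_pos & obs_pos).sum() / n_pos) if n_pos else None
        spec = float(((~pred_pos) & (~obs_pos)).sum() / n_neg) if n_neg else None
        out[name] = {
            "threshold": tau,
            "sensitivity": sens, "n_observed_positive": n_pos,
            "specificity": spec, "n_observed_negative": n_neg,
        }
    return out


@dataclass
class MetricsReport:
    """Per-outcome evaluation: one metrics block per prediction source."""

    outcome: str
    sources: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "MetricsReport":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(outcome=raw["outcome"], sources=raw["sources"])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for source, block in sorted(self.sources.items()):
            flat = {"outcome": self.outcome, "source": source}
            for key, val in block.items():
                if isinstance(val, dict):
                    for name, sub in val.items():
                        if isinstance(sub, dict):
                            for k2, v2 in sub.items():
                                flat[f"{key}_{name}_{k2}"] = v2
                        else:
                            flat[f"{key}_{name}"] = sub
                else:
                    flat[key] = val
            rows.append(flat)
        return pd.DataFrame(rows)


def evaluate_source(pairs: pd.DataFrame, outcome: str) -> dict:
    """All metrics for one (outcome, source) pair set."""
    block = {"n": int(len(pairs)), "mse": mse(pairs)}
    bias, n_used, n_zero = relative_bias(pairs)
    block["relative_bias"] = {"value": bias, "n": n_used, "n_zero_excluded": n_zero}
    prec, n_used, n_zero = relative_precision(pairs)
    block["relative_precision"] = {"value": prec, "n": n_used,
                                   "n_zero_excluded": n_zero}
    for level, tag in ((0.95, "coverage_95"), (0.80, "coverage_80")):
        cov, n_used, n_excl = effective_coverage(pairs, level)
        block[tag] = {"value": cov, "n": n_used, "n_excluded": n_excl}
    ts = thresholds_for(outcome)
    if ts is not None:
        block["classification"] = threshold_classification(pairs, ts)
    return block


def build_report(predictions: pd.DataFrame, observed: pd.DataFrame,
                 outcome: str) -> MetricsReport:
    """Evaluate one outcome's predictions against observed surveys, per
    source (train / loocv / holdout). Sources with no matched pairs are
    marked absent."""
    report = MetricsReport(outcome=outcome)
    preds = predictions[predictions["outcome"] == outcome]
    obs = observed[observed["outcome"] == outcome]
    for source in sorted(preds["source"].unique()):
        sub = preds[preds["source"] == source]
        try:
            pairs = match_pairs(sub, obs)
        except EvaluationError:
            report.sources[source] = {"absent": True}
            continue
        report.sources[source] = evaluate_source(pairs, outcome)
    return report


def plot_data(predictions: pd.DataFrame, observed: pd.DataFrame,
              outcome: str, bands=(0.01, 0.02, 0.03)) -> pd.DataFrame:
    """Predicted-vs-observed scatter data with absolute-deviance band
    membership at +/-1, 2, 3 percentage points and the threshold lines."""
    preds = predictions[predictions["outcome"] == outcome]
    obs = observed[observed["outcome"] == outcome]
    pairs = match_pairs(preds, obs)
    out = pairs[["stratum_id", "month", "outcome", "source", "point", "y"]].copy()
    dev = (out["point"] - out["y"]).abs()
    for band in bands:
        out[f"within_{band * 100:.0f}pct"] = dev <= band + 1e-12
    ts = thresholds_for(outcome)
    if ts is not None:
        out.attrs["threshold_lines"] = (ts.lower, ts.upper)
    return out
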