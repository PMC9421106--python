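"""Reanalysis of child-level anthropometric survey records.

Implements the standard SMART-style reanalysis chain: conversion of raw
weight/height readings to weight-for-height z-scores (WHZ) against an LMS
growth reference, flagging and exclusion of implausible records, dual case
definitions of acute malnutrition (weight-for-height based and MUAC based,
both with bilateral oedema overriding), survey quality/coverage weighting,
and design-based prevalence estimation with cluster-robust uncertainty.

Case definitions (children 6-59 months):

* WFH basis:  SAM  WHZ < -3 or oedema;  GAM  WHZ < -2 or oedema.
* MUAC basis: SAM  MUAC < 115 mm or oedema; GAM MUAC < 125 mm or oedema.

SAM is always a subset of GAM (MAM = GAM and not SAM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    ConfigError,
    EstimationError,
    ReferenceRangeError,
    UnclassifiableError,
)

__all__ = [
    "LmsReferenceTable",
    "CaseDefinition",
    "WFH_DEFINITION",
    "MUAC_DEFINITION",
    "PrevalenceEstimate",
    "compute_whz",
    "add_whz",
    "apply_exclusions",
    "classify_child",
    "classify_children",
    "rescale_quality",
    "sampling_coverage",
    "estimate_prevalence",
    "estimate_mean",
    "reanalyse",
    "BINARY_OUTCOMES",
    "CONTINUOUS_OUTCOMES",
]

#: binary outcome labels: (severity, basis)
BINARY_OUTCOMES = {
    "sam_wfh": ("sam", "wfh"),
    "gam_wfh": ("gam", "wfh"),
    "sam_muac": ("sam", "muac"),
    "gam_muac": ("gam", "muac"),
}
#: continuous outcome labels -> child column
CONTINUOUS_OUTCOMES = {"mean_whz": "whz", "mean_muac": "muac_mm"}


class LmsReferenceTable:
    """LMS (lambda-mu-sigma) growth-reference table keyed by sex and height.

    Parameters
    ----------
    table : DataFrame
        Columns ``sex`` ('f'/'m'), ``key`` (height/length in cm), ``L``,
        ``M``, ``S``. Keys must be unique per sex; M and S positive.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"sex", "key", "L", "M", "S"}
        if not required.issubset(table.columns):
            raise ConfigError(f"reference table needs columns {sorted(required)}")
        if (table["M"] <= 0).any() or (table["S"] <= 0).any():
            raise ConfigError("reference table requires M > 0 and S > 0")
        table = table.sort_values(["sex", "key"]).reset_index(drop=True)
        if table.duplicated(["sex", "key"]).any():
            raise ConfigError("duplicate (sex, key) rows in reference table")
        self.table = table
        self._by_sex = {
            s: g[["key", "L", "M", "S"]].to_numpy(float)
            for s, g in table.groupby("sex")
        }

    @classmethod
    def from_csv(cls, path) -> "LmsReferenceTable":
        return cls(pd.read_csv(path))

    @classmethod
    def synthetic(cls, key_min: float = 45.0, key_max: float = 120.0,
                  step: float = 0.5) -> "LmsReferenceTable":
        """Synthetic LMS reference for testing and simulation.

        Not the WHO 2006 standard: a smooth, monotone stand-in with the same
        structure (median weight rising with height, mild skewness, ~9%
        coefficient of variation) so that the z-score machinery can be
        exercised without the restricted reference tables.
        """
        keys = np.round(np.arange(key_min, key_max + step / 2, step), 1)
        rows = []
        for sex, mul in (("f", 1.0), ("m", 1.025)):
            m = 0.00035 * keys**2.3 * mul + 1.2
            l = 0.9 - 0.004 * (keys - key_min)
            s = 0.085 + 0.0002 * (keys - key_min)
            rows.append(pd.DataFrame({"sex": sex, "key": keys, "L": l, "M": m, "S": s}))
        return cls(pd.concat(rows, ignore_index=True))

    def range(self, sex: str) -> tuple[float, float]:
        arr = self._by_sex[sex]
        return float(arr[0, 0]), float(arr[-1, 0])

    def params(self, sex: str, key: float) -> tuple[float, float, float]:
        """Linearly interpolated (L, M, S) at ``key`` for ``sex``."""
        if sex not in self._by_sex:
            raise ReferenceRangeError(f"sex {sex!r} not in reference table")
        arr = self._by_sex[sex]
        lo, hi = arr[0, 0], arr[-1, 0]
        if not (lo <= key <= hi):
            raise ReferenceRangeError(
                f"key {key} outside reference range [{lo}, {hi}] for sex {sex!r}"
            )
        l = np.interp(key, arr[:, 0], arr[:, 1])
        m = np.interp(key, arr[:, 0], arr[:, 2])
        s = np.interp(key, arr[:, 0], arr[:, 3])
        return float(l), float(m), float(s)

    def params_vector(self, sex: np.ndarray, key: np.ndarray):
        """Vectorised (L, M, S, in_range) lookup for arrays of children."""
        sex = np.asarray(sex)
        key = np.asarray(key, float)
        l = np.full(key.shape, np.nan)
        m = np.full(key.shape, np.nan)
        s = np.full(key.shape, np.nan)
        ok = np.zeros(key.shape, bool)
        for sx, arr in self._by_sex.items():
            mask = (sex == sx) & np.isfinite(key)
            mask &= (key >= arr[0, 0]) & (key <= arr[-1, 0])
            if mask.any():
                l[mask] = np.interp(key[mask], arr[:, 0], arr[:, 1])
                m[mask] = np.interp(key[mask], arr[:, 0], arr[:, 2])
                s[mask] = np.interp(key[mask], arr[:, 0], arr[:, 3])
                ok[mask] = True
        return l, m, s, ok


def _lms_z(measure, l, m, s):
    measure = np.asarray(measure, float)
    l = np.asarray(l, float)
    m = np.asarray(m, float)
    s = np.asarray(s, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(
            np.abs(l) > 1e-12,
            ((measure / m) ** l - 1.0) / (l * s),
            np.log(measure / m) / s,
        )
    return z


def lms_inverse(z, l, m, s):
    """Measurement value at z-score ``z`` given LMS parameters."""
    l = np.asarray(l, float)
    z = np.asarray(z, float)
    return np.where(
        np.abs(l) > 1e-12,
        m * (1.0 + l * s * z) ** (1.0 / l),
        m * np.exp(s * z),
    )


def compute_whz(weight_kg: float, height_cm: float, sex: str,
                reference: LmsReferenceTable) -> float:
    """Weight-for-height z-score of one child via the LMS formula.

    z = ((w / M)^L - 1) / (L * S), with the log-form limit at L = 0.
    Raises :class:`ReferenceRangeError` when the height is outside the
    reference table's tabulated range.
    """
    if not (np.isfinite(weight_kg) and np.isfinite(height_cm)):
        raise ValueError("weight and height must be present")
    l, m, s = reference.params(sex, height_cm)
    return float(_lms_z(weight_kg, l, m, s))


def add_whz(children: pd.DataFrame, reference: LmsReferenceTable) -> pd.DataFrame:
    """Fill the ``whz`` column where absent, from weight/height/sex.

    Records with a precomputed ``whz`` are left untouched; records whose
    height falls outside the reference range keep ``whz`` = NaN (they will be
    labelled missing downstream).
    """
    out = children.copy()
    if "whz" not in out.columns:
        out["whz"] = np.nan
    need = out["whz"].isna() & out["weight_kg"].notna() & out["height_cm"].notna()
    if need.any():
        l, m, s, ok = reference.params_vector(
            out.loc[need, "sex"].to_numpy(), out.loc[need, "height_cm"].to_numpy()
        )
        z = _lms_z(out.loc[need, "weight_kg"].to_numpy(), l, m, s)
        z[~ok] = np.nan
        out.loc[need, "whz"] = z
    return out


def apply_exclusions(
    children: pd.DataFrame,
    flag_limit: float = 5.0,
    age_range: tuple[float, float] = (6.0, 59.0),
    center: str = "survey_mean",
    muac_bounds: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Label each record with at most one exclusion reason.

    Rules, applied in order (first match wins):

    1. ``missing`` - no WHZ and no MUAC (and no oedema), or missing age;
    2. ``age_out_of_range`` - age outside ``age_range`` months;
    3. ``flagged_outlier`` - |WHZ - center| > ``flag_limit`` z-units, where
       the center is the survey's observed WHZ mean (``center='survey_mean'``,
       the SMART convention) or the reference zero (``center='reference_zero'``).
       Optionally, MUAC outside ``muac_bounds`` mm (off by default).

    Oedema-positive records are never excluded by the flag rule: their case
    status does not depend on anthropometry. Records are retained with their
    reason, never dropped.
    """
    if center not in ("survey_mean", "reference_zero"):
        raise ConfigError(f"unknown flag center {center!r}")
    out = children.copy()
    whz = out["whz"] if "whz" in out else pd.Series(np.nan, index=out.index)
    muac = out["muac_mm"] if "muac_mm" in out else pd.Series(np.nan, index=out.index)
    oed = out["oedema"].fillna(False).astype(bool) if "oedema" in out else pd.Series(False, index=out.index)
    age = out["age_months"]

    missing = age.isna() | (whz.isna() & muac.isna() & ~oed)
    age_out = ~missing & ((age < age_range[0]) | (age > age_range[1]))

    eligible = ~missing & ~age_out
    if center == "survey_mean":
        centers = (
            whz.where(eligible)
            .groupby(out["survey_id"])
            .transform("mean")
            .fillna(0.0)
        )
    else:
        centers = pd.Series(0.0, index=out.index)
    flagged = eligible & ~oed & whz.notna() & ((whz - centers).abs() > flag_limit)
    if muac_bounds is not None:
        lo, hi = muac_bounds
        flagged |= eligible & ~oed & muac.notna() & ((muac < lo) | (muac > hi))

    reason = pd.Series(pd.array([None] * len(out), dtype="object"), index=out.index)
    reason[flagged] = "flagged_outlier"
    reason[age_out] = "age_out_of_range"
    reason[missing] = "missing"
    out["exclusion_reason"] = reason
    return out


@dataclass(frozen=True)
class CaseDefinition:
    """Dual-cutoff acute-malnutrition case definition.

    basis 'wfh' uses WHZ cutoffs (z-scores); basis 'muac' uses MUAC cutoffs
    (mm). Bilateral oedema always classifies as SAM, overriding anthropometry.
    """

    basis: str
    sam_cutoff: float
    gam_cutoff: float

    def __post_init__(self):
        if self.basis not in ("wfh", "muac"):
            raise ConfigError(f"unknown basis {self.basis!r}")
        if not self.sam_cutoff < self.gam_cutoff:
            raise ConfigError("SAM cutoff must be stricter (lower) than GAM cutoff")

    @property
    def measure_column(self) -> str:
        return "whz" if self.basis == "wfh" else "muac_mm"


WFH_DEFINITION = CaseDefinition("wfh", -3.0, -2.0)
MUAC_DEFINITION = CaseDefinition("muac", 115.0, 125.0)


def classify_child(record, definition: CaseDefinition) -> str:
    """Classify one child record as 'SAM', 'MAM' or 'none'.

    GAM is derived: GAM = SAM or MAM. ``record`` is any mapping with keys
    ``oedema`` and the basis measure (``whz`` or ``muac_mm``).
    """
    if bool(record.get("oedema", False) if hasattr(record, "get") else record["oedema"]):
        return "SAM"
    value = record[definition.measure_column]
    if value is None or (isinstance(value, float) and not np.isfinite(value)):
        raise UnclassifiableError(
            f"{definition.measure_column} absent and no oedema: unclassifiable"
        )
    if value < definition.sam_cutoff:
        return "SAM"
    if value < definition.gam_cutoff:
        return "MAM"
    return "none"


def classify_children(children: pd.DataFrame, definition: CaseDefinition) -> pd.DataFrame:
    """Vectorised classification; returns columns ``status`` and ``gam``.

    Records whose basis measure is absent and without oedema get status NaN
    (unclassifiable for this basis; they stay eligible for the other basis).
    """
    oed = children["oedema"].fillna(False).astype(bool)
    val = children[definition.measure_column]
    status = pd.Series(pd.array([None] * len(children), dtype="object"),
                       index=children.index)
    status[val.notna() & (val >= definition.gam_cutoff)] = "none"
    status[val.notna() & (val < definition.gam_cutoff)] = "MAM"
    status[val.notna() & (val < definition.sam_cutoff)] = "SAM"
    status[oed] = "SAM"
    return pd.DataFrame({
        "status": status,
        "gam": status.isin(["SAM", "MAM"]).where(status.notna()),
    }, index=children.index)


def rescale_quality(quality_score_raw: float) -> float:
    """Map the ENA quality score (0 = best ... 0.5 = worst) to [0, 1], 1 = best.

    Linear: rescaled = 1 - 2 * raw.
    """
    if not (0.0 <= quality_score_raw <= 0.5):
        raise ConfigError(
            f"ENA quality score must lie in [0, 0.5], got {quality_score_raw}"
        )
    return 1.0 - 2.0 * quality_score_raw


def sampling_coverage(accessible_units: float, total_units: float) -> float:
    """Fraction of the sampling frame that was accessible (e.g. 10/12)."""
    if total_units <= 0:
        raise ConfigError("total units must be positive")
    if not (0 < accessible_units <= total_units):
        raise ConfigError("accessible units must lie in (0, total]")
    return accessible_units / total_units


@dataclass
class PrevalenceEstimate:
    """Design-based survey estimate: point with CIs at requested levels."""

    n: int
    point: float
    cis: dict  # level -> (low, high)
    n_clusters: int
    warnings: list = field(default_factory=list)


_Z = {0.95: stats.norm.ppf(0.975), 0.80: stats.norm.ppf(0.90)}


def _cluster_score_var(scores: np.ndarray, clusters: np.ndarray,
                       small_sample: bool = True) -> tuple[float, int]:
    """Sum of squared cluster score totals, with G/(G-1) correction."""
    df = pd.DataFrame({"s": scores, "c": clusters})
    totals = df.groupby("c")["s"].sum().to_numpy()
    g = len(totals)
    b = float((totals**2).sum())
    if small_sample and g > 1:
        b *= g / (g - 1)
    return b, g


def estimate_prevalence(
    children: pd.DataFrame,
    definition: CaseDefinition,
    severity: str = "gam",
    levels: tuple[float, ...] = (0.95, 0.80),
    small_sample: bool = True,
) -> PrevalenceEstimate:
    """Survey prevalence with a cluster-robust CI.

    The point estimate is the case fraction among non-excluded, classifiable
    records. The CI comes from an intercept-only binomial model with a
    sandwich variance clustered on ``cluster_id`` (score form on the logit
    scale), equivalent to a design-based estimator for one-stage cluster
    samples. With a single cluster the model-based binomial variance is used
    with a warning; degenerate prevalences (0 or 1) fall back to
    Clopper-Pearson intervals.
    """
    if severity not in ("sam", "gam"):
        raise ConfigError(f"severity must be 'sam' or 'gam', got {severity!r}")
    kept = children[children["exclusion_reason"].isna()]
    cls = classify_children(kept, definition)
    kept = kept[cls["status"].notna()]
    cls = cls.loc[kept.index]
    if len(kept) == 0:
        raise EstimationError("no classifiable non-excluded records")
    y = (cls["status"] == "SAM") if severity == "sam" else cls["gam"].astype(bool)
    y = y.to_numpy(float)
    n = len(y)
    p = float(y.mean())
    clusters = kept["cluster_id"].to_numpy()
    g = len(np.unique(clusters))
    warns = []
    if p in (0.0, 1.0):
        warns.append("degenerate prevalence; Clopper-Pearson interval")
        k = int(y.sum())
        cis = {}
        for lev in levels:
            lo, hi = _clopper_pearson(k, n, lev)
            cis[lev] = (lo, hi)
        return PrevalenceEstimate(n, p, cis, g, warns)
    logit = np.log(p / (1 - p))
    a = n * p * (1 - p)
    if g == 1:
        warns.append("single cluster; falling back to unclustered variance")
        var_beta = 1.0 / a
    else:
        b, _ = _cluster_score_var(y - p, clusters, small_sample)
        var_beta = b / a**2
    se = np.sqrt(var_beta)
    cis = {}
    for lev in levels:
        z = _Z.get(lev, stats.norm.ppf(0.5 + lev / 2))
        lo = 1 / (1 + np.exp(-(logit - z * se)))
        hi = 1 / (1 + np.exp(-(logit + z * se)))
        cis[lev] = (float(lo), float(hi))
    return PrevalenceEstimate(n, p, cis, g, warns)


def _clopper_pearson(k: int, n: int, level: float) -> tuple[float, float]:
    alpha = 1 - level
    lo = 0.0 if k == 0 else stats.beta.ppf(alpha / 2, k, n - k + 1)
    hi = 1.0 if k == n else stats.beta.ppf(1 - alpha / 2, k + 1, n - k)
    return float(lo), float(hi)


def estimate_mean(
    children: pd.DataFrame,
    measure: str,
    levels: tuple[float, ...] = (0.95, 0.80),
    small_sample: bool = True,
) -> PrevalenceEstimate:
    """Gaussian analogue of :func:`estimate_prevalence` for mean WHZ/MUAC."""
    kept = children[children["exclusion_reason"].isna() & children[measure].notna()]
    if len(kept) == 0:
        raise EstimationError("no non-excluded records with the measure")
    x = kept[measure].to_numpy(float)
    n = len(x)
    mean = float(x.mean())
    clusters = kept["cluster_id"].to_numpy()
    g = len(np.unique(clusters))
    warns = []
    if g == 1:
        warns.append("single cluster; falling back to unclustered variance")
        var_mean = x.var(ddof=1) / n if n > 1 else 0.0
    else:
        b, _ = _cluster_score_var(x - mean, clusters, small_sample)
        var_mean = b / n**2
    se = np.sqrt(var_mean)
    cis = {}
    for lev in levels:
        z = _Z.get(lev, stats.norm.ppf(0.5 + lev / 2))
        cis[lev] = (mean - z * se, mean + z * se)
    return PrevalenceEstimate(n, mean, cis, g, warns)


def reanalyse(children: pd.DataFrame, meta: pd.DataFrame,
              outcomes: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Reanalyse every survey: one row per survey x outcome.

    ``children`` must carry ``whz`` and ``exclusion_reason`` (see
    :func:`add_whz`, :func:`apply_exclusions`); ``meta`` one row per survey
    with stratum, month and the analysis weight. Returns the observed table
    used as ground truth by the evaluation stage: n, point, 95% and 80% CI
    bounds, and the survey weight.
    """
    outcomes = tuple(outcomes or (list(BINARY_OUTCOMES) + list(CONTINUOUS_OUTCOMES)))
    rows = []
    for sid, grp in children.groupby("survey_id", sort=True):
        mrow = meta.loc[meta["survey_id"] == sid]
        if len(mrow) == 0:
            warnings.warn(f"survey {sid!r} has no metadata; skipped")
            continue
        mrow = mrow.iloc[0]
        for outcome in outcomes:
            try:
                if outcome in BINARY_OUTCOMES:
                    severity, basis = BINARY_OUTCOMES[outcome]
                    definition = WFH_DEFINITION if basis == "wfh" else MUAC_DEFINITION
                    est = estimate_prevalence(grp, definition, severity)
                else:
                    est = estimate_mean(grp, CONTINUOUS_OUTCOMES[outcome])
            except EstimationError:
                continue
            rows.append({
                "survey_id": sid,
                "stratum_id": mrow["stratum_id"],
                "month": mrow["month"],
                "outcome": outcome,
                "n": est.n,
                "point": est.point,
                "ci95_low": est.cis[0.95][0],
                "ci95_high": est.cis[0.95][1],
                "ci80_low": est.cis[0.80][0],
                "ci80_high": est.cis[0.80][1],
                "analysis_weight": mrow.get("analysis_weight", np.nan),
            })
    return pd.DataFrame(rows)
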