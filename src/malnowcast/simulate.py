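"""Synthetic crisis-setting world generator.

Generates the full data universe the prediction pipeline consumes, with
known ground truth: strata with static livelihood types, a monthly calendar,
stratum-month populations, autocorrelated predictor panels (conflict counts,
epidemic counts, climate series, market prices, displacement, humanitarian
presence) with injectable block missingness, a logistic-link true prevalence
surface driven by named coefficients on lagged predictor features, and
clustered SMART-style surveys of 6-59-month-old children drawn from that
surface.

Every quantity is reproducible bit-for-bit from (config, seed): each
operation derives an independent random stream from the world seed and the
identity of the object being generated, so surveys can be generated in any
order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from .anthro import LmsReferenceTable, lms_inverse
from .config import LIVELIHOODS, GeneratorConfig
from .exceptions import ConfigError

__all__ = [
    "SyntheticWorld",
    "generate_world",
    "generate_predictor_panel",
    "generate_survey",
    "generate_all_surveys",
    "VARIABLE_META",
    "TRUTH_LAGS",
    "icc_to_sigma",
]

#: panel variables and their kinds (drives rate conversion / smoothing /
#: market imputation downstream)
VARIABLE_META = {
    "conflict_deaths": {"kind": "count"},
    "measles_cases": {"kind": "count"},
    "rainfall": {"kind": "climate"},
    "ndvi": {"kind": "climate"},
    "water_price": {"kind": "price"},
    "terms_of_trade": {"kind": "price"},
    "displaced_prop": {"kind": "proportion"},
    "humanitarian_presence": {"kind": "continuous"},
    "livelihood": {"kind": "static"},
}

#: lag window (months prior, start..end) feeding each truth feature;
#: climate features use the allowed semester window, the others short
#: recent windows of the kind reported for conflict, epidemic and price
#: predictors (e.g. deaths 2-4 months prior, measles previous trimester).
TRUTH_LAGS = {
    "conflict_death_rate": (2, 4),
    "measles_rate": (1, 3),
    "rainfall": (1, 6),
    "ndvi": (1, 6),
    "water_price": (1, 3),
    "terms_of_trade": (4, 6),
    "displaced_prop": (1, 3),
    "humanitarian_presence": (1, 3),
}

#: maps truth feature name -> (source variable, uses per-population rate)
_FEATURE_SOURCE = {
    "conflict_death_rate": ("conflict_deaths", True),
    "measles_rate": ("measles_cases", True),
    "rainfall": ("rainfall", False),
    "ndvi": ("ndvi", False),
    "water_price": ("water_price", False),
    "terms_of_trade": ("terms_of_trade", False),
    "displaced_prop": ("displaced_prop", False),
    "humanitarian_presence": ("humanitarian_presence", False),
}

RATE_SCALE = 100_000.0


def icc_to_sigma(icc: float) -> float:
    """SD of the cluster-level logit random effect for a target latent ICC.

    Uses the latent-threshold identity icc = sigma^2 / (sigma^2 + pi^2/3).
    """
    if not (0.0 <= icc < 1.0):
        raise ConfigError("icc must lie in [0, 1)")
    if icc == 0.0:
        return 0.0
    return math.sqrt(icc / (1.0 - icc) * math.pi**2 / 3.0)


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(40)


def recentre_logit(p: float, sigma: float) -> float:
    """Intercept a such that E[expit(a + u)] = p for u ~ N(0, sigma^2).

    Gauss-Hermite quadrature plus root finding; keeps the marginal cluster
    prevalence exactly on target despite the nonlinear link.
    """
    if not (0.0 < p < 1.0):
        raise ConfigError("p must lie in (0, 1)")
    if sigma == 0.0:
        return float(logit(p))
    nodes = math.sqrt(2.0) * sigma * _GH_NODES
    w = _GH_WEIGHTS / math.sqrt(math.pi)

    def marginal(a):
        return float(np.sum(w * expit(a + nodes))) - p

    lo, hi = logit(p) - 6 * sigma - 1, logit(p) + 1
    return float(optimize.brentq(marginal, lo, hi, xtol=1e-12))


@dataclass
class SyntheticWorld:
    """A generated world with complete ground truth.

    ``panel_true`` is the complete (missingness-free) long predictor panel
    over the calendar including ``lead_months`` of pre-study history;
    ``truth_features`` holds the standardised lagged features entering the
    prevalence model; ``truth_prevalence`` the stratum-month true probability
    per outcome; ``survey_schedule`` which stratum-months get surveyed.
    """

    config: GeneratorConfig
    seed: int
    strata: pd.DataFrame
    months: np.ndarray
    calendar: np.ndarray
    population: pd.DataFrame
    panel_true: pd.DataFrame
    truth_features: pd.DataFrame
    truth_coefficients: dict
    truth_prevalence: pd.DataFrame
    survey_schedule: list
    reference: LmsReferenceTable = field(repr=False, default=None)

    def truth(self, stratum_id: str, month: int, outcome: str) -> float:
        sel = self.truth_prevalence[
            (self.truth_prevalence["stratum_id"] == stratum_id)
            & (self.truth_prevalence["month"] == month)
            & (self.truth_prevalence["outcome"] == outcome)
        ]
        if len(sel) == 0:
            raise KeyError(f"unknown stratum-month-outcome ({stratum_id}, {month}, {outcome})")
        return float(sel["p"].iloc[0])


def _ar1(rng: np.random.Generator, n: int, rho: float) -> np.ndarray:
    """Stationary AR(1) series with unit marginal variance."""
    x = np.empty(n)
    x[0] = rng.standard_normal()
    innov = rng.standard_normal(n - 1) * math.sqrt(1.0 - rho**2) if n > 1 else None
    for t in range(1, n):
        x[t] = rho * x[t - 1] + innov[t - 1]
    return x


def generate_world(config: GeneratorConfig) -> SyntheticWorld:
    """Generate strata, populations, the complete predictor panel and the
    true prevalence surface from the configured causal model."""
    rng = np.random.default_rng([config.seed, 11])
    n_s, n_m = config.n_strata, config.n_months
    months = np.arange(1, n_m + 1)
    calendar = np.arange(1 - config.lead_months, n_m + 1)

    strata_ids = [f"S{i + 1:02d}" for i in range(n_s)]
    livelihood = [LIVELIHOODS[i % len(LIVELIHOODS)] for i in range(n_s)]
    livelihood = list(rng.permutation(livelihood))
    strata = pd.DataFrame({"stratum_id": strata_ids, "livelihood": livelihood})

    # populations: stratum base size with mild growth and noise
    base = np.exp(rng.normal(math.log(80_000), 0.5, n_s))
    pop_rows = []
    for i, sid in enumerate(strata_ids):
        drift = (1.002) ** (calendar - calendar[0])
        noise = np.exp(rng.normal(0.0, 0.01, len(calendar)))
        pop = np.maximum(1, np.round(base[i] * drift * noise)).astype(int)
        pop_rows.append(pd.DataFrame(
            {"stratum_id": sid, "month": calendar, "population": pop}))
    population = pd.concat(pop_rows, ignore_index=True)

    # latent AR(1) per (variable, stratum) with a stratum offset
    rho = config.predictor_rho
    series = {}
    tv_vars = [v for v, m in VARIABLE_META.items() if m["kind"] != "static"]
    for vi, var in enumerate(tv_vars):
        for si, sid in enumerate(strata_ids):
            sub = np.random.default_rng([config.seed, 21, vi, si])
            lat = _ar1(sub, len(calendar), rho) + sub.normal(0.0, 0.6)
            series[(var, sid)] = (lat, sub)

    season = np.sin(2.0 * math.pi * (calendar % 12) / 12.0)
    panel_rows = []
    pop_wide = population.pivot(index="month", columns="stratum_id",
                                values="population")
    for si, sid in enumerate(strata_ids):
        pop = pop_wide[sid].to_numpy(float)
        for var in tv_vars:
            lat, sub = series[(var, sid)]
            if var == "rainfall":
                vals = np.clip(70 + 35 * lat + 30 * season, 0.0, None)
            elif var == "ndvi":
                vals = np.clip(0.25 + 0.08 * lat + 0.05 * season, 0.02, 0.80)
            elif var == "water_price":
                vals = np.exp(9.9 + 0.35 * lat)
            elif var == "terms_of_trade":
                vals = np.exp(10.3 + 0.30 * lat)
            elif var == "conflict_deaths":
                vals = sub.poisson(pop / RATE_SCALE * np.exp(1.2 + 0.9 * lat)).astype(float)
            elif var == "measles_cases":
                vals = sub.poisson(pop / RATE_SCALE * np.exp(0.8 + 1.0 * lat)).astype(float)
            elif var == "displaced_prop":
                vals = expit(-2.0 + 0.8 * lat)
            elif var == "humanitarian_presence":
                vals = np.clip(20 + 8 * lat, 0.0, None)
            else:  # pragma: no cover - new variables must be mapped
                raise ConfigError(f"no mapping for variable {var!r}")
            panel_rows.append(pd.DataFrame({
                "stratum_id": sid, "month": calendar, "variable": var,
                "value": vals, "is_imputed": False,
            }))
        panel_rows.append(pd.DataFrame({
            "stratum_id": sid, "month": calendar, "variable": "livelihood",
            "value": strata.loc[si, "livelihood"], "is_imputed": False,
        }))
    panel_true = pd.concat(panel_rows, ignore_index=True)

    truth_features = _build_truth_features(panel_true, population, strata, months)
    coefficients, truth_prevalence = _build_truth_surface(
        truth_features, strata, config)

    if config.survey_schedule is not None:
        schedule = [tuple(x) for x in config.survey_schedule]
        known = set(zip(truth_prevalence["stratum_id"], truth_prevalence["month"]))
        for key in schedule:
            if (key[0], key[1]) not in known:
                raise KeyError(f"scheduled stratum-month {key} not in world")
    else:
        srng = np.random.default_rng([config.seed, 31])
        keys = [(s, int(m)) for s in strata_ids for m in months]
        k = max(1, int(round(config.survey_fraction * len(keys))))
        idx = srng.choice(len(keys), size=k, replace=False)
        schedule = sorted(keys[i] for i in idx)

    return SyntheticWorld(
        config=config, seed=config.seed, strata=strata, months=months,
        calendar=calendar, population=population, panel_true=panel_true,
        truth_features=truth_features, truth_coefficients=coefficients,
        truth_prevalence=truth_prevalence, survey_schedule=schedule,
        reference=LmsReferenceTable.synthetic(),
    )


def _lag_window_mean(wide: pd.DataFrame, start: int, end: int) -> pd.DataFrame:
    """Trailing window mean over months t-end..t-start (columns = strata)."""
    w = end - start + 1
    return wide.rolling(w, min_periods=w).mean().shift(start)


def _build_truth_features(panel_true, population, strata, months) -> pd.DataFrame:
    pop_wide = population.pivot(index="month", columns="stratum_id",
                                values="population").astype(float)
    feats = {}
    for feat, (var, is_rate) in _FEATURE_SOURCE.items():
        sub = panel_true[panel_true["variable"] == var]
        wide = sub.pivot(index="month", columns="stratum_id", values="value").astype(float)
        if is_rate:
            wide = wide / pop_wide * RATE_SCALE
        start, end = TRUTH_LAGS[feat]
        lagged = _lag_window_mean(wide, start, end)
        lagged = lagged.loc[months]
        mu = float(np.nanmean(lagged.to_numpy()))
        sd = float(np.nanstd(lagged.to_numpy()))
        if sd <= 0:
            sd = 1.0
        feats[feat] = (lagged - mu) / sd
    long = {f: df.stack() for f, df in feats.items()}
    out = pd.DataFrame(long)
    out.index.names = ["month", "stratum_id"]
    out = out.reset_index().set_index(["stratum_id", "month"]).sort_index()
    liv = strata.set_index("stratum_id")["livelihood"]
    out["livelihood"] = liv.reindex(out.index.get_level_values(0)).to_numpy()
    return out


def _build_truth_surface(truth_features, strata, config):
    feats = truth_features
    eta_common = np.zeros(len(feats))
    for name, beta in config.effects.items():
        if name not in feats.columns:
            raise ConfigError(f"effect on unknown feature {name!r}")
        eta_common = eta_common + beta * feats[name].to_numpy(float)
    liv_eff = np.zeros(len(feats))
    for cat, beta in config.livelihood_effects.items():
        liv_eff = liv_eff + beta * (feats["livelihood"].to_numpy() == cat)
    eta_common = eta_common + liv_eff

    coefficients, rows = {}, []
    for outcome, alpha in config.intercepts.items():
        coefs = {"intercept": float(alpha)}
        coefs.update({k: float(v) for k, v in config.effects.items()})
        coefs.update({f"livelihood[{k}]": float(v)
                      for k, v in config.livelihood_effects.items()})
        coefficients[outcome] = coefs
        p = expit(alpha + eta_common)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        rows.append(pd.DataFrame({
            "stratum_id": feats.index.get_level_values(0),
            "month": feats.index.get_level_values(1),
            "outcome": outcome,
            "p": p,
        }))
    truth_prevalence = pd.concat(rows, ignore_index=True)
    return coefficients, truth_prevalence


def generate_predictor_panel(world: SyntheticWorld,
                             config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Observed panel: the true panel with block missingness injected.

    Missing spells follow a two-state Markov chain per (variable, stratum)
    whose stationary missing probability equals ``missingness_block_rate``
    and whose persistence produces multi-month blocks. Static variables are
    never masked. Cells removed are recorded with value NaN.
    """
    config = config or world.config
    rate, q = config.missingness_block_rate, config.missingness_persistence
    panel = world.panel_true.copy()
    if rate == 0.0:
        return panel
    p_enter = rate * (1.0 - q) / (1.0 - rate)
    if p_enter > 1.0:
        raise ConfigError("missingness persistence incompatible with rate")
    tv_vars = [v for v, m in VARIABLE_META.items() if m["kind"] != "static"]
    n_cal = len(world.calendar)
    strata_ids = list(world.strata["stratum_id"])
    mask_frames = []
    for vi, var in enumerate(tv_vars):
        for si, sid in enumerate(strata_ids):
            rng = np.random.default_rng([config.seed, 41, vi, si])
            miss = np.zeros(n_cal, bool)
            u = rng.uniform(size=n_cal)
            miss[0] = u[0] < rate
            for t in range(1, n_cal):
                miss[t] = u[t] < (q if miss[t - 1] else p_enter)
            mask_frames.append(pd.DataFrame({
                "stratum_id": sid, "month": world.calendar,
                "variable": var, "miss": miss,
            }))
    mask = pd.concat(mask_frames, ignore_index=True)
    panel = panel.merge(mask, on=["stratum_id", "month", "variable"], how="left")
    panel["miss"] = panel["miss"].astype("boolean").fillna(False).astype(bool)
    panel.loc[panel["miss"], "value"] = np.nan
    return panel.drop(columns="miss")


_WHZ_MIX = {  # status -> (mean, sd, lower, upper) truncated normal
    "SAM": (-3.5, 0.45, -4.9, -3.0),
    "MAM": (-2.35, 0.35, -3.0, -2.0),
    "none": (-0.40, 0.95, -2.0, 4.0),
    "oedema": (-1.5, 1.0, -4.0, 3.0),
}
_MUAC_MIX = {
    "SAM": (108.0, 4.0, 95.0, 115.0),
    "MAM": (120.0, 2.8, 115.0, 125.0),
    "none": (138.0, 9.0, 125.0, 180.0),
    "oedema": (125.0, 10.0, 100.0, 170.0),
}


def _draw_mixture(status: np.ndarray, mix: dict, rng) -> np.ndarray:
    out = np.empty(len(status))
    for key, (mu, sd, lo, hi) in mix.items():
        m = status == key
        if m.any():
            a, b = (lo - mu) / sd, (hi - mu) / sd
            out[m] = stats.truncnorm.rvs(a, b, loc=mu, scale=sd,
                                         size=int(m.sum()), random_state=rng)
    return out


def _nested_status(r: np.ndarray, p_sam: float, p_gam: float) -> np.ndarray:
    status = np.full(len(r), "none", dtype=object)
    status[r < p_gam] = "MAM"
    status[r < p_sam] = "SAM"
    return status


def generate_survey(world: SyntheticWorld, stratum_id: str, month: int,
                    config: GeneratorConfig | None = None):
    """Simulate one clustered SMART-style survey of a stratum-month.

    Children are drawn in clusters sharing a logit-scale random effect whose
    variance matches the configured intra-cluster correlation; case status
    per basis follows the world's true prevalence (marginally exact, thanks
    to intercept recentring); WHZ and MUAC are drawn from truncated-normal
    mixtures consistent with the drawn status, and raw weight is back-computed
    from WHZ through the synthetic growth reference so the reanalysis stage
    can recompute z-scores from raw anthropometry.

    Returns ``(children, meta)``: a DataFrame of child records and a dict of
    survey metadata (quality score, sampling coverage, analysis weight).
    """
    config = config or world.config
    strata_ids = list(world.strata["stratum_id"])
    if stratum_id not in strata_ids:
        raise KeyError(f"unknown stratum {stratum_id!r}")
    if int(month) not in set(int(m) for m in world.months):
        raise KeyError(f"unknown month {month!r}")
    si = strata_ids.index(stratum_id)
    rng = np.random.default_rng([config.seed, 51, si, int(month)])

    p = {o: world.truth(stratum_id, month, o) for o in config.intercepts}
    p_oed = config.oedema_prevalence
    sigma = icc_to_sigma(config.icc)

    def adjusted_intercepts(basis):
        out = {}
        for sev in ("sam", "gam"):
            key = f"{sev}_{basis}"
            padj = (p[key] - p_oed) / (1.0 - p_oed) if p_oed < p[key] else 0.0
            out[sev] = None if padj <= 0 else recentre_logit(min(padj, 1 - 1e-12), sigma)
        return out

    a_wfh = adjusted_intercepts("wfh")
    a_muac = adjusted_intercepts("muac")

    n_c, n_k = config.clusters_per_survey, config.children_per_cluster
    n = n_c * n_k
    u = rng.normal(0.0, sigma, n_c) if sigma > 0 else np.zeros(n_c)
    cluster_idx = np.repeat(np.arange(n_c), n_k)

    oedema = rng.uniform(size=n) < p_oed

    def basis_status(a):
        p_sam_c = expit(a["sam"] + u) if a["sam"] is not None else np.zeros(n_c)
        p_gam_c = expit(a["gam"] + u) if a["gam"] is not None else np.zeros(n_c)
        p_gam_c = np.maximum(p_gam_c, p_sam_c)
        r = rng.uniform(size=n)
        status = np.full(n, "none", dtype=object)
        pg, ps = p_gam_c[cluster_idx], p_sam_c[cluster_idx]
        status[r < pg] = "MAM"
        status[r < ps] = "SAM"
        return status

    status_wfh = basis_status(a_wfh)
    status_muac = basis_status(a_muac)

    draw_wfh = np.where(oedema, "oedema", status_wfh)
    draw_muac = np.where(oedema, "oedema", status_muac)
    whz = _draw_mixture(draw_wfh, _WHZ_MIX, rng)
    muac = _draw_mixture(draw_muac, _MUAC_MIX, rng)

    age = rng.integers(6, 60, size=n).astype(float)
    sex = np.where(rng.uniform(size=n) < 0.5, "f", "m")
    lo_ref, hi_ref = world.reference.range("f")
    height = np.clip(60.0 + 1.05 * age + rng.normal(0.0, 3.0, n),
                     lo_ref + 1.0, hi_ref - 1.0)
    l, m_, s, _ = world.reference.params_vector(sex, height)
    weight = lms_inverse(whz, l, m_, s)

    survey_id = f"{stratum_id}-m{int(month):03d}"
    children = pd.DataFrame({
        "survey_id": survey_id,
        "cluster_id": [f"{survey_id}-c{c + 1:02d}" for c in cluster_idx],
        "age_months": age,
        "sex": sex,
        "weight_kg": weight,
        "height_cm": height,
        "muac_mm": muac,
        "oedema": oedema,
        "whz": np.nan,
        "true_whz": whz,
        "true_status_wfh": np.where(oedema, "SAM", status_wfh),
        "true_status_muac": np.where(oedema, "SAM", status_muac),
    })

    quality_raw = float(rng.uniform(0.05, 0.35))
    coverage = 1.0 if rng.uniform() < 0.6 else float(rng.uniform(0.6, 1.0))
    quality_rescaled = 1.0 - 2.0 * quality_raw
    meta = {
        "survey_id": survey_id,
        "stratum_id": stratum_id,
        "month": int(month),
        "design": "cluster",
        "quality_score_raw": quality_raw,
        "quality_rescaled": quality_rescaled,
        "sampling_coverage": coverage,
        "analysis_weight": quality_rescaled * coverage,
    }
    return children, meta


def generate_all_surveys(world: SyntheticWorld,
                         config: GeneratorConfig | None = None):
    """Generate every scheduled survey; returns (children, meta) DataFrames."""
    frames, metas = [], []
    for sid, month in world.survey_schedule:
        ch, meta = generate_survey(world, sid, month, config)
        frames.append(ch)
        metas.append(meta)
    children = pd.concat(frames, ignore_index=True)
    meta = pd.DataFrame(metas)
    return children, meta
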