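"""Configuration objects for the simulator and the end-to-end pipeline.

Both configs round-trip through YAML so that a whole run is reproducible
from a single file plus a seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .exceptions import ConfigError

LIVELIHOODS = ("agriculturalist", "agropastoral", "pastoralist", "displaced", "urban")

#: default logit-scale intercepts per binary outcome; chosen so the null
#: model reproduces prevalence levels typical of crisis-affected settings
#: (GAM by weight-for-height ~15%, SAM ~3%, MUAC-based outcomes rarer).
DEFAULT_INTERCEPTS = {
    "gam_wfh": float(np.log(0.15 / 0.85)),
    "sam_wfh": float(np.log(0.03 / 0.97)),
    "gam_muac": float(np.log(0.08 / 0.92)),
    "sam_muac": float(np.log(0.012 / 0.988)),
}

#: default logit-scale effect sizes on standardised lagged predictors
DEFAULT_EFFECTS = {
    "conflict_death_rate": 0.30,
    "measles_rate": 0.25,
    "rainfall": -0.20,
    "ndvi": -0.25,
    "water_price": 0.30,
    "terms_of_trade": -0.20,
    "displaced_prop": 0.10,
    "humanitarian_presence": -0.10,
}

#: livelihood contrasts on the logit scale (reference: agriculturalist);
#: pastoralist and displaced strata fare better, mirroring field patterns.
DEFAULT_LIVELIHOOD_EFFECTS = {
    "agropastoral": -0.05,
    "pastoralist": -0.20,
    "displaced": -0.30,
    "urban": -0.15,
}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic world.

    Sizes default to a scaled-down crisis setting: a monthly calendar over
    three years, SMART-style surveys of 30 clusters x 20 children, and ground
    surveys covering 30% of stratum-months (sparse coverage as in settings
    where less than a third of districts are ever surveyed). The intra-cluster
    correlation and missingness defaults are placeholders for quantities the
    source datasets do not report; both are exposed here.
    """

    n_strata: int = 12
    n_months: int = 36
    clusters_per_survey: int = 30
    children_per_cluster: int = 20
    icc: float = 0.05
    missingness_block_rate: float = 0.10
    missingness_persistence: float = 0.8
    predictor_rho: float = 0.70
    survey_fraction: float = 0.30
    survey_schedule: list | None = None
    oedema_prevalence: float = 0.005
    intercepts: dict = field(default_factory=lambda: dict(DEFAULT_INTERCEPTS))
    effects: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    livelihood_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_LIVELIHOOD_EFFECTS))
    lead_months: int = 6
    seed: int = 0

    def __post_init__(self):
        if self.n_strata < 1 or self.n_months < 1:
            raise ConfigError("n_strata and n_months must be positive")
        if self.children_per_cluster < 1 or self.clusters_per_survey < 1:
            raise ConfigError("cluster sizes must be >= 1")
        if not (0.0 <= self.icc < 1.0):
            raise ConfigError("icc must lie in [0, 1)")
        if not (0.0 <= self.missingness_block_rate < 1.0):
            raise ConfigError("missingness_block_rate must lie in [0, 1)")
        if not (0.0 <= self.predictor_rho < 1.0):
            raise ConfigError("predictor autocorrelation must lie in [0, 1)")
        if not (0.0 < self.survey_fraction <= 1.0):
            raise ConfigError("survey_fraction must lie in (0, 1]")
        if not (0.0 <= self.oedema_prevalence < 1.0):
            raise ConfigError("oedema_prevalence must lie in [0, 1)")
        if self.lead_months < 0:
            raise ConfigError("lead_months must be >= 0")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if raw.get("survey_schedule"):
            raw["survey_schedule"] = [tuple(x) for x in raw["survey_schedule"]]
        return cls(**raw)


@dataclass
class PipelineConfig:
    """Settings for the model-fitting / evaluation stages of ``run_all``."""

    outcomes: tuple = ("sam_wfh", "gam_wfh")
    train_fraction: float = 0.70
    shortlist_fraction: float = 0.10
    max_terms: int | None = None
    enumeration_cap: int = 4096
    candidate_lags: tuple = ((1, 3), (2, 4), (4, 6), (1, 6))
    n_breakpoint_levels: int = 4
    n_draws: int = 2000
    forecast_offset: int = 0
    rf_n_trees: int = 1000
    rf_min_node: int = 5
    rf_loocv: bool = False
    glm_loocv: bool = True
    spline_lam: float = 5.0
    mice_iterations: int = 10

    def __post_init__(self):
        if not (0.0 < self.train_fraction < 1.0):
            raise ConfigError("train_fraction must lie in (0, 1)")
        if not (0.0 < self.shortlist_fraction <= 1.0):
            raise ConfigError("shortlist_fraction must lie in (0, 1]")
        if self.forecast_offset < 0:
            raise ConfigError("forecast_offset must be >= 0")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("outcomes",):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if "candidate_lags" in raw and raw["candidate_lags"] is not None:
            raw["candidate_lags"] = tuple(tuple(x) for x in raw["candidate_lags"])
        return cls(**raw)
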