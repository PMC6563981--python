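"""Synthetic data generator for the explanatory Rasch analysis.

Emulates the study conditions the package is designed for: a clinical
sample of illicit drug users (~573 persons, ~70% male, ~71% drinkers)
responding to 11 dichotomous substance-use-disorder criteria. The
generating model is the same latent-regression Rasch model the estimator
assumes:

    theta_j = sum_p J_p * Z_pj + e_j,           e_j ~ N(0, residual_sd^2)
    logit P(Y_ij = 1) = theta_j - (beta_i + dif shift_ij)

where beta_i are item severities and a DIF entry (item, covariate) -> d
shifts that item's severity by d * Z_cov for matching persons (positive d
= harder for the indicator-1 / higher-score group). The logistic residual
of the GLMM formulation (variance pi^2/3) is realised implicitly by
Bernoulli sampling through the logit link, not sampled as a parameter.

Defaults are the fitted values reported for that clinical sample (item
severities, latent-regression effects including the gender x alcohol
interaction, and the uniform DIF map); all are overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .items import (
    COVARIATES,
    ITEMS,
    PERSONALITY_COVARIATES,
    CovariateTable,
    ResponseTable,
)

#: Default item severities (logit units): the Rasch estimates for the
#: reference clinical sample. All negative: most participants sit high on
#: the disorder continuum, so every criterion is "easy" to endorse.
DEFAULT_SEVERITIES: dict[str, float] = {
    "Larger": -1.18,
    "Cut down": -2.05,
    "Time spent": -1.72,
    "Craving": -0.99,
    "Major role": -2.11,
    "Social": -2.42,
    "Give up": -2.58,
    "Hazard": -1.46,
    "Consistent use": -2.49,
    "Tolerance": -1.67,
    "Withdrawal": -1.69,
}

#: Default latent-regression effects (logit units per unit covariate;
#: personality per SD). Interaction terms use "a:b" naming.
DEFAULT_FIXED_EFFECTS: dict[str, float] = {
    "gender_female": -0.42,
    "alcohol_no": -0.76,
    "gender_female:alcohol_no": 0.92,
    "hopelessness": 0.17,
    "impulsivity": 0.23,
    "sensation_seeking": 0.55,
    "anxiety_sensitivity": 0.06,
}

#: Default uniform DIF, on the *severity* scale (positive = the criterion is
#: harder to endorse for the indicator-1 group / per SD of the score). These
#: are the negated item-by-covariate interaction effects of the reference
#: analysis, whose sign convention is easiness for the indicator-1 group.
DEFAULT_DIF_SEVERITY_SHIFTS: dict[tuple[str, str], float] = {
    ("Craving", "gender_female"): 0.73,
    ("Give up", "gender_female"): -1.00,
    ("Hazard", "gender_female"): 0.74,
    ("Consistent use", "gender_female"): -1.01,
    ("Tolerance", "gender_female"): 1.09,
    ("Withdrawal", "gender_female"): 1.23,
    ("Social", "alcohol_no"): 1.65,
    ("Give up", "alcohol_no"): 0.73,
    ("Social", "impulsivity"): 0.89,
    ("Give up", "sensation_seeking"): 0.62,
    ("Tolerance", "sensation_seeking"): -0.52,
}


def _identity4() -> np.ndarray:
    return np.eye(len(PERSONALITY_COVARIATES))


@dataclass
class GenerationConfig:
    """Generating truths for one synthetic dataset.

    residual_sd defaults to 1.50, the residual person SD reported once the
    default covariate effects are in the model; with all fixed effects zero
    the corresponding covariate-free spread is 1.60.
    """

    n_persons: int = 573
    severities: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SEVERITIES))
    fixed_effects: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_FIXED_EFFECTS))
    residual_sd: float = 1.50
    dif_severity_shifts: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_DIF_SEVERITY_SHIFTS)
    )
    p_female: float = 0.30
    p_alcohol_no: float = 0.29
    personality_corr: np.ndarray = field(default_factory=_identity4)
    missing_covariate_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_persons < 0:
            raise ValueError("n_persons must be >= 0")
        missing = [it for it in ITEMS if it not in self.severities]
        if missing:
            raise ValueError(f"severities missing for item(s): {missing}")
        if not all(np.isfinite(list(self.severities.values()))):
            raise ValueError("severities must be finite")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        for p, name in ((self.p_female, "p_female"), (self.p_alcohol_no, "p_alcohol_no"),
                        (self.missing_covariate_rate, "missing_covariate_rate")):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        corr = np.asarray(self.personality_corr, dtype=float)
        k = len(PERSONALITY_COVARIATES)
        if corr.shape != (k, k) or not np.allclose(corr, corr.T):
            raise ValueError("personality_corr must be a symmetric 4x4 matrix")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError("personality_corr must have unit diagonal")
        if np.linalg.eigvalsh(corr)[0] <= 1e-10:
            raise ValueError("personality_corr must be positive-definite")
        for (item, cov) in self.dif_severity_shifts:
            if item not in ITEMS:
                raise ValueError(f"DIF map references unknown item {item!r}")
            if cov not in COVARIATES:
                raise ValueError(f"DIF map references unknown covariate {cov!r}")
        self.personality_corr = corr

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_persons": self.n_persons,
            "severities": dict(self.severities),
            "fixed_effects": dict(self.fixed_effects),
            "residual_sd": self.residual_sd,
            "dif_severity_shifts": {f"{i}:{c}": v for (i, c), v in self.dif_severity_shifts.items()},
            "p_female": self.p_female,
            "p_alcohol_no": self.p_alcohol_no,
            "personality_corr": np.asarray(self.personality_corr).tolist(),
            "missing_covariate_rate": self.missing_covariate_rate,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GenerationConfig":
        d = dict(d)
        dif = {}
        for key, v in d.pop("dif_severity_shifts", {}).items():
            item, cov = key.rsplit(":", 1)
            dif[(item, cov)] = float(v)
        corr = np.asarray(d.pop("personality_corr", _identity4()), dtype=float)
        return cls(dif_severity_shifts=dif, personality_corr=corr, **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GenerationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def with_(self, **kwargs) -> "GenerationConfig":
        return replace(self, **kwargs)


@dataclass
class SimulatedDataset:
    responses: ResponseTable
    covariates: CovariateTable
    theta_true: pd.Series  # indexed by person_id
    config: GenerationConfig


def null_config(**overrides) -> GenerationConfig:
    """Covariate-free generating conditions: no latent-regression effects,
    no DIF, person SD 1.60 (the covariate-free spread of the reference
    sample)."""
    base = dict(fixed_effects={}, dif_severity_shifts={}, residual_sd=1.60)
    base.update(overrides)
    return GenerationConfig(**base)


# ---------------------------------------------------------------------------


def generate_covariates(
    config: GenerationConfig,
    rng: np.random.Generator | None = None,
    apply_missingness: bool = True,
) -> CovariateTable:
    """Draw gender/alcohol indicators and standardised personality scores.

    Personality scores are multivariate normal with the configured
    correlation matrix, then sample-standardised (mean 0, SD 1, ddof=1).
    Missingness (when requested) is person-wise: a person is flagged with
    probability ``missing_covariate_rate`` and one uniformly chosen
    covariate field is blanked.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_persons
    person_id = [f"p{i:05d}" for i in range(n)]
    gender = rng.binomial(1, config.p_female, size=n)
    alcohol = rng.binomial(1, config.p_alcohol_no, size=n)
    k = len(PERSONALITY_COVARIATES)
    chol = np.linalg.cholesky(np.asarray(config.personality_corr, dtype=float))
    pers = rng.standard_normal(size=(n, k)) @ chol.T
    if n >= 2:
        pers = (pers - pers.mean(axis=0)) / pers.std(axis=0, ddof=1)
    df = pd.DataFrame({"person_id": person_id, "gender_female": gender, "alcohol_no": alcohol})
    for j, name in enumerate(PERSONALITY_COVARIATES):
        df[name] = pers[:, j] if n else np.array([], dtype=float)
    if apply_missingness and config.missing_covariate_rate > 0 and n > 0:
        flagged = rng.random(n) < config.missing_covariate_rate
        which = rng.integers(0, len(COVARIATES), size=n)
        for i in np.flatnonzero(flagged):
            df.loc[i, COVARIATES[which[i]]] = np.nan
    return CovariateTable(df)


def _term_values(term: str, cov: pd.DataFrame) -> np.ndarray:
    """Evaluate a fixed-effect term name ('cov' or 'a:b' product) on rows."""
    out = np.ones(len(cov))
    for part in term.split(":"):
        if part not in cov.columns:
            raise ValueError(f"fixed-effect term {term!r} references unknown covariate {part!r}")
        vals = cov[part].to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError(f"fixed-effect term {term!r} has missing covariate values")
        out = out * vals
    return out


def generate_theta(
    covariates: CovariateTable,
    config: GenerationConfig,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Latent disorder level: fixed covariate effects plus normal residual."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cov = covariates.data
    theta = np.zeros(len(cov))
    for term, effect in config.fixed_effects.items():
        theta = theta + effect * _term_values(term, cov)
    theta = theta + config.residual_sd * rng.standard_normal(len(cov))
    return pd.Series(theta, index=pd.Index(cov["person_id"], name="person_id"), name="theta_true")


def generate_responses(
    theta_true: pd.Series,
    covariates: CovariateTable,
    config: GenerationConfig,
    rng: np.random.Generator | None = None,
) -> ResponseTable:
    """Bernoulli endorsements: logit = theta_j - (beta_i + DIF shift_ij)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cov = covariates.data
    n = len(cov)
    sev = np.array([config.severities[it] for it in ITEMS])
    shift = np.zeros((n, len(ITEMS)))
    for (item, covname), d in config.dif_severity_shifts.items():
        vals = cov[covname].to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError(f"DIF covariate {covname!r} has missing values")
        shift[:, ITEMS.index(item)] += d * vals
    logit = theta_true.to_numpy()[:, None] - (sev[None, :] + shift)
    with np.errstate(over="ignore"):
        prob = 1.0 / (1.0 + np.exp(-logit))
    y = (rng.random((n, len(ITEMS))) < prob).astype(np.int8)
    wide = pd.DataFrame(y, columns=list(ITEMS))
    wide.insert(0, "person_id", cov["person_id"].to_numpy())
    return ResponseTable.from_wide(wide)


def simulate_dataset(config: GenerationConfig, seed: int | None = None) -> SimulatedDataset:
    """Compose covariates -> theta -> responses; bit-reproducible from seed.

    Covariate missingness is applied *after* theta and responses are drawn,
    so the latent side always uses the complete underlying values (the mask
    is missing-completely-at-random).
    """
    if seed is not None:
        config = config.with_(seed=seed)
    rng = np.random.default_rng(config.seed)
    covariates = generate_covariates(config, rng, apply_missingness=False)
    if config.n_persons == 0:
        empty = ResponseTable(pd.DataFrame(columns=["person_id", "item_id", "response"]))
        return SimulatedDataset(empty, covariates, pd.Series(dtype=float), config)
    theta = generate_theta(covariates, config, rng)
    responses = generate_responses(theta, covariates, config, rng)
    if config.missing_covariate_rate > 0:
        n = config.n_persons
        df = covariates.data.copy()
        flagged = rng.random(n) < config.missing_covariate_rate
        which = rng.integers(0, len(COVARIATES), size=n)
        for i in np.flatnonzero(flagged):
            df.loc[i, COVARIATES[which[i]]] = np.nan
        covariates = CovariateTable(df)
    return SimulatedDataset(responses, covariates, theta, config)
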