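"""Explanatory item response models as random-intercept logit GLMMs.

A model is defined by a :class:`ModelSpec` term set on top of the 11 item
indicators (no global intercept): person covariates, person x person
interactions, item-property (LLTM) terms and item x person (DIF)
interactions. The linear predictor for an observed cell (j, i) is

    eta_ij = theta_j + x_ij' gamma,    theta_j ~ N(0, sigma^2),

where gamma stacks item easiness (= -severity) and covariate effects and
theta_j is the residual person effect after the covariate terms. Estimation
is marginal maximum likelihood: the random intercept is integrated out by
Gauss-Hermite quadrature and all fixed effects plus log sigma are optimised
jointly by L-BFGS with an analytic gradient. Standard errors come from the
observed information (central-difference Hessian of the marginal
log-likelihood).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import norm

from .items import ITEMS, CovariateTable, ResponseTable
from .quadrature import DEFAULT_RULE, QuadratureRule


class IdentifiabilityError(ValueError):
    """Raised when the requested term set yields a rank-deficient design."""


class ConvergenceWarning(UserWarning):
    pass


def _as_pairs(pairs) -> tuple[tuple[str, str], ...]:
    return tuple((str(a), str(b)) for a, b in pairs)


@dataclass(frozen=True)
class ModelSpec:
    """Term algebra for one explanatory model.

    ``person_terms`` are covariate main effects; ``person_interactions`` are
    covariate x covariate products; ``dif_terms`` are (item, covariate)
    uniform-DIF interactions; ``item_properties`` (optional) replaces the 11
    item indicators by an intercept plus item-property columns (LLTM).
    """

    name: str
    person_terms: tuple[str, ...] = ()
    person_interactions: tuple[tuple[str, str], ...] = ()
    dif_terms: tuple[tuple[str, str], ...] = ()
    item_properties: tuple[tuple[str, tuple[float, ...]], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "person_terms", tuple(self.person_terms))
        object.__setattr__(self, "person_interactions", _as_pairs(self.person_interactions))
        object.__setattr__(self, "dif_terms", _as_pairs(self.dif_terms))
        all_terms = self.term_names()
        if len(all_terms) != len(set(all_terms)):
            raise ValueError(f"duplicated term in spec {self.name!r}")
        for item, cov in self.dif_terms:
            if item not in ITEMS:
                raise ValueError(f"DIF term references unknown item {item!r}")

    # -- term bookkeeping ---------------------------------------------------

    @property
    def lltm(self) -> bool:
        return len(self.item_properties) > 0

    def item_columns(self) -> list[str]:
        if self.lltm:
            return ["property_intercept"] + [name for name, _ in self.item_properties]
        return list(ITEMS)

    def term_names(self) -> list[str]:
        """Non-item fixed-effect columns, in deterministic order."""
        cols = list(self.person_terms)
        cols += [f"{a}:{b}" for a, b in self.person_interactions]
        cols += [f"{item}:{cov}" for item, cov in self.dif_terms]
        return cols

    def columns(self) -> list[str]:
        return self.item_columns() + self.term_names()

    @property
    def df(self) -> int:
        """Number of estimated parameters (fixed effects + person variance)."""
        return len(self.columns()) + 1

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return (
            set(self.person_terms) <= set(other.person_terms)
            and set(self.person_interactions) <= set(other.person_interactions)
            and set(self.dif_terms) <= set(other.dif_terms)
            and self.item_properties == other.item_properties
        )

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "person_terms": list(self.person_terms),
            "person_interactions": [list(p) for p in self.person_interactions],
            "dif_terms": [list(p) for p in self.dif_terms],
            "item_properties": [[n, list(v)] for n, v in self.item_properties],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        return cls(
            name=d["name"],
            person_terms=tuple(d.get("person_terms", ())),
            person_interactions=tuple(tuple(p) for p in d.get("person_interactions", ())),
            dif_terms=tuple(tuple(p) for p in d.get("dif_terms", ())),
            item_properties=tuple((n, tuple(v)) for n, v in d.get("item_properties", ())),
        )

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def model_df(spec: ModelSpec) -> int:
    """Parameter count: item columns + covariate-side terms + 1 variance."""
    return spec.df


# ---------------------------------------------------------------------------
# Design matrix


def _covariate_column(cov: pd.DataFrame, name: str) -> np.ndarray:
    if name not in cov.columns:
        raise ValueError(f"spec references unknown covariate {name!r}")
    vals = cov[name].to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError(
            f"covariate {name!r} has missing values among modeled persons; "
            "apply filter_complete_cases first"
        )
    return vals


def build_design(
    responses: ResponseTable,
    covariates: CovariateTable | None,
    spec: ModelSpec,
) -> pd.DataFrame:
    """Long-format design: one row per observed cell, sorted by person then
    item; columns ``person_id``, ``item_id``, ``response`` plus one column
    per fixed effect in :meth:`ModelSpec.columns` order."""
    needs_cov = bool(spec.term_names())
    if needs_cov and covariates is None:
        raise ValueError(f"spec {spec.name!r} has covariate terms but no covariate table given")

    long = responses.data.copy()
    person_order = pd.Index(responses.persons)
    long["_p"] = pd.Categorical(long["person_id"], categories=person_order, ordered=True).codes
    long = long.sort_values(["_p", "item_id"], kind="stable").reset_index(drop=True)

    n_cells = len(long)
    cols: dict[str, np.ndarray] = {}
    item_codes = long["item_id"].cat.codes.to_numpy()
    if spec.lltm:
        cols["property_intercept"] = np.ones(n_cells)
        for name, values in spec.item_properties:
            v = np.asarray(values, dtype=float)
            if v.shape != (len(ITEMS),):
                raise ValueError(f"item property {name!r} must give one value per item")
            cols[name] = v[item_codes]
    else:
        for k, item in enumerate(ITEMS):
            cols[item] = (item_codes == k).astype(float)

    if needs_cov:
        cov = covariates.data.set_index("person_id").reindex(long["person_id"].to_numpy())
        for term in spec.person_terms:
            cols[term] = _covariate_column(cov, term)
        for a, b in spec.person_interactions:
            cols[f"{a}:{b}"] = _covariate_column(cov, a) * _covariate_column(cov, b)
        for item, covname in spec.dif_terms:
            cols[f"{item}:{covname}"] = _covariate_column(cov, covname) * (
                item_codes == ITEMS.index(item)
            )

    design = pd.DataFrame(cols, columns=spec.columns())
    design.insert(0, "response", long["response"].to_numpy())
    design.insert(0, "item_id", long["item_id"].to_numpy())
    design.insert(0, "person_id", long["person_id"].to_numpy())
    return design


# ---------------------------------------------------------------------------
# Marginal likelihood engine


def _person_segments(person_ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start offsets of person blocks (rows pre-sorted) + per-cell person index."""
    change = np.flatnonzero(np.r_[True, person_ids[1:] != person_ids[:-1]])
    person_of_cell = np.cumsum(np.r_[True, person_ids[1:] != person_ids[:-1]]) - 1
    return change, person_of_cell


class _MarginalLoglik:
    """Callable returning (-loglik, -gradient) over x = (gamma, log sigma)."""

    def __init__(self, y: np.ndarray, D: np.ndarray, person_ids: np.ndarray,
                 rule: QuadratureRule):
        self.y = y.astype(float)
        self.D = D
        self.starts, self.person_of_cell = _person_segments(person_ids)
        self.z = rule.nodes
        self.logw = np.log(rule.weights)
        self.sgn = 2.0 * self.y - 1.0

    def loglik_by_person(self, x: np.ndarray) -> np.ndarray:
        A = self._cell_matrix(x)
        return logsumexp(A + self.logw[None, :], axis=1)

    def _cell_matrix(self, x: np.ndarray) -> np.ndarray:
        gamma, log_sd = x[:-1], x[-1]
        sd = np.exp(log_sd)
        eta = self.D @ gamma
        S = eta[:, None] + sd * self.z[None, :]
        llc = -np.logaddexp(0.0, -self.sgn[:, None] * S)
        return np.add.reduceat(llc, self.starts, axis=0)

    def __call__(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        gamma, log_sd = x[:-1], x[-1]
        sd = np.exp(log_sd)
        eta = self.D @ gamma
        S = eta[:, None] + sd * self.z[None, :]
        llc = -np.logaddexp(0.0, -self.sgn[:, None] * S)
        A = np.add.reduceat(llc, self.starts, axis=0)
        B = A + self.logw[None, :]
        llj = logsumexp(B, axis=1)
        f = float(llj.sum())
        U = np.exp(B - llj[:, None])           # posterior node weights per person
        M = U[self.person_of_cell] * (self.y[:, None] - expit(S))
        g = np.empty(len(x))
        g[:-1] = self.D.T @ M.sum(axis=1)
        g[-1] = sd * float((M @ self.z).sum())
        return -f, -g


def marginal_loglik_engine(y, D, person_ids, params, rule) -> float:
    fn = _MarginalLoglik(y, D, person_ids, rule)
    return -fn(params)[0]


def _numerical_hessian(fun: _MarginalLoglik, x: np.ndarray) -> np.ndarray:
    """Central-difference Hessian of -loglik from the analytic gradient."""
    k = len(x)
    H = np.zeros((k, k))
    for i in range(k):
        h = 1e-4 * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        gp = fun(xp)[1]
        gm = fun(xm)[1]
        H[i] = (gp - gm) / (2 * h)
    return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# Model / Results


class EirmModel:
    """Explanatory Rasch model for a response table, covariates and spec.

    Statsmodels-flavoured: the model object holds the data and design;
    :meth:`fit` returns an :class:`EirmResults`.
    """

    def __init__(
        self,
        responses: ResponseTable,
        covariates: CovariateTable | None = None,
        spec: ModelSpec | None = None,
        quadrature: QuadratureRule | None = None,
    ):
        if responses.n_obs == 0:
            raise ValueError("empty response table")
        self.responses = responses
        self.covariates = covariates
        self.spec = spec if spec is not None else ModelSpec("null")
        self.rule = quadrature if quadrature is not None else DEFAULT_RULE
        self.design = build_design(responses, covariates, self.spec)
        self.param_names = self.spec.columns() + ["log_person_sd"]
        self._D = self.design[self.spec.columns()].to_numpy(dtype=float)
        self._y = self.design["response"].to_numpy(dtype=float)
        codes = pd.Categorical(
            self.design["person_id"], categories=pd.Index(responses.persons)
        ).codes.astype(np.int64)
        self._person_codes = codes
        self._fn = _MarginalLoglik(self._y, self._D, codes, self.rule)

    def _check_identifiable(self) -> None:
        G = self._D.T @ self._D
        scale = np.sqrt(np.clip(np.diag(G), 1e-300, None))
        corr = G / np.outer(scale, scale)
        eigmin = float(np.linalg.eigvalsh(corr)[0])
        if eigmin < 1e-8:
            raise IdentifiabilityError(
                f"design for spec {self.spec.name!r} is (near-)rank-deficient "
                f"(min scaled eigenvalue {eigmin:.2e}); a full item x covariate "
                "interaction set is collinear with that covariate's main effect"
            )
    def _check_fittable(self) -> None:
        # evaluation at fixed parameters is fine, but an all-0/all-1 item has
        # no finite easiness MLE
        if not self.spec.lltm:
            wide = self.responses.to_wide()
            for item in ITEMS:
                col = wide[item].dropna()
                if len(col) and (col.min() == col.max()):
                    raise ValueError(
                        f"item {item!r} has all-{int(col.iloc[0])} responses; "
                        "its easiness parameter is not finite"
                    )

    @classmethod
    def from_tables(cls, responses, covariates=None, spec=None, **kw) -> "EirmModel":
        return cls(responses, covariates, spec, **kw)

    def loglike(self, params: np.ndarray) -> float:
        """Marginal log-likelihood at (fixed effects..., log person_sd)."""
        return -self._fn(np.asarray(params, dtype=float))[0]

    def loglike_by_person(self, params: np.ndarray) -> np.ndarray:
        return self._fn.loglik_by_person(np.asarray(params, dtype=float))

    def _start(self) -> np.ndarray:
        x0 = np.zeros(len(self.param_names))
        if not self.spec.lltm:
            wide = self.responses.to_wide()
            for k, item in enumerate(ITEMS):
                p = float(np.clip(wide[item].mean(), 0.05, 0.95))
                x0[k] = np.log(p / (1 - p))
        return x0  # log sigma starts at 0 (sd = 1)

    def fit(
        self,
        start_params: np.ndarray | None = None,
        tol: float = 1e-7,
        max_iter: int = 500,
        compute_se: bool = True,
    ) -> "EirmResults":
        self._check_identifiable()
        self._check_fittable()
        x0 = np.asarray(start_params, dtype=float) if start_params is not None else self._start()
        res = minimize(
            self._fn, x0, jac=True, method="L-BFGS-B",
            options={"maxiter": max_iter, "maxfun": 4 * max_iter,
                     "ftol": 1e-13, "gtol": tol},
        )
        grad_inf = float(np.max(np.abs(res.jac)))
        converged = bool(res.success or grad_inf < 1e-3)
        if not converged:
            warnings.warn(
                f"MML optimisation did not converge for spec {self.spec.name!r}: "
                f"{res.message} (|grad|_inf = {grad_inf:.2e})",
                ConvergenceWarning,
            )
        cov_params = None
        if compute_se:
            H = _numerical_hessian(self._fn, res.x)
            try:
                cov_params = np.linalg.inv(H)
            except np.linalg.LinAlgError:
                warnings.warn("singular observed information; SEs unavailable", ConvergenceWarning)
        return EirmResults(self, res.x, -float(res.fun), converged, int(res.nit), cov_params)


class EirmResults:
    """Fitted explanatory model: estimates, uncertainty, fit statistics."""

    def __init__(self, model: EirmModel, params_internal, llf, converged, n_iter, cov_params):
        self.model = model
        self.spec = model.spec
        self._x = np.asarray(params_internal, dtype=float)
        self.llf = float(llf)
        self.converged = converged
        self.n_iter = n_iter
        self._cov = cov_params
        names = model.spec.columns()
        self.params = pd.Series(self._x[:-1], index=names, name="estimate")
        self.person_sd = float(np.exp(self._x[-1]))
        self.person_var = self.person_sd ** 2
        if cov_params is not None:
            se = np.sqrt(np.clip(np.diag(cov_params), 0, None))
            self.bse = pd.Series(se[:-1], index=names, name="se")
            # delta method: sd = exp(log_sd)
            self.person_sd_se = float(self.person_sd * se[-1])
        else:
            self.bse = pd.Series(np.nan, index=names, name="se")
            self.person_sd_se = np.nan

    # -- fit statistics -----------------------------------------------------

    @property
    def n_params(self) -> int:
        return len(self.params) + 1

    @property
    def df_model(self) -> int:
        return self.n_params

    @property
    def deviance(self) -> float:
        return -2.0 * self.llf

    @property
    def nobs(self) -> int:
        """Observed response cells (the BIC sample size)."""
        return self.model.responses.n_obs

    @property
    def aic(self) -> float:
        return self.deviance + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return self.deviance + np.log(self.nobs) * self.n_params

    # -- inference ----------------------------------------------------------

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2.0 * norm.sf(np.abs(self.zvalues)), index=self.params.index)

    @property
    def easiness(self) -> pd.Series:
        idx = [c for c in self.params.index if c in ITEMS]
        return self.params.loc[idx]

    @property
    def severity(self) -> pd.Series:
        """Item severities (sign-flipped easiness), canonical item order."""
        return (-self.easiness).rename("severity")

    def covariate_effects(self) -> pd.Series:
        idx = [c for c in self.params.index if c not in ITEMS]
        return self.params.loc[idx]

    def wald_table(self, terms: Sequence[str] | None = None) -> pd.DataFrame:
        """Estimate, SE, Wald z, two-sided p and star coding per term.

        Stars: ``***`` p < .001, ``**`` p < .01, ``*`` p < .05; a p equal to
        a boundary is not starred at that level.
        """
        if terms is None:
            terms = list(self.params.index)
        est, se = self.params.loc[terms], self.bse.loc[terms]
        z = est / se
        p = pd.Series(2.0 * norm.sf(np.abs(z)), index=est.index)
        out = pd.DataFrame({"estimate": est, "se": se, "z": z, "p": p})
        out["stars"] = [stars(v) for v in out["p"]]
        out["label"] = [
            f"{e:.2f}{s}({sd:.2f})" for e, s, sd in zip(out["estimate"], out["stars"], out["se"])
        ]
        return out

    def summary(self) -> str:
        lines = [
            f"Explanatory Rasch model: spec {self.spec.name!r}",
            f"  persons: {self.model.responses.n_persons}   observed cells: {self.nobs}",
            f"  log-likelihood: {self.llf:.1f}   deviance: {self.deviance:.1f}",
            f"  params: {self.n_params}   AIC: {self.aic:.1f}   BIC: {self.bic:.1f}",
            f"  person variance (SD): {self.person_var:.2f} ({self.person_sd:.2f})",
            f"  converged: {self.converged} in {self.n_iter} iterations",
            "",
            self.wald_table().to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<EirmResults spec={self.spec.name!r} llf={self.llf:.2f} "
                f"k={self.n_params} converged={self.converged}>")

    # -- person scoring -----------------------------------------------------

    def eap_scores(self) -> pd.DataFrame:
        """Posterior mean and SD of the residual person effect theta_j.

        Persons with no observed responses get the prior (0, person_sd).
        """
        m = self.model
        A = m._fn._cell_matrix(self._x)
        B = A + m._fn.logw[None, :]
        llj = logsumexp(B, axis=1)
        U = np.exp(B - llj[:, None])
        theta_nodes = self.person_sd * m.rule.nodes
        eap = U @ theta_nodes
        psd = np.sqrt(np.clip(U @ theta_nodes**2 - eap**2, 0, None))
        # segments follow person blocks actually present in the design
        present = pd.unique(m.design["person_id"])
        out = pd.DataFrame({"eap": eap, "psd": psd}, index=pd.Index(present, name="person_id"))
        out = out.reindex(m.responses.persons)
        out["eap"] = out["eap"].fillna(0.0)
        out["psd"] = out["psd"].fillna(self.person_sd)
        return out


def stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
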