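"""Dichotomous Rasch model with a normal latent trait, fitted by MML.

The measurement model: person j endorses criterion i with probability

    P(Y_ij = 1) = logistic(theta_j - beta_i),   theta_j ~ N(0, sigma^2),

beta_i the criterion severity (the latent level at which endorsement
probability is 0.5). Internally items carry *easiness* fixed effects
(easiness = -severity); severities are reported with the conventional sign.
This module is the covariate-free special case of :mod:`explirt.eirm` plus
EAP scoring helpers, item characteristic curves and marginal prevalence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .eirm import EirmModel, EirmResults, ModelSpec
from .items import ITEMS, ResponseTable
from .quadrature import DEFAULT_RULE, QuadratureRule


def logistic(x):
    """Stable logistic function 1 / (1 + exp(-x))."""
    return expit(np.asarray(x, dtype=float))


def marginal_loglik(
    responses: ResponseTable,
    easiness: np.ndarray | pd.Series,
    person_sd: float,
    rule: QuadratureRule | None = None,
) -> float:
    """Marginal log-likelihood of a covariate-free Rasch model.

    ``easiness`` is ordered as :data:`explirt.items.ITEMS` (or a Series
    indexed by item id). The person effect is integrated against
    N(0, person_sd^2) using ``rule``.
    """
    if responses.n_obs == 0:
        raise ValueError("empty response table")
    if person_sd <= 0:
        raise ValueError("person_sd must be > 0")
    rule = rule if rule is not None else DEFAULT_RULE
    if isinstance(easiness, pd.Series):
        easiness = easiness.reindex(list(ITEMS)).to_numpy()
    easiness = np.asarray(easiness, dtype=float)
    model = EirmModel(responses, spec=ModelSpec("null"), quadrature=rule)
    params = np.r_[easiness, np.log(person_sd)]
    return model.loglike(params)


def marginal_prevalence(
    easiness: float, person_sd: float, rule: QuadratureRule | None = None
) -> float:
    """Population endorsement rate: integral of logistic(theta + easiness)
    over theta ~ N(0, person_sd^2). Collapses to logistic(easiness) at
    person_sd = 0."""
    if person_sd < 0:
        raise ValueError("person_sd must be >= 0")
    if person_sd == 0:
        return float(expit(easiness))
    rule = rule if rule is not None else DEFAULT_RULE
    return float(rule.weights @ expit(easiness + person_sd * rule.nodes))


class RaschModel(EirmModel):
    """Covariate-free Rasch measurement model (11 easiness + 1 variance)."""

    def __init__(self, responses: ResponseTable, quadrature: QuadratureRule | None = None):
        super().__init__(responses, covariates=None, spec=ModelSpec("null"),
                         quadrature=quadrature)

    def fit(self, **kw) -> "RaschResults":
        res = super().fit(**kw)
        return RaschResults(self, res._x, res.llf, res.converged, res.n_iter, res._cov)


class RaschResults(EirmResults):
    """Rasch fit: severities, person variance, EAP scoring, ICCs."""

    def implied_prevalence(self, kind: str = "marginal") -> pd.Series:
        """Model-implied endorsement rate per item.

        ``kind="marginal"``: prior integral of the ICC over N(0, sigma^2) —
        the population rate the fitted model predicts. ``kind="posterior"``:
        sample average of each person's posterior-expected endorsement
        probability; the MML score equations make this *exactly* equal to
        the observed rate at the optimum, while the marginal rate matches
        only up to a O(1/sqrt(n)) finite-sample gap.
        """
        if kind == "marginal":
            vals = [
                marginal_prevalence(self.easiness[it], self.person_sd, self.model.rule)
                for it in ITEMS
            ]
            return pd.Series(vals, index=list(ITEMS), name="implied_prevalence")
        if kind != "posterior":
            raise ValueError("kind must be 'marginal' or 'posterior'")
        from scipy.special import logsumexp

        fn = self.model._fn
        A = fn._cell_matrix(self._x)
        B = A + fn.logw[None, :]
        U = np.exp(B - logsumexp(B, axis=1)[:, None])
        e = self.easiness.reindex(list(ITEMS)).to_numpy()
        P = expit(e[None, None, :] + self.person_sd * self.model.rule.nodes[None, :, None])
        vals = (U[:, :, None] * P).sum(axis=1).mean(axis=0)
        return pd.Series(vals, index=list(ITEMS), name="implied_prevalence")

    def icc_curve(self, item: str, grid: np.ndarray, dif_shift: float = 0.0) -> np.ndarray:
        return icc_curve(self, item, grid, dif_shift)


def eap_scores(responses: ResponseTable, fit: EirmResults,
               rule: QuadratureRule | None = None) -> pd.DataFrame:
    """EAP (posterior mean) and posterior SD of theta per person.

    Convenience wrapper around ``fit.eap_scores()`` that re-scores an
    arbitrary response table under the fitted item parameters.
    """
    if responses is fit.model.responses:
        return fit.eap_scores()
    model = EirmModel(responses, spec=ModelSpec("null"),
                      quadrature=rule or fit.model.rule)
    refit = EirmResults(model, fit._x, np.nan, fit.converged, 0, None)
    return refit.eap_scores()


def icc_curve(fit: EirmResults, item: str, grid: np.ndarray,
              dif_shift: float = 0.0) -> np.ndarray:
    """Item characteristic curve P(endorse | theta) over a theta grid.

    ``dif_shift`` adds a uniform severity shift (positive = harder), for
    plotting the focal group's curve next to the reference curve.
    """
    if item not in ITEMS:
        raise KeyError(f"unknown item {item!r}")
    severity = float(fit.severity[item]) + dif_shift
    return expit(np.asarray(grid, dtype=float) - severity)
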