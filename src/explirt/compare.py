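"""Nested model comparison and uniform-DIF scanning.

Likelihood-ratio tests compare nested explanatory models; AIC/BIC use the
number of *observed response cells* as the BIC sample size (persons x items
minus missing), the convention under which deviance, df and the criteria
stay mutually consistent for this model family. The DIF scan tests one
item x covariate interaction at a time against a base model, all other
items serving as anchors; this avoids the exact collinearity of a full
interaction set with the covariate's main effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .eirm import (
    ConvergenceWarning,
    EirmModel,
    EirmResults,
    IdentifiabilityError,
    ModelSpec,
    stars,
)
from .items import COVARIATES, ITEMS, CovariateTable, ResponseTable
from .quadrature import QuadratureRule
from .specs import LADDER


def aic(deviance: float, n_params: int) -> float:
    """Akaike information criterion from deviance (-2 loglik)."""
    if n_params < 1:
        warnings.warn("n_params < 1; AIC equals the deviance")
    return deviance + 2.0 * n_params


def bic(deviance: float, n_params: int, n_obs: int) -> float:
    """Bayesian information criterion; n_obs = observed response cells."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    if n_params < 1:
        warnings.warn("n_params < 1; BIC equals the deviance")
    return deviance + np.log(n_obs) * n_params


def lr_test(fit_small: EirmResults, fit_large: EirmResults) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested fits: (statistic, delta df, p)."""
    if not fit_small.spec.is_nested_in(fit_large.spec):
        raise ValueError(
            f"spec {fit_small.spec.name!r} is not nested in {fit_large.spec.name!r}"
        )
    delta_df = fit_large.n_params - fit_small.n_params
    if delta_df <= 0:
        raise ValueError("larger model must add at least one parameter")
    stat = fit_small.deviance - fit_large.deviance
    if stat < -1e-6:
        warnings.warn(
            f"negative LR statistic ({stat:.3g}): the larger model "
            f"{fit_large.spec.name!r} reached a lower likelihood; check convergence",
            ConvergenceWarning,
        )
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, delta_df))
    return float(stat), int(delta_df), p


@dataclass
class Comparison:
    smaller: str
    larger: str
    lr_stat: float
    delta_df: int
    p: float


@dataclass
class LadderResult:
    """All ladder fits plus the planned pairwise LR comparisons."""

    fits: dict[str, EirmResults]
    comparisons: list[Comparison]

    def table(self) -> pd.DataFrame:
        """Report table: one column per model; estimate(SE) rows with stars,
        person-variance row as 'var(sd)', then AIC/BIC/deviance/df and the
        LR rows."""
        names = list(self.fits)
        terms: list[str] = []
        for f in self.fits.values():
            for t in f.covariate_effects().index:
                if t not in terms:
                    terms.append(t)
        comp_by_larger = {c.larger: c for c in self.comparisons}
        rows: dict[str, list] = {"person_var": []}
        for t in terms:
            rows[t] = []
        for stat in ("AIC", "BIC", "deviance", "df", "lr_delta_df", "lr_stat"):
            rows[stat] = []
        for name in names:
            f = self.fits[name]
            rows["person_var"].append(f"{f.person_var:.2f}({f.person_sd:.2f})")
            wt = f.wald_table(list(f.covariate_effects().index))
            for t in terms:
                rows[t].append(wt.loc[t, "label"] if t in wt.index else "")
            rows["AIC"].append(f"{f.aic:.1f}")
            rows["BIC"].append(f"{f.bic:.1f}")
            rows["deviance"].append(f"{f.deviance:.1f}")
            rows["df"].append(str(f.n_params))
            c = comp_by_larger.get(name)
            rows["lr_delta_df"].append(str(c.delta_df) if c else "")
            rows["lr_stat"].append(f"{c.lr_stat:.2f}{stars(c.p)}" if c else "")
        return pd.DataFrame(rows, index=names).T

    def to_dict(self) -> dict:
        return {
            "models": {
                name: {
                    "estimates": f.params.to_dict(),
                    "se": f.bse.to_dict(),
                    "person_var": f.person_var,
                    "person_sd": f.person_sd,
                    "loglik": f.llf,
                    "deviance": f.deviance,
                    "df": f.n_params,
                    "aic": f.aic,
                    "bic": f.bic,
                    "converged": f.converged,
                }
                for name, f in self.fits.items()
            },
            "comparisons": [c.__dict__ for c in self.comparisons],
        }


def comparison_plan(specs: Sequence[ModelSpec]) -> list[tuple[str, str]]:
    """Pair each spec with the most recent earlier spec nested in it."""
    plan = []
    for i, spec in enumerate(specs[1:], start=1):
        smaller = None
        for prev in reversed(specs[:i]):
            if prev.is_nested_in(spec) and prev.df < spec.df:
                smaller = prev
                break
        if smaller is None:
            raise ValueError(
                f"spec {spec.name!r} has no earlier nested spec to compare against"
            )
        plan.append((smaller.name, spec.name))
    return plan


def run_ladder(
    responses: ResponseTable,
    covariates: CovariateTable | None,
    specs: Sequence[ModelSpec] | None = None,
    rule: QuadratureRule | None = None,
    compute_se: bool = True,
) -> LadderResult:
    """Fit an ordered nested ladder and run the planned LR tests.

    A non-convergent fit aborts the ladder; fits completed so far are
    attached to the raised error as ``partial``.
    """
    specs = list(specs) if specs is not None else list(LADDER)
    plan = comparison_plan(specs)
    fits: dict[str, EirmResults] = {}
    for spec in specs:
        f = EirmModel(responses, covariates, spec, quadrature=rule).fit(compute_se=compute_se)
        if not f.converged:
            err = RuntimeError(f"fit for spec {spec.name!r} did not converge")
            err.partial = fits  # type: ignore[attr-defined]
            raise err
        fits[spec.name] = f
    comparisons = [
        Comparison(sm, lg, *lr_test(fits[sm], fits[lg])) for sm, lg in plan
    ]
    return LadderResult(fits, comparisons)


# ---------------------------------------------------------------------------
# DIF


@dataclass
class DifResult:
    """One-at-a-time uniform DIF scan results.

    ``records``: one row per (item, covariate) with the interaction
    estimate (positive = easier endorsement for the indicator-1 / higher-
    score group), its SE, Wald z, p, and a flag at ``alpha`` (after the
    requested correction).
    """

    records: pd.DataFrame
    alpha: float
    correction: str
    base_spec: str
    anchor: str = "all-other-items"

    def flagged(self) -> pd.DataFrame:
        return self.records[self.records["flag"]].reset_index(drop=True)

    def table(self) -> pd.DataFrame:
        """Items x covariates table of flagged effects, 'est*** (se)' style."""
        items = [i for i in ITEMS if i in set(self.records["item_id"])]
        covs = list(dict.fromkeys(self.records["covariate"]))
        out = pd.DataFrame("", index=items, columns=covs)
        for _, r in self.records.iterrows():
            if r["flag"]:
                out.loc[r["item_id"], r["covariate"]] = (
                    f"{r['estimate']:.2f}{stars(r['p'])} ({r['se']:.2f})"
                )
        out.index.name = "item_id"
        return out


def dif_scan(
    responses: ResponseTable,
    covariates: CovariateTable,
    base_spec: ModelSpec | None = None,
    scan_covariates: Sequence[str] | None = None,
    items: Sequence[str] | None = None,
    alpha: float = 0.05,
    correction: str = "none",
    rule: QuadratureRule | None = None,
) -> DifResult:
    """Scan items for uniform DIF against each covariate.

    For every (item, covariate) pair a single interaction term is added to
    the base spec (the covariate's main effect is added too if absent, so
    the interaction measures a *differential* shift, not the group's mean
    difference) and tested by a Wald z on its estimate. ``correction`` is
    ``"none"`` or ``"BH"`` (Benjamini-Hochberg within each covariate).
    """
    if base_spec is None:
        base_spec = ModelSpec("null")
    if scan_covariates is None:
        scan_covariates = [c for c in COVARIATES if c in covariates.data.columns]
    for c in scan_covariates:
        if c not in covariates.data.columns:
            raise ValueError(f"covariate {c!r} not present in covariate table")
    if correction not in ("none", "BH"):
        raise ValueError("correction must be 'none' or 'BH'")
    items = list(items) if items is not None else list(ITEMS)

    rows = []
    for cov in scan_covariates:
        person_terms = base_spec.person_terms
        if cov not in person_terms:
            person_terms = person_terms + (cov,)
        for item in items:
            spec = ModelSpec(
                name=f"{base_spec.name}+{item}:{cov}",
                person_terms=person_terms,
                person_interactions=base_spec.person_interactions,
                dif_terms=base_spec.dif_terms + ((item, cov),),
            )
            try:
                fit = EirmModel(responses, covariates, spec, quadrature=rule).fit()
                if not fit.converged:
                    raise RuntimeError("non-convergent augmented fit")
                term = f"{item}:{cov}"
                est = float(fit.params[term])
                se = float(fit.bse[term])
                z = est / se
                p = float(2.0 * stats.norm.sf(abs(z)))
                rows.append((item, cov, est, se, z, p, True))
            except (RuntimeError, IdentifiabilityError) as exc:
                warnings.warn(f"DIF test for ({item}, {cov}) untestable: {exc}")
                rows.append((item, cov, np.nan, np.nan, np.nan, np.nan, False))
    rec = pd.DataFrame(
        rows, columns=["item_id", "covariate", "estimate", "se", "z", "p", "testable"]
    )
    rec["p_adj"] = rec["p"]
    if correction == "BH":
        for cov in scan_covariates:
            mask = (rec["covariate"] == cov) & rec["testable"]
            if mask.any():
                rec.loc[mask, "p_adj"] = stats.false_discovery_control(
                    rec.loc[mask, "p"].to_numpy(), method="bh"
                )
    rec["flag"] = rec["testable"] & (rec["p_adj"] < alpha)
    return DifResult(rec, alpha=alpha, correction=correction, base_spec=base_spec.name)
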