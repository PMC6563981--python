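"""Unidimensionality and reliability descriptives for binary items.

Eigenvalues of the item phi (Pearson) correlation matrix, single-factor
loadings by principal-axis factoring, the proportion of variance carried
by the first factor, and McDonald's coefficient omega

    omega = (sum lambda)^2 / ((sum lambda)^2 + sum (1 - lambda^2)).

Two eigenvalue conventions are reported: raw correlation-matrix
eigenvalues (trace = number of items) and reduced-matrix eigenvalues with
communalities on the diagonal, which is what factor-analysis software
typically prints and why trailing values can be near zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .items import ResponseTable


@dataclass
class UnidimSummary:
    eigenvalues: np.ndarray          # raw correlation-matrix eigenvalues, descending
    reduced_eigenvalues: np.ndarray  # communality-adjusted, descending
    prop_var_first: float            # first-factor common variance / n items
    loadings: pd.Series
    omega: float

    def to_frame(self) -> pd.DataFrame:
        k = len(self.eigenvalues)
        out = pd.DataFrame({
            "eigenvalue_raw": self.eigenvalues,
            "eigenvalue_reduced": self.reduced_eigenvalues,
        })
        out["loading"] = [self.loadings.iloc[i] if i < len(self.loadings) else np.nan
                          for i in range(k)]
        out["item_id"] = [self.loadings.index[i] if i < len(self.loadings) else ""
                          for i in range(k)]
        out["omega"] = self.omega
        out["prop_var_first"] = self.prop_var_first
        return out


def _phi_correlation(responses: ResponseTable) -> pd.DataFrame:
    wide = responses.to_wide()
    keep = []
    for item in wide.columns:
        col = wide[item].dropna()
        if len(col) < 2 or col.std(ddof=1) == 0:
            warnings.warn(f"item {item!r} is constant or unobserved; excluded")
        else:
            keep.append(item)
    if len(keep) < 2:
        raise ValueError("need at least 2 items with variance")
    return wide[keep].corr()


def correlation_eigenvalues(responses: ResponseTable) -> np.ndarray:
    """Descending eigenvalues of the item phi correlation matrix."""
    R = _phi_correlation(responses).to_numpy()
    return np.sort(np.linalg.eigvalsh(R))[::-1]


def _paf(R: np.ndarray, max_iter: int = 100, tol: float = 1e-6) -> np.ndarray:
    """Iterated principal-axis factoring of a correlation matrix.

    Communalities start at squared multiple correlations and are iterated to
    convergence; returns first-factor loadings (sum oriented positive).
    """
    h2 = 1.0 - 1.0 / np.diag(np.linalg.inv(R))  # SMC start
    lam = np.zeros(len(h2))
    for _ in range(max_iter):
        Rr = R.copy()
        np.fill_diagonal(Rr, h2)
        w, V = np.linalg.eigh(Rr)
        lam_new = V[:, -1] * np.sqrt(max(w[-1], 0.0))
        if lam_new.sum() < 0:
            lam_new = -lam_new
        h2_new = np.clip(lam_new**2, 0.0, 1.0)
        done = np.max(np.abs(h2_new - h2)) < tol
        lam, h2 = lam_new, h2_new
        if done:
            break
    return lam


def one_factor_loadings(
    responses: ResponseTable, max_iter: int = 100, tol: float = 1e-6
) -> pd.Series:
    """Single-factor loadings by iterated principal-axis factoring.

    Heywood cases (|loading| > 1) are clipped with a warning. Needs >= 3
    items (two items under-identify the factor).
    """
    Rdf = _phi_correlation(responses)
    if Rdf.shape[0] < 3:
        raise ValueError("one-factor model is under-identified with fewer than 3 items")
    lam = _paf(Rdf.to_numpy(), max_iter=max_iter, tol=tol)
    if np.any(np.abs(lam) > 1):
        warnings.warn("Heywood case: loading(s) clipped to |1|")
        lam = np.clip(lam, -1.0, 1.0)
    return pd.Series(lam, index=Rdf.columns, name="loading")


def reduced_eigenvalues(responses: ResponseTable) -> np.ndarray:
    """Descending eigenvalues of the correlation matrix with converged
    principal-axis communalities on the diagonal."""
    Rdf = _phi_correlation(responses)
    lam = one_factor_loadings(responses)
    R = Rdf.to_numpy().copy()
    np.fill_diagonal(R, (lam.to_numpy() ** 2))
    return np.sort(np.linalg.eigvalsh(R))[::-1]


def coefficient_omega(loadings: pd.Series | np.ndarray) -> float:
    """McDonald's omega from standardized single-factor loadings."""
    lam = np.asarray(loadings, dtype=float)
    if lam.size == 0:
        raise ValueError("empty loadings")
    if np.any(np.abs(lam) > 1):
        raise ValueError("loadings must lie in [-1, 1]")
    s = lam.sum()
    return float(s**2 / (s**2 + np.sum(1.0 - lam**2)))


def unidim_summary(responses: ResponseTable) -> UnidimSummary:
    eig = correlation_eigenvalues(responses)
    lam = one_factor_loadings(responses)
    red = reduced_eigenvalues(responses)
    omega = coefficient_omega(lam)
    prop = float(np.sum(lam**2) / len(eig))
    return UnidimSummary(eig, red, prop, lam, omega)
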