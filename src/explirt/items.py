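"""Typed containers and I/O for binary criterion responses and person covariates.

The response side is a persons x 11-criteria binary endorsement table held in
long form (one row per *observed* cell, so missing responses simply have no
row); the covariate side is one row per person with two binary indicators
(``gender_female``, ``alcohol_no``) and four continuous personality scores.
Readers validate against the fixed, ordered criterion set and both layouts
(wide/long) round-trip losslessly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: The 11 dichotomous DSM-5 substance-use-disorder criteria, in canonical
#: report order. All tables, design matrices and severity vectors use this
#: ordering.
ITEMS: tuple[str, ...] = (
    "Larger",
    "Cut down",
    "Time spent",
    "Craving",
    "Major role",
    "Social",
    "Give up",
    "Hazard",
    "Consistent use",
    "Tolerance",
    "Withdrawal",
)

#: Binary person covariates. Coding: female = 1 (reference male),
#: non-drinker = 1 (reference drinker).
BINARY_COVARIATES: tuple[str, ...] = ("gender_female", "alcohol_no")

#: Continuous personality risk scores (z-standardised before modelling).
PERSONALITY_COVARIATES: tuple[str, ...] = (
    "hopelessness",
    "impulsivity",
    "sensation_seeking",
    "anxiety_sensitivity",
)

COVARIATES: tuple[str, ...] = BINARY_COVARIATES + PERSONALITY_COVARIATES


class ValidationError(ValueError):
    """Raised when an input table violates a container invariant."""


def _check_items(item_ids: Iterable[str]) -> None:
    unknown = sorted(set(item_ids) - set(ITEMS))
    if unknown:
        raise ValidationError(f"unknown item id(s): {unknown}; expected a subset of {list(ITEMS)}")


@dataclass
class ResponseTable:
    """Long-form binary endorsement table.

    Parameters
    ----------
    data
        DataFrame with columns ``person_id``, ``item_id``, ``response``;
        one row per observed cell, ``response`` in {0, 1}.
    persons
        Ordered index of all persons, including any whose responses are all
        missing. Defaults to first-appearance order in ``data``.
    """

    data: pd.DataFrame
    persons: pd.Index = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        df = self.data
        required = ["person_id", "item_id", "response"]
        missing_cols = [c for c in required if c not in df.columns]
        if missing_cols:
            raise ValidationError(f"response table missing column(s) {missing_cols}")
        df = df.loc[df["response"].notna(), required].copy()
        _check_items(df["item_id"].unique())
        vals = df["response"].to_numpy()
        bad = ~np.isin(vals, (0, 1, 0.0, 1.0))
        if bad.any():
            row = df.iloc[int(np.flatnonzero(bad)[0])]
            raise ValidationError(
                f"response outside {{0,1,missing}} for person {row['person_id']!r}, "
                f"item {row['item_id']!r}: {row['response']!r}"
            )
        df["response"] = df["response"].astype(np.int8)
        dup = df.duplicated(subset=["person_id", "item_id"])
        if dup.any():
            row = df.loc[dup].iloc[0]
            raise ValidationError(
                f"duplicated (person,item) pair: ({row['person_id']!r}, {row['item_id']!r})"
            )
        df["item_id"] = pd.Categorical(df["item_id"], categories=ITEMS, ordered=True)
        if self.persons is None:
            self.persons = pd.Index(pd.unique(df["person_id"]))
        else:
            self.persons = pd.Index(self.persons)
            extra = set(df["person_id"]) - set(self.persons)
            if extra:
                raise ValidationError(f"responses for persons absent from person index: {sorted(extra)[:5]}")
        self.data = df.reset_index(drop=True)

    @property
    def n_persons(self) -> int:
        return len(self.persons)

    @property
    def n_obs(self) -> int:
        """Number of observed (person, item) cells."""
        return len(self.data)

    def __len__(self) -> int:
        return self.n_obs

    @classmethod
    def from_wide(cls, wide: pd.DataFrame) -> "ResponseTable":
        """Build from a persons x items frame with a ``person_id`` column."""
        if "person_id" not in wide.columns:
            raise ValidationError("wide table must have a 'person_id' column")
        item_cols = [c for c in wide.columns if c != "person_id"]
        _check_items(item_cols)
        absent = [it for it in ITEMS if it not in item_cols]
        if absent:
            raise ValidationError(f"wide table missing criterion column(s): {absent}")
        if wide["person_id"].duplicated().any():
            dupid = wide.loc[wide["person_id"].duplicated(), "person_id"].iloc[0]
            raise ValidationError(f"duplicated person_id in wide table: {dupid!r}")
        long = wide.melt(id_vars="person_id", value_vars=list(ITEMS),
                         var_name="item_id", value_name="response")
        return cls(long, persons=pd.Index(wide["person_id"]))

    def to_wide(self) -> pd.DataFrame:
        """Persons x items frame; missing cells are NaN. Row order = person order."""
        wide = (
            self.data.pivot(index="person_id", columns="item_id", values="response")
            .reindex(index=self.persons, columns=list(ITEMS))
        )
        wide.columns.name = None
        return wide

    def restrict_persons(self, keep: Sequence) -> "ResponseTable":
        keep_idx = pd.Index(keep)
        mask = self.data["person_id"].isin(set(keep_idx))
        return ResponseTable(self.data.loc[mask].copy(),
                             persons=self.persons[self.persons.isin(set(keep_idx))])


@dataclass
class CovariateTable:
    """One row per person: binary indicators plus personality scores.

    Any field may be missing; missingness is handled by complete-case
    filtering before model fitting (see :func:`filter_complete_cases`).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if "person_id" not in df.columns:
            raise ValidationError("covariate table must have a 'person_id' column")
        if df["person_id"].duplicated().any():
            dupid = df.loc[df["person_id"].duplicated(), "person_id"].iloc[0]
            raise ValidationError(f"duplicated person_id in covariate table: {dupid!r}")
        for col in BINARY_COVARIATES:
            if col in df.columns:
                vals = df[col].dropna().to_numpy()
                if not np.isin(vals, (0, 1, 0.0, 1.0)).all():
                    raise ValidationError(f"binary covariate {col!r} has values outside {{0,1,missing}}")
        self.data = df.reset_index(drop=True)

    @property
    def persons(self) -> pd.Index:
        return pd.Index(self.data["person_id"])

    @property
    def n_persons(self) -> int:
        return len(self.data)

    def fields(self) -> list[str]:
        return [c for c in self.data.columns if c != "person_id"]


# ---------------------------------------------------------------------------
# I/O


def load_responses(path: str | Path, layout: str = "wide") -> ResponseTable:
    """Read a response CSV in ``wide`` or ``long`` layout.

    Missing responses are encoded as empty fields or ``NA``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, na_values=["NA"], dtype={"person_id": str})
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    if layout == "wide":
        return ResponseTable.from_wide(df)
    if layout == "long":
        return ResponseTable(df)
    raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")


def write_responses(responses: ResponseTable, path: str | Path, layout: str = "wide") -> None:
    path = Path(path)
    if layout == "wide":
        responses.to_wide().reset_index().to_csv(path, index=False)
    elif layout == "long":
        out = responses.data.copy()
        out["item_id"] = out["item_id"].astype(str)
        out.to_csv(path, index=False)
    else:
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")


def load_covariates(path: str | Path) -> CovariateTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, na_values=["NA"], dtype={"person_id": str})
    return CovariateTable(df)


def write_covariates(covariates: CovariateTable, path: str | Path) -> None:
    covariates.data.to_csv(Path(path), index=False)


# ---------------------------------------------------------------------------
# Filtering, descriptives, scaling


def filter_complete_cases(
    responses: ResponseTable, covariates: CovariateTable
) -> tuple[ResponseTable, CovariateTable, int]:
    """Drop persons with any missing covariate value.

    Missing *responses* are retained (the marginal likelihood sums over
    observed cells only); missing covariates force person removal. Returns
    the filtered tables and the number of persons removed.
    """
    shared = covariates.persons.intersection(responses.persons)
    if len(shared) == 0:
        raise ValidationError("response and covariate tables share no person ids")
    cov = covariates.data[covariates.data["person_id"].isin(set(shared))]
    complete = cov.dropna(subset=covariates.fields())
    n_removed = len(cov) - len(complete)
    if len(complete) == 0:
        warnings.warn("no person has complete covariates; returning empty tables")
    keep = complete["person_id"]
    return (
        responses.restrict_persons(keep),
        CovariateTable(complete.copy()),
        int(n_removed),
    )


def describe_items(responses: ResponseTable) -> pd.DataFrame:
    """Per-item endorsement mean, SD (n-1 denominator) and prevalence %.

    The ``severity`` column is left NaN; it is filled from a Rasch fit when
    assembling the descriptive report table.
    """
    if responses.n_obs == 0:
        raise ValidationError("empty response table")
    rows = []
    wide = responses.to_wide()
    for item in ITEMS:
        col = wide[item].dropna()
        if len(col) == 0:
            warnings.warn(f"item {item!r} has zero observed responses; statistics set missing")
            rows.append((item, np.nan, np.nan, np.nan, 0))
            continue
        mean = float(col.mean())
        sd = float(col.std(ddof=1)) if len(col) > 1 else 0.0
        rows.append((item, mean, sd, 100.0 * mean, int(len(col))))
    out = pd.DataFrame(rows, columns=["item_id", "mean", "sd", "prevalence_pct", "n_obs"])
    out["severity"] = np.nan
    return out


def standardize(covariates: CovariateTable, fields: Sequence[str] | None = None) -> CovariateTable:
    """Z-standardise the named continuous fields (mean 0, SD 1, ddof=1).

    Binary indicators are never rescaled. Missing values are ignored when
    computing moments and stay missing. Idempotent up to float precision.
    """
    if fields is None:
        fields = [f for f in PERSONALITY_COVARIATES if f in covariates.data.columns]
    df = covariates.data.copy()
    for f in fields:
        if f not in df.columns:
            raise ValidationError(f"unknown covariate field {f!r}")
        col = df[f].astype(float)
        sd = col.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValidationError(f"cannot standardize constant field {f!r}")
        df[f] = (col - col.mean()) / sd
    return CovariateTable(df)
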