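"""Survey tables and their dichotomization into a binary deprivation matrix.

``read_survey`` loads a respondent-level CSV (one response column per
indicator, a sampling-weight column, arbitrary covariate columns) and
validates codes against a :class:`~mdepriv.codebook.Codebook`.
``dichotomize`` applies the codebook's deprived-code rules to produce the
n-by-m 0/1 matrix ``b_ij`` together with the aligned sampling weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal

import numpy as np
import pandas as pd

from .codebook import Codebook

__all__ = [
    "SurveyDataError",
    "SurveyRecord",
    "SurveyDataset",
    "DeprivationMatrix",
    "read_survey",
    "dichotomize",
    "covariate_for_matrix",
]

logger = logging.getLogger("mdepriv")

MissingPolicy = Literal["drop", "not_deprived"]


class SurveyDataError(ValueError):
    """Raised for malformed or inconsistent survey data."""


@dataclass(frozen=True)
class SurveyRecord:
    """A single respondent: responses keyed by indicator id, weight, covariates."""

    respondent_id: str
    responses: dict[str, int | None]
    sample_weight: float
    covariates: dict[str, object]


@dataclass
class SurveyDataset:
    """Respondent-level survey table.

    ``data`` holds one row per respondent with a ``respondent_id`` column, one
    integer response column per indicator, the weight column, and any
    covariate columns. ``indicator_ids`` records which columns are responses.
    """

    data: pd.DataFrame
    indicator_ids: list[str]
    weight_column: str = "weight"

    def __post_init__(self):
        if len(self.data) < 1:
            raise SurveyDataError("no records")
        self.data = self.data.reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def covariate_columns(self) -> list[str]:
        skip = {"respondent_id", self.weight_column, *self.indicator_ids}
        return [c for c in self.data.columns if c not in skip]

    def records(self) -> Iterator[SurveyRecord]:
        for _, row in self.data.iterrows():
            responses = {
                ind: (None if pd.isna(row[ind]) else int(row[ind]))
                for ind in self.indicator_ids
            }
            yield SurveyRecord(
                respondent_id=str(row["respondent_id"]),
                responses=responses,
                sample_weight=float(row[self.weight_column]),
                covariates={c: row[c] for c in self.covariate_columns},
            )


@dataclass
class DeprivationMatrix:
    """Binary deprivation status matrix b_ij with aligned sampling weights."""

    b: np.ndarray
    sample_weights: np.ndarray
    indicator_ids: list[str]
    row_ids: list[str]

    def __post_init__(self):
        self.b = np.asarray(self.b, dtype=np.int8)
        self.sample_weights = np.asarray(self.sample_weights, dtype=float)
        if self.b.ndim != 2:
            raise SurveyDataError("deprivation matrix must be two-dimensional")
        n, m = self.b.shape
        if not np.isin(self.b, (0, 1)).all():
            raise SurveyDataError("deprivation matrix entries must be 0 or 1")
        if len(self.sample_weights) != n or len(self.row_ids) != n:
            raise SurveyDataError("weights/row ids do not match matrix rows")
        if len(self.indicator_ids) != m:
            raise SurveyDataError("indicator ids do not match matrix columns")
        if (self.sample_weights < 0).any():
            raise SurveyDataError("sampling weights must be non-negative")

    @property
    def n(self) -> int:
        return self.b.shape[0]

    @property
    def m(self) -> int:
        return self.b.shape[1]

    def select(self, mask: np.ndarray) -> "DeprivationMatrix":
        """Row subset (boolean mask or integer index array)."""
        idx = np.asarray(mask)
        return DeprivationMatrix(
            b=self.b[idx],
            sample_weights=self.sample_weights[idx],
            indicator_ids=list(self.indicator_ids),
            row_ids=[self.row_ids[i] for i in np.flatnonzero(idx)]
            if idx.dtype == bool
            else [self.row_ids[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(self.b, columns=self.indicator_ids)
        out.insert(0, "respondent_id", self.row_ids)
        out["weight"] = self.sample_weights
        return out


def read_survey(
    csv_path: str | Path,
    codebook: Codebook,
    weight_column: str = "weight",
) -> SurveyDataset:
    """Load and validate a respondent-level survey CSV.

    Requires a ``respondent_id`` column, one column per codebook indicator id,
    and the weight column. Missing responses/covariates are preserved as NA;
    response codes outside an indicator's code set raise a
    :class:`SurveyDataError` naming the respondent and the indicator.
    """
    path = Path(csv_path)
    if not path.exists():
        raise SurveyDataError(f"survey file not found: {path}")
    try:
        data = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SurveyDataError(f"no records in {path}") from exc
    if len(data) == 0:
        raise SurveyDataError(f"no records in {path}")

    required = ["respondent_id", weight_column, *codebook.indicator_ids]
    missing_cols = [c for c in required if c not in data.columns]
    if missing_cols:
        raise SurveyDataError(f"missing mandatory columns: {missing_cols}")

    data = data.copy()
    data["respondent_id"] = data["respondent_id"].astype(str)
    weights = pd.to_numeric(data[weight_column], errors="coerce")
    if weights.isna().any():
        bad = data.loc[weights.isna(), "respondent_id"].iloc[0]
        raise SurveyDataError(f"unparseable weight for respondent {bad!r}")
    if (weights < 0).any():
        bad = data.loc[weights < 0, "respondent_id"].iloc[0]
        raise SurveyDataError(f"negative weight for respondent {bad!r}")
    data[weight_column] = weights.astype(float)

    for spec in codebook:
        col = pd.to_numeric(data[spec.indicator_id], errors="coerce")
        raw_missing = data[spec.indicator_id].isna()
        if (col.isna() & ~raw_missing).any():
            bad = data.loc[col.isna() & ~raw_missing, "respondent_id"].iloc[0]
            raise SurveyDataError(
                f"unparseable response for respondent {bad!r} in indicator "
                f"{spec.indicator_id!r}"
            )
        known = col.isin(list(spec.responses))
        unknown = ~known & ~col.isna()
        if unknown.any():
            bad = data.loc[unknown, "respondent_id"].iloc[0]
            code = int(col[unknown].iloc[0])
            raise SurveyDataError(
                f"respondent {bad!r}: response code {code} is not defined for "
                f"indicator {spec.indicator_id!r}"
            )
        data[spec.indicator_id] = col.astype("Int64")

    return SurveyDataset(
        data=data, indicator_ids=list(codebook.indicator_ids), weight_column=weight_column
    )


def dichotomize(
    dataset: SurveyDataset,
    codebook: Codebook,
    missing_policy: MissingPolicy = "drop",
) -> DeprivationMatrix:
    """Convert categorical responses to the binary deprivation matrix.

    ``b_ij = 1`` iff respondent i's response to indicator j is one of the
    codebook's deprived codes. Under ``missing_policy='drop'`` respondents
    with any missing indicator response are removed (the count is logged);
    under ``'not_deprived'`` a missing response counts as not deprived.
    """
    if missing_policy not in ("drop", "not_deprived"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if list(dataset.indicator_ids) != list(codebook.indicator_ids):
        raise SurveyDataError(
            "dataset indicators do not match codebook: "
            f"{dataset.indicator_ids} vs {codebook.indicator_ids}"
        )
    data = dataset.data
    resp = data[list(codebook.indicator_ids)]
    missing_any = resp.isna().any(axis=1)

    if missing_policy == "drop":
        n_dropped = int(missing_any.sum())
        if n_dropped:
            logger.info(
                "dichotomize: dropped %d of %d respondents with missing responses",
                n_dropped,
                len(data),
            )
        data = data.loc[~missing_any]
        resp = resp.loc[~missing_any]
        if len(data) == 0:
            raise SurveyDataError("all rows dropped: every respondent had a missing response")

    b = np.zeros((len(data), codebook.m), dtype=np.int8)
    for j, spec in enumerate(codebook):
        col = resp[spec.indicator_id]
        b[:, j] = col.isin(list(spec.deprived_codes)).to_numpy()

    return DeprivationMatrix(
        b=b,
        sample_weights=data[dataset.weight_column].to_numpy(dtype=float),
        indicator_ids=list(codebook.indicator_ids),
        row_ids=[str(r) for r in data["respondent_id"]],
    )


def covariate_for_matrix(
    dataset: SurveyDataset, matrix: DeprivationMatrix, name: str
) -> pd.Series:
    """A named covariate aligned to the matrix rows (after any drops)."""
    if name not in dataset.data.columns:
        raise SurveyDataError(f"unknown covariate {name!r}")
    by_id = dataset.data.set_index(dataset.data["respondent_id"].astype(str))[name]
    if by_id.index.has_duplicates:
        raise SurveyDataError("respondent ids are not unique")
    return by_id.reindex(matrix.row_ids).reset_index(drop=True)
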