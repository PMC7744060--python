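"""Subgroup decomposition and overlapping-deprivation summaries.

The adjusted headcount ratio is population-decomposable: with subgroup
weighted population shares ``s_g``, ``M = sum_g s_g M_g`` at every cutoff k.
``subgroup_decompose`` computes per-group AF profiles plus shares and
verifies the identity.  ``pairwise_overlap`` reports, for every indicator
pair, the weighted proportion deprived in both at once, along with the
weighted phi (Pearson) correlation of the binary indicators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .af import AFEstimate, af_profile
from .codebook import Codebook
from .survey import DeprivationMatrix

__all__ = ["SubgroupRow", "SubgroupTable", "OverlapMatrix", "subgroup_decompose", "pairwise_overlap"]

logger = logging.getLogger("mdepriv")


@dataclass(frozen=True)
class SubgroupRow:
    group: str
    population_share: float
    estimates: list[AFEstimate]


@dataclass(frozen=True)
class SubgroupTable:
    grouping_variable: str
    rows: list[SubgroupRow]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: group, share, k, hcr, a, m and their SEs."""
        records = []
        for row in self.rows:
            for est in row.estimates:
                records.append(
                    {
                        "group": row.group,
                        "population_share": row.population_share,
                        "k": est.k,
                        "hcr": est.hcr,
                        "se_hcr": est.se_hcr,
                        "intensity_a": est.intensity_a,
                        "se_a": est.se_a,
                        "adjusted_m": est.adjusted_m,
                        "se_m": est.se_m,
                        "n": est.n_effective,
                    }
                )
        return pd.DataFrame.from_records(records)


@dataclass(frozen=True)
class OverlapMatrix:
    """Pairwise joint deprivation rates and phi correlations.

    ``joint[i, j]`` is the weighted proportion deprived in indicators i and j
    simultaneously (diagonal: marginal rates); ``phi`` is the weighted
    Pearson correlation of the 0/1 columns (NaN where a column has zero
    variance).
    """

    joint: np.ndarray
    phi: np.ndarray
    indicator_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        records = []
        m = len(self.indicator_ids)
        for i in range(m):
            for j in range(i, m):
                records.append(
                    {
                        "indicator_1": self.indicator_ids[i],
                        "indicator_2": self.indicator_ids[j],
                        "joint_rate": self.joint[i, j],
                        "phi": self.phi[i, j],
                    }
                )
        return pd.DataFrame.from_records(records)


def subgroup_decompose(
    matrix: DeprivationMatrix,
    codebook: Codebook,
    groups: Sequence,
    ks: Optional[Sequence[int]] = None,
    se_method: str = "linearized",
    bootstrap_reps: int = 1000,
    seed: int = 20200403,
    grouping_variable: str = "group",
) -> SubgroupTable:
    """Per-group AF profiles with weighted population shares.

    ``groups`` is a length-n label vector aligned with the matrix rows
    (use :func:`mdepriv.survey.covariate_for_matrix` to extract one from a
    dataset). Rows with a missing group label are excluded and logged.
    Verifies the decomposition identity sum_g share_g * M_g = M_overall.
    """
    labels = pd.Series(list(groups))
    if len(labels) != matrix.n:
        raise ValueError(
            f"group labels (len {len(labels)}) do not align with matrix rows ({matrix.n})"
        )
    missing = labels.isna()
    if missing.all():
        raise ValueError(f"no respondent has a value for {grouping_variable!r}")
    if missing.any():
        logger.info(
            "subgroup_decompose(%s): excluding %d rows with missing group",
            grouping_variable,
            int(missing.sum()),
        )
    keep = matrix.select((~missing).to_numpy())
    labels = labels[~missing].reset_index(drop=True)
    total_w = keep.sample_weights.sum()

    rows = []
    for group in labels.unique():
        mask = (labels == group).to_numpy()
        gw = keep.sample_weights[mask].sum()
        if gw <= 0:
            raise ValueError(f"group {group!r} has zero total sampling weight")
        sub = keep.select(mask)
        ests = af_profile(
            sub, codebook, se_method=se_method, bootstrap_reps=bootstrap_reps,
            seed=seed, ks=ks,
        )
        rows.append(SubgroupRow(group=str(group), population_share=gw / total_w, estimates=ests))

    # decomposability check against the pooled estimate
    overall = af_profile(keep, codebook, se_method="linearized", ks=ks)
    for pos, est in enumerate(overall):
        recomposed = sum(
            r.population_share * r.estimates[pos].adjusted_m for r in rows
        )
        if abs(recomposed - est.adjusted_m) > 1e-9:
            raise AssertionError(
                f"decomposition identity violated at k={est.k}: "
                f"{recomposed} vs {est.adjusted_m}"
            )
    return SubgroupTable(grouping_variable=grouping_variable, rows=rows)


def _weighted_corr(b: np.ndarray, w: np.ndarray) -> np.ndarray:
    total = w.sum()
    means = (w @ b) / total
    centered = b - means
    cov = (centered * w[:, None]).T @ centered / total
    sd = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = cov / np.outer(sd, sd)
    phi[np.isinf(phi)] = np.nan
    np.fill_diagonal(phi, np.where(sd > 0, 1.0, np.nan))
    return phi


def pairwise_overlap(
    matrix: DeprivationMatrix,
    groups: Optional[Sequence] = None,
    subgroup: Optional[str] = None,
) -> OverlapMatrix:
    """Joint deprivation rates and phi correlations for all indicator pairs.

    With ``groups``/``subgroup`` given, restricts to the rows whose label
    equals ``subgroup`` ("deprived simultaneously" is read as deprived in at
    least both indicators of the pair).
    """
    work = matrix
    if subgroup is not None:
        if groups is None:
            raise ValueError("subgroup filtering requires the group label vector")
        labels = pd.Series(list(groups)).astype(str)
        mask = (labels == str(subgroup)).to_numpy()
        if not mask.any():
            raise ValueError(f"no respondents in subgroup {subgroup!r}")
        work = matrix.select(mask)
    if work.n == 0:
        raise ValueError("empty deprivation matrix")
    b = work.b.astype(float)
    w = work.sample_weights
    total = w.sum()
    if total <= 0:
        raise ValueError("total sampling weight is zero")
    joint = (b * w[:, None]).T @ b / total
    phi = _weighted_corr(b, w)
    return OverlapMatrix(joint=joint, phi=phi, indicator_ids=list(work.indicator_ids))
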