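"""Alkire-Foster dual-cutoff deprivation indices with survey weights.

Given the binary matrix ``b_ij`` and indicator weights ``w_j``, individual
i's weighted deprivation score is ``c_i = sum_j w_j b_ij``.  Individual i is
identified as multidimensionally deprived at cross-indicator cutoff ``k``
when ``c_i >= k/m``.  Three indices summarise the joint distribution:

* headcount ratio ``HCR`` — the (weight-adjusted) share of individuals
  identified at cutoff k;
* average intensity ``A`` — the mean score among the identified (a
  conditional mean, undefined when nobody is identified);
* adjusted headcount ratio ``M`` — the mean *censored* score over everyone
  (scores below the cutoff set to 0), so that ``M = HCR x A``.

Scores are exact rationals: indicator weights are Fractions, so each score
is an integer numerator over a common denominator, and the ``c_i >= k/m``
comparison is carried out in integer arithmetic.  The scalar estimators
(:func:`headcount_ratio`, :func:`average_intensity`,
:func:`adjusted_headcount`) return exact :class:`fractions.Fraction` values;
:func:`af_profile` is the vectorized float path that also produces
linearized or bootstrap standard errors for every cutoff k = 1..m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Literal, Optional, Sequence

import numpy as np

from .codebook import Codebook
from .survey import DeprivationMatrix

__all__ = [
    "ScoreVector",
    "AFEstimate",
    "deprivation_scores",
    "identify",
    "headcount_ratio",
    "average_intensity",
    "adjusted_headcount",
    "af_profile",
    "indicator_rates",
]


@dataclass(frozen=True)
class ScoreVector:
    """Weighted deprivation scores stored exactly.

    ``numerators[i] / denominator`` equals ``sum_j w_j b_ij`` for row i.
    """

    numerators: np.ndarray
    denominator: int
    sample_weights: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "numerators", np.asarray(self.numerators, dtype=np.int64)
        )
        object.__setattr__(
            self, "sample_weights", np.asarray(self.sample_weights, dtype=float)
        )
        if len(self.numerators) != len(self.sample_weights):
            raise ValueError("scores and sampling weights have different lengths")
        if self.denominator <= 0:
            raise ValueError("denominator must be positive")
        if (self.numerators < 0).any() or (self.numerators > self.denominator).any():
            raise ValueError("scores must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.numerators)

    @property
    def scores(self) -> list[Fraction]:
        return [Fraction(int(a), self.denominator) for a in self.numerators]

    @property
    def values(self) -> np.ndarray:
        """Scores as floats."""
        return self.numerators / self.denominator


@dataclass(frozen=True)
class AFEstimate:
    """HCR, A and M at one cutoff k, with standard errors.

    ``intensity_a``/``se_a`` are ``None`` when nobody is identified (A is a
    conditional mean). ``q_weighted`` is the weighted mass of the identified
    set, ``n_effective`` the unweighted count of rows used.
    """

    k: int
    hcr: float
    intensity_a: Optional[float]
    adjusted_m: float
    se_hcr: float
    se_a: Optional[float]
    se_m: float
    n_effective: int
    q_weighted: float

    def __post_init__(self):
        if not 0.0 <= self.adjusted_m <= self.hcr + 1e-12 <= 1.0 + 1e-12:
            raise ValueError(
                f"invalid AF estimate at k={self.k}: M={self.adjusted_m}, HCR={self.hcr}"
            )
        if self.intensity_a is not None:
            if abs(self.adjusted_m - self.hcr * self.intensity_a) > 1e-12:
                raise ValueError(
                    f"M != HCR*A at k={self.k}: "
                    f"{self.adjusted_m} vs {self.hcr * self.intensity_a}"
                )


def deprivation_scores(matrix: DeprivationMatrix, codebook: Codebook) -> ScoreVector:
    """Exact weighted deprivation scores sum_j w_j b_ij for every row."""
    if list(matrix.indicator_ids) != list(codebook.indicator_ids):
        raise ValueError(
            "matrix columns do not align with codebook indicators: "
            f"{matrix.indicator_ids} vs {codebook.indicator_ids}"
        )
    weights = codebook.weights
    denom = math.lcm(*(w.denominator for w in weights))
    int_w = np.array([int(w * denom) for w in weights], dtype=np.int64)
    numerators = matrix.b.astype(np.int64) @ int_w
    return ScoreVector(
        numerators=numerators,
        denominator=denom,
        sample_weights=matrix.sample_weights,
    )


def _check_k(k: int, m: int) -> None:
    if not (isinstance(k, (int, np.integer)) and 1 <= k <= m):
        raise ValueError(f"cutoff k must be an integer in 1..{m}, got {k!r}")


def identify(scores: ScoreVector, k: int, m: int) -> np.ndarray:
    """Boolean membership of the multidimensionally deprived set Q at cutoff k.

    Exact integer comparison of ``score_i >= k/m``.
    """
    _check_k(k, m)
    return scores.numerators * m >= k * scores.denominator


def _weight_fractions(weights: np.ndarray) -> list[Fraction]:
    # floats are binary rationals, so Fraction(w) is exact
    return [Fraction(w) for w in weights.tolist()]


def headcount_ratio(scores: ScoreVector, k: int, m: int) -> Fraction:
    """Weighted proportion identified at cutoff k (q/n under unit weights)."""
    members = identify(scores, k, m)
    w = scores.sample_weights
    total = w.sum()
    if total <= 0:
        raise ValueError("total sampling weight is zero")
    if np.array_equal(w, np.round(w)):  # integral weights: fast exact path
        return Fraction(int(np.round(w[members].sum())), int(np.round(total)))
    wf = _weight_fractions(w)
    num = sum((wf[i] for i in np.flatnonzero(members)), Fraction(0))
    return num / sum(wf, Fraction(0))


def average_intensity(scores: ScoreVector, k: int, m: int) -> Optional[Fraction]:
    """Weighted mean score among the identified; None when the set is empty."""
    members = identify(scores, k, m)
    if not members.any():
        return None
    w = scores.sample_weights
    idx = np.flatnonzero(members)
    wf = _weight_fractions(w)
    num = sum(
        (wf[i] * Fraction(int(scores.numerators[i]), scores.denominator) for i in idx),
        Fraction(0),
    )
    den = sum((wf[i] for i in idx), Fraction(0))
    if den == 0:
        return None
    return num / den


def adjusted_headcount(scores: ScoreVector, k: int, m: int) -> Fraction:
    """Weighted mean of the censored score over all respondents (M = HCR x A)."""
    members = identify(scores, k, m)
    w = scores.sample_weights
    wf = _weight_fractions(w)
    total = sum(wf, Fraction(0))
    if total == 0:
        raise ValueError("total sampling weight is zero")
    num = sum(
        (wf[i] * Fraction(int(scores.numerators[i]), scores.denominator)
         for i in np.flatnonzero(members)),
        Fraction(0),
    )
    return num / total


def _linearized_se(w: np.ndarray, resid: np.ndarray) -> float:
    """SE of a weighted mean via its linearization: sqrt(sum w^2 r^2) / sum w."""
    total = w.sum()
    return float(np.sqrt(np.sum((w * resid) ** 2)) / total)


def _af_point(values: np.ndarray, w: np.ndarray, members: np.ndarray):
    total = w.sum()
    hcr = float(w[members].sum() / total)
    censored = np.where(members, values, 0.0)
    m_idx = float(np.sum(w * censored) / total)
    a = m_idx / hcr if hcr > 0 else None
    return hcr, a, m_idx, censored


def af_profile(
    matrix: DeprivationMatrix,
    codebook: Codebook,
    se_method: Literal["linearized", "bootstrap"] = "linearized",
    bootstrap_reps: int = 1000,
    seed: int = 20200403,
    ks: Optional[Sequence[int]] = None,
) -> list[AFEstimate]:
    """HCR, A, M and standard errors for each cutoff k (default 1..m).

    ``linearized`` treats each index as a (ratio-estimated) weighted mean:
    HCR as a weighted proportion, M as the weighted mean of the censored
    score, and A = M/HCR by the delta method.  ``bootstrap`` resamples rows
    with replacement (``bootstrap_reps`` draws, seeded and reproducible).
    """
    if matrix.n == 0:
        raise ValueError("empty deprivation matrix")
    if se_method not in ("linearized", "bootstrap"):
        raise ValueError(f"unknown se_method {se_method!r}")
    if se_method == "bootstrap" and bootstrap_reps < 2:
        raise ValueError("bootstrap needs at least 2 replicates")
    sv = deprivation_scores(matrix, codebook)
    m = codebook.m
    ks = list(range(1, m + 1)) if ks is None else list(ks)
    values = sv.values
    w = sv.sample_weights
    total = w.sum()
    if total <= 0:
        raise ValueError("total sampling weight is zero")

    if se_method == "bootstrap":
        rng = np.random.default_rng(seed)
        boot_idx = rng.integers(0, sv.n, size=(bootstrap_reps, sv.n))

    out = []
    for k in ks:
        members = identify(sv, k, m)
        hcr, a, m_idx, censored = _af_point(values, w, members)

        if se_method == "linearized":
            se_h = _linearized_se(w, members.astype(float) - hcr)
            se_m = _linearized_se(w, censored - m_idx)
            if a is None:
                se_a = None
            else:
                u = members.astype(float) - hcr
                v = censored - m_idx
                var_h = np.sum((w * u) ** 2) / total**2
                var_m = np.sum((w * v) ** 2) / total**2
                cov = np.sum(w**2 * u * v) / total**2
                var_a = (var_m - 2 * a * cov + a**2 * var_h) / hcr**2
                se_a = float(np.sqrt(max(var_a, 0.0)))
        else:
            h_reps, a_reps, m_reps = [], [], []
            member_f = members.astype(float)
            for idx in boot_idx:
                wb = w[idx]
                tb = wb.sum()
                if tb <= 0:
                    continue
                hb = float(np.sum(wb * member_f[idx]) / tb)
                mb = float(np.sum(wb * censored[idx]) / tb)
                h_reps.append(hb)
                m_reps.append(mb)
                if hb > 0:
                    a_reps.append(mb / hb)
            se_h = float(np.std(h_reps, ddof=1))
            se_m = float(np.std(m_reps, ddof=1))
            se_a = float(np.std(a_reps, ddof=1)) if len(a_reps) >= 2 and a is not None else None

        out.append(
            AFEstimate(
                k=k,
                hcr=hcr,
                intensity_a=a,
                adjusted_m=m_idx,
                se_hcr=se_h,
                se_a=se_a,
                se_m=se_m,
                n_effective=int(sv.n),
                q_weighted=float(w[members].sum()),
            )
        )
    return out


def indicator_rates(matrix: DeprivationMatrix) -> np.ndarray:
    """Weighted proportion deprived in each indicator (dashboard rates)."""
    if matrix.n == 0:
        raise ValueError("empty deprivation matrix")
    w = matrix.sample_weights
    total = w.sum()
    if total <= 0:
        raise ValueError("total sampling weight is zero")
    return (w @ matrix.b) / total
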