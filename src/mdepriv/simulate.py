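"""Synthetic SHED-like survey generator and Monte-Carlo validation tools.

The generator draws categorical survey responses whose dichotomization has
known structure, so every pipeline stage can be validated against analytic
truth without any external data:

* marginal deprivation probabilities per indicator (optionally per
  race/ethnicity group);
* inter-indicator dependence via a single standard-normal latent hardship
  factor with loading ``sqrt(rho)`` and probit thresholds, so each
  indicator's marginal is preserved while ``rho`` controls the positive
  association between indicators;
* demographic covariates drawn from configurable category mixes;
* lognormal sampling weights normalized to mean 1 (post-stratification
  style);
* optionally, a known Poisson regression truth: deprivation counts drawn
  from ``Poisson(exp(x_i' beta))`` (truncated at m) for parameter-recovery
  studies.

Analytic oracles: :func:`implied_hcr_independent` enumerates the
Poisson-binomial tail exactly, and :func:`af_truth` integrates the
latent-factor model by Gauss-Hermite quadrature to give population HCR/A/M
at every cutoff.  :func:`recovery_study` runs repeated generate-estimate
cycles and reports bias, RMSE and confidence-interval coverage.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .af import af_profile
from .codebook import Codebook, load_default_codebook
from .regression import impute_income
from .survey import SurveyDataset, dichotomize

__all__ = [
    "SyntheticConfig",
    "shed_like",
    "generate_survey",
    "implied_hcr_independent",
    "af_truth",
    "recovery_study",
]

# Default demographic category mixes, mirroring the emulated survey's sample
# composition (race/ethnicity, age bands, education, marital status,
# household size, income bands, metro share).
RACE_MIX = {"white": 0.632, "black": 0.118, "other": 0.072, "hispanic": 0.164, "two_plus": 0.014}
AGE_BANDS = {(18, 29): 0.209, (30, 44): 0.251, (45, 59): 0.247, (60, 79): 0.293}
EDUC_MIX = {1: 0.106, 2: 0.283, 3: 0.278, 4: 0.333}  # <HS, HS, some college, BA+
MARITAL_MIX = {"married": 0.536, "partner": 0.058, "other": 0.406}
HH_SIZE_MIX = {1: 0.25, 2: 0.312, 3: 0.20, 4: 0.12, 5: 0.062, 6: 0.03, 7: 0.016, 8: 0.01}
FEMALE_P = 0.516
METRO_P = 0.874
N_STATES = 51
N_STAYHOME_STATES = 31  # states with stay-at-home orders before April 1, 2020


def _default_income_mix() -> np.ndarray:
    # roughly matches the emulated sample's income bands:
    # <40k ~ 25% (cats 1-10), 40-99k ~ 37% (cats 11-15), 100k+ ~ 38% (16-21)
    p = np.concatenate(
        [np.full(10, 0.249 / 10), np.full(5, 0.369 / 5), np.full(6, 0.382 / 6)]
    )
    return p / p.sum()


@dataclass(frozen=True)
class SyntheticConfig:
    """Conditions under which a synthetic survey is drawn (seeded)."""

    n: int = 1030
    marginal_probs: Sequence[float] = (0.205, 0.12, 0.23, 0.148)
    rho: float = 0.0
    group_marginals: Optional[Mapping[str, Sequence[float]]] = None
    race_mix: Mapping[str, float] = field(default_factory=lambda: dict(RACE_MIX))
    weight_sigma: float = 0.5
    regression_truth: Optional[Mapping[str, float]] = None
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be at least 1")
        p = np.asarray(self.marginal_probs, dtype=float)
        if ((p < 0) | (p > 1)).any():
            raise ValueError("marginal probabilities must lie in [0, 1]")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("dependence loading rho must lie in [0, 1)")
        mix = np.asarray(list(self.race_mix.values()), dtype=float)
        if abs(mix.sum() - 1.0) > 1e-9 or (mix < 0).any():
            raise ValueError("race mix probabilities must be non-negative and sum to 1")
        if self.group_marginals is not None:
            for g, gp in self.group_marginals.items():
                gp = np.asarray(gp, dtype=float)
                if g not in self.race_mix:
                    raise ValueError(f"group marginals given for unknown group {g!r}")
                if len(gp) != len(p) or ((gp < 0) | (gp > 1)).any():
                    raise ValueError(f"invalid marginals for group {g!r}")


def shed_like(seed: int = 0, **overrides) -> SyntheticConfig:
    """Preset emulating the April-2020 supplemental survey conditions.

    n = 1030 weighted respondents, indicator marginals approximately
    (0.205, 0.12, 0.23, 0.148), and a common-factor loading rho = 0.6
    encoding the strong positive association between economic hardships.
    These are emulation inputs, not estimates.
    """
    defaults = dict(n=1030, marginal_probs=(0.205, 0.12, 0.23, 0.148), rho=0.6, seed=seed)
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


def _draw_categorical(rng, categories, probs, size):
    idx = rng.choice(len(categories), size=size, p=np.asarray(probs, dtype=float))
    return [categories[i] for i in idx]


def _pick_codes(rng, codes: np.ndarray, size: int) -> np.ndarray:
    return codes[rng.integers(0, len(codes), size=size)]


def generate_survey(
    config: SyntheticConfig, codebook: Optional[Codebook] = None
) -> SurveyDataset:
    """Draw a synthetic survey reproducibly from ``config.seed``.

    Dichotomizing the result with the same codebook recovers Bernoulli
    deprivation indicators with the configured marginals and latent-factor
    dependence; the specific response code within the deprived or
    non-deprived code set is uniform.
    """
    codebook = codebook if codebook is not None else load_default_codebook()
    m = codebook.m
    p = np.asarray(config.marginal_probs, dtype=float)
    if len(p) != m:
        raise ValueError(f"need {m} marginal probabilities, got {len(p)}")
    rng = np.random.default_rng(config.seed)
    n = config.n

    races = _draw_categorical(
        rng, list(config.race_mix), list(config.race_mix.values()), n
    )
    band_keys = list(AGE_BANDS)
    bands = rng.choice(len(band_keys), size=n, p=np.asarray(list(AGE_BANDS.values())))
    age = np.array(
        [rng.integers(band_keys[b][0], band_keys[b][1] + 1) for b in bands]
    )
    education = rng.choice(list(EDUC_MIX), size=n, p=np.asarray(list(EDUC_MIX.values())))
    gender = np.where(rng.random(n) < FEMALE_P, "female", "male")
    marital = _draw_categorical(rng, list(MARITAL_MIX), list(MARITAL_MIX.values()), n)
    hh_size = rng.choice(list(HH_SIZE_MIX), size=n, p=np.asarray(list(HH_SIZE_MIX.values())))
    income_cat = rng.choice(np.arange(1, 22), size=n, p=_default_income_mix())
    metro = (rng.random(n) < METRO_P).astype(int)
    state = rng.integers(0, N_STATES, size=n)
    stay_home = (state < N_STAYHOME_STATES).astype(int)

    # per-row marginals (group-specific rates override the base marginals)
    p_rows = np.tile(p, (n, 1))
    if config.group_marginals:
        race_arr = np.asarray(races)
        for g, gp in config.group_marginals.items():
            p_rows[race_arr == g] = np.asarray(gp, dtype=float)

    if config.regression_truth is not None:
        deprived = _counts_from_truth(rng, config, races, age, education, gender,
                                      marital, hh_size, income_cat, metro, stay_home, m)
    else:
        # common latent hardship factor with probit thresholds
        z = rng.standard_normal(n)
        e = rng.standard_normal((n, m))
        x = np.sqrt(config.rho) * z[:, None] + np.sqrt(1.0 - config.rho) * e
        deprived = x <= ndtri(np.clip(p_rows, 1e-12, 1 - 1e-12))
        deprived &= p_rows > 0
        deprived |= p_rows >= 1

    columns = {"respondent_id": [f"r{i + 1}" for i in range(n)]}
    for j, spec in enumerate(codebook):
        dep_codes = np.array(sorted(spec.deprived_codes))
        ok_codes = np.array(sorted(set(spec.responses) - spec.deprived_codes))
        col = np.where(
            deprived[:, j],
            _pick_codes(rng, dep_codes, n),
            _pick_codes(rng, ok_codes, n),
        )
        columns[spec.indicator_id] = col

    weights = rng.lognormal(mean=-config.weight_sigma**2 / 2, sigma=config.weight_sigma, size=n)
    columns["weight"] = weights / weights.mean()  # scale-normalized, mean 1

    columns.update(
        race_ethnicity=races,
        age=age,
        education=education,
        gender=gender,
        marital=marital,
        household_size=hh_size,
        income_category=income_cat,
        metro=metro,
        stay_home=stay_home,
        state=state,
    )
    return SurveyDataset(
        data=pd.DataFrame(columns),
        indicator_ids=list(codebook.indicator_ids),
        weight_column="weight",
    )


def _counts_from_truth(rng, config, races, age, education, gender, marital,
                       hh_size, income_cat, metro, stay_home, m):
    """Deprivation indicators implied by a known Poisson design link."""
    beta = dict(config.regression_truth)
    race_arr = np.asarray(races)
    values = {
        "const": np.ones(len(race_arr)),
        "white": (race_arr == "white").astype(float),
        "black": (race_arr == "black").astype(float),
        "hispanic": (race_arr == "hispanic").astype(float),
        "log_income": np.log([impute_income(int(c)) for c in income_cat]),
        "hh_size": np.asarray(hh_size, dtype=float),
        "age": np.asarray(age, dtype=float),
        "educ": np.asarray(education, dtype=float),
        "female": (np.asarray(gender) == "female").astype(float),
        "married": (np.asarray(marital) == "married").astype(float),
        "metro": np.asarray(metro, dtype=float),
        "stay_home": np.asarray(stay_home, dtype=float),
    }
    unknown = set(beta) - set(values)
    if unknown:
        raise ValueError(f"regression_truth has unknown terms: {sorted(unknown)}")
    eta = sum(b * values[t] for t, b in beta.items())
    lam = np.exp(eta)
    counts = np.minimum(rng.poisson(lam), m)
    # place the counts uniformly across indicators
    order = np.argsort(rng.random((len(counts), m)), axis=1)
    deprived = order < counts[:, None]
    return deprived


def implied_hcr_independent(p: Sequence[float], k: int) -> float:
    """Exact Poisson-binomial tail P(#deprivations >= k) under independence.

    Assumes equal indicator weights; enumerates all 2^m outcomes (guarded at
    m <= 20).
    """
    p = np.asarray(p, dtype=float)
    m = len(p)
    if m > 20:
        raise ValueError("enumeration limited to m <= 20 indicators")
    if not 1 <= k <= m:
        raise ValueError(f"cutoff k must be in 1..{m}")
    total = 0.0
    for pattern in itertools.product((0, 1), repeat=m):
        if sum(pattern) >= k:
            prob = np.prod(np.where(np.array(pattern) == 1, p, 1 - p))
            total += float(prob)
    return total


def _count_distribution(p: Sequence[float], rho: float, quad_points: int = 101) -> np.ndarray:
    """P(#deprivations = c), c = 0..m, under the common-factor model."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    if rho == 0.0:
        p_nodes = p[None, :]
        node_w = np.array([1.0])
    else:
        x, w = np.polynomial.hermite_e.hermegauss(quad_points)
        node_w = w / np.sqrt(2 * np.pi)
        c = ndtri(np.clip(p, 1e-12, 1 - 1e-12))
        p_nodes = ndtr((c[None, :] - np.sqrt(rho) * x[:, None]) / np.sqrt(1 - rho))
        p_nodes[:, p == 0] = 0.0
        p_nodes[:, p == 1] = 1.0
    dist = np.zeros(m + 1)
    for pattern in itertools.product((0, 1), repeat=m):
        arr = np.array(pattern)
        probs = np.prod(np.where(arr == 1, p_nodes, 1 - p_nodes), axis=1)
        dist[arr.sum()] += float(node_w @ probs)
    return dist


def af_truth(p: Sequence[float], rho: float = 0.0) -> pd.DataFrame:
    """Population HCR/A/M at every cutoff under the generator's model.

    Equal indicator weights; integrates the latent-factor model exactly
    (Gauss-Hermite quadrature), reducing to the Poisson-binomial under
    rho = 0.
    """
    p = np.asarray(p, dtype=float)
    m = len(p)
    dist = _count_distribution(p, rho)
    counts = np.arange(m + 1)
    rows = []
    for k in range(1, m + 1):
        tail = dist[k:].sum()
        m_idx = float((dist[k:] * counts[k:] / m).sum())
        rows.append(
            {
                "k": k,
                "hcr": float(tail),
                "intensity_a": m_idx / tail if tail > 0 else np.nan,
                "adjusted_m": m_idx,
            }
        )
    return pd.DataFrame(rows).set_index("k")


def _mixture_truth(config: SyntheticConfig) -> pd.DataFrame:
    if not config.group_marginals:
        return af_truth(config.marginal_probs, config.rho)
    parts = []
    for g, share in config.race_mix.items():
        gp = config.group_marginals.get(g, config.marginal_probs)
        parts.append((share, af_truth(gp, config.rho)))
    out = parts[0][1] * 0.0
    for share, tab in parts:
        out = out.add(tab * share)
    out["intensity_a"] = out["adjusted_m"] / out["hcr"]
    return out


def recovery_study(
    config: SyntheticConfig,
    reps: int = 500,
    codebook: Optional[Codebook] = None,
    min_normal_count: float = 5.0,
) -> pd.DataFrame:
    """Bias, RMSE and 95%-interval coverage of the AF estimators.

    Draws ``reps`` synthetic surveys under ``config`` (child seeds derived
    from ``config.seed``), runs the full dichotomize + estimate pipeline
    with linearized SEs, and compares against the analytic population truth.

    Coverage of the normal-theory interval ``est +/- 1.96 se`` is reported
    for every cell; ``coverage_applicable`` marks the cells where the
    binomial normal approximation is adequate (expected identified count
    satisfies n*p*(1-p) >= ``min_normal_count``), which is where nominal
    coverage can be expected.
    """
    if reps < 50:
        raise ValueError("recovery study needs at least 50 replications")
    codebook = codebook if codebook is not None else load_default_codebook()
    truth = _mixture_truth(config)
    m = codebook.m
    seeds = np.random.SeedSequence(config.seed).generate_state(reps) % (2**31)

    est = {stat: np.full((reps, m), np.nan) for stat in ("hcr", "intensity_a", "adjusted_m")}
    ses = {stat: np.full((reps, m), np.nan) for stat in ("hcr", "intensity_a", "adjusted_m")}
    for r in range(reps):
        cfg = replace(config, seed=int(seeds[r]))
        dataset = generate_survey(cfg, codebook)
        matrix = dichotomize(dataset, codebook, missing_policy="drop")
        for pos, e in enumerate(af_profile(matrix, codebook, se_method="linearized")):
            est["hcr"][r, pos] = e.hcr
            est["adjusted_m"][r, pos] = e.adjusted_m
            ses["hcr"][r, pos] = e.se_hcr
            ses["adjusted_m"][r, pos] = e.se_m
            if e.intensity_a is not None:
                est["intensity_a"][r, pos] = e.intensity_a
                ses["intensity_a"][r, pos] = e.se_a

    rows = []
    for stat in ("hcr", "intensity_a", "adjusted_m"):
        for pos, k in enumerate(range(1, m + 1)):
            tr = truth.loc[k, stat]
            vals = est[stat][:, pos]
            se_vals = ses[stat][:, pos]
            ok = ~np.isnan(vals)
            mean = float(np.nanmean(vals)) if ok.any() else np.nan
            bias = mean - tr
            mc_se = float(np.nanstd(vals, ddof=1) / np.sqrt(ok.sum())) if ok.sum() > 1 else np.nan
            rmse = float(np.sqrt(np.nanmean((vals - tr) ** 2))) if ok.any() else np.nan
            cover = np.abs(vals - tr) <= 1.96 * se_vals
            coverage = float(np.nanmean(np.where(ok, cover, np.nan))) if ok.any() else np.nan
            exp_count = config.n * truth.loc[k, "hcr"] * (1 - truth.loc[k, "hcr"])
            rows.append(
                {
                    "statistic": stat,
                    "k": k,
                    "truth": float(tr) if np.isfinite(tr) else np.nan,
                    "mean_estimate": mean,
                    "bias": float(bias) if np.isfinite(bias) else np.nan,
                    "mc_se": mc_se,
                    "rmse": rmse,
                    "coverage_95": coverage,
                    "n_defined": int(ok.sum()),
                    "coverage_applicable": bool(exp_count >= min_normal_count),
                }
            )
    return pd.DataFrame(rows)
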