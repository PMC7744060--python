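"""End-to-end analysis runs producing publication-style output tables.

``run_full_analysis`` orchestrates the whole pipeline on one survey file:
dichotomization, the AF profile over k = 1..m (table3-style), per-grouping
subgroup decompositions (table4/table6-style), indicator dashboard rates
(fig1) and pairwise overlaps (fig2), count regressions (table5-style), and
a JSON metadata file recording the seed, versions, and dropped-row counts.

Display convention: HCR and M are reported in percent, A on [0, 1]; every
displayed percentage is the stored full-precision value rounded half-even
to one decimal.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .af import af_profile, indicator_rates
from .codebook import Codebook, CodebookError, load_codebook
from .regression import BASIC_TERMS, FULL_TERMS, RegressionSpec, build_design, fit_count_model
from .subgroups import pairwise_overlap, subgroup_decompose
from .survey import SurveyDataError, covariate_for_matrix, dichotomize, read_survey

__all__ = ["RunConfig", "run_full_analysis", "round_half_even", "profile_frame"]

logger = logging.getLogger("mdepriv")


def round_half_even(x: float, decimals: int = 1) -> float:
    """Banker's rounding used for all displayed percentages."""
    return float(np.round(x, decimals))


@dataclass
class RunConfig:
    """Everything one full analysis run needs."""

    survey_path: Path
    codebook_path: Optional[Path] = None
    output_dir: Path = Path("mdepriv_output")
    missing_policy: str = "drop"
    se_method: str = "linearized"
    bootstrap_reps: int = 1000
    seed: int = 20200403
    groupings: Sequence[str] = field(default_factory=list)
    ks: Optional[Sequence[int]] = None
    regression_families: Sequence[str] = ("ols", "poisson")
    regression_weighted: bool = False


def profile_frame(estimates) -> pd.DataFrame:
    """AF profile as a table3-style frame (HCR/M in percent, A on [0,1])."""
    rows = []
    for e in estimates:
        rows.append(
            {
                "k": e.k,
                "hcr_pct": round_half_even(e.hcr * 100),
                "se_hcr_pct": round_half_even(e.se_hcr * 100, 2),
                "intensity_a": round_half_even(e.intensity_a, 2)
                if e.intensity_a is not None
                else np.nan,
                "se_a": round_half_even(e.se_a, 2) if e.se_a is not None else np.nan,
                "m_pct": round_half_even(e.adjusted_m * 100),
                "se_m_pct": round_half_even(e.se_m * 100, 2),
                "hcr": e.hcr,
                "intensity_a_full": e.intensity_a if e.intensity_a is not None else np.nan,
                "adjusted_m": e.adjusted_m,
                "se_hcr": e.se_hcr,
                "se_m": e.se_m,
                "n": e.n_effective,
            }
        )
    return pd.DataFrame(rows)


def run_full_analysis(config: RunConfig) -> dict:
    """Run every pipeline stage and write the output bundle.

    Returns a dict mapping artifact names to the written paths. Any stage
    failure is re-raised with the stage name after partial outputs are
    removed.
    """
    out_dir = Path(config.output_dir)
    written: dict[str, Path] = {}
    stage = "configuration"
    try:
        if config.codebook_path is not None:
            codebook = load_codebook(config.codebook_path)
        else:
            from .codebook import load_default_codebook

            codebook = load_default_codebook()
        survey_path = Path(config.survey_path)
        if not survey_path.exists():
            raise CodebookError(f"survey file not found: {survey_path}")
        out_dir.mkdir(parents=True, exist_ok=True)

        stage = "read_survey"
        dataset = read_survey(survey_path, codebook)
        stage = "dichotomize"
        matrix = dichotomize(dataset, codebook, missing_policy=config.missing_policy)
        dropped = dataset.n - matrix.n

        stage = "af_profile"
        estimates = af_profile(
            matrix,
            codebook,
            se_method=config.se_method,
            bootstrap_reps=config.bootstrap_reps,
            seed=config.seed,
            ks=config.ks,
        )
        path = out_dir / "table3_af_profile.csv"
        profile_frame(estimates).to_csv(path, index=False)
        written["af_profile"] = path

        stage = "indicator_rates"
        rates = indicator_rates(matrix)
        path = out_dir / "fig1_indicator_rates.csv"
        pd.DataFrame(
            {
                "indicator": matrix.indicator_ids,
                "rate_pct": [round_half_even(r * 100) for r in rates],
                "rate": rates,
            }
        ).to_csv(path, index=False)
        written["indicator_rates"] = path

        stage = "overlap"
        overlap = pairwise_overlap(matrix)
        frame = overlap.to_frame()
        frame["joint_pct"] = [round_half_even(v * 100) for v in frame["joint_rate"]]
        path = out_dir / "fig2_overlap.csv"
        frame.to_csv(path, index=False)
        written["overlap"] = path

        for grouping in config.groupings:
            stage = f"subgroups:{grouping}"
            groups = covariate_for_matrix(dataset, matrix, grouping)
            table = subgroup_decompose(
                matrix,
                codebook,
                groups,
                ks=config.ks,
                se_method=config.se_method,
                bootstrap_reps=config.bootstrap_reps,
                seed=config.seed,
                grouping_variable=grouping,
            )
            frame = table.to_frame()
            frame["hcr_pct"] = [round_half_even(v * 100) for v in frame["hcr"]]
            frame["m_pct"] = [round_half_even(v * 100) for v in frame["adjusted_m"]]
            path = out_dir / f"table4_subgroups_{grouping}.csv"
            frame.to_csv(path, index=False)
            written[f"subgroups_{grouping}"] = path

        regression_covariates = {"race_ethnicity", "income_category", "household_size",
                                 "age", "education", "gender", "marital", "metro", "stay_home"}
        have_covariates = regression_covariates <= set(dataset.data.columns)
        if have_covariates:
            for family in config.regression_families:
                for label, terms in (("basic", BASIC_TERMS), ("full", FULL_TERMS)):
                    stage = f"regression:{family}:{label}"
                    spec = RegressionSpec(
                        family=family,
                        terms=terms,
                        use_sample_weights=config.regression_weighted,
                    )
                    X, y, info = build_design(dataset, matrix, spec)
                    result = fit_count_model(X, y, spec, sample_weights=info["weights"])
                    frame = result.to_frame()
                    for key, value in result.fit_stats.items():
                        frame[key] = value
                    path = out_dir / f"table5_{family}_{label}.csv"
                    frame.to_csv(path, index=False)
                    written[f"regression_{family}_{label}"] = path
        else:
            logger.info("regression stage skipped: covariate columns not present")

        stage = "metadata"
        meta = {
            "package_version": __version__,
            "survey_path": str(survey_path),
            "codebook_path": str(config.codebook_path) if config.codebook_path else "packaged default",
            "n_respondents": dataset.n,
            "n_used": matrix.n,
            "n_dropped_missing_responses": dropped,
            "missing_policy": config.missing_policy,
            "se_method": config.se_method,
            "seed": config.seed,
            "regression_included": have_covariates,
            "outputs": {k: str(v) for k, v in written.items()},
        }
        path = out_dir / "run_metadata.json"
        path.write_text(json.dumps(meta, indent=2))
        written["metadata"] = path
        return written
    except Exception as exc:
        for p in written.values():
            try:
                Path(p).unlink()
            except OSError:
                pass
        exc.args = (f"[stage {stage}] {exc}",)
        raise
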