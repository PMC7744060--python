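"""Packaged example data.

``worked_example`` ships the five-respondent illustrative survey whose
dichotomization yields the classic 5x4 deprivation matrix used to introduce
the dual-cutoff indices (scores 3/4, 0, 4/4, 2/4, 1/4; HCR = 3/5, A = 9/12,
M = 9/20 at k = 2 with unit weights).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .codebook import Codebook, load_default_codebook
from .survey import SurveyDataset, read_survey

__all__ = ["worked_example_path", "worked_example"]


def worked_example_path() -> Path:
    """Path of the packaged five-respondent example survey CSV."""
    return Path(resources.files("mdepriv").joinpath("data/table2_example.csv"))


def worked_example(codebook: Codebook | None = None) -> SurveyDataset:
    """The five-respondent worked example as a validated SurveyDataset."""
    codebook = codebook if codebook is not None else load_default_codebook()
    return read_survey(worked_example_path(), codebook)
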