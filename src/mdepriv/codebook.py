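"""Indicator codebooks: how categorical survey responses map to deprivation.

A codebook lists the indicators of a multidimensional deprivation measure.
Each indicator carries the full set of response codes offered by the survey
question, the subset of codes that flag deprivation, and the indicator weight
``w_j``.  Weights are stored as exact rationals so that the sum-to-one
constraint and the ``k/m`` identification thresholds are checked without
floating-point slop.

The packaged default codebook (``shed_april2020.yaml``) encodes the four
economic-deprivation indicators of the April 2020 SHED supplemental survey:
overall financial condition, employment status, month-over-month income
change, and ability to pay bills in full, each weighted 1/4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

__all__ = [
    "CodebookError",
    "IndicatorSpec",
    "Codebook",
    "load_codebook",
    "default_codebook_path",
    "load_default_codebook",
]


class CodebookError(ValueError):
    """Raised when a codebook file or indicator specification is invalid."""


def _as_fraction(value) -> Fraction:
    """Parse a weight given as '1/4', '0.25', 0.25 or a Fraction."""
    if isinstance(value, Fraction):
        return value
    if isinstance(value, int):
        return Fraction(value)
    # route floats through their decimal repr so YAML "0.3" means 3/10
    return Fraction(str(value))


@dataclass(frozen=True)
class IndicatorSpec:
    """One deprivation indicator: its question, codes, and weight w_j."""

    indicator_id: str
    question: str
    responses: Mapping[int, str]
    deprived_codes: frozenset[int]
    weight: Fraction

    def __post_init__(self):
        object.__setattr__(self, "responses", dict(self.responses))
        object.__setattr__(self, "deprived_codes", frozenset(self.deprived_codes))
        object.__setattr__(self, "weight", _as_fraction(self.weight))
        codes = set(self.responses)
        if not self.deprived_codes:
            raise CodebookError(
                f"indicator {self.indicator_id!r}: deprived code set is empty"
            )
        if not self.deprived_codes < codes:
            raise CodebookError(
                f"indicator {self.indicator_id!r}: deprived codes "
                f"{sorted(self.deprived_codes)} must be a proper subset of the "
                f"response codes {sorted(codes)}"
            )
        if self.weight <= 0:
            raise CodebookError(
                f"indicator {self.indicator_id!r}: weight must be positive, "
                f"got {self.weight}"
            )

    def is_deprived(self, code: int) -> bool:
        if code not in self.responses:
            raise CodebookError(
                f"indicator {self.indicator_id!r}: unknown response code {code}"
            )
        return code in self.deprived_codes


@dataclass(frozen=True)
class Codebook:
    """Ordered collection of indicators with weights summing to one."""

    indicators: Sequence[IndicatorSpec] = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(self, "indicators", tuple(self.indicators))
        if len(self.indicators) < 2:
            raise CodebookError("a codebook needs at least two indicators")
        ids = [spec.indicator_id for spec in self.indicators]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CodebookError(f"duplicate indicator ids: {dupes}")
        total = sum((spec.weight for spec in self.indicators), Fraction(0))
        if total != 1:
            raise CodebookError(
                f"indicator weights must sum to 1 exactly, got {total} "
                f"for indicators {ids}"
            )

    @property
    def m(self) -> int:
        return len(self.indicators)

    @property
    def indicator_ids(self) -> list[str]:
        return [spec.indicator_id for spec in self.indicators]

    @property
    def weights(self) -> list[Fraction]:
        return [spec.weight for spec in self.indicators]

    def __iter__(self):
        return iter(self.indicators)

    def __getitem__(self, indicator_id: str) -> IndicatorSpec:
        for spec in self.indicators:
            if spec.indicator_id == indicator_id:
                return spec
        raise KeyError(indicator_id)


def load_codebook(config_path: str | Path) -> Codebook:
    """Read and validate a YAML codebook file.

    The file holds a top-level ``indicators`` list; each entry has ``id``,
    ``question``, ``responses`` (code -> label), ``deprived`` (codes) and
    ``weight`` (rational string such as ``1/4`` or a decimal).
    """
    path = Path(config_path)
    if not path.exists():
        raise CodebookError(f"codebook file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise CodebookError(f"could not parse codebook {path}: {exc}") from exc
    if not isinstance(raw, dict) or "indicators" not in raw:
        raise CodebookError(f"codebook {path} must contain an 'indicators' list")
    specs = []
    for entry in raw["indicators"]:
        try:
            specs.append(
                IndicatorSpec(
                    indicator_id=str(entry["id"]),
                    question=str(entry.get("question", "")),
                    responses={int(c): str(lbl) for c, lbl in entry["responses"].items()},
                    deprived_codes=frozenset(int(c) for c in entry["deprived"]),
                    weight=_as_fraction(entry["weight"]),
                )
            )
        except KeyError as exc:
            raise CodebookError(
                f"indicator entry {entry.get('id', '<unnamed>')!r} is missing "
                f"required field {exc}"
            ) from exc
    return Codebook(specs)


def default_codebook_path() -> Path:
    """Path of the packaged SHED April-2020 codebook."""
    return Path(resources.files("mdepriv").joinpath("data/shed_april2020.yaml"))


def load_default_codebook() -> Codebook:
    return load_codebook(default_codebook_path())
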