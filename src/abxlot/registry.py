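"""Closed vocabularies used throughout the pipeline.

Two small configuration tables are shipped with the package and can be
replaced at runtime by hospital-specific files of the same shape:

* the **indication registry** — the closed list of registered-indication
  codes a prescriber can select at order entry, on tract level with a
  further specification for urinary- and respiratory-tract infections,
  plus the indications that in general require more than 21 days of
  treatment (bone/joint infection, S. aureus bacteraemia, ...);
* the **guideline table** — the recommended treatment-duration range
  (min/max calendar days) per indication, after the national Dutch
  guidelines; fixed durations are encoded as min == max.

Codes named ``other`` (on tract or specification level) never receive a
guideline entry and are never assessable for duration adherence.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "Indication",
    "IndicationRegistry",
    "GuidelineEntry",
    "GuidelineTable",
    "packaged_data_path",
]


def packaged_data_path(name: str) -> Path:
    """Return the filesystem path of a packaged data file."""
    return Path(str(resources.files("abxlot") / "data" / name))


@dataclass(frozen=True)
class Indication:
    """One row of the indication registry."""

    code: str
    tract: str
    specification: str | None
    long_treatment: bool

    @property
    def is_other(self) -> bool:
        return self.tract == "other" or self.specification == "other"


class IndicationRegistry:
    """The closed indication-code vocabulary."""

    def __init__(self, table: pd.DataFrame):
        required = {"code", "tract", "specification", "long_treatment"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"indication registry missing columns: {sorted(missing)}")
        if table["code"].duplicated().any():
            raise ValueError("duplicate indication codes in registry")
        self._by_code: dict[str, Indication] = {}
        for row in table.itertuples(index=False):
            spec = row.specification if isinstance(row.specification, str) and row.specification else None
            self._by_code[row.code] = Indication(
                code=row.code,
                tract=row.tract,
                specification=spec,
                long_treatment=bool(int(row.long_treatment)),
            )

    @classmethod
    def from_csv(cls, path: str | Path) -> "IndicationRegistry":
        return cls(pd.read_csv(path, dtype=str, keep_default_na=False))

    @classmethod
    def default(cls) -> "IndicationRegistry":
        return cls.from_csv(packaged_data_path("indications.csv"))

    def __contains__(self, code: object) -> bool:
        return code in self._by_code

    def __len__(self) -> int:
        return len(self._by_code)

    def get(self, code: str) -> Indication:
        return self._by_code[code]

    def codes(self) -> list[str]:
        return list(self._by_code)

    def long_treatment_codes(self) -> list[str]:
        return [c for c, i in self._by_code.items() if i.long_treatment]

    def is_other(self, code: str) -> bool:
        return self._by_code[code].is_other


@dataclass(frozen=True)
class GuidelineEntry:
    """Recommended duration range for one indication, in calendar days."""

    code: str
    min_days: int
    max_days: int

    def __post_init__(self) -> None:
        if not (1 <= self.min_days <= self.max_days):
            raise ValueError(f"invalid guideline range for {self.code}: {self.min_days}-{self.max_days}")


class GuidelineTable:
    """Recommended treatment-duration ranges, at most one entry per code."""

    def __init__(self, entries: list[GuidelineEntry]):
        codes = [e.code for e in entries]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate guideline entries")
        self._by_code = {e.code: e for e in entries}

    @classmethod
    def from_csv(cls, path: str | Path) -> "GuidelineTable":
        df = pd.read_csv(path)
        return cls([
            GuidelineEntry(code=r.code, min_days=int(r.min_days), max_days=int(r.max_days))
            for r in df.itertuples(index=False)
        ])

    @classmethod
    def default(cls) -> "GuidelineTable":
        return cls.from_csv(packaged_data_path("guidelines.csv"))

    def get(self, code: str) -> GuidelineEntry | None:
        return self._by_code.get(code)

    def entries(self) -> list[GuidelineEntry]:
        return list(self._by_code.values())

    def assessable(self, code: str, registry: IndicationRegistry | None = None) -> bool:
        """A course is assessable for duration adherence only when a guideline
        range exists and the code is not an ``other`` category."""
        if code not in self._by_code:
            return False
        if registry is not None and code in registry and registry.is_other(code):
            return False
        # "other" categories are unassessable even in user-supplied tables
        return "other" not in code.lower().split("-")
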