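"""Common prediction vocabulary and model-version identities.

Every vendor-specific (Q)SAR output term is harmonized to one of four
categories: POSITIVE, NEGATIVE, EQUIVOCAL or OOD (out-of-domain). For
consensus purposes the categories carry a severity ordering

    POSITIVE > EQUIVOCAL > OOD > NEGATIVE

so that combining two complementary models reduces to taking the more
severe of the two calls.
"""

from __future__ import annotations

import enum
import functools
from dataclasses import dataclass

__all__ = [
    "Call",
    "CATEGORIES",
    "ModelVersion",
    "ModelId",
    "STATISTICAL",
    "RULE_BASED",
    "MODEL_TYPES",
]

STATISTICAL = "statistical"
RULE_BASED = "rule_based"
MODEL_TYPES = (STATISTICAL, RULE_BASED)


@functools.total_ordering
class Call(enum.Enum):
    """Harmonized prediction category.

    The comparison operators order calls by severity (POSITIVE highest,
    NEGATIVE lowest), which is the ordering used by the consensus rules.
    """

    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    EQUIVOCAL = "EQUIVOCAL"
    OOD = "OOD"

    @property
    def severity(self) -> int:
        return _SEVERITY[self]

    def __lt__(self, other: "Call") -> bool:
        if not isinstance(other, Call):
            return NotImplemented
        return self.severity < other.severity

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_SEVERITY = {
    Call.NEGATIVE: 0,
    Call.OOD: 1,
    Call.EQUIVOCAL: 2,
    Call.POSITIVE: 3,
}

#: Canonical display/reporting order (matches the marginal-count tables:
#: positive, negative, equivocal, out-of-domain).
CATEGORIES: tuple[Call, ...] = (
    Call.POSITIVE,
    Call.NEGATIVE,
    Call.EQUIVOCAL,
    Call.OOD,
)


@dataclass(frozen=True, order=True)
class ModelId:
    """A model identity: one vendor's statistical or rule-based system."""

    vendor: str
    model_type: str

    def __post_init__(self) -> None:
        if self.model_type not in MODEL_TYPES:
            raise ValueError(
                f"model_type must be one of {MODEL_TYPES}, got {self.model_type!r}"
            )

    def __str__(self) -> str:
        return f"{self.vendor}/{self.model_type}"


@dataclass(frozen=True)
class ModelVersion:
    """A released version of one vendor's model.

    (vendor, model_type, version_label) identifies the version uniquely;
    release_year orders versions in time and must be plausible (1990-2100).
    """

    vendor: str
    model_type: str
    version_label: str
    release_year: int

    def __post_init__(self) -> None:
        if self.model_type not in MODEL_TYPES:
            raise ValueError(
                f"model_type must be one of {MODEL_TYPES}, got {self.model_type!r}"
            )
        if not (1990 <= int(self.release_year) <= 2100):
            raise ValueError(
                f"release_year {self.release_year!r} outside plausible range 1990-2100"
            )

    @property
    def model_id(self) -> ModelId:
        return ModelId(self.vendor, self.model_type)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.vendor, self.model_type, self.version_label)

    @property
    def sort_key(self) -> tuple[str, str, int, str]:
        return (self.vendor, self.model_type, self.release_year, self.version_label)

    def __str__(self) -> str:
        return f"{self.vendor}/{self.model_type}/{self.version_label} ({self.release_year})"
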