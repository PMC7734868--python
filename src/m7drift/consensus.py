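"""ICH M7 two-model consensus calls.

The guideline pairs one statistical and one expert rule-based model; the
combined call is:

* positive if at least one model is positive,
* else equivocal if at least one model is equivocal,
* negative only if both models are negative,
* OOD otherwise (negative+OOD and OOD+OOD).

These rules coincide with taking the maximum under the severity order
POSITIVE > EQUIVOCAL > OOD > NEGATIVE; the closed form is kept as an
independent cross-check of the rule list, not as the implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .calls import Call, ModelId, ModelVersion, RULE_BASED, STATISTICAL
from .table import PredictionTable, TableError

__all__ = [
    "ConsensusCombination",
    "consensus_call",
    "consensus_call_closed_form",
    "consensus_calls",
    "consensus_table",
]


@dataclass(frozen=True)
class ConsensusCombination:
    """A statistical x rule-based model pairing, intra- or inter-vendor."""

    stat: ModelId
    rule: ModelId

    def __post_init__(self) -> None:
        if self.stat.model_type != STATISTICAL:
            raise ValueError(f"stat member must be statistical, got {self.stat}")
        if self.rule.model_type != RULE_BASED:
            raise ValueError(f"rule member must be rule_based, got {self.rule}")

    @property
    def label(self) -> str:
        return "intra" if self.stat.vendor == self.rule.vendor else "inter"

    def __str__(self) -> str:
        return f"{self.stat.vendor}-stat + {self.rule.vendor}-rule ({self.label})"


def consensus_call(stat_call: Call, rule_call: Call) -> Call:
    """Combine one statistical and one rule-based call (rule-list form).

    Symmetric in its two arguments. The equivocal+equivocal pair, which
    the enumerated rules do not cover, resolves to equivocal (the
    conservative max-severity extension).
    """
    pair = (stat_call, rule_call)
    if Call.POSITIVE in pair:
        return Call.POSITIVE
    if Call.EQUIVOCAL in pair:
        return Call.EQUIVOCAL
    if stat_call is Call.NEGATIVE and rule_call is Call.NEGATIVE:
        return Call.NEGATIVE
    return Call.OOD


def consensus_call_closed_form(stat_call: Call, rule_call: Call) -> Call:
    """Equivalent closed form: the more severe of the two calls."""
    return max(stat_call, rule_call)


def consensus_calls(
    table: PredictionTable,
    stat_version: ModelVersion,
    rule_version: ModelVersion,
) -> pd.Series:
    """Per-compound consensus vector for two concrete model versions."""
    if stat_version.model_type != STATISTICAL:
        raise ValueError(f"{stat_version} is not a statistical model version")
    if rule_version.model_type != RULE_BASED:
        raise ValueError(f"{rule_version} is not a rule-based model version")
    s = table.calls(stat_version)
    r = table.calls(rule_version)
    return pd.Series(
        [consensus_call(a, b) for a, b in zip(s, r)], index=s.index, name="consensus"
    )


def consensus_table(
    table: PredictionTable,
    combo: ConsensusCombination,
    year: int,
) -> pd.Series:
    """Consensus vector for a combination at a time point.

    Each member model contributes its latest version released in or before
    `year`; a member with no such version raises :class:`TableError`.
    The returned series is tagged with the intra/inter label.
    """
    stat_v = table.version_at(combo.stat.vendor, STATISTICAL, year)
    rule_v = table.version_at(combo.rule.vendor, RULE_BASED, year)
    out = consensus_calls(table, stat_v, rule_v)
    out.attrs["combination"] = str(combo)
    out.attrs["label"] = combo.label
    return out
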