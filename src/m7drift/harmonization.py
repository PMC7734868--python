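"""Vendor-vocabulary harmonization.

Each vendor's raw output term (e.g. "Indeterminate", "Inconclusive",
"Negative with unclassified features") is mapped to the common
four-category vocabulary so predictions from different software and
versions can be tabulated together. The shipped default map covers the
Leadscope, MultiCASE and Lhasa statistical and rule-based systems,
including the Lhasa rule-based special cases (misclassified features ->
NEGATIVE, unclassified features -> OOD, alerting structures with
reasoning equivocal or higher -> POSITIVE).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd
import yaml

from .calls import Call, ModelVersion
from .table import PredictionTable

__all__ = [
    "VocabMap",
    "VocabError",
    "HarmonizationError",
    "load_vocab_map",
    "default_vocab_map",
    "harmonize_call",
    "harmonize_table",
]

REQUIRED_COLUMNS = (
    "compound_id",
    "vendor",
    "model_type",
    "version_label",
    "release_year",
    "raw_call",
)


class VocabError(ValueError):
    """Raised for malformed vocabulary configs (duplicate keys, bad calls)."""


class HarmonizationError(ValueError):
    """Raised for prediction data the vocabulary cannot account for."""


def _norm_term(term: str) -> str:
    return " ".join(str(term).strip().split()).casefold()


def _norm_key(vendor: str, model_type: str, term: str) -> tuple[str, str, str]:
    return (str(vendor).strip().casefold(), str(model_type).strip().casefold(), _norm_term(term))


@dataclass
class VocabMap:
    """Validated (vendor, model_type, raw_term) -> Call lookup.

    Raw terms are matched case-insensitively after whitespace trimming.
    ``forbidden`` lists calls a given model identity must never produce
    (e.g. EQUIVOCAL for the Lhasa rule-based system); ``preferred`` gives
    the canonical raw term to emit per call when writing vendor-style
    output (used by the synthetic generator).
    """

    entries: dict[tuple[str, str, str], Call]
    forbidden: dict[tuple[str, str], frozenset[Call]] = field(default_factory=dict)
    preferred: dict[tuple[str, str, Call], str] = field(default_factory=dict)

    def lookup(self, vendor: str, model_type: str, raw_term: str) -> Call:
        key = _norm_key(vendor, model_type, raw_term)
        try:
            return self.entries[key]
        except KeyError:
            raise HarmonizationError(
                f"unmapped raw term {raw_term!r} for model {vendor}/{model_type}"
            ) from None

    def raw_term_for(self, vendor: str, model_type: str, call: Call) -> str:
        key = (str(vendor).strip().casefold(), str(model_type).strip().casefold(), call)
        try:
            return self.preferred[key]
        except KeyError:
            raise HarmonizationError(
                f"no raw output term for call {call.value} in model {vendor}/{model_type}"
            ) from None

    def validate(self) -> None:
        for (vendor, mtype), calls in self.forbidden.items():
            for key, call in self.entries.items():
                if key[:2] == (vendor, mtype) and call in calls:
                    raise VocabError(
                        f"model {vendor}/{mtype} maps {key[2]!r} to forbidden call {call.value}"
                    )


class _StrictLoader(yaml.SafeLoader):
    """SafeLoader that rejects duplicate mapping keys instead of overwriting."""


def _strict_map(loader, node, deep=False):
    mapping = {}
    for key_node, value_node in node.value:
        key = loader.construct_object(key_node, deep=deep)
        if key in mapping:
            raise VocabError(f"duplicate key {key!r} in vocabulary config")
        mapping[key] = loader.construct_object(value_node, deep=deep)
    return mapping


_StrictLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _strict_map
)


def load_vocab_map(config) -> VocabMap:
    """Build a :class:`VocabMap` from a YAML/JSON path, file object or dict.

    The config is keyed vendor -> model_type -> {terms: raw_term -> call},
    with optional ``forbidden`` and ``preferred`` blocks per model identity.
    Duplicate keys (including case/whitespace variants of the same raw
    term) and unknown call names raise :class:`VocabError`.
    """
    if isinstance(config, Mapping):
        data = config
    elif hasattr(config, "read"):
        data = yaml.load(config.read(), Loader=_StrictLoader)
    else:
        with open(config, "r", encoding="utf-8") as fh:
            data = yaml.load(fh.read(), Loader=_StrictLoader)
    if not isinstance(data, Mapping) or "vendors" not in data:
        raise VocabError("vocabulary config must be a mapping with a 'vendors' block")

    entries: dict[tuple[str, str, str], Call] = {}
    forbidden: dict[tuple[str, str], frozenset[Call]] = {}
    preferred: dict[tuple[str, str, Call], str] = {}
    for vendor, models in data["vendors"].items():
        for model_type, block in models.items():
            ident = (str(vendor).strip().casefold(), str(model_type).strip().casefold())
            terms = block.get("terms", {})
            for raw_term, call_name in terms.items():
                try:
                    call = Call(str(call_name).strip().upper())
                except ValueError:
                    raise VocabError(
                        f"unknown call {call_name!r} for term {raw_term!r} "
                        f"({vendor}/{model_type})"
                    ) from None
                key = _norm_key(vendor, model_type, raw_term)
                if key in entries:
                    raise VocabError(
                        f"duplicate raw term {raw_term!r} for model {vendor}/{model_type}"
                    )
                entries[key] = call
            if "forbidden" in block:
                forbidden[ident] = frozenset(
                    Call(str(c).strip().upper()) for c in block["forbidden"]
                )
            for call_name, term in block.get("preferred", {}).items():
                preferred[(*ident, Call(str(call_name).strip().upper()))] = str(term)

    vm = VocabMap(entries=entries, forbidden=forbidden, preferred=preferred)
    vm.validate()
    return vm


def default_vocab_map() -> VocabMap:
    """The shipped default map over the six vendor/model-type identities."""
    ref = importlib.resources.files("m7drift").joinpath("data/default_vocab.yaml")
    return load_vocab_map(yaml.load(ref.read_text(encoding="utf-8"), Loader=_StrictLoader))


def harmonize_call(raw_term: str, model: ModelVersion, vocab: VocabMap) -> Call:
    """Map one raw vendor term to the common vocabulary (exact lookup after
    case/whitespace normalization); unmapped terms raise
    :class:`HarmonizationError` naming the term and model."""
    return vocab.lookup(model.vendor, model.model_type, raw_term)


def harmonize_table(raw_predictions: pd.DataFrame, vocab: VocabMap) -> PredictionTable:
    """Harmonize a long-form raw prediction table into a complete matrix.

    Input columns: compound_id, vendor, model_type, version_label,
    release_year, raw_call. Every (compound, model-version) cell must be
    present exactly once; duplicates, missing cells, inconsistent release
    years and unmapped terms each raise :class:`HarmonizationError` with
    row coordinates.
    """
    df = pd.DataFrame(raw_predictions).copy()
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise HarmonizationError(f"missing required columns: {missing_cols}")

    key_cols = ["compound_id", "vendor", "model_type", "version_label"]
    dup = df.duplicated(subset=key_cols, keep=False)
    if dup.any():
        rows = df.index[dup].tolist()[:10]
        raise HarmonizationError(
            f"duplicate (compound, model-version) cells at rows {rows}"
        )

    vkey = ["vendor", "model_type", "version_label"]
    years = df.groupby(vkey)["release_year"].nunique()
    bad = years[years > 1]
    if not bad.empty:
        raise HarmonizationError(
            f"inconsistent release_year for model version(s) {bad.index.tolist()}"
        )

    calls = []
    for idx, row in df.iterrows():
        try:
            calls.append(vocab.lookup(row["vendor"], row["model_type"], row["raw_call"]))
        except HarmonizationError as exc:
            raise HarmonizationError(f"row {idx}: {exc}") from None
    df["call"] = calls
    return PredictionTable.from_long(df)
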