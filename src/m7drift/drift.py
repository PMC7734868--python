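"""Version-to-version prediction drift analysis.

Given a complete harmonized prediction table, this module quantifies how
calls move between software versions: 4x4 from/to transition matrices
(cumulative, earliest-to-latest by default), change percentages under a
total-compounds or per-from-category denominator, per-version marginal
counts, the full statistical x rule-based combination grid with
intra/inter-vendor labels, and per-combination unchanged percentages with
their mean.

The :class:`VersionDriftModel` / :class:`VersionDriftResults` pair wraps
the same computations in a fit/results interface: build the model from a
table (or a raw dataframe plus a vocabulary), call ``fit()``, and read
estimates, matrices and a ``summary()`` table off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calls import CATEGORIES, Call, ModelId, ModelVersion, RULE_BASED, STATISTICAL
from .consensus import ConsensusCombination, consensus_table
from .table import PredictionTable, TableError

__all__ = [
    "TransitionMatrix",
    "ChangeSummary",
    "transition_matrix",
    "consensus_transition_matrix",
    "change_percentages",
    "marginal_counts",
    "combination_grid",
    "unchanged_report",
    "conservation_check",
    "check_external_counts",
    "VersionDriftModel",
    "VersionDriftResults",
]

TOTAL = "total"
FROM_CATEGORY = "from_category"
_CAT_INDEX = {c: i for i, c in enumerate(CATEGORIES)}
_CAT_NAMES = [c.value for c in CATEGORIES]


@dataclass
class TransitionMatrix:
    """4x4 from-category/to-category counts between two time points."""

    counts: np.ndarray
    from_label: str
    to_label: str

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (4, 4):
            raise ValueError("transition counts must be 4x4")
        if (self.counts < 0).any():
            raise ValueError("transition counts must be non-negative")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def unchanged(self) -> int:
        return int(np.trace(self.counts))

    def count(self, from_call: Call, to_call: Call) -> int:
        return int(self.counts[_CAT_INDEX[from_call], _CAT_INDEX[to_call]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=_CAT_NAMES, columns=_CAT_NAMES)

    def to_long(self) -> pd.DataFrame:
        rows = [
            {
                "from_call": f.value,
                "to_call": t.value,
                "count": self.count(f, t),
            }
            for f in CATEGORIES
            for t in CATEGORIES
        ]
        return pd.DataFrame(rows)


@dataclass
class ChangeSummary:
    """Transition percentages plus the unchanged percentage.

    TOTAL mode divides every cell by the compound count (so all 16 cells
    sum to 100%); FROM_CATEGORY divides by the row sum, giving conditional
    rates, with empty rows reported as NaN (undefined, not zero). The
    unchanged percentage is always on the total denominator.
    """

    percentages: np.ndarray
    denominator_mode: str
    unchanged_percent: float
    n_total: int

    def percent(self, from_call: Call, to_call: Call) -> float:
        return float(self.percentages[_CAT_INDEX[from_call], _CAT_INDEX[to_call]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.percentages, index=_CAT_NAMES, columns=_CAT_NAMES)


def _count_transitions(frm: Sequence[Call], to: Sequence[Call]) -> np.ndarray:
    counts = np.zeros((4, 4), dtype=int)
    for f, t in zip(frm, to, strict=True):
        counts[_CAT_INDEX[f], _CAT_INDEX[t]] += 1
    return counts


def transition_matrix(
    table: PredictionTable,
    vendor: str,
    model_type: str,
    from_version: str,
    to_version: str,
) -> TransitionMatrix:
    """Cross-tabulate one model's calls between two of its versions."""
    fv = table.find_version(vendor, model_type, from_version)
    tv = table.find_version(vendor, model_type, to_version)
    frm = table.calls(fv)
    to = table.calls(tv)
    return TransitionMatrix(
        counts=_count_transitions(list(frm), list(to)),
        from_label=str(fv),
        to_label=str(tv),
    )


def consensus_transition_matrix(
    table: PredictionTable,
    combo: ConsensusCombination,
    from_year: int,
    to_year: int,
) -> TransitionMatrix:
    """Per-compound consensus at each time point, then transitions counted."""
    frm = consensus_table(table, combo, from_year)
    to = consensus_table(table, combo, to_year)
    return TransitionMatrix(
        counts=_count_transitions(list(frm), list(to)),
        from_label=f"{combo} @ {from_year}",
        to_label=f"{combo} @ {to_year}",
    )


def change_percentages(
    matrix: TransitionMatrix, denominator_mode: str = TOTAL
) -> ChangeSummary:
    """Convert a transition matrix to percentages under the chosen denominator."""
    n = matrix.n_total
    if n <= 0:
        raise ValueError("transition matrix is empty (n_total = 0)")
    counts = matrix.counts.astype(float)
    if denominator_mode == TOTAL:
        pct = 100.0 * counts / n
    elif denominator_mode == FROM_CATEGORY:
        row_sums = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(row_sums > 0, 100.0 * counts / row_sums, np.nan)
    else:
        raise ValueError(f"unknown denominator mode {denominator_mode!r}")
    return ChangeSummary(
        percentages=pct,
        denominator_mode=denominator_mode,
        unchanged_percent=100.0 * matrix.unchanged / n,
        n_total=n,
    )


def marginal_counts(table: PredictionTable, version: ModelVersion) -> dict[Call, int]:
    """Number of compounds in each category for one model version."""
    col = table.calls(version)
    return {c: int(sum(1 for x in col if x is c)) for c in CATEGORIES}


def combination_grid(table: PredictionTable) -> list[ConsensusCombination]:
    """Full Cartesian product of statistical x rule-based model identities."""
    stats = [m for m in table.models if m.model_type == STATISTICAL]
    rules = [m for m in table.models if m.model_type == RULE_BASED]
    if not stats or not rules:
        raise TableError(
            "combination grid needs at least one statistical and one rule-based model"
        )
    return [ConsensusCombination(s, r) for s in stats for r in rules]


def unchanged_report(
    table: PredictionTable,
    grid: Sequence[ConsensusCombination],
    from_year: int,
    to_year: int,
) -> pd.DataFrame:
    """Per-combination unchanged percentage between two years, plus the mean.

    Returns a frame with one row per combination (columns: combination,
    label, unchanged_percent, n) and a final "mean" row carrying the
    arithmetic mean across combinations.
    """
    if not grid:
        raise ValueError("combination grid is empty")
    rows = []
    for combo in grid:
        tm = consensus_transition_matrix(table, combo, from_year, to_year)
        rows.append(
            {
                "combination": str(combo),
                "label": combo.label,
                "unchanged_percent": 100.0 * tm.unchanged / tm.n_total,
                "n": tm.n_total,
            }
        )
    df = pd.DataFrame(rows)
    mean_row = {
        "combination": "mean",
        "label": "",
        "unchanged_percent": float(df["unchanged_percent"].mean()),
        "n": int(df["n"].iloc[0]),
    }
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)


def conservation_check(table: PredictionTable) -> pd.DataFrame:
    """Verify every version's marginal counts sum to the compound total."""
    rows = []
    for v in table.versions:
        counts = marginal_counts(table, v)
        total = sum(counts.values())
        rows.append(
            {
                "version": str(v),
                **{c.value: counts[c] for c in CATEGORIES},
                "sum": total,
                "expected": table.n_compounds,
                "ok": total == table.n_compounds,
            }
        )
    return pd.DataFrame(rows)


def check_external_counts(
    counts: Mapping[str, Mapping[str, int]], expected_total: int
) -> pd.DataFrame:
    """Conservation check on externally entered category counts.

    `counts` maps a version label to {category name: count} (categories
    POSITIVE/NEGATIVE/EQUIVOCAL/OOD; missing categories count as 0, as for
    a model with no equivocal output). Rows that do not sum to
    `expected_total` are flagged, never corrected.
    """
    rows = []
    for label, cat_counts in counts.items():
        parsed = {c: int(cat_counts.get(c.value, 0)) for c in CATEGORIES}
        unknown = set(cat_counts) - {c.value for c in CATEGORIES}
        if unknown:
            raise ValueError(f"unknown categories {sorted(unknown)} for {label!r}")
        total = sum(parsed.values())
        rows.append(
            {
                "version": label,
                **{c.value: parsed[c] for c in CATEGORIES},
                "sum": total,
                "expected": int(expected_total),
                "ok": total == int(expected_total),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model / results interface


class VersionDriftModel:
    """Drift of harmonized (Q)SAR calls across model versions, fit-style.

    Parameters
    ----------
    table : PredictionTable
        Complete harmonized matrix.
    from_year, to_year : int, optional
        Release-year window; defaults to the earliest year at which every
        model has a released version, through the latest year in the
        table. Each model contributes its latest version released in or
        before each endpoint (the cumulative earliest-vs-contemporary
        comparison).
    denominator : {"total", "from_category"}
        Denominator for change percentages (total compounds, matching the
        "% of the compounds" convention, or conditional per-row rates).
    """

    def __init__(
        self,
        table: PredictionTable,
        from_year: int | None = None,
        to_year: int | None = None,
        denominator: str = TOTAL,
    ):
        if denominator not in (TOTAL, FROM_CATEGORY):
            raise ValueError(f"unknown denominator {denominator!r}")
        self.table = table
        if from_year is None:
            # earliest year at which every model has a released version
            from_year = max(
                min(v.release_year for v in table.versions_of(m.vendor, m.model_type))
                for m in table.models
            )
        if to_year is None:
            to_year = max(v.release_year for v in table.versions)
        self.from_year = int(from_year)
        self.to_year = int(to_year)
        if self.from_year > self.to_year:
            raise ValueError("from_year must not exceed to_year")
        self.denominator = denominator

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        vocab=None,
        **kwargs,
    ) -> "VersionDriftModel":
        """Build from a long-form dataframe.

        If the frame has a ``raw_call`` column it is harmonized first
        (with the shipped default vocabulary unless one is given);
        a ``call`` column with category names is taken as already
        harmonized.
        """
        from .harmonization import default_vocab_map, harmonize_table

        df = pd.DataFrame(df)
        if "raw_call" in df.columns:
            table = harmonize_table(df, vocab or default_vocab_map())
        elif "call" in df.columns:
            work = df.copy()
            work["call"] = [
                c if isinstance(c, Call) else Call(str(c).strip().upper())
                for c in work["call"]
            ]
            table = PredictionTable.from_long(work)
        else:
            raise ValueError("dataframe needs a 'raw_call' or 'call' column")
        return cls(table, **kwargs)

    def fit(self) -> "VersionDriftResults":
        table = self.table
        single: dict[ModelId, TransitionMatrix] = {}
        for mid in table.models:
            fv = table.version_at(mid.vendor, mid.model_type, self.from_year)
            tv = table.version_at(mid.vendor, mid.model_type, self.to_year)
            single[mid] = transition_matrix(
                table, mid.vendor, mid.model_type, fv.version_label, tv.version_label
            )
        grid = combination_grid(table)
        cons = {
            combo: consensus_transition_matrix(
                table, combo, self.from_year, self.to_year
            )
            for combo in grid
        }
        marginals = conservation_check(table)
        unchanged = unchanged_report(table, grid, self.from_year, self.to_year)
        return VersionDriftResults(
            model=self,
            single_model_transitions=single,
            consensus_transitions=cons,
            grid=grid,
            marginals=marginals,
            unchanged=unchanged,
        )


@dataclass
class VersionDriftResults:
    """Estimates produced by :meth:`VersionDriftModel.fit`."""

    model: VersionDriftModel
    single_model_transitions: dict[ModelId, TransitionMatrix]
    consensus_transitions: dict[ConsensusCombination, TransitionMatrix]
    grid: list[ConsensusCombination]
    marginals: pd.DataFrame
    unchanged: pd.DataFrame
    _single_pct: dict = field(default_factory=dict, repr=False)
    _cons_pct: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        mode = self.model.denominator
        self._single_pct = {
            mid: change_percentages(tm, mode)
            for mid, tm in self.single_model_transitions.items()
        }
        self._cons_pct = {
            combo: change_percentages(tm, mode)
            for combo, tm in self.consensus_transitions.items()
        }

    # -- scalar estimates --------------------------------------------------

    @property
    def mean_unchanged_percent(self) -> float:
        return float(
            self.unchanged.loc[
                self.unchanged["combination"] == "mean", "unchanged_percent"
            ].iloc[0]
        )

    def single_model_change(self, from_call: Call, to_call: Call) -> pd.Series:
        """Per-model change percentage for one from/to cell."""
        return pd.Series(
            {str(mid): cs.percent(from_call, to_call) for mid, cs in self._single_pct.items()}
        )

    def consensus_change(self, from_call: Call, to_call: Call) -> pd.Series:
        """Per-combination consensus change percentage for one from/to cell."""
        return pd.Series(
            {str(c): cs.percent(from_call, to_call) for c, cs in self._cons_pct.items()}
        )

    def mean_consensus_change(self, from_call: Call, to_call: Call) -> float:
        """Mean over the combination grid (NaN-propagating, as undefined
        conditional rows should poison an average, not vanish from it)."""
        return float(self.consensus_change(from_call, to_call).mean(skipna=False))

    def consensus_change_matrix(self) -> pd.DataFrame:
        """Grid-mean change percentage for every from/to cell."""
        out = np.zeros((4, 4))
        for i, f in enumerate(CATEGORIES):
            for j, t in enumerate(CATEGORIES):
                out[i, j] = self.mean_consensus_change(f, t)
        return pd.DataFrame(out, index=_CAT_NAMES, columns=_CAT_NAMES)

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        m = self.model
        lines = [
            "Version drift analysis",
            "=" * 70,
            f"Compounds: {m.table.n_compounds}   window: {m.from_year}-{m.to_year}   "
            f"denominator: {m.denominator}",
            "",
            "Single-model cumulative changes (% of compounds):",
        ]
        for mid, cs in self._single_pct.items():
            tm = self.single_model_transitions[mid]
            lines.append(
                f"  {str(mid):35s} N->P {cs.percent(Call.NEGATIVE, Call.POSITIVE):5.1f}  "
                f"P->N {cs.percent(Call.POSITIVE, Call.NEGATIVE):5.1f}  "
                f"unchanged {cs.unchanged_percent:5.1f}  (n={tm.n_total})"
            )
        lines += ["", "Consensus combinations:"]
        for combo, cs in self._cons_pct.items():
            lines.append(
                f"  {str(combo):42s} N->P {cs.percent(Call.NEGATIVE, Call.POSITIVE):5.1f}  "
                f"P->N {cs.percent(Call.POSITIVE, Call.NEGATIVE):5.1f}  "
                f"unchanged {cs.unchanged_percent:5.1f}"
            )
        lines += [
            "",
            f"Mean consensus N->P: {self.mean_consensus_change(Call.NEGATIVE, Call.POSITIVE):.1f}%   "
            f"mean P->N: {self.mean_consensus_change(Call.POSITIVE, Call.NEGATIVE):.1f}%   "
            f"mean unchanged: {self.mean_unchanged_percent:.1f}%",
        ]
        return "\n".join(lines)
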