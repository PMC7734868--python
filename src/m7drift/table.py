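"""The complete (compound x model-version) matrix of harmonized calls."""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .calls import Call, ModelId, ModelVersion

__all__ = ["PredictionTable", "TableError"]


class TableError(ValueError):
    """Raised when a prediction table is not a complete, unique matrix."""


class PredictionTable:
    """Complete matrix of harmonized calls over (compound, model-version).

    Internally a wide DataFrame indexed by compound_id with one column per
    :class:`ModelVersion`; construction validates that every compound has
    exactly one call for every listed version. Versions are grouped by
    (vendor, model_type) and ordered by release_year then version_label.
    """

    def __init__(self, wide: pd.DataFrame, versions: Sequence[ModelVersion]):
        versions = sorted(versions, key=lambda v: v.sort_key)
        wide = wide.loc[:, [v for v in versions]]
        if wide.isna().any().any():
            n = int(wide.isna().sum().sum())
            raise TableError(f"incomplete matrix: {n} missing cell(s)")
        for col in wide.columns:
            bad = [x for x in wide[col] if not isinstance(x, Call)]
            if bad:
                raise TableError(f"non-Call value(s) in column {col}: {bad[:3]}")
        self._wide = wide
        self._versions = list(versions)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "PredictionTable":
        """Build from long form with columns compound_id, vendor, model_type,
        version_label, release_year and call (as :class:`Call`)."""
        df = pd.DataFrame(df)
        versions = {}
        for (vendor, mtype, label, year), _ in df.groupby(
            ["vendor", "model_type", "version_label", "release_year"]
        ):
            mv = ModelVersion(str(vendor), str(mtype), str(label), int(year))
            if mv.key in versions:
                raise TableError(f"model version {mv} listed with two release years")
            versions[mv.key] = mv

        key_cols = ["compound_id", "vendor", "model_type", "version_label"]
        if df.duplicated(subset=key_cols).any():
            raise TableError("duplicate (compound, model-version) cells")
        wide = df.pivot(
            index="compound_id",
            columns=["vendor", "model_type", "version_label"],
            values="call",
        )
        wide.columns = [
            versions[(str(a), str(b), str(c))] for a, b, c in wide.columns
        ]
        return cls(wide, list(versions.values()))

    # -- basic accessors ---------------------------------------------------

    @property
    def compounds(self) -> list[str]:
        return list(self._wide.index)

    @property
    def n_compounds(self) -> int:
        return len(self._wide.index)

    @property
    def versions(self) -> list[ModelVersion]:
        return list(self._versions)

    @property
    def models(self) -> list[ModelId]:
        seen: dict[ModelId, None] = {}
        for v in self._versions:
            seen.setdefault(v.model_id)
        return list(seen)

    def versions_of(self, vendor: str, model_type: str) -> list[ModelVersion]:
        return [
            v
            for v in self._versions
            if v.vendor == vendor and v.model_type == model_type
        ]

    def find_version(
        self, vendor: str, model_type: str, version_label: str
    ) -> ModelVersion:
        for v in self._versions:
            if v.key == (vendor, model_type, version_label):
                return v
        raise TableError(f"version {vendor}/{model_type}/{version_label} not in table")

    def version_at(self, vendor: str, model_type: str, year: int) -> ModelVersion:
        """Latest version of the model released in or before `year`."""
        cands = [
            v
            for v in self.versions_of(vendor, model_type)
            if v.release_year <= year
        ]
        if not cands:
            raise TableError(
                f"no version of {vendor}/{model_type} released by {year}"
            )
        return cands[-1]

    def calls(self, version: ModelVersion) -> pd.Series:
        """Per-compound call vector for one model version."""
        if version not in self._wide.columns:
            raise TableError(f"version {version} not in table")
        return self._wide[version]

    # -- export ------------------------------------------------------------

    def to_long(self) -> pd.DataFrame:
        rows = []
        for v in self._versions:
            col = self._wide[v]
            for cid, call in col.items():
                rows.append(
                    {
                        "compound_id": cid,
                        "vendor": v.vendor,
                        "model_type": v.model_type,
                        "version_label": v.version_label,
                        "release_year": v.release_year,
                        "call": call.value,
                    }
                )
        return pd.DataFrame(rows)

    def filter_years(self, min_year: int | None = None, max_year: int | None = None) -> "PredictionTable":
        """Restrict to versions inside a release-year window (inclusive)."""
        keep = [
            v
            for v in self._versions
            if (min_year is None or v.release_year >= min_year)
            and (max_year is None or v.release_year <= max_year)
        ]
        if not keep:
            raise TableError("year window leaves no versions")
        return PredictionTable(self._wide.loc[:, keep], keep)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PredictionTable):
            return NotImplemented
        return self._versions == other._versions and self._wide.equals(other._wide)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<PredictionTable {self.n_compounds} compounds x "
            f"{len(self._versions)} model versions>"
        )
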