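"""Readers and writers for the pipeline's file formats.

Structures come in as SMILES files (one per line, optional tab-separated
id), CSV with id,smiles columns, or SDF (via RDKit). Predictions travel
as long-form CSV (compound_id, vendor, model_type, version_label,
release_year, raw_call or call). All CSVs are UTF-8, comma-delimited,
with a mandatory header row.
"""

from __future__ import annotations

import os
from typing import Sequence

import pandas as pd
from rdkit import Chem

from .curation import CompoundRecord, SimilarityGraph

__all__ = [
    "read_structures",
    "write_records",
    "read_predictions",
    "write_predictions",
    "write_edge_list",
    "write_alert_profile",
]


def read_structures(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read (id, smiles) pairs from .smi/.txt, .csv or .sdf by extension.

    SMILES lines may be "SMILES" or "SMILES<TAB>id"; missing ids are
    numbered from the file's base name.
    """
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    base = os.path.splitext(os.path.basename(path))[0]
    if ext == ".csv":
        df = pd.read_csv(path, dtype=str)
        cols = {c.lower(): c for c in df.columns}
        if "smiles" not in cols:
            raise ValueError(f"{path}: CSV needs a 'smiles' column")
        id_col = cols.get("id") or cols.get("compound_id")
        out = []
        for i, row in df.iterrows():
            cid = str(row[id_col]) if id_col else f"{base}-{i + 1:04d}"
            out.append((cid, str(row[cols["smiles"]])))
        return out
    if ext == ".sdf":
        out = []
        supplier = Chem.SDMolSupplier(path, sanitize=False)
        for i, mol in enumerate(supplier, start=1):
            if mol is None:
                out.append((f"{base}-{i:04d}", ""))  # kept as an INVALID record
                continue
            cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"{base}-{i:04d}"
            out.append((cid, Chem.MolToSmiles(mol)))
        return out
    # default: one structure per line, optional tab-separated id
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smi = parts[0].strip()
            cid = parts[1].strip() if len(parts) > 1 and parts[1].strip() else f"{base}-{i:04d}"
            out.append((cid, smi))
    return out


def write_records(records: Sequence[CompoundRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "smiles_raw": r.smiles_raw,
                "smiles_std": r.smiles_std or "",
                "status": r.status,
                "reject_reason": r.reject_reason or "",
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def read_predictions(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={
            "compound_id": str,
            "vendor": str,
            "model_type": str,
            "version_label": str,
        },
    )
    if "release_year" in df.columns:
        df["release_year"] = df["release_year"].astype(int)
    return df


def write_predictions(df: pd.DataFrame, path) -> None:
    pd.DataFrame(df).to_csv(path, index=False)


def write_edge_list(graph: SimilarityGraph, path) -> None:
    pd.DataFrame(
        graph.edge_list(), columns=["source", "target", "weight"]
    ).to_csv(path, index=False)


def write_alert_profile(profile, path) -> None:
    rows = [
        {"alert": name, "count": count} for name, count in profile.counts.items()
    ]
    rows.append({"alert": "other", "count": profile.other})
    df = pd.DataFrame(rows)
    df["total_compounds"] = profile.total_compounds
    df.to_csv(path, index=False)
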