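"""Chemical-space-matched dataset curation.

Implements the curation funnel used to build an impurity-like evaluation
set from an arbitrary structure pool: standardize every structure
(validation, normalization, contextualization), reject mixtures and
structures containing metals outside groups I/II, fingerprint the
survivors with linear fragment paths, keep the query compounds whose best
Tanimoto similarity to a reference set reaches a cutoff, drop structures
that also occur in exclusion sets (model training sets, assay databases),
and profile structural-alert (SMARTS) frequencies. A thresholded
similarity graph over query+reference compounds is exposed for cluster /
singleton analysis and export to external layout tools.
"""

from __future__ import annotations

import hashlib
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "CompoundRecord",
    "Fingerprint",
    "SimilarityGraph",
    "AlertProfile",
    "StandardizationPolicy",
    "DEFAULT_POLICY",
    "standardize_structure",
    "standardize_all",
    "fragment_fingerprint",
    "tanimoto",
    "select_similar",
    "exclude_known",
    "build_similarity_graph",
    "profile_alerts",
    "CurationResult",
    "curate",
]

# Rejection reasons, checked in this fixed order per structure.
INVALID = "INVALID"
MIXTURE = "MIXTURE"
DISALLOWED_METAL = "DISALLOWED_METAL"
EXCLUDED_KNOWN = "EXCLUDED_KNOWN"

GROUP_I = frozenset({"Li", "Na", "K", "Rb", "Cs", "Fr"})
GROUP_II = frozenset({"Be", "Mg", "Ca", "Sr", "Ba", "Ra"})
#: Organic subset: anything else (other than group I/II metals) is rejected.
ORGANIC_ELEMENTS = frozenset(
    {"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Br", "I", "Se"}
)


@dataclass(frozen=True)
class StandardizationPolicy:
    """Configuration of the validation/normalization/contextualization step.

    allowed_elements : elements accepted in the organic parent
    allowed_metals   : metals accepted (group I/II by default); single-atom
                       fragments of these are stripped as counterions before
                       the mixture test
    neutralize       : neutralize charges where valence allows
    strip_stereo     : remove stereochemistry (contextualization)
    strip_isotopes   : remove isotope labels (contextualization)
    """

    allowed_elements: frozenset[str] = ORGANIC_ELEMENTS
    allowed_metals: frozenset[str] = GROUP_I | GROUP_II
    neutralize: bool = True
    strip_stereo: bool = True
    strip_isotopes: bool = True


DEFAULT_POLICY = StandardizationPolicy()


@dataclass
class CompoundRecord:
    """One input structure with its standardization outcome."""

    compound_id: str
    smiles_raw: str
    smiles_std: str | None = None
    status: str = "KEPT"  # KEPT | REJECTED
    reject_reason: str | None = None

    @property
    def kept(self) -> bool:
        return self.status == "KEPT"


def _parse(raw: str) -> Chem.Mol | None:
    try:
        return Chem.MolFromSmiles(raw)
    except Exception:
        return None


def standardize_structure(
    raw: str,
    compound_id: str = "",
    policy: StandardizationPolicy = DEFAULT_POLICY,
) -> CompoundRecord:
    """Standardize one structure line into a :class:`CompoundRecord`.

    Failures are encoded as REJECTED records (never raised), with the first
    failing reason in the fixed order INVALID -> DISALLOWED_METAL -> MIXTURE.
    Group I/II counterion fragments are stripped before the mixture test, so
    simple alkali / alkaline-earth salts survive as their organic parent.
    """
    rec = CompoundRecord(compound_id=compound_id, smiles_raw=raw)
    raw = (raw or "").strip()
    if not raw:
        return _reject(rec, INVALID)
    mol = _parse(raw)
    if mol is None:
        return _reject(rec, INVALID)

    symbols = {a.GetSymbol() for a in mol.GetAtoms()}
    allowed = policy.allowed_elements | policy.allowed_metals
    if not symbols <= allowed:
        return _reject(rec, DISALLOWED_METAL)

    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    parents = [
        f
        for f in frags
        if not all(a.GetSymbol() in policy.allowed_metals for a in f.GetAtoms())
    ]
    if not parents:
        # nothing but counterions (e.g. "[Na+]"): no organic parent to keep
        return _reject(rec, INVALID)
    if len(parents) > 1:
        return _reject(rec, MIXTURE)

    mol = parents[0]
    try:
        Chem.SanitizeMol(mol)
        if policy.neutralize:
            mol = rdMolStandardize.Uncharger().uncharge(mol)
        if policy.strip_stereo:
            Chem.RemoveStereochemistry(mol)
        if policy.strip_isotopes:
            for atom in mol.GetAtoms():
                atom.SetIsotope(0)
        Chem.SanitizeMol(mol)
        rec.smiles_std = Chem.MolToSmiles(mol)
    except Exception:
        return _reject(rec, INVALID)
    return rec


def _reject(rec: CompoundRecord, reason: str) -> CompoundRecord:
    rec.status = "REJECTED"
    rec.reject_reason = reason
    rec.smiles_std = None
    return rec


def standardize_all(
    structures: Iterable[tuple[str, str] | str],
    policy: StandardizationPolicy = DEFAULT_POLICY,
    id_prefix: str = "C",
) -> list[CompoundRecord]:
    """Standardize an iterable of SMILES or (id, SMILES) pairs.

    Bare strings are given sequential ids ``{id_prefix}0001`` etc.
    Duplicate ids raise ValueError (ids must be unique within a dataset).
    """
    records: list[CompoundRecord] = []
    seen: set[str] = set()
    for i, item in enumerate(structures, start=1):
        if isinstance(item, str):
            cid, smi = f"{id_prefix}{i:04d}", item
        else:
            cid, smi = item
        if cid in seen:
            raise ValueError(f"duplicate compound_id {cid!r}")
        seen.add(cid)
        records.append(standardize_structure(smi, cid, policy))
    return records


# ---------------------------------------------------------------------------
# fragment fingerprints


@dataclass(frozen=True)
class Fingerprint:
    """Set of hashed linear-fragment identifiers at a given path depth."""

    bits: frozenset[int]
    depth: int

    def __len__(self) -> int:
        return len(self.bits)


_BOND_TOKEN = {
    Chem.BondType.SINGLE: "-",
    Chem.BondType.DOUBLE: "=",
    Chem.BondType.TRIPLE: "#",
    Chem.BondType.AROMATIC: ":",
}


def _atom_token(atom: Chem.Atom) -> str:
    sym = atom.GetSymbol()
    return sym.lower() if atom.GetIsAromatic() else sym


def _hash64(tokens: Sequence[str]) -> int:
    digest = hashlib.blake2b("|".join(tokens).encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big")


def fragment_fingerprint(structure: str | Chem.Mol, depth: int = 7) -> Fingerprint:
    """Hash all linear atom-bond paths of 0..`depth` bonds into a bit set.

    Atoms are typed by element + aromaticity, bonds by bond order; each
    path is labelled by the lexicographically smaller of its two reading
    directions, so the bit set is independent of atom numbering and of the
    input SMILES writing. Raises ValueError on an unparseable structure.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if isinstance(structure, Chem.Mol):
        mol = structure
    else:
        mol = _parse(structure)
        if mol is None:
            raise ValueError(f"unparseable structure: {structure!r}")

    bits: set[int] = set()
    atoms = list(mol.GetAtoms())
    for atom in atoms:
        bits.add(_hash64((_atom_token(atom),)))

    def extend(last: Chem.Atom, visited: list[int], tokens: list[str]) -> None:
        if (len(tokens) - 1) // 2 >= depth:
            return
        for bond in last.GetBonds():
            nbr = bond.GetOtherAtom(last)
            if nbr.GetIdx() in visited:
                continue
            btok = _BOND_TOKEN.get(bond.GetBondType(), str(bond.GetBondType()))
            new_tokens = tokens + [btok, _atom_token(nbr)]
            canon = min(tuple(new_tokens), tuple(reversed(new_tokens)))
            bits.add(_hash64(canon))
            extend(nbr, visited + [nbr.GetIdx()], new_tokens)

    for atom in atoms:
        extend(atom, [atom.GetIdx()], [_atom_token(atom)])
    return Fingerprint(bits=frozenset(bits), depth=depth)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|a∩b| / |a∪b| over fragment bit sets.

    Both fingerprints must come from the same depth setting. Two empty
    sets (empty molecules) compare as 1.0 by convention.
    """
    if a.depth != b.depth:
        raise ValueError(f"fingerprint depth mismatch: {a.depth} vs {b.depth}")
    if not a.bits and not b.bits:
        return 1.0
    inter = len(a.bits & b.bits)
    union = len(a.bits | b.bits)
    return inter / union


# ---------------------------------------------------------------------------
# similarity selection / graph


def _fps(records: Sequence[CompoundRecord], depth: int) -> dict[str, Fingerprint]:
    out = {}
    for r in records:
        if not r.kept or r.smiles_std is None:
            raise ValueError(f"record {r.compound_id!r} is not a KEPT standardized record")
        out[r.compound_id] = fragment_fingerprint(r.smiles_std, depth)
    return out


def select_similar(
    query: Sequence[CompoundRecord],
    reference: Sequence[CompoundRecord],
    cutoff: float = 0.5,
    depth: int = 7,
) -> list[str]:
    """Ids of query compounds whose best Tanimoto to the reference set >= cutoff.

    Each id appears once regardless of how many reference structures it
    matches (dataset membership is a set). Query order is preserved.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    if not reference:
        raise ValueError("reference set is empty")
    qfp = _fps(query, depth)
    rfp = _fps(reference, depth)
    selected = []
    for rec in query:
        best = max(tanimoto(qfp[rec.compound_id], f) for f in rfp.values())
        if best >= cutoff:
            selected.append(rec.compound_id)
    return selected


def exclude_known(
    selected: Sequence[str],
    records: Sequence[CompoundRecord] | Mapping[str, CompoundRecord],
    exclusion_sets: Iterable[Iterable[str]],
    policy: StandardizationPolicy = DEFAULT_POLICY,
) -> list[str]:
    """Drop selected ids whose standardized structure occurs in any exclusion set.

    Exclusion structures are standardized with the same policy, so the match
    is structural (canonical-form equality), not id-based: duplicate
    structures under different ids are all removed. Order is preserved.
    """
    by_id = (
        dict(records)
        if isinstance(records, Mapping)
        else {r.compound_id: r for r in records}
    )
    excluded_forms: set[str] = set()
    for exclusion in exclusion_sets:
        for smi in exclusion:
            rec = standardize_structure(smi, policy=policy)
            if rec.kept and rec.smiles_std:
                excluded_forms.add(rec.smiles_std)
    out = []
    for cid in selected:
        rec = by_id[cid]
        if rec.smiles_std not in excluded_forms:
            out.append(cid)
    return out


@dataclass
class SimilarityGraph:
    """Thresholded Tanimoto similarity graph over query + reference compounds."""

    graph: nx.Graph
    threshold: float

    @property
    def n_components(self) -> int:
        return nx.number_connected_components(self.graph)

    @property
    def n_singletons(self) -> int:
        return sum(1 for n in self.graph.nodes if self.graph.degree(n) == 0)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_list(self) -> list[tuple[str, str, float]]:
        return [
            (u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)
        ]

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def build_similarity_graph(
    query: Sequence[CompoundRecord],
    reference: Sequence[CompoundRecord],
    threshold: float = 0.5,
    depth: int = 7,
) -> SimilarityGraph:
    """All-pairs (within and between sets) Tanimoto graph at a threshold.

    Nodes carry a ``dataset`` label (query vs reference); edges exist for
    every unordered pair with similarity >= threshold; no self-edges.
    Compound ids must be unique across the union of the two sets.
    """
    ids = [r.compound_id for r in query] + [r.compound_id for r in reference]
    if len(set(ids)) != len(ids):
        raise ValueError("compound ids must be unique across query and reference sets")
    g = nx.Graph()
    fps: dict[str, Fingerprint] = {}
    for label, records in (("query", query), ("reference", reference)):
        for r in records:
            g.add_node(r.compound_id, dataset=label)
        fps.update(_fps(records, depth))
    order = list(fps)
    for i, u in enumerate(order):
        for v in order[i + 1 :]:
            w = tanimoto(fps[u], fps[v])
            if w >= threshold:
                g.add_edge(u, v, weight=w)
    return SimilarityGraph(graph=g, threshold=threshold)


# ---------------------------------------------------------------------------
# structural-alert profiling


@dataclass
class AlertProfile:
    """Per-alert compound counts with an "other" bin outside the top_k."""

    counts: dict[str, int]  # top_k alerts, descending count then name
    other: int
    total_compounds: int
    top_k: int
    all_counts: dict[str, int] = field(default_factory=dict)


def profile_alerts(
    compounds: Sequence[CompoundRecord],
    alerts: Sequence[tuple[str, str]],
    top_k: int = 6,
) -> AlertProfile:
    """Count compounds matching each named SMARTS alert; bin the tail as "other".

    A compound counts once per alert no matter how many times the pattern
    occurs in it. Ranks are by descending count with ties broken by alert
    name; alerts outside the top_k are summed into the "other" bin.
    Unparseable SMARTS raise ValueError.
    """
    if top_k < 0:
        raise ValueError("top_k must be >= 0")
    patterns = []
    for name, smarts in alerts:
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"invalid SMARTS for alert {name!r}: {smarts!r}")
        patterns.append((name, patt))

    counter: Counter[str] = Counter({name: 0 for name, _ in patterns})
    mols = []
    for rec in compounds:
        if rec.kept and rec.smiles_std:
            m = _parse(rec.smiles_std)
            if m is not None:
                mols.append(m)
    for name, patt in patterns:
        counter[name] = sum(1 for m in mols if m.HasSubstructMatch(patt))

    ranked = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    top = dict(ranked[:top_k])
    other = sum(c for _, c in ranked[top_k:])
    return AlertProfile(
        counts=top,
        other=other,
        total_compounds=len(mols),
        top_k=top_k,
        all_counts=dict(ranked),
    )


# ---------------------------------------------------------------------------
# end-to-end funnel


@dataclass
class CurationResult:
    """Outcome of the full curation funnel with conservation bookkeeping."""

    records: list[CompoundRecord]
    selected_ids: list[str]
    final_ids: list[str]

    @property
    def kept_ids(self) -> list[str]:
        return [r.compound_id for r in self.records if r.kept]

    @property
    def excluded_ids(self) -> list[str]:
        final = set(self.final_ids)
        return [cid for cid in self.selected_ids if cid not in final]

    def funnel(self) -> dict[str, int]:
        reasons = Counter(
            r.reject_reason for r in self.records if not r.kept
        )
        return {
            "input": len(self.records),
            "kept": len(self.kept_ids),
            **{f"rejected_{k.lower()}": v for k, v in sorted(reasons.items())},
            "selected": len(self.selected_ids),
            "excluded_known": len(self.excluded_ids),
            "final": len(self.final_ids),
        }


def curate(
    query: Iterable[tuple[str, str] | str],
    reference: Iterable[tuple[str, str] | str],
    cutoff: float = 0.5,
    depth: int = 7,
    exclusion_sets: Iterable[Iterable[str]] = (),
    policy: StandardizationPolicy = DEFAULT_POLICY,
) -> CurationResult:
    """Run the whole funnel: standardize, similarity-select, exclude known."""
    q_records = standardize_all(query, policy, id_prefix="Q")
    r_records = [r for r in standardize_all(reference, policy, id_prefix="R") if r.kept]
    kept = [r for r in q_records if r.kept]
    selected = select_similar(kept, r_records, cutoff=cutoff, depth=depth)
    final = exclude_known(selected, kept, exclusion_sets, policy)
    dropped = set(selected) - set(final)
    for rec in q_records:
        # structural match against an exclusion set; canonical form retained
        if rec.compound_id in dropped:
            rec.status = "REJECTED"
            rec.reject_reason = EXCLUDED_KNOWN
    return CurationResult(records=q_records, selected_ids=selected, final_ids=final)
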