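"""Synthetic study-condition generator.

Two generators make every analysis stage testable without proprietary
software: (a) multi-vendor, multi-version categorical prediction
histories — per-compound calls drawn from per-model initial marginals and
evolved version-to-version by row-stochastic 4x4 transition kernels, with
an optional shared latent "true mutagenicity" Bernoulli coupling a
vendor's statistical and rule-based models — and (b) small
drug-impurity-like organic structures assembled from a scaffold +
substituent grammar that echoes the common mutagenicity alert classes
(aryl amines, nitroaromatics, acyl halides, alkyl esters, aldehydes,
epoxides), with a configurable fraction of deliberate defects (mixtures,
disallowed metals, exact duplicates) to exercise the curation filters.

The default history spec mirrors the published study conditions: 3367
compounds, three vendors each contributing a statistical and a rule-based
model with a 2014 and a 2018 release, initial marginals read off the
published per-version category counts, and kernels of the magnitude of
the reported cumulative changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .calls import CATEGORIES, Call, RULE_BASED, STATISTICAL
from .table import PredictionTable

__all__ = [
    "ModelHistorySpec",
    "HistorySpec",
    "simulate_history",
    "to_raw_frame",
    "generate_structures",
    "default_history_spec",
    "coupled_conditionals",
]

_TOL = 1e-9


def _as_prob_vector(v, what: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.shape != (4,):
        raise ValueError(f"{what} must have 4 entries (P, N, E, OOD order)")
    if (arr < 0).any() or abs(arr.sum() - 1.0) > _TOL:
        raise ValueError(f"{what} must be non-negative and sum to 1")
    return arr


def _as_kernel(k, what: str) -> np.ndarray:
    arr = np.asarray(k, dtype=float)
    if arr.shape != (4, 4):
        raise ValueError(f"{what} must be 4x4")
    if (arr < 0).any() or (np.abs(arr.sum(axis=1) - 1.0) > _TOL).any():
        raise ValueError(f"{what} rows must be non-negative and sum to 1")
    return arr


@dataclass
class ModelHistorySpec:
    """One model's version history and stochastic behaviour.

    Category vectors and kernel rows/columns follow the order
    POSITIVE, NEGATIVE, EQUIVOCAL, OOD.

    conditional_initial, when given together with a spec-level latent
    prevalence, is a 2x4 matrix of initial-call distributions given the
    compound's latent mutagenicity (row 0: non-mutagenic, row 1:
    mutagenic); it must be consistent with `initial` only in the sense
    that both are valid distributions — the latent mixture replaces the
    unconditional draw.
    """

    vendor: str
    model_type: str
    versions: Sequence[tuple[str, int]]  # (version_label, release_year)
    initial: np.ndarray
    kernels: Sequence[np.ndarray]  # one per version step
    conditional_initial: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.model_type not in (STATISTICAL, RULE_BASED):
            raise ValueError(f"bad model_type {self.model_type!r}")
        if not self.versions:
            raise ValueError("at least one version required")
        self.initial = _as_prob_vector(self.initial, f"{self.vendor} initial marginals")
        self.kernels = [
            _as_kernel(k, f"{self.vendor}/{self.model_type} kernel step {i}")
            for i, k in enumerate(self.kernels)
        ]
        if len(self.kernels) != len(self.versions) - 1:
            raise ValueError(
                f"{self.vendor}/{self.model_type}: need one kernel per version step "
                f"({len(self.versions) - 1}), got {len(self.kernels)}"
            )
        if self.conditional_initial is not None:
            ci = np.asarray(self.conditional_initial, dtype=float)
            if ci.shape != (2, 4):
                raise ValueError("conditional_initial must be 2x4")
            for row in ci:
                _as_prob_vector(row, "conditional initial marginals")
            self.conditional_initial = ci


@dataclass
class HistorySpec:
    """Full specification of a synthetic multi-model prediction history."""

    n_compounds: int
    models: Sequence[ModelHistorySpec]
    seed: int
    latent_prevalence: float | None = None

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be >= 1")
        if not self.models:
            raise ValueError("at least one model required")
        if self.latent_prevalence is not None and not (
            0.0 <= self.latent_prevalence <= 1.0
        ):
            raise ValueError("latent_prevalence must be in [0, 1]")


def coupled_conditionals(
    marginals, prevalence: float, strength: float = 0.9
) -> np.ndarray:
    """Conditional initial distributions preserving given marginals.

    Splits an unconditional category vector m into distributions given the
    latent mutagenicity flag such that prevalence-weighted mixing returns
    m exactly. `strength` in (0, 1] sets how much of the maximum feasible
    positive-call enrichment the mutagenic stratum receives
    (P(call=POS | mutagenic) = strength * min(1, m_P / prevalence)).
    """
    m = _as_prob_vector(marginals, "marginals")
    if not (0 < prevalence < 1):
        raise ValueError("prevalence must be in (0, 1)")
    if not (0 < strength <= 1):
        raise ValueError("strength must be in (0, 1]")
    p_pos_mut = strength * min(1.0, m[0] / prevalence)
    p_pos_non = (m[0] - prevalence * p_pos_mut) / (1.0 - prevalence)
    rest = m[1:]
    rest_frac = rest / rest.sum() if rest.sum() > 0 else np.array([1.0, 0.0, 0.0])
    cond_mut = np.concatenate([[p_pos_mut], (1 - p_pos_mut) * rest_frac])
    cond_non = np.concatenate([[p_pos_non], (1 - p_pos_non) * rest_frac])
    return np.vstack([cond_non, cond_mut])


def simulate_history(spec: HistorySpec) -> PredictionTable:
    """Draw a complete harmonized prediction table from a history spec.

    Per model: initial calls from the initial marginals (or from the
    latent-conditional marginals when coupling is on), then evolved
    version-to-version by the model's kernels, independently per compound.
    Fully reproducible for a fixed seed; each model gets its own
    deterministic substream.
    """
    streams = np.random.SeedSequence(spec.seed).spawn(len(spec.models) + 1)
    latent_rng = np.random.default_rng(streams[0])
    if spec.latent_prevalence is not None:
        latent = latent_rng.random(spec.n_compounds) < spec.latent_prevalence
    else:
        latent = None

    compounds = [f"C{i:05d}" for i in range(1, spec.n_compounds + 1)]
    frames = []
    for model, stream in zip(spec.models, streams[1:]):
        rng = np.random.default_rng(stream)
        if latent is not None and model.conditional_initial is not None:
            state = np.empty(spec.n_compounds, dtype=int)
            for flag in (0, 1):
                mask = latent == bool(flag)
                state[mask] = rng.choice(
                    4, size=int(mask.sum()), p=model.conditional_initial[flag]
                )
        else:
            state = rng.choice(4, size=spec.n_compounds, p=model.initial)

        states = [state]
        for kernel in model.kernels:
            nxt = np.empty_like(state)
            for cat in range(4):
                mask = state == cat
                if mask.any():
                    nxt[mask] = rng.choice(4, size=int(mask.sum()), p=kernel[cat])
            state = nxt
            states.append(state)

        for (label, year), st in zip(model.versions, states, strict=True):
            frames.append(
                pd.DataFrame(
                    {
                        "compound_id": compounds,
                        "vendor": model.vendor,
                        "model_type": model.model_type,
                        "version_label": label,
                        "release_year": year,
                        "call": [CATEGORIES[i] for i in st],
                    }
                )
            )
    return PredictionTable.from_long(pd.concat(frames, ignore_index=True))


def to_raw_frame(table: PredictionTable, vocab) -> pd.DataFrame:
    """Render a harmonized table in the vendor-vocabulary CSV dialect.

    Each call is written as the model's preferred raw term so the
    harmonization stage can be exercised end-to-end on synthetic data.
    """
    long = table.to_long()
    long["raw_call"] = [
        vocab.raw_term_for(v, m, Call(c))
        for v, m, c in zip(long["vendor"], long["model_type"], long["call"])
    ]
    return long.drop(columns=["call"])


# ---------------------------------------------------------------------------
# study-shaped default spec


def _kernel(np_=0.0, ne=0.0, no=0.0, pn=0.0, pe=0.0, po=0.0,
            ep=0.0, en=0.0, eo=0.0, op=0.0, on=0.0, oe=0.0) -> np.ndarray:
    """Build a 4x4 kernel (P, N, E, OOD order) from off-diagonal rates."""
    k = np.array(
        [
            [1 - pn - pe - po, pn, pe, po],
            [np_, 1 - np_ - ne - no, ne, no],
            [ep, en, 1 - ep - en - eo, eo],
            [op, on, oe, 1 - op - on - oe],
        ]
    )
    return _as_kernel(k, "kernel")


def _marg(counts) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    return arr / arr.sum()


#: Initial category fractions per model, read off the published 2014-era
#: per-version counts (normalized by their own row sum), order P, N, E, OOD.
_DEFAULT_MARGINALS = {
    ("Leadscope", STATISTICAL): _marg([505, 2413, 287, 162]),
    ("Leadscope", RULE_BASED): _marg([1031, 2216, 41, 79]),
    ("MultiCASE", STATISTICAL): _marg([683, 1961, 530, 193]),
    ("MultiCASE", RULE_BASED): _marg([1014, 2134, 16, 201]),
    ("Lhasa", STATISTICAL): _marg([593, 2058, 553, 163]),
    ("Lhasa", RULE_BASED): _marg([1009, 2256, 0, 102]),
}

#: Cumulative 2014->2018 kernels (conditional rates), magnitudes set from
#: the reported per-category cumulative change ranges: negative-to-positive
#: small everywhere (<5% of compounds), the young Leadscope rule-based and
#: Lhasa statistical systems moving most, the mature Lhasa rule-based
#: system nearly static apart from its negative->OOD reclassification, and
#: out-of-domain pools shrinking (mostly into negative) for every model.
_DEFAULT_KERNELS = {
    ("Leadscope", STATISTICAL): _kernel(
        np_=0.020, ne=0.030, no=0.002, pn=0.080, pe=0.050, po=0.002,
        ep=0.050, en=0.250, eo=0.005, op=0.050, on=0.300, oe=0.050,
    ),
    ("Leadscope", RULE_BASED): _kernel(
        np_=0.030, ne=0.080, no=0.001, pn=0.120, pe=0.150, po=0.001,
        ep=0.050, en=0.100, eo=0.005, op=0.050, on=0.250, oe=0.030,
    ),
    ("MultiCASE", STATISTICAL): _kernel(
        np_=0.010, ne=0.050, no=0.002, pn=0.050, pe=0.030, po=0.002,
        ep=0.020, en=0.080, eo=0.005, op=0.030, on=0.200, oe=0.020,
    ),
    ("MultiCASE", RULE_BASED): _kernel(
        np_=0.020, ne=0.010, no=0.002, pn=0.100, pe=0.020, po=0.002,
        ep=0.050, en=0.200, eo=0.005, op=0.040, on=0.200, oe=0.010,
    ),
    ("Lhasa", STATISTICAL): _kernel(
        np_=0.040, ne=0.020, no=0.002, pn=0.060, pe=0.080, po=0.002,
        ep=0.100, en=0.200, eo=0.005, op=0.050, on=0.150, oe=0.020,
    ),
    ("Lhasa", RULE_BASED): _kernel(
        np_=0.005, ne=0.0, no=0.030, pn=0.020, pe=0.0, po=0.001,
        op=0.010, on=0.050,
    ),
}


def default_history_spec(
    n_compounds: int = 3367,
    seed: int = 0,
    latent_prevalence: float | None = 0.30,
    coupling_strength: float = 0.9,
) -> HistorySpec:
    """Three vendors x (statistical, rule-based), one 2014->2018 step each.

    Initial marginals and kernel magnitudes mirror the published study
    conditions; the latent-Bernoulli coupling (prevalence 0.30, about the
    positive-call fraction) correlates each vendor's two models.
    """
    models = []
    for (vendor, mtype), marg in _DEFAULT_MARGINALS.items():
        cond = (
            coupled_conditionals(marg, latent_prevalence, coupling_strength)
            if latent_prevalence is not None
            else None
        )
        models.append(
            ModelHistorySpec(
                vendor=vendor,
                model_type=mtype,
                versions=[("V2014", 2014), ("V2018", 2018)],
                initial=marg,
                kernels=[_DEFAULT_KERNELS[(vendor, mtype)]],
                conditional_initial=cond,
            )
        )
    return HistorySpec(
        n_compounds=n_compounds,
        models=models,
        seed=seed,
        latent_prevalence=latent_prevalence,
    )


# ---------------------------------------------------------------------------
# structure generation

_SCAFFOLDS = [
    "c1ccccc1{g}",          # benzene
    "c1ccc2ccccc2c1{g}",    # naphthalene
    "c1ccncc1{g}",          # pyridine
    "C1CCCCC1{g}",          # cyclohexane
    "CCCC{g}",
    "CCOCC{g}",
    "CC(C){g}",
]

#: Substituents echoing the common mutagenicity alert classes plus
#: innocuous groups.
_GROUPS = [
    "N",                # (aryl) amine
    "[N+](=O)[O-]",     # nitro
    "C(=O)Cl",          # acyl chloride
    "C(=O)OC",          # methyl ester
    "C=O",              # aldehyde
    "C1CO1",            # epoxide
    "OS(C)(=O)=O",      # alkyl sulfonate ester
    "B(O)O",            # boronic acid
    "NN",               # hydrazine
    "O",                # alcohol
    "Cl",
    "C",
    "OC",
    "C#N",
]

_METAL_FRAGMENTS = [".[Fe]", ".[Cu]", ".[Zn]", ".[Pt]"]
_MIXTURE_PARTNERS = ["CCO", "CC(=O)O", "CCN", "ClCCl"]


def generate_structures(
    n: int,
    seed: int,
    defect_fraction: float = 0.0,
    defect_kinds: Sequence[str] = ("mixture", "metal", "duplicate"),
) -> list[str]:
    """Deterministically generate n small impurity-like SMILES.

    With probability `defect_fraction` a structure is replaced by a defect
    of a kind drawn from `defect_kinds`: a two-component mixture, a
    transition-metal-containing record, or an exact duplicate of an
    earlier structure. Same seed, same list.
    """
    from rdkit import Chem

    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= defect_fraction <= 1.0:
        raise ValueError("defect_fraction must be in [0, 1]")
    if defect_fraction > 0 and not defect_kinds:
        raise ValueError("defect_kinds empty with non-zero defect_fraction")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out: list[str] = []
    clean: list[str] = []
    while len(out) < n:
        scaffold = _SCAFFOLDS[rng.integers(len(_SCAFFOLDS))]
        group = _GROUPS[rng.integers(len(_GROUPS))]
        smi = scaffold.format(g=group)
        if Chem.MolFromSmiles(smi) is None:  # grammar slip: try again
            continue
        if defect_fraction > 0 and rng.random() < defect_fraction:
            kind = defect_kinds[rng.integers(len(defect_kinds))]
            if kind == "mixture":
                smi = smi + "." + _MIXTURE_PARTNERS[rng.integers(len(_MIXTURE_PARTNERS))]
            elif kind == "metal":
                smi = smi + _METAL_FRAGMENTS[rng.integers(len(_METAL_FRAGMENTS))]
            elif kind == "duplicate" and clean:
                smi = clean[rng.integers(len(clean))]
            elif kind != "duplicate":
                raise ValueError(f"unknown defect kind {kind!r}")
        else:
            clean.append(smi)
        out.append(smi)
    return out
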