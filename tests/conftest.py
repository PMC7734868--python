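import numpy as np
import pandas as pd
import pytest

from m7drift import Call, PredictionTable, default_vocab_map
from m7drift.calls import CATEGORIES


@pytest.fixture(scope="session")
def vocab():
    return default_vocab_map()


def make_table(calls_by_version, compounds=None) -> PredictionTable:
    """Build a PredictionTable from {(vendor, mtype, label, year): [Call, ...]}."""
    rows = []
    n = len(next(iter(calls_by_version.values())))
    compounds = compounds or [f"C{i:03d}" for i in range(1, n + 1)]
    for (vendor, mtype, label, year), calls in calls_by_version.items():
        assert len(calls) == n
        for cid, call in zip(compounds, calls):
            rows.append(
                {
                    "compound_id": cid,
                    "vendor": vendor,
                    "model_type": mtype,
                    "version_label": label,
                    "release_year": year,
                    "call": call,
                }
            )
    return PredictionTable.from_long(pd.DataFrame(rows))


def random_table(rng: np.random.Generator, max_compounds=200, max_versions=4) -> PredictionTable:
    """Random complete table over two vendors x both model types."""
    n = int(rng.integers(2, max_compounds + 1))
    n_versions = int(rng.integers(2, max_versions + 1))
    spec = {}
    for vendor in ("AcmeTox", "BetaSoft"):
        for mtype in ("statistical", "rule_based"):
            for k in range(n_versions):
                calls = [CATEGORIES[i] for i in rng.integers(0, 4, size=n)]
                spec[(vendor, mtype, f"v{k + 1}", 2014 + k)] = calls
    return make_table(spec)


@pytest.fixture
def toy_transition_table():
    """5 compounds, one model, two versions: from [P,N,N,E,O] to [N,N,P,E,O]."""
    P, N, E, O = Call.POSITIVE, Call.NEGATIVE, Call.EQUIVOCAL, Call.OOD
    return make_table(
        {
            ("AcmeTox", "statistical", "v1", 2014): [P, N, N, E, O],
            ("AcmeTox", "statistical", "v2", 2018): [N, N, P, E, O],
        }
    )
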