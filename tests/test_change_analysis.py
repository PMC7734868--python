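"""Transition matrices, change percentages, grids and conservation."""

import math

import numpy as np
import pandas as pd
import pytest

from m7drift import (
    Call,
    ConsensusCombination,
    ModelId,
    VersionDriftModel,
    change_percentages,
    check_external_counts,
    combination_grid,
    consensus_transition_matrix,
    conservation_check,
    marginal_counts,
    transition_matrix,
    unchanged_report,
)
from m7drift.calls import CATEGORIES
from m7drift.consensus import consensus_call
from m7drift.drift import FROM_CATEGORY, TOTAL
from tests.conftest import make_table, random_table

P, N, E, O = Call.POSITIVE, Call.NEGATIVE, Call.EQUIVOCAL, Call.OOD


class TestTransitionMatrix:
    def test_identical_columns_diagonal(self):
        calls = [P, N, N, E, O, O]
        t = make_table(
            {
                ("V", "statistical", "v1", 2014): calls,
                ("V", "statistical", "v2", 2018): calls,
            }
        )
        tm = transition_matrix(t, "V", "statistical", "v1", "v2")
        assert tm.unchanged == tm.n_total == 6
        assert (tm.counts == np.diag(np.diag(tm.counts))).all()

    def test_hand_enumeration(self, toy_transition_table):
        tm = transition_matrix(toy_transition_table, "AcmeTox", "statistical", "v1", "v2")
        assert tm.count(P, N) == 1
        assert tm.count(N, P) == 1
        assert tm.count(N, N) == 1
        assert tm.count(E, E) == 1
        assert tm.count(O, O) == 1
        assert tm.unchanged == 3
        assert tm.n_total == 5

    def test_reversal_transposes(self, toy_transition_table):
        fwd = transition_matrix(toy_transition_table, "AcmeTox", "statistical", "v1", "v2")
        rev = transition_matrix(toy_transition_table, "AcmeTox", "statistical", "v2", "v1")
        assert (fwd.counts.T == rev.counts).all()

    def test_unknown_version_rejected(self, toy_transition_table):
        with pytest.raises(ValueError, match="not in table"):
            transition_matrix(toy_transition_table, "AcmeTox", "statistical", "v1", "v9")


class TestChangePercentages:
    def test_total_mode_hand_values(self, toy_transition_table):
        tm = transition_matrix(toy_transition_table, "AcmeTox", "statistical", "v1", "v2")
        cs = change_percentages(tm, TOTAL)
        assert cs.percent(N, P) == 20.0
        assert cs.unchanged_percent == 60.0
        assert math.isclose(cs.percentages.sum(), 100.0)

    def test_diagonal_matrix_all_unchanged(self):
        calls = [P, N, E, O]
        t = make_table(
            {
                ("V", "statistical", "v1", 2014): calls,
                ("V", "statistical", "v2", 2018): calls,
            }
        )
        cs = change_percentages(
            transition_matrix(t, "V", "statistical", "v1", "v2"), TOTAL
        )
        off = cs.percentages - np.diag(np.diag(cs.percentages))
        assert (off == 0).all()
        assert cs.unchanged_percent == 100.0

    def test_from_category_empty_row_is_nan_not_zero(self):
        calls = [P, P, N]  # no equivocal or OOD compounds at v1
        t = make_table(
            {
                ("V", "statistical", "v1", 2014): calls,
                ("V", "statistical", "v2", 2018): [P, N, N],
            }
        )
        cs = change_percentages(
            transition_matrix(t, "V", "statistical", "v1", "v2"), FROM_CATEGORY
        )
        assert math.isnan(cs.percent(E, E))
        assert math.isnan(cs.percent(O, N))
        assert cs.percent(P, N) == 50.0


class TestMarginals:
    def test_toy_counts(self):
        t = make_table({("V", "statistical", "v1", 2014): [P, P, N, E, O, N]})
        counts = marginal_counts(t, t.find_version("V", "statistical", "v1"))
        assert counts == {P: 2, N: 2, E: 1, O: 1}
        assert sum(counts.values()) == t.n_compounds

    def test_conservation_check_passes_on_complete_table(self):
        t = make_table(
            {
                ("V", "statistical", "v1", 2014): [P, N, E, O],
                ("V", "rule_based", "r1", 2014): [N, N, N, N],
            }
        )
        report = conservation_check(t)
        assert report["ok"].all()
        assert (report["sum"] == 4).all()


class TestExternalCounts:
    def test_published_row_sums_to_dataset_size(self):
        report = check_external_counts(
            {"LS rule-based V1 (2014)": {"POSITIVE": 1031, "NEGATIVE": 2216,
                                         "EQUIVOCAL": 41, "OOD": 79}},
            expected_total=3367,
        )
        assert report["ok"].all()

    def test_short_row_flagged_never_corrected(self):
        report = check_external_counts(
            {"MC rule-based V1520 (2014)": {"POSITIVE": 1014, "NEGATIVE": 2134,
                                            "EQUIVOCAL": 16, "OOD": 201}},
            expected_total=3367,
        )
        assert not report["ok"].any()
        assert report["sum"].iloc[0] == 3365

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="unknown categories"):
            check_external_counts({"v": {"MAYBE": 1}}, expected_total=1)


class TestGrid:
    def test_three_by_three_product(self):
        spec = {}
        for vendor in ("A", "B", "C"):
            spec[(vendor, "statistical", "s1", 2014)] = [P, N]
            spec[(vendor, "rule_based", "r1", 2014)] = [N, N]
        grid = combination_grid(make_table(spec))
        assert len(grid) == 9
        labels = [c.label for c in grid]
        assert labels.count("intra") == 3
        assert labels.count("inter") == 6

    def test_single_vendor_intra_only(self):
        t = make_table(
            {
                ("A", "statistical", "s1", 2014): [P],
                ("A", "rule_based", "r1", 2014): [N],
            }
        )
        grid = combination_grid(t)
        assert len(grid) == 1 and grid[0].label == "intra"

    def test_stat_only_vendor_in_inter_pairs_only(self):
        t = make_table(
            {
                ("A", "statistical", "s1", 2014): [P],
                ("B", "statistical", "s1", 2014): [N],
                ("B", "rule_based", "r1", 2014): [N],
            }
        )
        grid = combination_grid(t)
        a_combos = [c for c in grid if c.stat.vendor == "A"]
        assert a_combos and all(c.label == "inter" for c in a_combos)
        assert all(c.rule.vendor != "A" for c in grid)

    def test_grid_requires_both_types(self):
        t = make_table({("A", "statistical", "s1", 2014): [P]})
        with pytest.raises(ValueError, match="rule-based"):
            combination_grid(t)


class TestUnchangedReport:
    def test_identity_all_hundred(self):
        spec = {}
        for vendor in ("A", "B"):
            for mtype, lbl in (("statistical", "s"), ("rule_based", "r")):
                calls = [P, N, E, O, N]
                spec[(vendor, mtype, f"{lbl}1", 2014)] = calls
                spec[(vendor, mtype, f"{lbl}2", 2018)] = calls
        t = make_table(spec)
        rep = unchanged_report(t, combination_grid(t), 2014, 2018)
        assert (rep["unchanged_percent"] == 100.0).all()

    def test_mean_is_arithmetic(self):
        # one combination at 80%, one at 60% -> mean 70%
        t = make_table(
            {
                ("A", "statistical", "s1", 2014): [N] * 5,
                ("A", "statistical", "s2", 2018): [P, N, N, N, N],
                ("A", "rule_based", "r1", 2014): [N] * 5,
                ("A", "rule_based", "r2", 2018): [N] * 5,
                ("B", "statistical", "s1", 2014): [N] * 5,
                ("B", "statistical", "s2", 2018): [P, P, N, N, N],
                # B has no rule-based model; grid = {A-stat,B-stat} x {A-rule}
            }
        )
        rep = unchanged_report(t, combination_grid(t), 2014, 2018)
        by_combo = dict(zip(rep["combination"], rep["unchanged_percent"]))
        assert by_combo["A-stat + A-rule (intra)"] == 80.0
        assert by_combo["B-stat + A-rule (inter)"] == 60.0
        assert by_combo["mean"] == 70.0


class TestConsensusTransitions:
    def test_all_negative_stays_diagonal(self):
        t = make_table(
            {
                ("A", "statistical", "s1", 2014): [N, N, N],
                ("A", "statistical", "s2", 2018): [N, N, N],
                ("A", "rule_based", "r1", 2014): [N, N, N],
                ("A", "rule_based", "r2", 2018): [N, N, N],
            }
        )
        combo = ConsensusCombination(ModelId("A", "statistical"), ModelId("A", "rule_based"))
        tm = consensus_transition_matrix(t, combo, 2014, 2018)
        assert tm.count(N, N) == tm.n_total == 3

    def test_flip_masked_when_partner_already_positive(self):
        # compound 1: stat flips N->P with rule N (consensus N->P)
        # compound 2: stat flips N->P but rule already P (consensus P->P)
        t = make_table(
            {
                ("A", "statistical", "s1", 2014): [N, N, N, N],
                ("A", "statistical", "s2", 2018): [P, P, N, N],
                ("A", "rule_based", "r1", 2014): [N, P, N, P],
                ("A", "rule_based", "r2", 2018): [N, P, N, P],
            }
        )
        combo = ConsensusCombination(ModelId("A", "statistical"), ModelId("A", "rule_based"))
        tm = consensus_transition_matrix(t, combo, 2014, 2018)
        assert tm.count(N, P) == 1
        assert tm.count(P, P) == 2
        assert tm.count(N, N) == 1


class TestBruteForceOracle:
    """Vectorized/table computations vs an independent per-compound recount."""

    def test_random_tables_match_recount(self):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            t = random_table(rng, max_compounds=60, max_versions=3)
            versions = t.versions_of("AcmeTox", "statistical")
            fv, tv = versions[0], versions[-1]
            tm = transition_matrix(t, "AcmeTox", "statistical",
                                   fv.version_label, tv.version_label)

            frm, to = t.calls(fv), t.calls(tv)
            recount = {}
            for a, b in zip(frm, to):
                recount[(a, b)] = recount.get((a, b), 0) + 1
            for a in CATEGORIES:
                for b in CATEGORIES:
                    assert tm.count(a, b) == recount.get((a, b), 0)

            cs_tot = change_percentages(tm, TOTAL)
            cs_cat = change_percentages(tm, FROM_CATEGORY)
            n = t.n_compounds
            for a in CATEGORIES:
                row_n = sum(v for (x, _), v in recount.items() if x is a)
                for b in CATEGORIES:
                    c = recount.get((a, b), 0)
                    assert cs_tot.percent(a, b) == 100.0 * c / n
                    if row_n == 0:
                        assert math.isnan(cs_cat.percent(a, b))
                    else:
                        assert cs_cat.percent(a, b) == 100.0 * c / row_n
            unchanged = sum(v for (a, b), v in recount.items() if a is b)
            assert cs_tot.unchanged_percent == 100.0 * unchanged / n

            mc = marginal_counts(t, fv)
            for a in CATEGORIES:
                assert mc[a] == sum(1 for c in frm if c is a)

    def test_unchanged_report_matches_per_compound_comparison(self):
        rng = np.random.default_rng(5)
        t = random_table(rng, max_compounds=80, max_versions=3)
        years = sorted({v.release_year for v in t.versions})
        grid = combination_grid(t)
        rep = unchanged_report(t, grid, years[0], years[-1])
        for combo in grid:
            sv0 = t.version_at(combo.stat.vendor, "statistical", years[0])
            rv0 = t.version_at(combo.rule.vendor, "rule_based", years[0])
            sv1 = t.version_at(combo.stat.vendor, "statistical", years[-1])
            rv1 = t.version_at(combo.rule.vendor, "rule_based", years[-1])
            same = 0
            for s0, r0, s1, r1 in zip(
                t.calls(sv0), t.calls(rv0), t.calls(sv1), t.calls(rv1)
            ):
                if consensus_call(s0, r0) is consensus_call(s1, r1):
                    same += 1
            expect = 100.0 * same / t.n_compounds
            got = rep.loc[rep["combination"] == str(combo), "unchanged_percent"].iloc[0]
            assert got == expect


class TestModelResults:
    def test_fit_summary_and_estimates(self):
        rng = np.random.default_rng(42)
        t = random_table(rng, max_compounds=100, max_versions=3)
        res = VersionDriftModel(t).fit()
        assert set(res.single_model_transitions) == set(t.models)
        assert len(res.consensus_transitions) == len(res.grid) == 4
        assert res.marginals["ok"].all()
        text = res.summary()
        assert "unchanged" in text and "N->P" in text
        assert 0.0 <= res.mean_unchanged_percent <= 100.0

    def test_from_dataframe_with_raw_calls(self, vocab):
        df = pd.DataFrame(
            [
                ("c1", "Leadscope", "statistical", "V2", 2010, "Positive"),
                ("c2", "Leadscope", "statistical", "V2", 2010, "Negative"),
                ("c1", "Leadscope", "statistical", "V4", 2018, "Negative"),
                ("c2", "Leadscope", "statistical", "V4", 2018, "Negative"),
                ("c1", "Leadscope", "rule_based", "V1", 2014, "Positive"),
                ("c2", "Leadscope", "rule_based", "V1", 2014, "Negative"),
                ("c1", "Leadscope", "rule_based", "V5", 2018, "Positive"),
                ("c2", "Leadscope", "rule_based", "V5", 2018, "Indeterminate"),
            ],
            columns=["compound_id", "vendor", "model_type", "version_label",
                     "release_year", "raw_call"],
        )
        res = VersionDriftModel.from_dataframe(df, vocab).fit()
        combo = res.grid[0]
        tm = res.consensus_transitions[combo]
        # c1: (P,P)->(N,P)=P->P ; c2: (N,N)->(N,E)=N->E
        assert tm.count(P, P) == 1
        assert tm.count(N, E) == 1

    def test_year_window_filter(self):
        t = make_table(
            {
                ("A", "statistical", "s1", 2010): [P, N],
                ("A", "statistical", "s2", 2014): [N, N],
                ("A", "statistical", "s3", 2018): [N, P],
                ("A", "rule_based", "r1", 2014): [N, N],
                ("A", "rule_based", "r2", 2018): [N, N],
            }
        )
        res = VersionDriftModel(t, from_year=2014, to_year=2018).fit()
        tm = res.single_model_transitions[ModelId("A", "statistical")]
        # windowed comparison is s2 (2014) vs s3 (2018), not s1
        assert tm.count(N, P) == 1
        assert tm.count(P, N) == 0
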