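"""Mean scores, ranks, mobility and the UMG selection rule."""

import itertools

import numpy as np
import pandas as pd
import pytest

from umg.selection import (
    BETA_BY_COHORT,
    DependencyData,
    UMGCriteria,
    _strip_symbol,
    build_ranking,
    depmap_filter,
    intersect_networks,
    mean_scores,
    mobility,
    rank_scores,
    select_umgs,
)

from _utils import brute_force_ranks, brute_force_select


class TestMeanScores:
    def test_arithmetic_average(self):
        S0 = pd.DataFrame([[2, 0, 0, 0]], index=["g"])
        IS, _ = mean_scores(S0, S0)
        assert IS["g"] == 0.5

    def test_all_zero_gene(self):
        S0 = pd.DataFrame([[0, 0]], index=["g"])
        IS, _ = mean_scores(S0, S0)
        assert IS["g"] == 0

    def test_zero_samples_errors(self):
        empty = pd.DataFrame(index=["g"])
        with pytest.raises(ValueError):
            mean_scores(empty, empty)

    def test_final_scores_from_propagation_oracle(self):
        from umg.netio import WeightedNetwork
        from umg.propagate import column_normalize, propagate_closed_form

        adj = column_normalize(WeightedNetwork.from_edges([("a", "b", 1.0)]))
        final = propagate_closed_form(adj, np.array([1.0, 0.0]), alpha=0.5)
        Sf = pd.DataFrame(final, index=list(adj.nodes))
        _, FS = mean_scores(Sf * 0, Sf)
        assert FS["a"] == pytest.approx(2 / 3)
        assert FS["b"] == pytest.approx(1 / 3)


class TestRanks:
    def test_distinct(self):
        assert rank_scores(pd.Series([5, 3, 1])).tolist() == [1, 2, 3]

    def test_tied_block_average(self):
        assert rank_scores(pd.Series([5, 5, 1])).tolist() == [1.5, 1.5, 3]

    def test_all_tied(self):
        n = 7
        assert rank_scores(pd.Series([2.0] * n)).tolist() == [(n + 1) / 2] * n

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            vals = rng.choice([0.0, 0.5, 1.0, 2.0], size=12)
            s = pd.Series(vals, index=[f"g{i}" for i in range(12)])
            expected = brute_force_ranks(dict(s))
            assert rank_scores(s).to_dict() == pytest.approx(expected)

    def test_ordinal_mode(self):
        r = rank_scores(pd.Series([5, 5, 1]), method="first")
        assert r.tolist() == [1, 2, 3]

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            rank_scores(pd.Series([1.0, np.inf]))


class TestMobility:
    def test_difference(self):
        ms = mobility(pd.Series({"g": 800}), pd.Series({"g": 200}))
        assert ms["g"] == 600

    def test_unchanged_rank(self):
        assert mobility(pd.Series({"g": 5}), pd.Series({"g": 5}))["g"] == 0

    def test_sums_to_zero_for_tie_free_permutations(self):
        rng = np.random.default_rng(2)
        n = 30
        idx = [f"g{i}" for i in range(n)]
        ris = pd.Series(rng.permutation(n) + 1.0, index=idx)
        rfs = pd.Series(rng.permutation(n) + 1.0, index=idx)
        assert mobility(ris, rfs).sum() == 0


class TestSelectUMGs:
    def ranking_from(self, ris, rfs):
        idx = list(ris)
        return pd.DataFrame(
            {
                "IS": 0.0,
                "FS": 0.0,
                "RIS": pd.Series(ris),
                "RFS": pd.Series(rfs),
                "MS": pd.Series(ris) - pd.Series(rfs),
            },
            index=idx,
        )

    def test_direct_rule(self):
        r = self.ranking_from({"g": 8.0, "h": 2.0}, {"g": 2.0, "h": 8.0})
        out = select_umgs(r, UMGCriteria(beta=0.2, rank_threshold=3), g_size=10)
        assert out == ["g"]

    def test_top_initial_gene_never_selected(self):
        r = self.ranking_from({"d": 1.0, "g": 9.0}, {"d": 1.0, "g": 2.0})
        out = select_umgs(r, UMGCriteria(beta=0.1, rank_threshold=10), g_size=10)
        assert "d" not in out

    def test_boundary_inclusive(self):
        # MS exactly beta*|G| and RFS exactly T are both selected
        r = self.ranking_from({"g": 5.0}, {"g": 3.0})  # MS = 2 = 0.2*10, RFS = 3 = T
        assert select_umgs(r, UMGCriteria(beta=0.2, rank_threshold=3), g_size=10) == ["g"]

    def test_ordered_by_final_rank(self):
        r = self.ranking_from({"a": 9.0, "b": 10.0}, {"a": 2.0, "b": 1.0})
        out = select_umgs(r, UMGCriteria(beta=0.1, rank_threshold=5), g_size=10)
        assert out == ["b", "a"]

    def test_exhaustive_small_universes_against_brute_force(self):
        """All permutation pairs for |G| <= 5 over a beta/T grid match brute force."""
        for n in (3, 4, 5):
            genes = [f"g{i}" for i in range(n)]
            perms = list(itertools.permutations(range(1, n + 1)))
            for ris_p in perms:
                for rfs_p in perms:
                    ris = dict(zip(genes, map(float, ris_p)))
                    rfs = dict(zip(genes, map(float, rfs_p)))
                    r = self.ranking_from(ris, rfs)
                    for beta in (0.1, 0.3, 0.6):
                        for T in (1, 2, n):
                            got = set(select_umgs(r, UMGCriteria(beta=beta, rank_threshold=T)))
                            assert got == brute_force_select(ris, rfs, beta, T)

    def test_randomized_larger_universes_against_brute_force(self):
        rng = np.random.default_rng(3)
        for n in range(6, 13):
            genes = [f"g{i}" for i in range(n)]
            for _ in range(40):
                ris = dict(zip(genes, (rng.permutation(n) + 1).astype(float)))
                rfs = dict(zip(genes, (rng.permutation(n) + 1).astype(float)))
                r = self.ranking_from(ris, rfs)
                beta = float(rng.uniform(0.05, 0.8))
                T = int(rng.integers(1, n + 1))
                got = set(select_umgs(r, UMGCriteria(beta=beta, rank_threshold=T)))
                assert got == brute_force_select(ris, rfs, beta, T)

    def test_monotone_nesting_in_beta_and_T(self):
        rng = np.random.default_rng(4)
        n = 50
        genes = [f"g{i}" for i in range(n)]
        ris = dict(zip(genes, (rng.permutation(n) + 1).astype(float)))
        rfs = dict(zip(genes, (rng.permutation(n) + 1).astype(float)))
        r = self.ranking_from(ris, rfs)
        betas, Ts = [0.05, 0.1, 0.2, 0.4], [5, 10, 25, 50]
        for T in Ts:
            sets = [set(select_umgs(r, UMGCriteria(beta=b, rank_threshold=T))) for b in betas]
            for small, big in zip(sets[1:], sets):
                assert small <= big  # raising beta never adds genes
        for b in betas:
            sets = [set(select_umgs(r, UMGCriteria(beta=b, rank_threshold=T))) for T in Ts]
            for small, big in zip(sets, sets[1:]):
                assert small <= big  # lowering T never adds genes


def make_dep(crispr, rnai=None, annotations=None):
    assays = {"CRISPR": crispr}
    if rnai is not None:
        assays["RNAi"] = rnai
    ann = pd.Series(annotations or {})
    return DependencyData(assays=assays, annotations=ann)


class TestDepmapFilter:
    def test_max_over_assays(self):
        lines = [f"c{i}" for i in range(5)]
        ann = {line: "BRCA" for line in lines}
        crispr = pd.DataFrame([[-1, -1, -1, 1, 1]], index=["g"], columns=lines)
        rnai = pd.DataFrame([[-1, -1, 1, 1, 1]], index=["g"], columns=lines)
        kept, dm, _ = depmap_filter(["g"], make_dep(crispr, rnai, ann), "BRCA", 0.5)
        assert kept == ["g"] and dm["g"] == pytest.approx(0.6)

    def test_no_negative_lines_removed(self):
        lines = ["c0", "c1"]
        ann = {line: "BRCA" for line in lines}
        crispr = pd.DataFrame([[0.2, 0.1]], index=["g"], columns=lines)
        kept, dm, _ = depmap_filter(["g"], make_dep(crispr, annotations=ann), "BRCA", 0.5)
        assert kept == [] and dm["g"] == 0.0

    def test_unannotated_cancer_type_falls_back_to_all_lines(self):
        lines = ["c0", "c1", "c2", "c3"]
        crispr = pd.DataFrame([[-1, -1, -1, 1]], index=["g"], columns=lines)
        dep = make_dep(crispr, annotations={line: "LUAD" for line in lines})
        kept, dm, _ = depmap_filter(["g"], dep, "NOSUCH", 0.5)
        assert kept == ["g"] and dm["g"] == pytest.approx(0.75)

    def test_gene_absent_everywhere_kept_with_flag(self):
        crispr = pd.DataFrame([[-1.0]], index=["g"], columns=["c0"])
        kept, dm, flags = depmap_filter(["other"], make_dep(crispr), None, 0.5)
        assert kept == ["other"]
        assert np.isnan(dm["other"])
        assert flags["other"] == "no dependency data"

    def test_strictly_negative_counts(self):
        crispr = pd.DataFrame([[0.0, -0.1]], index=["g"], columns=["c0", "c1"])
        _, dm, _ = depmap_filter(["g"], make_dep(crispr), None, 0.5)
        assert dm["g"] == pytest.approx(0.5)  # exact zero is not negative

    def test_symbol_with_entrez_id_stripped(self):
        assert _strip_symbol("TP53 (7157)") == "TP53"
        assert _strip_symbol("TP53(7157)") == "TP53"
        assert _strip_symbol("KRAS") == "KRAS"


class TestIntersection:
    def test_basic(self):
        out = intersect_networks({"a": ["A", "B", "C"], "b": ["B", "C", "D"]})
        assert set(out) == {"B", "C"}

    def test_single_network_identity(self):
        assert intersect_networks({"a": ["X", "Y"]}) == ["X", "Y"]

    def test_disjoint_lists_warn_and_empty(self):
        with pytest.warns(UserWarning, match="empty"):
            out = intersect_networks({"a": ["A"], "b": ["B"]})
        assert out == []

    def test_ordered_by_mean_final_rank(self):
        rankings = {
            "a": pd.DataFrame({"RFS": {"X": 10.0, "Y": 2.0}}),
            "b": pd.DataFrame({"RFS": {"X": 4.0, "Y": 30.0}}),
        }
        out = intersect_networks({"a": ["X", "Y"], "b": ["X", "Y"]}, rankings)
        assert out == ["X", "Y"]  # mean 7 vs 16


class TestCriteria:
    def test_cohort_beta_defaults(self):
        assert BETA_BY_COHORT["BRCA"] == 0.25
        assert BETA_BY_COHORT["KIRC"] == 0.20
        assert BETA_BY_COHORT["READ"] == 0.15
        assert BETA_BY_COHORT["THCA"] == 0.05
        assert UMGCriteria.for_cohort("LUAD").beta == 0.25

    def test_unknown_cohort_needs_explicit_beta(self):
        with pytest.raises(ValueError, match="beta"):
            UMGCriteria.for_cohort("NOPE")
        assert UMGCriteria.for_cohort("NOPE", beta=0.1).beta == 0.1

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            UMGCriteria(beta=0.0)
        with pytest.raises(ValueError):
            UMGCriteria(beta=0.2, rank_threshold=0)


def test_build_ranking_assembles_consistent_table():
    S0 = pd.DataFrame({"s1": [4, 0, 1], "s2": [2, 0, 1]}, index=["a", "b", "c"])
    Sf = pd.DataFrame({"s1": [1.0, 2.0, 0.5], "s2": [1.0, 2.0, 0.5]}, index=["a", "b", "c"])
    r = build_ranking(S0, Sf)
    assert r.loc["a", "IS"] == 3.0
    assert r.loc["b", "RFS"] == 1.0
    assert (r["MS"] == r["RIS"] - r["RFS"]).all()
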