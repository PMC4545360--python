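"""Tests of the vote table, contingency tests, ranking and plot data."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency, fisher_exact

from egwas_meta import (
    AnalysisConfig,
    bonferroni_threshold,
    build_vote_table,
    fisher_exact_two_sided,
    gene_contingency_test,
    manhattan_data,
    pearson_chi2_2x2,
    rank_and_flag,
    run_contingency_tests,
)


def fisher_oracle(a, b, c, d):
    """Independent two-sided Fisher: exact Fractions over the row margin."""
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    denom = math.comb(r1 + r2, r1)
    pobs = Fraction(math.comb(c1, a) * math.comb(c2, b), denom)
    total = Fraction(0)
    for x in range(max(0, r1 - c2), min(r1, c1) + 1):
        p = Fraction(math.comb(c1, x) * math.comb(c2, r1 - x), denom)
        if p <= pobs:
            total += p
    return float(total)


def calls_frame(rows, genes):
    return pd.DataFrame(rows, index=[f"E{i}" for i in range(len(rows))], columns=genes)


class TestVoteTable:
    def test_single_positive_experiment(self):
        votes = build_vote_table(calls_frame([["positive"]], ["G"]))
        assert (votes.counts.loc["G", "n_pos"], votes.counts.loc["G", "n_neg"]) == (1, 0)

    def test_all_null_gene(self):
        votes = build_vote_table(calls_frame([["null"], ["null"]], ["G"]))
        assert (votes.counts.loc["G", "n_pos"], votes.counts.loc["G", "n_neg"]) == (0, 0)
        assert votes.counts.loc["G", "n_tested"] == 2

    def test_not_measured_excluded_from_n_tested(self):
        votes = build_vote_table(calls_frame([["not_measured"], ["positive"]], ["G"]))
        assert votes.counts.loc["G", "n_tested"] == 1

    def test_totals_match_brute_force_summation(self):
        rng = np.random.default_rng(2)
        states = ["positive", "negative", "null", "not_measured"]
        rows = rng.choice(states, size=(5, 12))
        calls = calls_frame(rows.tolist(), [f"G{j}" for j in range(12)])
        votes = build_vote_table(calls)
        brute_pos = sum(r.count("positive") for r in rows.tolist())
        brute_neg = sum(r.count("negative") for r in rows.tolist())
        assert votes.total_pos == brute_pos and votes.total_neg == brute_neg
        for j, gene in enumerate(calls.columns):
            col = [rows[i][j] for i in range(5)]
            assert votes.counts.loc[gene, "n_pos"] == col.count("positive")
            assert votes.counts.loc[gene, "n_neg"] == col.count("negative")
            assert votes.counts.loc[gene, "n_tested"] == 5 - col.count("not_measured")

    def test_empty_matrix_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            build_vote_table(pd.DataFrame())


class TestContingency:
    def test_identical_proportions_chi2_zero(self):
        p, stat, used = gene_contingency_test((5, 5), (500, 500))
        assert used == "chi2" and stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_never_called_gene_p_one(self):
        p, stat, used = gene_contingency_test((0, 0), (100, 100))
        assert p == 1.0 and used == "none"

    def test_skewed_gene_routes_to_fisher_and_matches_oracle(self):
        p, stat, used = gene_contingency_test((8, 0), (400, 400))
        assert used == "fisher"
        assert p == pytest.approx(fisher_oracle(8, 0, 400, 400), abs=1e-12)

    def test_fisher_branch_matches_fraction_oracle_on_grid(self):
        for a in range(0, 7):
            for b in range(0, 7):
                for c in range(0, 9):
                    for d in range(0, 9):
                        got = fisher_exact_two_sided(a, b, c, d)
                        assert got == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-12)

    def test_fisher_agrees_with_scipy_spot_checks(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 25, size=4)
            ours = fisher_exact_two_sided(int(a), int(b), int(c), int(d))
            ref = fisher_exact([[a, b], [c, d]])[1]
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_fisher_monotone_in_directional_skew(self):
        # holding the gene's total votes and the background fixed, a more
        # lopsided split never looks less surprising
        for total in (6, 10):
            for bg in ((50, 50), (200, 180)):
                ps = []
                for k in range(total // 2, total + 1):
                    ps.append(fisher_exact_two_sided(k, total - k, *bg))
                assert all(ps[i + 1] <= ps[i] + 1e-12 for i in range(len(ps) - 1))

    def test_chi2_branch_matches_scipy(self):
        for table in [((30, 10), (400, 380)), ((12, 20), (100, 90)), ((7, 9), (60, 70))]:
            (a, b), (c, d) = table
            p, stat, used = gene_contingency_test((a, b), (c, d), AnalysisConfig(fisher_switch_expected=5))
            assert used == "chi2"
            ref = chi2_contingency([[a, b], [c, d]], correction=False)
            assert stat == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_negative_cells_error(self):
        with pytest.raises(ValueError):
            gene_contingency_test((-1, 2), (3, 4))
        with pytest.raises(ValueError):
            fisher_exact_two_sided(1, 2, -3, 4)

    def test_all_zero_background_error(self):
        with pytest.raises(ValueError, match="background"):
            gene_contingency_test((1, 0), (0, 0))


class TestBonferroni:
    def test_division(self):
        assert bonferroni_threshold(1, 0.05) == 0.05
        assert bonferroni_threshold(100, 0.01) == pytest.approx(1e-4)

    def test_zero_genes_error(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0, 0.05)


class TestRanking:
    def records(self, genes, p, n_pos, n_neg):
        return pd.DataFrame(
            {
                "gene": genes,
                "n_pos": n_pos,
                "n_neg": n_neg,
                "n_tested": [10] * len(genes),
                "p_value": p,
                "chromosome": ["1"] * len(genes),
                "position": range(1, len(genes) + 1),
            }
        )

    def test_all_ties_follow_tie_break_order(self):
        df = self.records(["B", "A", "C"], [1.0, 1.0, 1.0], [2, 1, 2], [0, 0, 0])
        ranked = rank_and_flag(df, 1e-6)
        assert list(ranked.index) == ["B", "C", "A"]  # votes desc, then symbol
        assert not ranked["significant"].any()

    def test_single_significant_gene(self):
        df = self.records(["A", "B"], [1e-9, 0.2], [8, 1], [0, 1])
        ranked = rank_and_flag(df, 1e-6)
        assert ranked["significant"].sum() == 1 and ranked["significant"]["A"]

    def test_threshold_is_strict_inequality(self):
        df = self.records(["A"], [1e-6], [5], [0])
        assert not rank_and_flag(df, 1e-6)["significant"].any()

    def test_ordering_matches_brute_force_sort_oracle(self):
        rng = np.random.default_rng(8)
        genes = [f"G{i:02d}" for i in range(20)]
        p = rng.choice([1.0, 0.5, 0.01, 0.01, 1e-7], size=20)
        n_pos = rng.integers(0, 6, size=20)
        n_neg = rng.integers(0, 6, size=20)
        ranked = rank_and_flag(self.records(genes, p, n_pos, n_neg), 1e-6)
        oracle = sorted(
            zip(genes, p, n_pos + n_neg), key=lambda t: (t[1], -t[2], t[0])
        )
        assert list(ranked.index) == [g for g, _, _ in oracle]
        assert sorted(ranked["rank"]) == list(range(1, 21))


class TestManhattan:
    def records(self):
        return pd.DataFrame(
            {
                "gene": ["A", "B", "C", "D"],
                "n_pos": [1, 2, 3, 0],
                "n_neg": [0, 0, 0, 1],
                "p_value": [1.0, 1.55e-6, 1e-8, 0.5],
                "significant": [False, False, True, False],
                "chromosome": ["2", "1", "X", None],
                "position": [500, 100, 42, np.nan],
            }
        )

    def test_y_is_minus_log10_p(self):
        out = manhattan_data(self.records(), threshold=1.55e-6)["table"]
        y = dict(zip(out["gene"], out["neg_log10_p"]))
        assert y["A"] == pytest.approx(0.0)
        assert y["B"] == pytest.approx(5.81, abs=0.005)

    def test_row_count_and_threshold_metadata(self):
        out = manhattan_data(self.records(), threshold=1.55e-6)
        assert len(out["table"]) == 4
        assert out["threshold"] == pytest.approx(1.55e-6)

    def test_chromosome_order_and_unplaced_bin(self):
        out = manhattan_data(self.records())
        offsets = out["chromosome_offsets"]
        assert list(offsets) == ["1", "2", "X", "unplaced"]
        tab = out["table"].set_index("gene")
        assert tab.loc["B", "x"] < tab.loc["A", "x"] < tab.loc["C", "x"] < tab.loc["D", "x"]
        assert tab.loc["D", "chromosome"] == "unplaced"

    def test_labels_only_for_significant(self):
        tab = manhattan_data(self.records())["table"].set_index("gene")
        assert tab.loc["C", "label"] == "C" and tab.loc["A", "label"] == ""


def test_run_contingency_tests_assembles_records():
    calls = pd.DataFrame(
        [["positive", "positive", "null"], ["positive", "null", "negative"]],
        index=["E1", "E2"],
        columns=["G1", "G2", "G3"],
    )
    votes = build_vote_table(calls)
    records = run_contingency_tests(votes)
    assert list(records.index) == ["G1", "G2", "G3"]
    assert (records["p_value"] <= 1).all() and (records["p_value"] >= 0).all()
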