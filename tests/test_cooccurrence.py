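import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cyanorhythm import (
    DomainError,
    bh_adjust,
    build_network,
    cooccurrence_network,
    fisher_right,
    pairwise_cooccurrence,
    read_presence_matrix,
)
from _oracles import bh_oracle, fisher_right_enum, hypergeom_tail_table


class TestFisherRight:
    def test_perfect_cooccurrence_4v4(self):
        assert fisher_right([[4, 0], [0, 4]]) == pytest.approx(1.0 / 70.0, abs=1e-12)

    def test_balanced_table(self):
        assert fisher_right([[2, 2], [2, 2]]) == pytest.approx(53.0 / 70.0, abs=1e-12)

    @pytest.mark.parametrize("table", [
        [[0, 0], [3, 4]], [[0, 3], [0, 4]], [[5, 0], [2, 0]],
    ])
    def test_zero_margin_gives_one(self, table):
        assert fisher_right(table) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(DomainError):
            fisher_right([[-1, 2], [3, 4]])

    def test_matches_enumeration_small_margins(self):
        """Exact tail enumeration agreement for all tables with N <= 25."""
        for n_total in range(0, 26):
            for row1 in range(n_total + 1):
                for col1 in range(n_total + 1):
                    a_vals, tails = hypergeom_tail_table(n_total, row1, col1)
                    for a, expected in zip(a_vals, tails):
                        table = [[a, row1 - a], [col1 - a, n_total - row1 - col1 + a]]
                        assert fisher_right(table) == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_joint_count(self):
        """At fixed margins, enrichment p decreases as the both-present
        count grows."""
        n_total, row1, col1 = 40, 18, 22
        a_vals, _ = hypergeom_tail_table(n_total, row1, col1)
        ps = [
            fisher_right([[a, row1 - a], [col1 - a, n_total - row1 - col1 + a]])
            for a in a_vals
        ]
        assert all(p1 >= p2 - 1e-15 for p1, p2 in zip(ps, ps[1:]))


def presence(genomes, proteins, rows):
    return pd.DataFrame(rows, index=genomes, columns=proteins).astype(bool)


class TestPairwiseCooccurrence:
    def build(self):
        rng = np.random.default_rng(3)
        genomes = [f"g{i}" for i in range(10)]
        anchor = np.ones(10, int)
        a = (np.arange(10) < 5).astype(int)
        b = a.copy()
        c = rng.integers(0, 2, 10)
        return presence(genomes, ["anchor", "A", "B", "C"],
                        np.column_stack([anchor, a, b, c]))

    def test_perfect_pair_probability(self):
        df = self.build()
        pairs = pairwise_cooccurrence(df, "anchor")
        row = pairs[(pairs.protein_a == "A") & (pairs.protein_b == "B")]
        assert row.p_raw.iloc[0] == pytest.approx(1.0 / 252.0, abs=1e-12)
        assert row.p_raw.iloc[0] == pytest.approx(fisher_right_enum(5, 0, 0, 5), abs=1e-15)

    def test_anchor_pairs_degenerate_but_self_pair_excluded(self):
        df = self.build()
        pairs = pairwise_cooccurrence(df, "anchor")
        assert not ((pairs.protein_a == "anchor") & (pairs.protein_b == "anchor")).any()
        anchor_rows = pairs[(pairs.protein_a == "anchor") | (pairs.protein_b == "anchor")]
        assert (anchor_rows.p_raw == 1.0).all()  # anchor present in every universe genome

    def test_row_permutation_invariance(self, rng):
        df = self.build()
        shuffled = df.sample(frac=1.0, random_state=5)
        p1 = pairwise_cooccurrence(df, "anchor").sort_values(["protein_a", "protein_b"])
        p2 = pairwise_cooccurrence(shuffled, "anchor").sort_values(["protein_a", "protein_b"])
        np.testing.assert_allclose(p1.p_raw.to_numpy(), p2.p_raw.to_numpy(), atol=1e-15)

    def test_universe_restriction(self):
        # anchor splits the genomes; co-occurrence only counted inside it
        df = presence(
            ["g1", "g2", "g3", "g4"], ["anchor", "A", "B"],
            [[1, 1, 1], [1, 0, 0], [0, 1, 0], [0, 0, 1]],
        )
        pairs = pairwise_cooccurrence(df, "anchor")
        row = pairs[(pairs.protein_a == "A") & (pairs.protein_b == "B")]
        assert row.p_raw.iloc[0] == pytest.approx(fisher_right_enum(1, 0, 0, 1), abs=1e-15)

    def test_missing_anchor(self):
        with pytest.raises(KeyError):
            pairwise_cooccurrence(self.build(), "nope")


class TestBHAdjust:
    def test_single_discovery_example(self):
        adjusted, flags = bh_adjust([0.001, 0.02, 0.5], q=0.01)
        assert flags.sum() == 1 and flags[0]
        exp_adj, exp_flags = bh_oracle([0.001, 0.02, 0.5], 0.01)
        np.testing.assert_allclose(adjusted, exp_adj, atol=1e-12)
        np.testing.assert_array_equal(flags, exp_flags)

    def test_all_ones(self):
        _, flags = bh_adjust([1.0, 1.0, 1.0], q=0.01)
        assert flags.sum() == 0

    def test_single_p(self):
        _, flags = bh_adjust([0.009], q=0.01)
        assert flags.sum() == 1

    def test_adjusted_not_below_raw(self, rng):
        p = rng.uniform(0, 1, 40)
        adjusted, _ = bh_adjust(p, q=0.05)
        assert (adjusted >= p - 1e-12).all()
        np.testing.assert_allclose(adjusted, bh_oracle(p, 0.05)[0], atol=1e-12)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    def test_discoveries_monotone_in_q(self, pvals):
        counts = [bh_adjust(pvals, q)[1].sum() for q in (0.001, 0.01, 0.05, 0.2, 1.0)]
        assert all(c1 <= c2 for c1, c2 in zip(counts, counts[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            bh_adjust([0.5, 1.5], q=0.01)


class TestNetwork:
    def test_degrees_from_edges(self):
        pairs = pd.DataFrame(
            {
                "protein_a": ["A", "B", "A"],
                "protein_b": ["B", "C", "C"],
                "p_adj": [0.001, 0.005, 0.5],
            }
        )
        net = build_network(pairs, threshold=0.01)
        assert net.degrees == {"A": 1, "B": 2, "C": 1}

    def test_no_significant_edges(self):
        pairs = pd.DataFrame(
            {"protein_a": ["A"], "protein_b": ["B"], "p_adj": [0.9]}
        )
        net = build_network(pairs, threshold=0.01)
        assert net.retained.empty
        assert net.degrees == {"A": 0, "B": 0}

    def test_threshold_one_gives_complete_graph(self):
        df = TestPairwiseCooccurrence().build()
        net = cooccurrence_network(df, "anchor", threshold=1.0)
        n = len(net.degrees)
        assert len(net.retained) == n * (n - 1) // 2

    def test_perfect_triple_forms_clique(self, rng):
        """Three proteins sharing an identical 15-of-30-genome profile are
        recovered as a 3-clique at FDR 0.01."""
        genomes = [f"g{i}" for i in range(30)]
        profile = (np.arange(30) < 15).astype(int)
        noise = rng.integers(0, 2, (30, 3))
        df = presence(
            genomes, ["anchor", "X", "Y", "Z", "n1", "n2", "n3"],
            np.column_stack([np.ones(30, int), profile, profile, profile, noise]),
        )
        net = cooccurrence_network(df, "anchor", q=0.01)
        clique = {("X", "Y"), ("X", "Z"), ("Y", "Z")}
        got = {
            tuple(sorted(e))
            for e in net.retained[["protein_a", "protein_b"]].itertuples(index=False, name=None)
        }
        assert clique <= got
        assert net.degrees["X"] >= 2 and net.degrees["Y"] >= 2 and net.degrees["Z"] >= 2


class TestReadMatrix:
    def test_round_trip(self):
        csv = "genome,A,B\ng1,1,0\ng2,0,1\ng3,1,1\n"
        df = read_presence_matrix(io.StringIO(csv))
        assert df.dtypes.unique().tolist() == [np.dtype(bool)]
        assert df.loc["g3", "A"]
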