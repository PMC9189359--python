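import itertools

import numpy as np
import pytest

from gseachain import (LeadingEdgeUnion, ValidationError, apriori,
                       correlation_matrix, d_norm, d_statistic,
                       rank_frequent, refine, support)
from gseachain.interactions import TransactionSet
from gseachain.mining import FrequentSetRecord, contains_contiguous


class TestSupport:
    def test_tabulated_values(self, we, we_transactions):
        """All tabulated supports except (B,C) reproduce exactly; the
        tabulated (B,C)=2 is inconsistent with the other eight under any
        containment rule, and contiguous counting gives 4 (the fixture's
        known_discrepancy)."""
        for chain, expected in we.support_table.items():
            got = support(chain, we_transactions)
            if chain in we.known_discrepancy:
                assert got == we.known_discrepancy[chain] == 4
            else:
                assert got == expected, chain

    def test_absent_gene_zero(self, we_transactions):
        assert support(("Q",), we_transactions) == 0
        assert support(("Q", "A"), we_transactions) == 0

    def test_contiguity_required(self, we_transactions):
        # (A, D) occurs in (A, C, D) but not consecutively there
        assert support(("A", "D"), we_transactions) == 1

    @pytest.mark.parametrize("transaction,candidate,expected", [
        (("A", "B", "C"), ("B", "C"), True),
        (("A", "B", "C"), ("A", "C"), False),
        (("A", "B", "C"), ("A", "B", "C"), True),
        (("A",), ("A", "B"), False),
        (("A", "B"), (), False),
    ])
    def test_contains_contiguous(self, transaction, candidate, expected):
        assert contains_contiguous(transaction, candidate) is expected

    def test_anti_monotone_on_worked_example(self, we_transactions):
        txs = we_transactions.all_transactions()
        for sup in txs:
            for k in range(1, len(sup)):
                for i in range(len(sup) - k + 1):
                    sub = sup[i:i + k]
                    assert support(sub, we_transactions) >= \
                        support(sup, we_transactions)


class TestApriori:
    def test_worked_example_trace(self, we, we_transactions):
        state = apriori(we_transactions, min_support=we.min_support)
        assert state.frequent_by_level[0] == [("A",), ("B",), ("C",), ("D",)]
        assert state.infrequent_by_level[0] == []
        level2 = state.frequent_by_level[1]
        assert ("A", "B") in level2 and ("C", "D") in level2
        assert ("A", "C") in state.infrequent_by_level[1]
        assert ("A", "D") in state.infrequent_by_level[1]
        # divergence from the tabulated trace: contiguous support makes
        # (B, C) frequent (support 4), so it is not pruned upstream
        assert ("B", "C") in level2

    def test_level3_pruning(self, we, we_transactions):
        """(A,C,D) contains the infrequent (A,C) and never becomes a
        candidate; (B,C,D) survives pruning (because (B,C) is frequent
        under the contiguous rule) but is itself infrequent."""
        state = apriori(we_transactions, min_support=3)
        scored = set(state.frequent) | set(state.infrequent)
        assert ("A", "C", "D") not in scored
        assert state.infrequent[("B", "C", "D")] == 2
        assert ("A", "B", "C", "D") not in scored  # pruned at level 4
        assert set(state.frequent) == {("A",), ("B",), ("C",), ("D",),
                                       ("A", "B"), ("B", "C"), ("C", "D")}

    def test_empty_transactions(self):
        state = apriori(TransactionSet(levels=[]), min_support=3)
        assert state.frequent == {} and state.infrequent == {}

    def test_min_support_one_keeps_everything(self, we_transactions):
        state = apriori(we_transactions, min_support=1)
        assert set(state.frequent) == set(we_transactions.all_transactions())

    def test_invalid_threshold(self, we_transactions):
        with pytest.raises(ValidationError):
            apriori(we_transactions, min_support=0)


def brute_force_frequent(transactions: TransactionSet, min_support: int):
    """Enumerate every contiguous sub-chain of every transaction, count,
    threshold — the oracle the pruned mining must match."""
    txs = transactions.all_transactions()
    candidates = set()
    for t in txs:
        for k in range(1, len(t) + 1):
            for i in range(len(t) - k + 1):
                candidates.add(t[i:i + k])
    return {c: s for c in candidates
            if (s := sum(contains_contiguous(t, c) for t in txs))
            >= min_support}


class TestAprioriOracle:
    @pytest.mark.parametrize("seed", range(25))
    def test_matches_bruteforce(self, seed):
        from gseachain import InteractionRecord, build_graph, \
            generate_transactions

        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 11))
        genes = [f"n{i}" for i in range(n)]
        records = [InteractionRecord(u, v, int(rng.choice([1, -1])))
                   for u, v in itertools.permutations(genes, 2)
                   if rng.random() < 0.3]
        graph = build_graph(records, restrict_to=genes)
        tx = generate_transactions(genes, graph, max_len=4)
        min_support = int(rng.integers(1, 5))
        state = apriori(tx, min_support=min_support)
        assert state.frequent == brute_force_frequent(tx, min_support)


class TestDStatistic:
    def test_two_gene_closed_form(self):
        m = np.array([[1, 1], [0, 1]])
        rng = np.random.default_rng(0)
        for a, b in rng.normal(size=(25, 2)):
            assert np.allclose(d_statistic([a, b], m), [a, a + b])

    def test_four_gene_closed_form(self, we, we_graph):
        m = correlation_matrix(we.genes, we_graph)
        rng = np.random.default_rng(1)
        for a, b, c, d in rng.normal(size=(25, 4)):
            assert np.allclose(d_statistic([a, b, c, d], m),
                               we.d_closed_form(a, b, c, d))

    def test_unit_delta_instance(self, we, we_graph):
        m = correlation_matrix(we.genes, we_graph)
        d = d_statistic([1.0, 1.0, 1.0, 1.0], m)
        assert np.allclose(d, [1, 2, -1, 3])
        assert d_norm(d) == pytest.approx(np.sqrt(15))

    def test_dimension_mismatch(self):
        with pytest.raises(ValidationError):
            d_statistic([1.0, 2.0], np.eye(3))

    def test_linearity_in_delta(self, we, we_graph):
        m = correlation_matrix(we.genes, we_graph)
        rng = np.random.default_rng(2)
        d1, d2 = rng.normal(size=(2, 4))
        a, b = 0.7, -2.5
        assert np.allclose(d_statistic(a * d1 + b * d2, m),
                           a * d_statistic(d1, m) + b * d_statistic(d2, m))


class TestDNorm:
    def test_single_gene_absolute_value(self):
        assert d_norm(d_statistic([-2.5], np.array([[1]]))) == 2.5

    def test_zero_vector(self):
        assert d_norm(np.zeros(4)) == 0.0

    def test_reordering_invariance(self, we, we_graph):
        rng = np.random.default_rng(3)
        delta = rng.normal(size=4)
        m = correlation_matrix(we.genes, we_graph)
        base = d_norm(d_statistic(delta, m))
        for _ in range(10):
            perm = rng.permutation(4)
            genes = tuple(np.array(we.genes, dtype=object)[perm])
            mp = correlation_matrix(genes, we_graph)
            assert d_norm(d_statistic(delta[perm], mp)) == pytest.approx(base)

    def test_concordance_rewards_agreement(self):
        """For X→Y (+1) and x > 0, a concordant y beats the discordant −y:
        x² + (x+y)² > x² + (x−y)²."""
        m = np.array([[1, 1], [0, 1]])
        rng = np.random.default_rng(4)
        for x, y in np.abs(rng.normal(size=(25, 2))) + 1e-3:
            assert d_norm(d_statistic([x, y], m)) > \
                d_norm(d_statistic([x, -y], m))


class TestRanking:
    def _rec(self, chain, norm):
        k = len(chain)
        return FrequentSetRecord(chain=chain, support=3,
                                 delta=np.ones(k), matrix=np.eye(k, dtype=int),
                                 d=np.ones(k), d_norm=norm)

    def test_sorted_within_cardinality(self):
        groups = rank_frequent([self._rec(("A", "B"), 1.0),
                                self._rec(("C", "D"), 3.0)])
        assert [r.chain for r in groups[2]] == [("C", "D"), ("A", "B")]
        assert [r.rank for r in groups[2]] == [1, 2]

    def test_cardinalities_never_mixed(self):
        groups = rank_frequent([self._rec(("A", "B"), 1.0),
                                self._rec(("A", "B", "C"), 0.5)])
        assert set(groups) == {2, 3}
        assert groups[2][0].rank == 1 and groups[3][0].rank == 1

    def test_tie_breaks_lexicographically(self):
        groups = rank_frequent([self._rec(("B", "C"), 2.0),
                                self._rec(("A", "D"), 2.0)])
        assert [r.chain for r in groups[2]] == [("A", "D"), ("B", "C")]


class TestRefine:
    def test_worked_example_unit_deltas(self, we, we_graph):
        leading = LeadingEdgeUnion(genes=we.genes, delta=np.ones(4))
        ranking = refine(leading, we_graph, min_support=3, max_len=4)
        singles = ranking[1]
        assert {r.chain for r in singles} == {("A",), ("B",), ("C",), ("D",)}
        assert all(r.d_norm == pytest.approx(1.0) for r in singles)
        assert {r.chain for r in ranking[2]} == {("A", "B"), ("B", "C"),
                                                 ("C", "D")}

    def test_empty_leading_edge(self, we_graph):
        leading = LeadingEdgeUnion(genes=(), delta=np.array([]))
        assert refine(leading, we_graph) == {}
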