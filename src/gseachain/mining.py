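"""Frequent-chain mining and the d statistic.

The support of a candidate chain is the number of transactions that contain
it as a CONTIGUOUS subsequence (each transaction counts at most once).  This
containment is anti-monotone — a super-chain can never be more frequent than
its sub-chains — which is exactly the property the Apriori pruning step
relies on.

The two-step Apriori procedure walks the transaction levels bottom-up: at
level i every surviving candidate with support ≥ min_support joins the
frequent set F, the rest join F̄, and any level-(i+1) transaction containing
a member of F̄ is removed before its level is scored.  Iteration stops when
a level has no surviving candidates.

Each frequent chain is then weighted by d = δ·M, the row-vector product of
its expression differences (in chain order) with its correlation matrix,
and scored by the Euclidean norm ‖d‖; for a single gene this reduces to
|δ|.  Because ‖d‖ grows with the number of genes, rankings are formed
within each cardinality only, ‖d‖ descending, ties broken lexicographically
by chain symbols.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .gsea import LeadingEdgeUnion
from .interactions import (Chain, InteractionGraph, TransactionSet,
                           correlation_matrix, generate_transactions,
                           DEFAULT_MAX_CHAIN_LEN)
from .io import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_MIN_SUPPORT = 3


def contains_contiguous(transaction: Chain, candidate: Chain) -> bool:
    """True iff ``candidate`` occurs as consecutive elements of ``transaction``."""
    k = len(candidate)
    if k == 0 or k > len(transaction):
        return False
    return any(transaction[i:i + k] == candidate
               for i in range(len(transaction) - k + 1))


def support(candidate: Chain, transactions: TransactionSet) -> int:
    """Number of transactions (over all lengths) containing the candidate."""
    candidate = tuple(candidate)
    return sum(contains_contiguous(t, candidate)
               for t in transactions.all_transactions())


@dataclass
class AprioriState:
    """Final state of the mining run.

    ``frequent`` and ``infrequent`` map chains to their support, grouped by
    level in ``frequent_by_level`` / ``infrequent_by_level``; the two sets
    are disjoint by construction.
    """

    frequent: dict[Chain, int] = field(default_factory=dict)
    infrequent: dict[Chain, int] = field(default_factory=dict)
    frequent_by_level: list[list[Chain]] = field(default_factory=list)
    infrequent_by_level: list[list[Chain]] = field(default_factory=list)
    min_support: int = DEFAULT_MIN_SUPPORT
    levels_run: int = 0


def apriori(transactions: TransactionSet,
            min_support: int = DEFAULT_MIN_SUPPORT) -> AprioriState:
    """Two-step Apriori over the chain transaction set.

    Candidates at each level are that level's transactions, minus any
    containing an already-infrequent chain as a contiguous subsequence.
    Support is always counted over the full original transaction set.
    """
    if min_support < 1:
        raise ValidationError("min_support must be >= 1")
    state = AprioriState(min_support=min_support)
    all_tx = transactions.all_transactions()
    if not all_tx:
        return state

    def supp(candidate: Chain) -> int:
        return sum(contains_contiguous(t, candidate) for t in all_tx)

    infrequent: list[Chain] = []
    for level_idx in range(transactions.max_len):
        candidates = [
            c for c in transactions.levels[level_idx]
            if not any(contains_contiguous(c, bad) for bad in infrequent)
        ]
        if not candidates:
            break
        state.levels_run = level_idx + 1
        freq_here: list[Chain] = []
        infreq_here: list[Chain] = []
        for cand in candidates:
            s = supp(cand)
            if s >= min_support:
                state.frequent[cand] = s
                freq_here.append(cand)
            else:
                state.infrequent[cand] = s
                infreq_here.append(cand)
        state.frequent_by_level.append(freq_here)
        state.infrequent_by_level.append(infreq_here)
        infrequent.extend(infreq_here)
    return state


def d_statistic(delta_sub: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """d = δ·M (row vector times correlation matrix)."""
    delta_sub = np.asarray(delta_sub, dtype=float)
    matrix = np.asarray(matrix)
    if delta_sub.ndim != 1 or matrix.shape != (len(delta_sub), len(delta_sub)):
        raise ValidationError(
            f"dimension mismatch: delta {delta_sub.shape}, M {matrix.shape}"
        )
    return delta_sub @ matrix


def d_norm(d: np.ndarray) -> float:
    """Euclidean norm ‖d‖; for a single gene this is |δ|."""
    return float(np.linalg.norm(np.asarray(d, dtype=float)))


@dataclass
class FrequentSetRecord:
    """A frequent chain with its support, M, d and ‖d‖."""

    chain: Chain
    support: int
    delta: np.ndarray
    matrix: np.ndarray
    d: np.ndarray
    d_norm: float
    rank: int | None = None  # 1-based rank within its cardinality group

    @property
    def cardinality(self) -> int:
        return len(self.chain)


def rank_frequent(records: list[FrequentSetRecord]
                  ) -> dict[int, list[FrequentSetRecord]]:
    """Group by cardinality; sort each group by ‖d‖ descending.

    Ties break lexicographically by chain symbols.  Chains of different
    cardinality are never compared.
    """
    groups: dict[int, list[FrequentSetRecord]] = {}
    for rec in records:
        groups.setdefault(rec.cardinality, []).append(rec)
    out: dict[int, list[FrequentSetRecord]] = {}
    for card in sorted(groups):
        ordered = sorted(groups[card], key=lambda r: (-r.d_norm, r.chain))
        for pos, rec in enumerate(ordered, start=1):
            rec.rank = pos
        out[card] = ordered
    return out


def refine(leading: LeadingEdgeUnion, graph: InteractionGraph,
           min_support: int = DEFAULT_MIN_SUPPORT,
           max_len: int = DEFAULT_MAX_CHAIN_LEN
           ) -> dict[int, list[FrequentSetRecord]]:
    """Full refinement: transactions → Apriori → d → within-cardinality ranks.

    ``leading`` supplies both the seed genes (in rank order) and their δ
    values; the result maps each cardinality to its ranked records.
    """
    if len(leading) == 0:
        return {}
    transactions = generate_transactions(leading.genes, graph,
                                         max_len=max_len)
    state = apriori(transactions, min_support=min_support)
    delta_by_gene = dict(zip(leading.genes, leading.delta))
    records = []
    for chain, supp in state.frequent.items():
        delta_sub = np.array([delta_by_gene[g] for g in chain])
        m = correlation_matrix(chain, graph)
        d = d_statistic(delta_sub, m)
        records.append(FrequentSetRecord(
            chain=chain, support=supp, delta=delta_sub, matrix=m,
            d=d, d_norm=d_norm(d)))
    return rank_frequent(records)
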