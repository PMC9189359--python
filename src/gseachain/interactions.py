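"""Signed interaction graphs, correlation matrices and chain generation.

Prior knowledge enters as directed gene–gene edges signed +1 (upregulation)
or −1 (downregulation).  For an ordered gene tuple (g₁…g_k) the correlation
matrix M has a_ii = 1 and, for i ≠ j, a_ij = +1/−1/0 according to whether gᵢ
up-/down-regulates gⱼ or has no recorded effect — M covers ALL ordered pairs
in the tuple, not only consecutive ones.

A chain (transaction) is an ordered tuple of distinct genes where each
consecutive pair is a signed edge.  Starting from singletons of the
leading-edge union, chains grow one gene at a time through out-neighbours of
their last gene, never revisiting a gene, up to a maximum length (default
4).  Enumeration order is deterministic: input order of the seed genes, then
lexicographic neighbour order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .io import InteractionRecord, ValidationError

logger = logging.getLogger(__name__)

Chain = tuple[str, ...]

DEFAULT_MAX_CHAIN_LEN = 4


class InteractionGraph:
    """Directed graph with a ±1 sign per edge, backed by networkx."""

    def __init__(self, graph: nx.DiGraph | None = None):
        self._g = graph if graph is not None else nx.DiGraph()

    @property
    def nx(self) -> nx.DiGraph:
        return self._g

    @property
    def nodes(self) -> list[str]:
        return list(self._g.nodes)

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def sign(self, source: str, target: str) -> int:
        """+1/−1 for a recorded edge, 0 for no effect."""
        data = self._g.get_edge_data(source, target)
        return 0 if data is None else data["sign"]

    def out_neighbors(self, gene: str) -> list[str]:
        if gene not in self._g:
            return []
        return sorted(self._g.successors(gene))

    def edges(self) -> list[tuple[str, str, int]]:
        return [(u, v, d["sign"]) for u, v, d in self._g.edges(data=True)]


def build_graph(records: Iterable[InteractionRecord],
                restrict_to: Iterable[str] | None = None) -> InteractionGraph:
    """Assemble the signed graph, resolving duplicate edges.

    Concordant duplicates collapse to one edge; an ordered pair recorded
    with both signs is contradictory and collapses to NO edge (a_ij = 0),
    with a logged warning.  With ``restrict_to``, only records whose two
    endpoints are both in the given gene set are kept.
    """
    keep = set(restrict_to) if restrict_to is not None else None
    signs: dict[tuple[str, str], set[int]] = {}
    for rec in records:
        if keep is not None and (rec.source not in keep or
                                 rec.target not in keep):
            continue
        signs.setdefault((rec.source, rec.target), set()).add(rec.sign)
    g = nx.DiGraph()
    if keep is not None:
        g.add_nodes_from(sorted(keep))
    n_conflicts = 0
    for (u, v), ss in signs.items():
        if len(ss) > 1:
            n_conflicts += 1
            continue
        g.add_edge(u, v, sign=next(iter(ss)))
    if n_conflicts:
        logger.warning("build_graph: %d ordered pair(s) had contradictory "
                       "signs and were dropped", n_conflicts)
    return InteractionGraph(g)


def correlation_matrix(genes: Sequence[str],
                       graph: InteractionGraph) -> np.ndarray:
    """M over an ordered gene tuple: a_ii = 1, a_ij = sign of gᵢ→gⱼ else 0."""
    genes = tuple(genes)
    if not genes:
        raise ValidationError("empty gene tuple")
    if len(set(genes)) != len(genes):
        raise ValidationError(f"repeated gene in tuple {genes}")
    k = len(genes)
    m = np.eye(k, dtype=int)
    for i, gi in enumerate(genes):
        for j, gj in enumerate(genes):
            if i != j:
                m[i, j] = graph.sign(gi, gj)
    return m


@dataclass
class TransactionSet:
    """Chains grouped by length: ``levels[0]`` holds I₁ (singletons)."""

    levels: list[list[Chain]]

    @property
    def max_len(self) -> int:
        return len(self.levels)

    def level(self, i: int) -> list[Chain]:
        """Chains of length ``i`` (1-based level index)."""
        return self.levels[i - 1]

    def all_transactions(self) -> list[Chain]:
        return [c for level in self.levels for c in level]

    def __len__(self) -> int:
        return sum(len(level) for level in self.levels)


def generate_transactions(genes: Sequence[str], graph: InteractionGraph,
                          max_len: int = DEFAULT_MAX_CHAIN_LEN
                          ) -> TransactionSet:
    """Grow chains from singletons through signed out-edges.

    Level i+1 extends every level-i chain by each out-neighbour of its last
    gene that is (a) among the seed genes and (b) not already in the chain.
    """
    if max_len < 1:
        raise ValidationError("max_len must be >= 1")
    seeds = list(dict.fromkeys(genes))  # preserve order, drop duplicates
    universe = set(seeds)
    levels: list[list[Chain]] = [[(g,) for g in seeds]]
    for _ in range(1, max_len):
        nxt: list[Chain] = []
        for chain in levels[-1]:
            for nb in graph.out_neighbors(chain[-1]):
                if nb in universe and nb not in chain:
                    nxt.append(chain + (nb,))
        if not nxt:
            break
        levels.append(nxt)
    return TransactionSet(levels=levels)
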