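"""Weighted running-sum enrichment with permutation p-values.

For a ranked gene list g with differences δ (non-increasing) and a gene set,
the membership indicator r marks hits.  The enrichment score is accumulated
by the recurrence

    es_0 = 0
    es_i = r_i |δ_i|^p / N_R + (r_i - 1) / (n - N_H) + es_{i-1}

with N_H = Σ r_i (hit count) and N_R = Σ r_i |δ_i|^p (total hit weight); the
weight exponent p defaults to 1.  The recurrence telescopes to zero at i = n
whenever N_R > 0, and the curve is defined as identically zero when N_R = 0
(no member of the set appears in the list).  The reported statistic is
es_max = sign(es_k) · max_i |es_i|, with k the first index attaining the
maximum absolute value.

Significance is assessed by disrupting the order of genes in g (δ stays tied
to rank positions), recording |es'_max| for each of v permutations, and
reading the p-value off the plain empirical CDF:
p = 1 − F̂_v(|es_max|), where F̂_v(x) = #{|es'_max| ≤ x} / v.  No continuity
correction is applied, so p = 0 is attainable and is reported together with
v.

The leading-edge subset collects the hits at or before the peak for a
positive es_max (at or after it for a negative one); a ``strict`` mode
instead uses the strictly-before convention for positive peaks, under which
a peak at the first hit yields an empty subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import false_discovery_control

from .io import GeneSetCollection, ValidationError
from .prep import RankedList

logger = logging.getLogger(__name__)

DEFAULT_WEIGHT_P = 1.0
DEFAULT_PERMUTATIONS = 1000
DEFAULT_ALPHA = 0.05


@dataclass
class IndicatorVector:
    """0/1 membership of each ranked gene in a gene set, plus N_H and N_R."""

    r: np.ndarray
    n_hits: int
    n_r: float
    p: float

    def __len__(self) -> int:
        return len(self.r)


@dataclass
class NullDistribution:
    """Sorted |es'_max| values from v gene-order permutations."""

    abs_max: np.ndarray  # ascending
    seed: int
    v: int

    def __post_init__(self) -> None:
        self.abs_max = np.sort(np.asarray(self.abs_max, dtype=float))
        if len(self.abs_max) != self.v:
            raise ValidationError("null distribution size != v")
        if (self.abs_max < 0).any():
            raise ValidationError("null |es_max| values must be >= 0")


@dataclass
class EnrichmentResult:
    set_id: str
    es_max: float
    peak_index: int  # 1-based
    p_value: float
    leading_edge: tuple[str, ...]
    n_permutations: int
    n_hits: int
    bh_fdr: float | None = None


def indicator(ranked: RankedList, members: Iterable[str],
              p: float = DEFAULT_WEIGHT_P) -> IndicatorVector:
    """Membership indicator r over the ranked list, with N_H and N_R."""
    members = set(members)
    r = np.fromiter((g in members for g in ranked.genes), dtype=float,
                    count=len(ranked))
    n_r = float(np.sum(r * np.abs(ranked.delta) ** p))
    return IndicatorVector(r=r, n_hits=int(r.sum()), n_r=n_r, p=p)


def es_curve(delta: np.ndarray, r: np.ndarray | IndicatorVector,
             p: float = DEFAULT_WEIGHT_P) -> np.ndarray:
    """Evaluate the running-sum recurrence over the whole list.

    Returns es_1..es_n.  When N_R = 0 the curve is identically zero (the
    division-by-zero guard); when every gene is a hit the miss term is never
    evaluated.
    """
    if isinstance(r, IndicatorVector):
        p = r.p
        r = r.r
    delta = np.asarray(delta, dtype=float)
    r = np.asarray(r, dtype=float)
    if delta.shape != r.shape:
        raise ValidationError("delta and indicator lengths differ")
    n = len(delta)
    weights = np.abs(delta) ** p
    n_r = float(np.sum(r * weights))
    if n_r == 0.0:
        return np.zeros(n)
    n_h = int(r.sum())
    steps = r * weights / n_r
    if n_h < n:
        steps = steps + (r - 1.0) / (n - n_h)
    return np.cumsum(steps)


def es_max(curve: np.ndarray) -> tuple[float, int]:
    """Signed extremum of the curve and its 1-based peak index.

    Returns sign(es_k)·max|es_i| with k the first index attaining the
    maximum absolute value.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.size == 0:
        raise ValidationError("empty ES curve")
    k = int(np.argmax(np.abs(curve)))
    return float(curve[k]), k + 1


def _null_abs_max(delta: np.ndarray, member_mask: np.ndarray,
                  perm_idx: np.ndarray, p: float) -> np.ndarray:
    """|es'_max| for each row of permuted gene orders.

    ``perm_idx`` holds v permutations of 0..n-1: row k places gene
    ``perm_idx[k, i]`` at rank position i, so the permuted indicator is a
    gather of the membership mask while |δ|^p stays tied to positions.
    """
    weights = np.abs(np.asarray(delta, dtype=float)) ** p
    n = len(weights)
    r_mat = member_mask[perm_idx].astype(float)  # v × n
    n_h = int(member_mask.sum())
    n_r = r_mat @ weights
    ok = n_r > 0
    steps = r_mat * weights[None, :]
    steps[ok] /= n_r[ok, None]
    if n_h < n:
        steps += (r_mat - 1.0) / (n - n_h)
    steps[~ok] = 0.0
    curves = np.cumsum(steps, axis=1)
    out = np.max(np.abs(curves), axis=1)
    out[~ok] = 0.0
    return out


def permutation_null(ranked: RankedList, members: Iterable[str], v: int,
                     seed: int, p: float = DEFAULT_WEIGHT_P
                     ) -> NullDistribution:
    """Null distribution of |es'_max| under v random gene-order shuffles."""
    if v < 1:
        raise ValidationError("v must be >= 1")
    rng = np.random.default_rng(seed)
    members = set(members)
    mask = np.fromiter((g in members for g in ranked.genes), dtype=bool,
                       count=len(ranked))
    perm_idx = _random_permutations(rng, v, len(ranked))
    null = _null_abs_max(ranked.delta, mask, perm_idx, p)
    return NullDistribution(abs_max=null, seed=seed, v=v)


def _random_permutations(rng: np.random.Generator, v: int, n: int
                         ) -> np.ndarray:
    idx = np.tile(np.arange(n), (v, 1))
    return rng.permuted(idx, axis=1)


def empirical_p(observed_abs: float, null: NullDistribution) -> float:
    """p = 1 − F̂_v(observed) with the plain empirical CDF of the null."""
    if observed_abs < 0:
        raise ValidationError("observed |es_max| must be >= 0")
    if null.v == 0 or len(null.abs_max) == 0:
        raise ValidationError("empty null distribution")
    cdf = np.searchsorted(null.abs_max, observed_abs, side="right") / null.v
    return float(1.0 - cdf)


def leading_edge(ranked: RankedList, r: IndicatorVector | np.ndarray,
                 es_max_value: float, peak_index: int,
                 mode: str = "inclusive") -> tuple[str, ...]:
    """Hits at/before the peak (positive es_max) or at/after it (negative).

    ``mode="strict"`` uses strictly-before for positive peaks, so a
    peak at the first hit yields an empty subset; negative peaks use >= in
    both modes.  A zero es_max always yields the empty subset.
    """
    if mode not in ("inclusive", "strict"):
        raise ValidationError(f"unknown leading-edge mode {mode!r}")
    rv = r.r if isinstance(r, IndicatorVector) else np.asarray(r)
    if es_max_value == 0:
        return ()
    if not 1 <= peak_index <= len(ranked):
        raise ValidationError("peak index out of range")
    i = peak_index - 1
    if es_max_value > 0:
        stop = i if mode == "strict" else i + 1
        sel = np.nonzero(rv[:stop] == 1)[0]
    else:
        sel = i + np.nonzero(rv[i:] == 1)[0]
    return tuple(ranked.genes[sel])


def run_gsea(
    ranked: RankedList,
    collection: GeneSetCollection,
    permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    p: float = DEFAULT_WEIGHT_P,
    leading_edge_mode: str = "inclusive",
) -> list[EnrichmentResult]:
    """Score every gene set of a collection against the ranked list.

    One block of ``permutations`` gene-order shuffles is drawn per run and
    shared by all sets, so each permuted ordering yields one |es'_max| per
    pathway.  Genes in a set but absent from the ranked list are ignored.
    Sets with no overlap (all-zero curve) report es_max 0, empty leading
    edge and p = 1 by convention.  A Benjamini–Hochberg FDR column is
    attached as supplementary output; selection downstream uses raw p only.
    """
    results: list[EnrichmentResult] = []
    if len(collection) == 0:
        logger.warning("run_gsea: empty gene-set collection")
        return results
    rng = np.random.default_rng(seed)
    perm_idx = _random_permutations(rng, permutations, len(ranked))
    for gene_set in collection:
        ind = indicator(ranked, gene_set.members, p=p)
        curve = es_curve(ranked.delta, ind)
        observed, peak = es_max(curve)
        if ind.n_r == 0.0:
            results.append(EnrichmentResult(
                set_id=gene_set.set_id, es_max=0.0, peak_index=peak,
                p_value=1.0, leading_edge=(), n_permutations=permutations,
                n_hits=ind.n_hits))
            continue
        null = _null_abs_max(ranked.delta, ind.r.astype(bool), perm_idx, p)
        pval = float(np.count_nonzero(null > abs(observed)) / permutations)
        le = leading_edge(ranked, ind, observed, peak, mode=leading_edge_mode)
        results.append(EnrichmentResult(
            set_id=gene_set.set_id, es_max=observed, peak_index=peak,
            p_value=pval, leading_edge=le, n_permutations=permutations,
            n_hits=ind.n_hits))
    if results:
        fdr = false_discovery_control([r.p_value for r in results],
                                      method="bh")
        for r, q in zip(results, fdr):
            r.bh_fdr = float(q)
    return results


def union_leading_edges(results: Sequence[EnrichmentResult],
                        ranked: RankedList,
                        alpha: float = DEFAULT_ALPHA) -> "LeadingEdgeUnion":
    """Union of leading edges over results with p < alpha.

    Genes are deduplicated and ordered by their best (smallest-numbered)
    rank in the list; each carries its δ for the downstream d statistic.
    ``alpha >= 1`` disables the significance filter entirely, so every set
    contributes its leading edge.
    """
    genes: set[str] = set()
    for res in results:
        if alpha >= 1.0 or res.p_value < alpha:
            genes.update(res.leading_edge)
    positions = {g: i for i, g in enumerate(ranked.genes)}
    ordered = sorted(genes, key=lambda g: positions[g])
    delta = np.array([ranked.delta[positions[g]] for g in ordered])
    return LeadingEdgeUnion(genes=tuple(ordered), delta=delta)


@dataclass
class LeadingEdgeUnion:
    """Deduplicated leading-edge genes, rank-ordered, with their δ values."""

    genes: tuple[str, ...]
    delta: np.ndarray

    def __len__(self) -> int:
        return len(self.genes)

    def delta_of(self, gene: str) -> float:
        return float(self.delta[self.genes.index(gene)])
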