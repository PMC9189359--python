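"""Built-in worked example and parameterised simulations.

Two generators cover everything the pipeline needs without any downloads:

* :func:`worked_example` — the constant four-gene fixture (A, B, C, D) with
  its signed relations, expected transactions, support table, correlation
  matrix and the closed form of d, used to pin down every mining operation.
  The fixture's tabulated support for (B, C) is 2 while contiguous
  containment over the listed transactions gives 4; the entry is stored as
  tabulated and flagged ``known_discrepancy`` so tests can assert both the
  implementation's rule and the documented divergence.

* :func:`simulate_experiment` — a seeded end-to-end experiment: a control
  sample with log-normal (long right tail) expression, a treatment sample
  shifted on the log2 scale by planted effects plus Gaussian noise, a
  pathway collection with one planted (up-shifted) pathway, and a sparse
  random signed network in which a concordant regulatory path is forced.
  The planted chain is the middle 3-gene stretch of a 5-gene forced path:
  with a maximum chain length of 4 and contiguous-subsequence support, a
  chain recurs across transactions (and can therefore be frequent) only
  when it has flanking interactions, so one upstream and one downstream
  regulator are planted around it.  The flanking regulators carry the
  pathway-level effect (so they sit safely inside the leading edge), while
  the chain genes carry a distinctly stronger one (pathway effect + 1 by
  default): the tracked chain is the strongest concordant signal, and path
  windows that include a flank are correspondingly weaker in ‖d‖.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .interactions import Chain
from .io import (ExpressionTable, GeneSet, GeneSetCollection,
                 InteractionRecord, ValidationError)


# ---------------------------------------------------------------------------
# Worked example
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WorkedExample:
    """Immutable four-gene fixture with all expected intermediate values."""

    genes: tuple[str, ...]
    records: tuple[InteractionRecord, ...]
    transactions_by_level: tuple[tuple[Chain, ...], ...]
    #: tabulated support values; (B, C) is flagged below
    support_table: dict[Chain, int]
    #: chains whose tabulated support disagrees with contiguous counting,
    #: mapped to the value the contiguous rule gives
    known_discrepancy: dict[Chain, int]
    matrix: tuple[tuple[int, ...], ...]
    min_support: int
    max_len: int

    def d_closed_form(self, a: float, b: float, c: float, d: float
                      ) -> tuple[float, float, float, float]:
        """d for the tuple (A,B,C,D) under the fixture's M."""
        return (a, a + b, -a - b + c, a + c + d)


def worked_example() -> WorkedExample:
    """The constant (A, B, C, D) fixture."""
    records = (
        InteractionRecord("A", "B", +1),
        InteractionRecord("A", "C", -1),
        InteractionRecord("A", "D", +1),
        InteractionRecord("B", "C", -1),
        InteractionRecord("C", "D", +1),
    )
    transactions = (
        (("A",), ("B",), ("C",), ("D",)),
        (("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("C", "D")),
        (("A", "B", "C"), ("A", "C", "D"), ("B", "C", "D")),
        (("A", "B", "C", "D"),),
    )
    support_table = {
        ("A",): 7, ("B",): 6, ("C",): 8, ("D",): 6,
        ("A", "B"): 3, ("A", "C"): 2, ("A", "D"): 1,
        ("B", "C"): 2, ("C", "D"): 4,
    }
    matrix = (
        (1, 1, -1, 1),
        (0, 1, -1, 0),
        (0, 0, 1, 1),
        (0, 0, 0, 1),
    )
    return WorkedExample(
        genes=("A", "B", "C", "D"),
        records=records,
        transactions_by_level=transactions,
        support_table=support_table,
        known_discrepancy={("B", "C"): 4},
        matrix=matrix,
        min_support=3,
        max_len=4,
    )


# ---------------------------------------------------------------------------
# Simulated experiments
# ---------------------------------------------------------------------------


@dataclass
class PlantedChain:
    """Ordered genes, edge signs and per-gene log2 effect sizes."""

    genes: tuple[str, ...]
    signs: tuple[int, ...]
    effects: tuple[float, ...]


@dataclass
class SimulationSpec:
    """Study conditions for one simulated knockdown-style experiment.

    Defaults: 2,000 genes, 50 pathways of 40 members, one planted pathway
    shifted by 2.0 log2 units, Gaussian log2 noise with SD 0.3, and a sparse
    background network (directed edge probability 0.001, giving a few
    thousand signed edges over the universe).
    """

    n_genes: int = 2000
    n_pathways: int = 50
    pathway_size: tuple[int, int] = (40, 40)
    planted_pathway_effect: float = 2.0
    noise_sd: float = 0.3
    network_edge_prob: float = 0.001
    chain_len: int = 3
    chain_effect: float | None = None  # defaults to pathway effect + 1
    flank_effect: float | None = None  # defaults to the pathway effect
    seed: int = 0
    #: log-normal parameters for control expression (long right tail)
    lognormal_mean: float = 3.0
    lognormal_sigma: float = 1.5


@dataclass
class TruthRecord:
    """Planted identities for scoring recovery."""

    pathway_id: str
    pathway_members: tuple[str, ...]
    chain: PlantedChain
    #: forced 5-gene path: flank_up → chain genes → flank_down
    forced_path: tuple[str, ...]


def _gene_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def simulate_experiment(spec: SimulationSpec) -> tuple[
        ExpressionTable, ExpressionTable, GeneSetCollection,
        list[InteractionRecord], TruthRecord]:
    """Generate (treatment, control, pathways, network, truth) from a spec.

    Control counts follow a log-normal law; treatment counts multiply the
    control by 2**(effect + noise) per gene, so the TPM log2 fold-change
    recovers the planted effect up to noise and a small compositional
    offset.  All randomness flows from ``spec.seed``.
    """
    lo, hi = spec.pathway_size
    if hi > spec.n_genes or lo < 1 or lo > hi:
        raise ValidationError("infeasible pathway size range "
                              f"{spec.pathway_size} for {spec.n_genes} genes")
    if spec.chain_len + 2 > hi:
        raise ValidationError("planted path (chain + 2 flanks) exceeds the "
                              "planted pathway size")
    rng = np.random.default_rng(spec.seed)
    genes = np.array(_gene_names(spec.n_genes), dtype=object)
    lengths = pd.Series(rng.integers(200, 10_001, size=spec.n_genes),
                        index=pd.Index(genes, name="gene"))

    # planted regulatory path: flank_up -> c1 -> c2 -> ... -> flank_down
    n_path = spec.chain_len + 2
    path_genes = tuple(rng.choice(genes, size=n_path, replace=False))
    chain_genes = path_genes[1:-1]
    effect = (spec.planted_pathway_effect + 1.0 if spec.chain_effect is None
              else spec.chain_effect)
    planted_chain = PlantedChain(
        genes=chain_genes,
        signs=tuple([+1] * (spec.chain_len - 1)),
        effects=tuple([effect] * spec.chain_len),
    )

    # planted pathway: path genes plus random extra members
    size = int(rng.integers(lo, hi + 1))
    others = [g for g in genes if g not in set(path_genes)]
    extra = rng.choice(np.array(others, dtype=object),
                       size=size - n_path, replace=False)
    planted_members = tuple(path_genes) + tuple(extra)

    sets = [GeneSet("PLANTED", "planted pathway", (),
                    frozenset(planted_members))]
    for k in range(1, spec.n_pathways):
        sz = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=sz, replace=False)
        sets.append(GeneSet(f"NULL{k:03d}", f"background pathway {k}", (),
                            frozenset(members)))
    collection = GeneSetCollection(sets)

    # expression: control log-normal counts, treatment shifted on log2 scale
    control_counts = rng.lognormal(mean=spec.lognormal_mean,
                                   sigma=spec.lognormal_sigma,
                                   size=spec.n_genes)
    shift = np.zeros(spec.n_genes)
    member_idx = {g: i for i, g in enumerate(genes)}
    flank = (spec.planted_pathway_effect if spec.flank_effect is None
             else spec.flank_effect)
    for g in planted_members:
        shift[member_idx[g]] = spec.planted_pathway_effect
    for g in chain_genes:
        shift[member_idx[g]] = effect
    shift[member_idx[path_genes[0]]] = flank
    shift[member_idx[path_genes[-1]]] = flank
    noise = rng.normal(0.0, spec.noise_sd, size=spec.n_genes)
    treatment_counts = control_counts * 2.0 ** (shift + noise)

    idx = pd.Index(genes, name="gene")
    control = ExpressionTable(
        data=pd.DataFrame({"control": control_counts}, index=idx),
        lengths=lengths, unit="counts")
    treatment = ExpressionTable(
        data=pd.DataFrame({"treatment": treatment_counts}, index=idx),
        lengths=lengths, unit="counts")

    # background network: sparse random signed digraph, forced path on top
    records: list[InteractionRecord] = []
    n_background = rng.binomial(spec.n_genes * (spec.n_genes - 1),
                                spec.network_edge_prob)
    src = rng.integers(0, spec.n_genes, size=n_background)
    tgt = rng.integers(0, spec.n_genes, size=n_background)
    sgn = rng.choice([1, -1], size=n_background)
    forced_pairs = set(zip(path_genes[:-1], path_genes[1:]))
    seen: set[tuple[str, str]] = set()
    for s, t, x in zip(src, tgt, sgn):
        if s == t:
            continue
        u, v = genes[s], genes[t]
        if (u, v) in seen or (u, v) in forced_pairs:
            continue
        seen.add((u, v))
        records.append(InteractionRecord(u, v, int(x), "background"))
    for u, v in zip(path_genes[:-1], path_genes[1:]):
        records.append(InteractionRecord(u, v, +1, "planted"))

    truth = TruthRecord(pathway_id="PLANTED",
                        pathway_members=planted_members,
                        chain=planted_chain,
                        forced_path=tuple(path_genes))
    return treatment, control, collection, records, truth
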