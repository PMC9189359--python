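"""Expression preprocessing: TPM, low-expression filter, δ and ranking.

The contrast of interest is a treatment sample against a control sample
(e.g. a miRNA-knockdown retina against its negative control).  Expression is
normalised to transcripts per million (TPM), genes below a TPM floor in any
compared sample are removed, and the per-gene expression difference is the
log2 fold-change δ = log2(TPM_treatment / TPM_control).  Replicate contrasts
may be combined by a sign-concordance filter.  The ranked list (δ
non-increasing) is the substrate of the enrichment engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionTable, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_TPM_FLOOR = 1.0e-6


@dataclass
class DifferenceVector:
    """Per-gene expression differences δ (log2 fold-change of TPM).

    ``genes`` and ``delta`` are aligned; symbols are unique and every δ is
    finite.
    """

    genes: np.ndarray
    delta: np.ndarray

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.delta = np.asarray(self.delta, dtype=float)
        if self.genes.shape != self.delta.shape:
            raise ValidationError("genes and delta must have equal length")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene symbols in difference vector")
        if not np.all(np.isfinite(self.delta)):
            raise ValidationError("non-finite delta value")

    def __len__(self) -> int:
        return len(self.genes)

    def as_series(self) -> pd.Series:
        return pd.Series(self.delta, index=pd.Index(self.genes, name="gene"),
                         name="delta")


@dataclass
class RankedList(DifferenceVector):
    """A :class:`DifferenceVector` ordered so δ is non-increasing.

    Rank positions are 1-based: the gene with the largest δ has rank 1.
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(np.diff(self.delta) > 0):
            raise ValidationError("ranked list must be non-increasing in delta")

    def rank_of(self, gene: str) -> int:
        idx = np.nonzero(self.genes == gene)[0]
        if idx.size == 0:
            raise KeyError(gene)
        return int(idx[0]) + 1


def compute_tpm(table: ExpressionTable) -> ExpressionTable:
    """Convert read counts to TPM.

    Per gene, rate = count / (length in kb); per sample,
    TPM = rate / Σ rate × 1e6, so every sample column sums to 1e6.
    """
    if table.unit != "counts":
        raise ValidationError("compute_tpm requires a counts table")
    kb = table.lengths.values / 1000.0
    rates = table.data.values / kb[:, None]
    totals = rates.sum(axis=0)
    zero = totals == 0
    if zero.any():
        bad = [s for s, z in zip(table.samples, zero) if z]
        raise ValidationError(f"all-zero sample column(s): {bad}")
    tpm = rates / totals * 1.0e6
    data = pd.DataFrame(tpm, index=table.genes, columns=table.samples)
    return ExpressionTable(data=data, lengths=table.lengths.copy(), unit="tpm")


def filter_low_expression(table: ExpressionTable,
                          floor: float = DEFAULT_TPM_FLOOR) -> ExpressionTable:
    """Keep genes whose TPM is >= ``floor`` in every sample.

    Genes with TPM below the floor in any compared sample are excluded;
    equality at the boundary retains the gene.
    """
    if table.unit != "tpm":
        raise ValidationError("filter_low_expression requires a TPM table")
    keep = (table.data.values >= floor).all(axis=1)
    if not keep.any():
        logger.warning("low-expression filter removed every gene "
                       "(floor=%g)", floor)
    return ExpressionTable._subset(table.data.loc[keep],
                                   table.lengths.loc[keep], "tpm")


def log2_fold_change(treatment: pd.Series,
                     control: pd.Series) -> DifferenceVector:
    """δ = log2(treatment / control) over genes shared by both samples.

    Genes absent from either side are dropped (count logged).  Both inputs
    must already be floor-filtered: a zero or negative TPM reaching this
    operation is a contract violation.
    """
    shared = treatment.index.intersection(control.index)
    n_dropped = (len(treatment) - len(shared)) + (len(control) - len(shared))
    if n_dropped:
        logger.info("log2_fold_change: dropped %d gene(s) absent from one side",
                    n_dropped)
    t = treatment.loc[shared].values.astype(float)
    c = control.loc[shared].values.astype(float)
    if np.any(t <= 0) or np.any(c <= 0):
        raise ValidationError(
            "zero or negative TPM reached log2_fold_change; apply "
            "filter_low_expression first"
        )
    return DifferenceVector(genes=shared.values, delta=np.log2(t / c))


def concordance_filter(replicate_deltas: list[DifferenceVector]
                       ) -> DifferenceVector:
    """Keep genes whose δ sign agrees across every replicate contrast.

    A gene passes iff it is present in all vectors and its δ values are all
    strictly positive or all strictly negative (an exact zero anywhere drops
    it).  The output δ is the mean over replicates.  With a single replicate
    this is the identity.
    """
    if not replicate_deltas:
        raise ValidationError("concordance_filter needs >=1 replicate vector")
    if len(replicate_deltas) == 1:
        return replicate_deltas[0]
    frames = [dv.as_series() for dv in replicate_deltas]
    mat = pd.concat(frames, axis=1, join="inner")
    signs = np.sign(mat.values)
    concordant = (signs > 0).all(axis=1) | (signs < 0).all(axis=1)
    kept = mat.loc[concordant]
    return DifferenceVector(genes=kept.index.values,
                            delta=kept.values.mean(axis=1))


def rank_genes(dv: DifferenceVector) -> RankedList:
    """Order genes by descending δ; ties break by ascending gene symbol."""
    order = np.lexsort((dv.genes.astype(str), -dv.delta))
    return RankedList(genes=dv.genes[order], delta=dv.delta[order])


def prepare_ranked_list(
    counts: ExpressionTable,
    treatment_samples: list[str],
    control_samples: list[str],
    floor: float = DEFAULT_TPM_FLOOR,
) -> RankedList:
    """Counts → TPM → floor filter → per-replicate δ → concordance → ranking.

    ``treatment_samples[i]`` is contrasted with ``control_samples[i]``; the
    replicate δ vectors then pass the sign-concordance filter.
    """
    if len(treatment_samples) != len(control_samples):
        raise ValidationError("treatment and control sample lists must pair up")
    if not treatment_samples:
        raise ValidationError("at least one treatment/control pair required")
    tpm = compute_tpm(counts) if counts.unit == "counts" else counts
    deltas = []
    for t_name, c_name in zip(treatment_samples, control_samples):
        pair = ExpressionTable._subset(tpm.data[[t_name, c_name]],
                                       tpm.lengths, "tpm")
        kept = filter_low_expression(pair, floor=floor)
        deltas.append(log2_fold_change(kept.data[t_name], kept.data[c_name]))
    return rank_genes(concordance_filter(deltas))
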