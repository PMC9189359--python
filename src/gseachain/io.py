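"""Readers and writers for on-disk artifacts.

Four file families are handled:

* expression tables — TSV with ``gene``, ``length`` and one column per
  sample, holding read counts or precomputed TPM;
* gene-set collections — standard GMT, or a KEGG ko00001-style nested JSON
  hierarchy with category-based exclusion;
* signed gene–gene interaction networks in the Reactome
  ``FIsInGene ... with annotations`` tab-separated dialect;
* result reports (enrichment results and frequent-set records) as TSV or
  JSON, round-tripping all numeric fields.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TPM_SUM = 1.0e6
TPM_SUM_RTOL = 1.0e-9


class ParseError(ValueError):
    """A file did not conform to its declared dialect."""


class ValidationError(ValueError):
    """Parsed content violated a domain invariant."""


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------


@dataclass
class ExpressionTable:
    """Gene-level expression values for one or more samples.

    Parameters
    ----------
    data
        DataFrame indexed by unique gene symbol, one column per sample,
        all values nonnegative.
    lengths
        Transcript length in base pairs per gene (positive), aligned to
        ``data.index``.
    unit
        ``"counts"`` for raw read counts, ``"tpm"`` once normalised; in the
        latter state every sample column sums to 1e6 within relative
        tolerance 1e-9.
    """

    data: pd.DataFrame
    lengths: pd.Series
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in ("counts", "tpm"):
            raise ValidationError(f"unknown unit_state {self.unit!r}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique()
            raise ValidationError(f"duplicate gene symbols: {list(dupes)}")
        if (self.data.values < 0).any():
            raise ValidationError("expression values must be >= 0")
        if (self.lengths.values <= 0).any():
            raise ValidationError("transcript lengths must be > 0")
        if not self.lengths.index.equals(self.data.index):
            raise ValidationError("lengths not aligned to gene index")
        if self.unit == "tpm":
            sums = self.data.sum(axis=0)
            if not np.allclose(sums, TPM_SUM, rtol=TPM_SUM_RTOL, atol=0.0):
                raise ValidationError(
                    f"TPM columns must sum to 1e6; got {sums.to_dict()}"
                )

    @classmethod
    def _subset(cls, data: pd.DataFrame, lengths: pd.Series,
                unit: str) -> "ExpressionTable":
        """Build a table without the TPM column-sum check.

        Used for row subsets of a TPM table (e.g. after the low-expression
        filter), whose columns legitimately no longer sum to 1e6.
        """
        obj = cls.__new__(cls)
        obj.data = data
        obj.lengths = lengths
        obj.unit = unit
        return obj

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def sample(self, name: str) -> pd.Series:
        return self.data[name]


def read_expression_table(path: str | Path, unit: str = "counts") -> ExpressionTable:
    """Read a ``gene  length  <sample...>`` TSV into an :class:`ExpressionTable`.

    Duplicate gene rows, negative values and malformed rows are rejected
    with errors naming the offending symbol or line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={0: str})
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: no data rows") from None
    if df.shape[0] == 0:
        raise ParseError(f"{path}: no data rows")
    cols = [c.strip() for c in df.columns]
    df.columns = cols
    if len(cols) < 3 or cols[0] != "gene" or cols[1] not in ("length", "length_bp"):
        raise ParseError(
            f"{path}: header must be 'gene', 'length', then >=1 sample column; "
            f"got {cols}"
        )
    sample_cols = cols[2:]
    length_col = cols[1]
    numeric = df[[length_col, *sample_cols]].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        # +2: one for the header row, one for 1-based line numbers
        line = int(bad.idxmax()) + 2
        raise ParseError(f"{path}:{line}: malformed (non-numeric) row")
    genes = df["gene"]
    if genes.duplicated().any():
        dupes = sorted(genes[genes.duplicated()].unique())
        raise ValidationError(f"{path}: duplicated gene symbol(s): {dupes}")
    if (numeric[sample_cols].values < 0).any():
        raise ValidationError(f"{path}: negative expression value")
    data = numeric[sample_cols].copy()
    data.index = pd.Index(genes, name="gene")
    lengths = numeric[length_col].copy()
    lengths.index = data.index
    return ExpressionTable(data=data, lengths=lengths, unit=unit)


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    out = table.data.copy()
    out.insert(0, "length", table.lengths)
    out.to_csv(path, sep="\t", index_label="gene", float_format="%.12g")


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    category_path: tuple[str, ...]
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.set_id!r} is empty")


class GeneSetCollection:
    """Ordered collection of gene sets with unique identifiers."""

    def __init__(self, sets: Iterable[GeneSet]):
        self.sets: list[GeneSet] = list(sets)
        seen: set[str] = set()
        for s in self.sets:
            if s.set_id in seen:
                raise ValidationError(f"duplicate set_id {s.set_id!r}")
            seen.add(s.set_id)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        for s in self.sets:
            if s.set_id == set_id:
                return s
        raise KeyError(set_id)


def _parse_gmt(path: Path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT row needs id, "
                                 "description and >=1 gene")
            set_id, name, *genes = parts
            genes = [g for g in genes if g]
            sets.append(GeneSet(set_id, name, (), frozenset(genes)))
    return sets


def _walk_kegg(node: dict, path: tuple[str, ...], out: list[GeneSet]) -> None:
    name = node.get("name", "")
    children = node.get("children")
    if children is None:
        return
    if children and all("children" not in c for c in children):
        # a node whose children are all leaves is a pathway; leaves name genes
        members = frozenset(c["name"].split()[0] for c in children if c.get("name"))
        set_id = name.split()[0] if name else name
        if members:
            out.append(GeneSet(set_id, name, path, members))
        return
    for child in children:
        _walk_kegg(child, path + (name,) if name else path, out)


def read_gene_sets(
    path: str | Path,
    dialect: str = "gmt",
    exclude_categories: Sequence[str] = (),
) -> GeneSetCollection:
    """Read a gene-set collection in GMT or KEGG ko00001-style JSON.

    ``exclude_categories`` removes every set whose ``category_path`` contains
    one of the given hierarchy labels (e.g. the disease/Brite branches of the
    KEGG hierarchy that are irrelevant to a tissue-development contrast).
    """
    path = Path(path)
    if dialect == "gmt":
        sets = _parse_gmt(path)
    elif dialect == "kegg_json":
        with open(path) as fh:
            root = json.load(fh)
        sets = []
        _walk_kegg(root, (), sets)
    else:
        raise ParseError(f"unknown gene-set dialect {dialect!r}")
    if exclude_categories:
        excl = set(exclude_categories)
        sets = [s for s in sets if not excl.intersection(s.category_path)]
    return GeneSetCollection(sets)


# ---------------------------------------------------------------------------
# Interaction networks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InteractionRecord:
    """One signed directed gene–gene interaction (+1 up-, -1 downregulation)."""

    source: str
    target: str
    sign: int
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise ValidationError(f"sign must be +1 or -1, got {self.sign}")
        if self.source == self.target:
            raise ValidationError(f"self-interaction {self.source!r}")


#: direction token -> list of (source_is_gene1, sign) expansions
_DIRECTION_TOKENS: dict[str, list[tuple[bool, int]]] = {
    "->": [(True, 1)],
    "-|": [(True, -1)],
    "<-": [(False, 1)],
    "|-": [(False, -1)],
    "<->": [(True, 1), (False, 1)],
    "|-|": [(True, -1), (False, -1)],
    "<-|": [(False, 1), (True, -1)],
    "|->": [(True, 1), (False, -1)],
}


@dataclass
class InteractionReadResult:
    """Signed records plus counters for rows dropped on read."""

    records: list[InteractionRecord] = field(default_factory=list)
    n_unsigned: int = 0
    n_unknown: int = 0
    n_self: int = 0

    def __iter__(self) -> Iterator[InteractionRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def read_interaction_network(
    path: str | Path, strict: bool = False
) -> InteractionReadResult:
    """Read a Reactome FIsInGene-style network into signed directed records.

    Columns are ``gene1  gene2  annotation  direction  score`` (a header row
    is tolerated).  Direction tokens expand as: ``->``/``-|`` act gene1→gene2
    with sign +1/-1; ``<-``/``|-`` act gene2→gene1; ``<->`` and ``|-|`` give
    both directions; ``<-|`` and ``|->`` give one record per side with its
    own sign.  Undirected ``-`` rows carry no sign and are dropped with a
    logged count.  Unknown tokens are dropped with a warning, or raise when
    ``strict`` is set.
    """
    path = Path(path)
    result = InteractionReadResult()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: expected >=4 tab-separated "
                                 "columns")
            g1, g2, annotation, direction = (p.strip() for p in parts[:4])
            if lineno == 1 and direction.lower() == "direction":
                continue  # header
            if direction == "-":
                result.n_unsigned += 1
                continue
            expansion = _DIRECTION_TOKENS.get(direction)
            if expansion is None:
                if strict:
                    raise ParseError(
                        f"{path}:{lineno}: unknown direction token {direction!r}"
                    )
                logger.warning("%s:%d: unknown direction token %r dropped",
                               path, lineno, direction)
                result.n_unknown += 1
                continue
            for g1_is_source, sign in expansion:
                src, tgt = (g1, g2) if g1_is_source else (g2, g1)
                if src == tgt:
                    result.n_self += 1
                    continue
                result.records.append(
                    InteractionRecord(src, tgt, sign, provenance=annotation)
                )
    if result.n_unsigned:
        logger.info("%s: dropped %d unsigned '-' interactions",
                    path, result.n_unsigned)
    return result


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

_ENRICH_COLUMNS = ["set_id", "es_max", "peak_index", "p_value", "bh_fdr",
                   "n_hits", "leading_edge"]
_FREQUENT_COLUMNS = ["cardinality", "chain", "support", "d_vector", "d_norm",
                     "rank_within_cardinality"]


def _fmt(x: float) -> str:
    # shortest repr that round-trips the double exactly (>= 12 sig. digits)
    return repr(float(x))


def write_report(results: Sequence, path: str | Path, format: str = "tsv",
                 allow_empty: bool = False) -> None:
    """Write enrichment results or frequent-set records to TSV or JSON.

    Numeric fields round-trip to 12 significant digits.  Raises unless the
    result list is nonempty or ``allow_empty`` is set.  The record kind is
    dispatched on the first element (``EnrichmentResult`` vs
    ``FrequentSetRecord``); an empty list writes a header-only enrichment
    table in TSV or ``[]`` in JSON.
    """
    if not results and not allow_empty:
        raise ValidationError("refusing to write an empty report "
                              "(pass allow_empty=True)")
    if format not in ("tsv", "json"):
        raise ParseError(f"unknown report format {format!r}")
    rows = [_record_to_dict(r) for r in results]
    path = Path(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=1)
        return
    if rows and "chain" in rows[0]:
        columns = _FREQUENT_COLUMNS
    else:
        columns = _ENRICH_COLUMNS
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(_tsv_cell(row[c]) for c in columns) + "\n")


def _tsv_cell(value) -> str:
    if isinstance(value, float):
        return _fmt(value)
    if isinstance(value, (list, tuple)):
        return ",".join(_fmt(v) if isinstance(v, float) else str(v)
                        for v in value)
    return str(value)


def _record_to_dict(record) -> dict:
    # late imports: io has no dependency on the analysis modules
    from .gsea import EnrichmentResult
    from .mining import FrequentSetRecord

    if isinstance(record, EnrichmentResult):
        return {
            "set_id": record.set_id,
            "es_max": float(record.es_max),
            "peak_index": int(record.peak_index),
            "p_value": float(record.p_value),
            "bh_fdr": float("nan") if record.bh_fdr is None
            else float(record.bh_fdr),
            "n_hits": int(record.n_hits),
            "leading_edge": list(record.leading_edge),
            "n_permutations": int(record.n_permutations),
        }
    if isinstance(record, FrequentSetRecord):
        return {
            "cardinality": record.cardinality,
            "chain": list(record.chain),
            "support": int(record.support),
            "delta": [float(x) for x in record.delta],
            "d_vector": [float(x) for x in record.d],
            "d_norm": float(record.d_norm),
            "M": [[int(x) for x in row] for row in record.matrix],
            "rank_within_cardinality": int(record.rank or 0),
        }
    raise ValidationError(f"cannot serialise record of type {type(record)!r}")


def read_report(path: str | Path, kind: str, format: str = "tsv") -> list:
    """Read back a report written by :func:`write_report`.

    ``kind`` is ``"enrichment"`` or ``"frequent"``.  JSON reports
    reconstruct full records; TSV reconstructs the tabulated fields.
    """
    from .gsea import EnrichmentResult
    from .mining import FrequentSetRecord

    path = Path(path)
    if format == "json":
        with open(path) as fh:
            rows = json.load(fh)
    elif format == "tsv":
        rows = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                cells = line.rstrip("\n").split("\t")
                rows.append(dict(zip(header, cells)))
    else:
        raise ParseError(f"unknown report format {format!r}")

    out = []
    for row in rows:
        if kind == "enrichment":
            le = row["leading_edge"]
            if isinstance(le, str):
                le = [g for g in le.split(",") if g]
            fdr = row.get("bh_fdr")
            fdr = None if fdr is None or (isinstance(fdr, float) and
                                          math.isnan(fdr)) else float(fdr)
            if isinstance(fdr, str):
                fdr = None if fdr == "nan" else float(fdr)
            out.append(EnrichmentResult(
                set_id=str(row["set_id"]),
                es_max=float(row["es_max"]),
                peak_index=int(row["peak_index"]),
                p_value=float(row["p_value"]),
                leading_edge=tuple(le),
                n_permutations=int(row.get("n_permutations", 0)),
                n_hits=int(row["n_hits"]),
                bh_fdr=fdr,
            ))
        elif kind == "frequent":
            chain = row["chain"]
            if isinstance(chain, str):
                chain = chain.split(",")
            d = row["d_vector"]
            if isinstance(d, str):
                d = [float(x) for x in d.split(",")]
            delta = row.get("delta")
            if isinstance(delta, str):
                delta = [float(x) for x in delta.split(",")]
            matrix = row.get("M")
            out.append(FrequentSetRecord(
                chain=tuple(chain),
                support=int(row["support"]),
                delta=np.asarray(delta if delta is not None else
                                 [float("nan")] * len(chain)),
                matrix=np.asarray(matrix) if matrix is not None
                else np.full((len(chain), len(chain)), 0),
                d=np.asarray(d, dtype=float),
                d_norm=float(row["d_norm"]),
                rank=int(row["rank_within_cardinality"]),
            ))
        else:
            raise ParseError(f"unknown report kind {kind!r}")
    return out
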