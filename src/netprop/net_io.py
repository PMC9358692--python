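"""Readers and writers for the file dialects the pipeline touches.

Covers STRING-style protein-links and protein-info files, plain gene
lists, tab-delimited expression tables with phenotype labels, and
tab-delimited result reports.  All outputs are UTF-8 with LF line
endings.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

import pandas as pd

logger = logging.getLogger("netprop.net_io")

EDGE_COLUMNS = ["protein_a", "protein_b", "combined_score"]

__all__ = [
    "EdgeTable",
    "IdMap",
    "ExpressionStudy",
    "GeneSet",
    "read_ppi_links",
    "write_ppi_links",
    "read_protein_info",
    "write_protein_info",
    "read_expression_table",
    "write_expression_study",
    "read_gene_list",
    "write_gene_list",
]

# An EdgeTable is a DataFrame with columns protein_a, protein_b,
# combined_score: one row per undirected pair, scores in [1, 999],
# no self-edges, duplicate orientations collapsed keeping the max score.
EdgeTable = pd.DataFrame


class ParseError(ValueError):
    """Raised when an input file violates its dialect."""


def _open_maybe_gzip(path: Path, gzipped: bool | None) -> IO[str]:
    if gzipped is None:
        gzipped = path.suffix == ".gz"
    if gzipped:
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def _canonical_edges(records: list[tuple[str, str, int]]) -> EdgeTable:
    """Collapse orientations/duplicates to one undirected record, max score."""
    df = pd.DataFrame(records, columns=EDGE_COLUMNS)
    df = df[df["protein_a"] != df["protein_b"]]
    lo = df[["protein_a", "protein_b"]].min(axis=1)
    hi = df[["protein_a", "protein_b"]].max(axis=1)
    df = pd.DataFrame(
        {"protein_a": lo, "protein_b": hi, "combined_score": df["combined_score"]}
    )
    df = (
        df.groupby(["protein_a", "protein_b"], as_index=False)["combined_score"]
        .max()
        .sort_values(["protein_a", "protein_b"])
        .reset_index(drop=True)
    )
    return df


def read_ppi_links(path: str | Path, gzipped: bool | None = None) -> EdgeTable:
    """Read a STRING-dialect protein links file into an :data:`EdgeTable`.

    The dialect is whitespace-delimited ``protein_a protein_b
    combined_score`` with an optional header line; scores are integers in
    [1, 999].  STRING lists each undirected edge in both orientations;
    these are collapsed to a single record keeping the maximum score, and
    self-edges are dropped.
    """
    path = Path(path)
    records: list[tuple[str, str, int]] = []
    with _open_maybe_gzip(path, gzipped) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected >=3 whitespace-delimited fields"
                )
            if lineno == 1 and not parts[2].lstrip("-").isdigit():
                continue  # header
            try:
                score = int(parts[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-integer combined_score {parts[2]!r}"
                ) from exc
            if not 1 <= score <= 999:
                raise ParseError(
                    f"{path}:{lineno}: combined_score {score} outside [1, 999]"
                )
            records.append((parts[0], parts[1], score))
    if not records:
        raise ParseError(f"{path}: no edge records found")
    table = _canonical_edges(records)
    logger.info("read %d undirected edges from %s (%d lines)", len(table), path, lineno)
    return table


def write_ppi_links(
    table: EdgeTable, path: str | Path, gzipped: bool | None = None, header: bool = True
) -> None:
    """Write an EdgeTable in the STRING links dialect (one orientation)."""
    path = Path(path)
    if gzipped is None:
        gzipped = path.suffix == ".gz"
    opener = gzip.open if gzipped else open
    with opener(path, "wt", encoding="utf-8", newline="\n") as fh:
        if header:
            fh.write("protein1 protein2 combined_score\n")
        for row in table.itertuples(index=False):
            fh.write(f"{row.protein_a} {row.protein_b} {row.combined_score}\n")


@dataclass
class IdMap:
    """Bidirectional accession <-> gene symbol mapping.

    One accession maps to at most one symbol; duplicated symbols are
    tolerated (logged at load time) and resolve to the lexicographically
    first accession.  Unknown keys raise ``KeyError`` rather than failing
    silently.
    """

    accession_to_symbol: dict[str, str]
    symbol_to_accession: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        rev: dict[str, str] = {}
        for acc in sorted(self.accession_to_symbol):
            sym = self.accession_to_symbol[acc]
            rev.setdefault(sym, acc)
        self.symbol_to_accession = rev

    def symbol(self, accession: str) -> str:
        return self.accession_to_symbol[accession]

    def accession(self, symbol: str) -> str:
        return self.symbol_to_accession[symbol]

    def __contains__(self, accession: str) -> bool:
        return accession in self.accession_to_symbol

    def __len__(self) -> int:
        return len(self.accession_to_symbol)


def read_protein_info(path: str | Path) -> IdMap:
    """Read a STRING-dialect protein info file (accession TAB symbol ...)."""
    path = Path(path)
    mapping: dict[str, str] = {}
    seen_symbols: set[str] = set()
    dup_symbols: set[str] = set()
    with _open_maybe_gzip(path, None) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected >=2 tab-delimited columns")
            acc, sym = parts[0], parts[1]
            if lineno == 1 and acc.lower() in {"protein_id", "#string_protein_id", "string_protein_id"}:
                continue
            if acc in mapping:
                raise ParseError(f"{path}:{lineno}: duplicated accession {acc!r}")
            mapping[acc] = sym
            if sym in seen_symbols:
                dup_symbols.add(sym)
            seen_symbols.add(sym)
    if dup_symbols:
        logger.warning("%d symbols map to multiple accessions: %s", len(dup_symbols),
                       sorted(dup_symbols)[:10])
    return IdMap(mapping)


def write_protein_info(idmap: IdMap, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write("protein_id\tpreferred_name\n")
        for acc in sorted(idmap.accession_to_symbol):
            fh.write(f"{acc}\t{idmap.accession_to_symbol[acc]}\n")


@dataclass
class ExpressionStudy:
    """A genes x samples log2-scale expression matrix with phenotypes.

    ``matrix`` is indexed by unique gene symbols with sample IDs as
    columns; ``labels`` maps every sample to ``case`` or ``control`` in
    column order.  Both phenotypes must have at least two samples and the
    matrix must be complete (no NaN).
    """

    cohort_id: str
    matrix: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if list(self.matrix.columns) != list(self.labels.index):
            self.labels = self.labels.reindex(self.matrix.columns)
        if self.labels.isna().any():
            missing = list(self.labels.index[self.labels.isna()])
            raise ValueError(f"{self.cohort_id}: samples without labels: {missing}")
        bad = set(self.labels.unique()) - {"case", "control"}
        if bad:
            raise ValueError(f"{self.cohort_id}: unknown phenotype labels {bad}")
        counts = self.labels.value_counts()
        if counts.get("case", 0) < 2 or counts.get("control", 0) < 2:
            raise ValueError(
                f"{self.cohort_id}: need >=2 samples per phenotype, got {dict(counts)}"
            )
        if self.matrix.isna().any().any():
            raise ValueError(f"{self.cohort_id}: expression matrix contains NaN")
        if self.matrix.index.duplicated().any():
            raise ValueError(f"{self.cohort_id}: duplicate gene IDs after loading")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def n_case(self) -> int:
        return int((self.labels == "case").sum())

    @property
    def n_control(self) -> int:
        return int((self.labels == "control").sum())

    def case_matrix(self) -> pd.DataFrame:
        return self.matrix.loc[:, self.labels == "case"]

    def control_matrix(self) -> pd.DataFrame:
        return self.matrix.loc[:, self.labels == "control"]


def read_expression_table(
    path: str | Path, labels_path: str | Path, cohort_id: str
) -> ExpressionStudy:
    """Load a TSV expression matrix plus a two-column sample->label TSV.

    Duplicate gene symbols are collapsed by row-wise mean (logged).
    Samples present in the matrix but absent from the labels file are an
    error; labelled samples absent from the matrix are ignored.
    """
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    if matrix.isna().any().any():
        raise ParseError(f"{path}: missing values in expression matrix")
    if matrix.index.duplicated().any():
        n_dup = int(matrix.index.duplicated().sum())
        logger.info("%s: collapsing %d duplicate gene rows by mean", cohort_id, n_dup)
        matrix = matrix.groupby(level=0).mean()
    labels_df = pd.read_csv(labels_path, sep="\t", header=None, dtype=str)
    if labels_df.shape[1] < 2:
        raise ParseError(f"{labels_path}: expected two tab-delimited columns")
    if labels_df.iloc[0, 0].lower() in {"sample", "sample_id"}:
        labels_df = labels_df.iloc[1:]
    labels = pd.Series(
        labels_df.iloc[:, 1].values, index=labels_df.iloc[:, 0].values, name="label"
    )
    unlabeled = [s for s in matrix.columns if s not in labels.index]
    if unlabeled:
        raise ParseError(f"{path}: samples missing from labels file: {unlabeled}")
    labels = labels.loc[matrix.columns]
    return ExpressionStudy(cohort_id=cohort_id, matrix=matrix, labels=labels)


def write_expression_study(study: ExpressionStudy, path: str | Path,
                           labels_path: str | Path) -> None:
    study.matrix.to_csv(path, sep="\t", lineterminator="\n")
    with open(labels_path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write("sample\tlabel\n")
        for sample, label in study.labels.items():
            fh.write(f"{sample}\t{label}\n")


@dataclass(frozen=True)
class GeneSet:
    """A named set of unique gene symbols.

    Readers reject empty sets; derived sets (e.g. an intersection) may
    legitimately be empty, which callers should treat as a warning state.
    """

    name: str
    members: frozenset[str]

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def __iter__(self):
        return iter(sorted(self.members))

    @classmethod
    def from_iterable(cls, name: str, genes: Iterable[str]) -> "GeneSet":
        return cls(name=name, members=frozenset(genes))


def read_gene_list(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a one-symbol-per-line gene list; ``#`` comments are ignored."""
    path = Path(path)
    genes: set[str] = set()
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            genes.add(line.split()[0])
    if not genes:
        raise ParseError(f"{path}: no gene symbols found")
    return GeneSet(name=name or path.stem, members=frozenset(genes))


def write_gene_list(genes: GeneSet, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for g in sorted(genes.members):
            fh.write(g + "\n")
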