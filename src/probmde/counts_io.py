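"""Input/output for tag-count expression data and gene-set annotations.

The count-table dialect is plain TSV: a header row of library identifiers,
a first column of gene/tag identifiers, and non-negative integer cells.
Lines starting with ``#`` are comments.  Library totals ``T`` (the number of
sequenced tags) are either the column sums (``totals_mode="column_sum"``) or
taken from a reserved row whose identifier is ``TOTAL``
(``totals_mode="explicit_row"``), which accommodates SAGE libraries whose
sequenced-tag total exceeds the sum of retained tags after filtering.
Files ending in ``.gz`` are decompressed transparently.

Gene-set annotations are accepted as Broad-convention GMT
(``term <tab> description <tab> gene ...``) or as a 2-3 column TSV
(``gene <tab> term [<tab> weight]``) where the optional weight in [0, 1]
expresses probabilistic (fuzzy) membership of the gene in the term.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import FormatError

logger = logging.getLogger(__name__)

TOTALS_ROW_ID = "TOTAL"


@dataclass
class CountLibrary:
    """One sequenced library: per-gene tag counts N and total tag count T."""

    library_id: str
    counts: dict[str, int]
    total_tags: int

    def __post_init__(self) -> None:
        if self.total_tags <= 0:
            raise ValueError(
                f"library {self.library_id!r}: total_tags must be positive, "
                f"got {self.total_tags}"
            )
        for gene, n in self.counts.items():
            if n < 0:
                raise ValueError(
                    f"library {self.library_id!r}: negative count {n} for gene {gene!r}"
                )
            if n > self.total_tags:
                raise ValueError(
                    f"library {self.library_id!r}: count {n} for gene {gene!r} "
                    f"exceeds total tags {self.total_tags}"
                )

    def count(self, gene_id: str) -> int:
        """Count for ``gene_id``; a gene never observed has count 0."""
        return self.counts.get(gene_id, 0)


@dataclass
class ExpressionDataset:
    """An ordered collection of count libraries over a shared gene universe.

    A gene absent from a library is treated as observed zero times out of
    that library's ``T`` tags, which yields a Beta(1, T+1) posterior
    downstream: absence of a tag is an observation of zero counts.
    """

    libraries: list[CountLibrary]
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [lib.library_id for lib in self.libraries]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate library ids: {ids}")
        if not self.gene_ids:
            seen: dict[str, None] = {}
            for lib in self.libraries:
                for g in lib.counts:
                    seen.setdefault(g)
            self.gene_ids = list(seen)
        self._by_id = {lib.library_id: lib for lib in self.libraries}

    @property
    def library_ids(self) -> list[str]:
        return [lib.library_id for lib in self.libraries]

    @property
    def gene_universe(self) -> set[str]:
        return set(self.gene_ids)

    def library(self, library_id: str) -> CountLibrary:
        try:
            return self._by_id[library_id]
        except KeyError:
            raise KeyError(f"unknown library id {library_id!r}") from None

    def counts_for(self, gene_id: str, library_id: str) -> tuple[int, int]:
        """Return (N, T) for one gene in one library."""
        lib = self.library(library_id)
        return lib.count(gene_id), lib.total_tags


@dataclass
class AnnotationSet:
    """Gene-set annotation: term -> [(gene_id, membership weight in [0,1])]."""

    terms: dict[str, list[tuple[str, float]]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, members in self.terms.items():
            genes = [g for g, _ in members]
            if len(set(genes)) != len(genes):
                raise ValueError(f"term {term!r}: duplicate (term, gene) pairs")
            for g, w in members:
                if not 0.0 <= w <= 1.0:
                    raise ValueError(
                        f"term {term!r}, gene {g!r}: weight {w} outside [0, 1]"
                    )

    @property
    def term_ids(self) -> list[str]:
        return list(self.terms)

    def genes_of(self, term_id: str) -> dict[str, float]:
        return dict(self.terms[term_id])


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def _data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_count_table(
    path: str | Path, totals_mode: str = "column_sum"
) -> ExpressionDataset:
    """Read a TSV count table into an :class:`ExpressionDataset`.

    Parameters
    ----------
    path:
        TSV (optionally gzipped) with a header row of library ids and a
        first column of gene/tag ids.
    totals_mode:
        ``"column_sum"`` derives each library's total tag count T as the
        column sum; ``"explicit_row"`` reads T from the reserved ``TOTAL``
        row, which must then be present and dominate every count.
    """
    if totals_mode not in ("column_sum", "explicit_row"):
        raise ValueError(f"unknown totals_mode {totals_mode!r}")

    lines = iter(_data_lines(path))
    try:
        _, header = next(lines)
    except StopIteration:
        raise FormatError(f"{path}: empty count table") from None
    cols = header.split("\t")
    library_ids = cols[1:]
    if not library_ids:
        raise FormatError(f"{path}: header row has no library columns")
    if len(set(library_ids)) != len(library_ids):
        raise FormatError(f"{path}: duplicate library ids in header")

    gene_order: list[str] = []
    rows: dict[str, list[int]] = {}
    totals_row: list[int] | None = None
    for lineno, line in lines:
        fields = line.split("\t")
        if len(fields) != len(cols):
            raise FormatError(
                f"{path}:{lineno}: expected {len(cols)} columns, got {len(fields)}"
            )
        gene = fields[0]
        values: list[int] = []
        for lib_id, cell in zip(library_ids, fields[1:]):
            try:
                v = int(cell)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer count {cell!r} "
                    f"(gene {gene!r}, library {lib_id!r})"
                ) from None
            if v < 0:
                raise FormatError(
                    f"{path}:{lineno}: negative count {v} "
                    f"(gene {gene!r}, library {lib_id!r})"
                )
            values.append(v)
        if gene == TOTALS_ROW_ID:
            if totals_mode == "column_sum":
                raise FormatError(
                    f"{path}:{lineno}: reserved row {TOTALS_ROW_ID!r} present; "
                    "read with totals_mode='explicit_row'"
                )
            totals_row = values
            continue
        if gene in rows:
            raise FormatError(f"{path}:{lineno}: duplicate gene id {gene!r}")
        gene_order.append(gene)
        rows[gene] = values

    if totals_mode == "explicit_row":
        if totals_row is None:
            raise FormatError(
                f"{path}: totals_mode='explicit_row' but no {TOTALS_ROW_ID!r} row found"
            )
        totals = totals_row
        for j, lib_id in enumerate(library_ids):
            for gene in gene_order:
                if rows[gene][j] > totals[j]:
                    raise FormatError(
                        f"{path}: count {rows[gene][j]} for gene {gene!r} exceeds "
                        f"explicit total {totals[j]} in library {lib_id!r}"
                    )
    else:
        totals = [sum(rows[g][j] for g in gene_order) for j in range(len(library_ids))]

    libraries = [
        CountLibrary(
            library_id=lib_id,
            counts={g: rows[g][j] for g in gene_order},
            total_tags=totals[j],
        )
        for j, lib_id in enumerate(library_ids)
    ]
    return ExpressionDataset(libraries=libraries, gene_ids=gene_order)


def write_count_table(dataset: ExpressionDataset, path: str | Path) -> None:
    """Write a dataset back to the TSV dialect read by :func:`read_count_table`.

    A ``TOTAL`` row is emitted only when some library's total differs from
    its column sum (i.e. the dataset requires ``totals_mode="explicit_row"``
    to round-trip).
    """
    col_sums = [
        sum(lib.count(g) for g in dataset.gene_ids) for lib in dataset.libraries
    ]
    need_totals = any(
        lib.total_tags != s for lib, s in zip(dataset.libraries, col_sums)
    )
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(dataset.library_ids) + "\n")
        if need_totals:
            fh.write(
                TOTALS_ROW_ID
                + "\t"
                + "\t".join(str(lib.total_tags) for lib in dataset.libraries)
                + "\n"
            )
        for g in dataset.gene_ids:
            fh.write(
                g + "\t" + "\t".join(str(lib.count(g)) for lib in dataset.libraries) + "\n"
            )


def read_annotation(path: str | Path) -> AnnotationSet:
    """Read a gene-set annotation from GMT or 2-3 column TSV.

    GMT is detected by the ``.gmt`` extension (``.gmt.gz`` included);
    everything else is parsed as ``gene <tab> term [<tab> weight]`` with the
    weight defaulting to 1.0 (crisp membership).
    """
    path = Path(path)
    name = path.name[:-3] if path.suffix == ".gz" else path.name
    if name.endswith(".gmt"):
        return _read_gmt(path)
    return _read_annotation_tsv(path)


def _read_gmt(path: Path) -> AnnotationSet:
    terms: dict[str, list[tuple[str, float]]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT line needs term, description and >=1 gene"
            )
        term, desc, genes = fields[0], fields[1], fields[2:]
        if not term:
            logger.warning("%s:%d: empty term id, line skipped", path, lineno)
            continue
        members: list[tuple[str, float]] = []
        seen: set[str] = set()
        for g in genes:
            if g and g not in seen:
                members.append((g, 1.0))
                seen.add(g)
        terms[term] = members
        descriptions[term] = desc
    return AnnotationSet(terms=terms, descriptions=descriptions)


def _read_annotation_tsv(path: Path) -> AnnotationSet:
    terms: dict[str, list[tuple[str, float]]] = {}
    seen_pairs: set[tuple[str, str]] = set()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) not in (2, 3):
            raise FormatError(
                f"{path}:{lineno}: expected 2 or 3 columns (gene, term[, weight])"
            )
        gene, term = fields[0], fields[1]
        if not term:
            logger.warning("%s:%d: empty term id, line skipped", path, lineno)
            continue
        weight = 1.0
        if len(fields) == 3:
            try:
                weight = float(fields[2])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric weight {fields[2]!r}"
                ) from None
            if not 0.0 <= weight <= 1.0:
                raise FormatError(
                    f"{path}:{lineno}: weight {weight} outside [0, 1]"
                )
        if (term, gene) in seen_pairs:
            raise FormatError(f"{path}:{lineno}: duplicate pair ({gene!r}, {term!r})")
        seen_pairs.add((term, gene))
        terms.setdefault(term, []).append((gene, weight))
    return AnnotationSet(terms=terms)


def read_tag_map(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV mapping tag id -> gene id."""
    mapping: dict[str, str] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns (tag, gene)")
        tag, gene = fields
        if tag in mapping and mapping[tag] != gene:
            raise FormatError(
                f"{path}:{lineno}: tag {tag!r} maps to both "
                f"{mapping[tag]!r} and {gene!r}"
            )
        mapping[tag] = gene
    return mapping


def apply_tag_map(
    dataset: ExpressionDataset, tag_to_gene: Mapping[str, str]
) -> ExpressionDataset:
    """Collapse tag-level rows to gene-level rows by summing counts.

    Tags mapping to the same gene are summed per library (tag sampling is
    additive).  Tags absent from the map keep their own identifier; map
    entries for tags not in the data are ignored.  The number of unmapped
    tags is logged.
    """
    if not tag_to_gene:
        return dataset

    new_order: list[str] = []
    seen: set[str] = set()
    n_unmapped = 0
    for tag in dataset.gene_ids:
        target = tag_to_gene.get(tag)
        if target is None:
            n_unmapped += 1
            target = tag
        if target not in seen:
            new_order.append(target)
            seen.add(target)
    if n_unmapped:
        logger.warning(
            "%d of %d tags had no gene mapping and were kept under their tag id",
            n_unmapped,
            len(dataset.gene_ids),
        )

    libraries = []
    for lib in dataset.libraries:
        counts: dict[str, int] = {}
        for tag in dataset.gene_ids:
            target = tag_to_gene.get(tag, tag)
            counts[target] = counts.get(target, 0) + lib.count(tag)
        libraries.append(
            CountLibrary(
                library_id=lib.library_id, counts=counts, total_tags=lib.total_tags
            )
        )
    return ExpressionDataset(libraries=libraries, gene_ids=new_order)
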