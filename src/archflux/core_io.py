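"""Data model and readers/writers shared by every analysis stage.

Coordinate convention
---------------------
All coordinates are stored 0-based, half-open, on the forward strand.
GFF3 input (1-based, inclusive) is converted on read.  Genes on a circular
chromosome may wrap past the coordinate origin; such records are stored with
``start > end`` and ``wraps=True`` and their midpoints are computed modulo the
genome length.

Bootstrap supports are normalised to a percent scale in [0, 100]; inputs that
look like fractions in [0, 1] are multiplied by 100 with a warning.  A missing
support is ``None``, never 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CircularGenome",
    "GeneRecord",
    "OrthologMatrix",
    "Alignment",
    "read_genome",
    "write_genome",
    "read_gene_table",
    "write_gene_table",
    "read_ortholog_matrix",
    "write_ortholog_matrix",
    "read_trees",
    "write_trees",
    "get_support",
    "CoreIOError",
]

_DNA_OK = set("ACGTN")


class CoreIOError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass
class CircularGenome:
    """A circular chromosome with annotated replication origin and terminus."""

    id: str
    length: int
    ori: int
    ter: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise CoreIOError(f"genome {self.id!r}: length must be positive")
        self.ori = int(self.ori) % self.length
        self.ter = int(self.ter) % self.length
        if self.ori == self.ter:
            raise CoreIOError(f"genome {self.id!r}: ori and ter coincide")
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if len(self.sequence) != self.length:
                raise CoreIOError(
                    f"genome {self.id!r}: sequence length {len(self.sequence)} "
                    f"!= declared length {self.length}"
                )
            bad = set(self.sequence) - _DNA_OK
            if bad:
                raise CoreIOError(
                    f"genome {self.id!r}: non-DNA characters {sorted(bad)}"
                )


@dataclass
class GeneRecord:
    """One annotated gene in internal (0-based, half-open) coordinates."""

    gene_id: str
    genome_id: str
    start: int
    end: int
    strand: str
    category: str = ""
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise CoreIOError(
                f"gene {self.gene_id!r}: unknown strand {self.strand!r}"
            )
        if self.start < 0 or self.end < 0:
            raise CoreIOError(f"gene {self.gene_id!r}: negative coordinate")

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    def span(self, genome_length: int) -> int:
        if self.wraps:
            return genome_length - self.start + self.end
        return self.end - self.start

    def midpoint(self, genome_length: int) -> int:
        """Integer midpoint along the gene's span, modulo genome length."""
        return (self.start + self.span(genome_length) // 2) % genome_length


class OrthologMatrix:
    """Families x taxa matrix of non-negative integer ortholog copy counts."""

    def __init__(self, counts: pd.DataFrame):
        counts = counts.copy()
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()].tolist()
            raise CoreIOError(f"duplicate family ids: {dup}")
        if counts.columns.has_duplicates:
            dup = counts.columns[counts.columns.duplicated()].tolist()
            raise CoreIOError(f"duplicate taxon ids: {dup}")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            flo = counts.astype(float).to_numpy()
            if not np.all(flo == np.floor(flo)):
                raise CoreIOError("non-integer copy counts")
            counts = counts.astype(int)
            arr = counts.to_numpy()
        if (arr < 0).any():
            raise CoreIOError("negative copy counts")
        zero = counts.index[(arr == 0).all(axis=1)].tolist()
        if zero:
            raise CoreIOError(f"families with all-zero counts: {zero}")
        self.counts = counts

    @property
    def families(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, OrthologMatrix) and self.counts.equals(other.counts)


@dataclass
class Alignment:
    """A multiple sequence alignment: equal-length rows over {A,C,G,T,N,-}."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise CoreIOError("ids and rows differ in number")
        if len(self.rows) < 2:
            raise CoreIOError("alignment needs at least 2 rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise CoreIOError(f"ragged alignment rows: lengths {sorted(lengths)}")
        self.rows = [r.upper() for r in self.rows]
        if len(set(self.ids)) != len(self.ids):
            raise CoreIOError("duplicate sequence ids in alignment")

    @property
    def n_sites(self) -> int:
        return len(self.rows[0])

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise CoreIOError(f"unknown sequence id {seq_id!r}") from None

    @classmethod
    def read_fasta(cls, path: str | Path) -> "Alignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise CoreIOError(f"no sequences in {path}")
        return cls([r.id for r in records], [str(r.seq) for r in records])

    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(row), id=sid, description="")
            for sid, row in zip(self.ids, self.rows)
        ]
        SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# genomes


def read_genome(
    path: str | Path,
    ori: int,
    ter: int,
    record_id: str | None = None,
) -> CircularGenome:
    """Read a single circular genome from FASTA with declared ori/ter (bp).

    Coordinates are normalised modulo the sequence length.  If the file holds
    several records, ``record_id`` selects one; otherwise multiple records are
    an error.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise CoreIOError(f"no FASTA records in {path}")
    if record_id is not None:
        matches = [r for r in records if r.id == record_id]
        if not matches:
            raise CoreIOError(f"record {record_id!r} not found in {path}")
        rec = matches[0]
    elif len(records) > 1:
        raise CoreIOError(
            f"{path} holds {len(records)} records; pass record_id to choose one"
        )
    else:
        rec = records[0]
    seq = str(rec.seq).upper()
    return CircularGenome(id=rec.id, length=len(seq), ori=ori, ter=ter, sequence=seq)


def write_genome(genome: CircularGenome, path: str | Path) -> None:
    if genome.sequence is None:
        raise CoreIOError(f"genome {genome.id!r} has no sequence to write")
    SeqIO.write(
        [SeqRecord(Seq(genome.sequence), id=genome.id, description="")],
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# gene tables

_TSV_COLUMNS = ["gene_id", "genome_id", "start", "end", "strand", "category", "flags"]


def _gene_from_gff_fields(
    line_no: int,
    seqid: str,
    start_1based: int,
    end_1based: int,
    strand: str,
    gene_id: str,
    category: str,
    flags: set[str],
    genome_lengths: Mapping[str, int] | None,
) -> GeneRecord:
    if strand not in {"+", "-"}:
        raise CoreIOError(f"line {line_no}: unknown strand {strand!r}")
    start = start_1based - 1  # 1-based inclusive -> 0-based half-open
    end = end_1based
    if genome_lengths is not None and seqid in genome_lengths:
        L = genome_lengths[seqid]
        if start >= L:
            raise CoreIOError(
                f"line {line_no}: gene {gene_id!r} start {start_1based} beyond "
                f"genome length {L}"
            )
        end = end % L if end > L else end
    return GeneRecord(gene_id, seqid, start, end, strand, category, flags)


def read_gene_table(
    path: str | Path,
    genome_lengths: Mapping[str, int] | None = None,
) -> list[GeneRecord]:
    """Read gene records from GFF3 or TSV.

    GFF3 coordinates (1-based inclusive) are converted to the internal 0-based
    half-open convention.  A ``category`` attribute/column supplies the
    functional label; a ``flags`` attribute/column holds comma-separated class
    flags (e.g. ``secreted``).  Wrap-around genes end up with start > end.
    """
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        return _read_gff3(path, genome_lengths)
    return _read_gene_tsv(path, genome_lengths)


def _read_gff3(
    path: Path, genome_lengths: Mapping[str, int] | None
) -> list[GeneRecord]:
    from gffutils.iterators import DataIterator

    genes: list[GeneRecord] = []
    for i, feat in enumerate(DataIterator(str(path)), start=1):
        attrs = feat.attributes
        gene_id = (attrs.get("ID") or attrs.get("Name") or [f"gene{i}"])[0]
        category = (attrs.get("category") or attrs.get("COG") or [""])[0]
        raw_flags = attrs.get("flags") or []
        flags = {f for entry in raw_flags for f in entry.split(",") if f}
        genes.append(
            _gene_from_gff_fields(
                i, feat.seqid, int(feat.start), int(feat.end), feat.strand,
                gene_id, category, flags, genome_lengths,
            )
        )
    return genes


def _read_gene_tsv(
    path: Path, genome_lengths: Mapping[str, int] | None
) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"gene_id", "genome_id", "start", "end", "strand"} - set(df.columns)
    if missing:
        raise CoreIOError(f"{path}: missing columns {sorted(missing)}")
    genes: list[GeneRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.strand not in {"+", "-"}:
            raise CoreIOError(f"{path} line {i}: unknown strand {row.strand!r}")
        start, end = int(row.start), int(row.end)
        if genome_lengths is not None and row.genome_id in genome_lengths:
            if start >= genome_lengths[row.genome_id]:
                raise CoreIOError(
                    f"{path} line {i}: start {start} beyond genome length"
                )
        flags_str = getattr(row, "flags", "")
        flags = {f for f in flags_str.split(",") if f}
        genes.append(
            GeneRecord(
                row.gene_id, row.genome_id, start, end, row.strand,
                getattr(row, "category", ""), flags,
            )
        )
    return genes


def write_gene_table(genes: Iterable[GeneRecord], path: str | Path) -> None:
    """Write gene records as TSV in internal coordinates (round-trip safe)."""
    rows = [
        {
            "gene_id": g.gene_id,
            "genome_id": g.genome_id,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
            "category": g.category,
            "flags": ",".join(sorted(g.flags)),
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ortholog matrices


def read_ortholog_matrix(path: str | Path) -> OrthologMatrix:
    """Read a families x taxa copy-number matrix from TSV.

    Header row names the taxa; the first column holds family ids.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise CoreIOError(f"{path}: malformed TSV ({exc})") from exc
    if df.isna().to_numpy().any():
        raise CoreIOError(f"{path}: ragged rows or missing counts")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return OrthologMatrix(df)


def write_ortholog_matrix(matrix: OrthologMatrix, path: str | Path) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="family")


# ---------------------------------------------------------------------------
# trees


def _parse_support_label(label: str | None) -> float | None:
    if label is None or label == "":
        return None
    try:
        value = float(label)
    except ValueError:
        return None
    return value


def _annotate_supports(tree: dendropy.Tree) -> None:
    """Attach a ``support`` attribute (percent scale or None) to every node.

    Internal-node labels that parse as numbers are treated as supports;
    values in [0, 1] are rescaled to percent with a warning.
    """
    raw: dict[dendropy.Node, float | None] = {}
    for node in tree:
        if node.is_leaf():
            node.support = None
            continue
        raw[node] = _parse_support_label(node.label)
    values = [v for v in raw.values() if v is not None]
    rescale = bool(values) and max(values) <= 1.0
    if rescale:
        warnings.warn(
            "supports look like fractions in [0,1]; rescaling to percent",
            stacklevel=3,
        )
    for node, value in raw.items():
        if value is None:
            node.support = None
        else:
            v = round(value * 100.0, 10) if rescale else value
            if not 0.0 <= v <= 100.0:
                raise CoreIOError(f"support {value} outside [0,100]")
            node.support = v


def get_support(node: dendropy.Node) -> float | None:
    """Percent-scale support of a node, or None when absent."""
    return getattr(node, "support", None)


def _check_leaf_names(tree: dendropy.Tree) -> None:
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise CoreIOError(f"duplicate leaf names: {dup}")


def read_trees(
    path: str | Path,
    multi: bool = False,
    taxon_namespace: dendropy.TaxonNamespace | None = None,
) -> dendropy.Tree | dendropy.TreeList:
    """Read one rooted tree (or a newline-delimited set) from Newick.

    Internal node labels are parsed as bootstrap supports on the percent
    scale; unlabeled nodes get support ``None`` (missing, not zero).
    """
    kwargs = dict(
        path=str(path),
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    if taxon_namespace is not None:
        kwargs["taxon_namespace"] = taxon_namespace
    try:
        if multi:
            trees = dendropy.TreeList.get(**kwargs)
        else:
            tree = dendropy.Tree.get(**kwargs)
    except dendropy.utility.error.DataParseError as exc:
        if "uplicate" in str(exc) or "Multiple occurrences" in str(exc):
            raise CoreIOError(f"{path}: duplicate leaf names ({exc})") from exc
        raise CoreIOError(f"{path}: malformed Newick ({exc})") from exc
    if multi:
        if len(trees) == 0:
            raise CoreIOError(f"no trees in {path}")
        for t in trees:
            _check_leaf_names(t)
            _annotate_supports(t)
        return trees
    _check_leaf_names(tree)
    _annotate_supports(tree)
    return tree


def write_trees(
    trees: dendropy.Tree | dendropy.TreeList | Sequence[dendropy.Tree],
    path: str | Path,
) -> None:
    """Write trees as Newick, storing supports as internal node labels."""
    if isinstance(trees, dendropy.Tree):
        trees = [trees]
    with open(path, "w") as fh:
        for tree in trees:
            clone = tree.clone(depth=1)
            for node in clone:
                if not node.is_leaf():
                    s = get_support(node)
                    node.label = None if s is None else format(s, "g")
            fh.write(
                clone.as_string(
                    schema="newick",
                    suppress_rooting=True,
                    unquoted_underscores=True,
                ).strip()
                + "\n"
            )
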