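"""Readers and writers for the flat formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere; conversion to and
from 1-based inclusive conventions (FASTA-adjacent tables, GFF3) happens
only at the I/O boundary.  Selenocysteine ('U') is kept as a residue and
flagged; in-frame stop characters ('*') are stripped with a warning and
the record retained, because selenoproteins are routinely truncated or
stop-misread by gene callers and must not be rejected outright.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("hdrakit.io")

#: ordered conserved-domain vocabulary used throughout the pipeline
DOMAIN_LABELS = (
    "FeS_N",
    "TRX_FAD",
    "TRX_FeS",
    "Fd_ins",
    "Fd_C",
    "MvhD",
    "GltD",
    "FeS_extra",
)

#: motif-level evidence labels emitted by the built-in scanner
MOTIF_LABELS = ("FeS4", "FeS2", "ROSS_NAD", "ROSS_NADP")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: the residue alphabet records may use: 20 standard + U (Sec) + X (unknown)
RESIDUE_ALPHABET = frozenset(AMINO_ACIDS + "UX")


class ParseError(ValueError):
    """Malformed input that cannot be normalised."""


@dataclass
class ProteinRecord:
    """An identified protein sequence with provenance and quality flags."""

    id: str
    seq: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ParseError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - RESIDUE_ALPHABET
        if bad:
            raise ParseError(
                f"record {self.id!r}: non-residue characters {sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def sec_flag(self) -> bool:
        """True when the sequence contains selenocysteine."""
        return "U" in self.seq


@dataclass(frozen=True)
class DomainHitRow:
    """One piece of domain evidence on a protein (builtin motif or external)."""

    protein_id: str
    domain_label: str
    start: int  # 0-based
    end: int  # half-open
    score: float
    origin: str = "builtin"  # "builtin" | "external"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ParseError(
                f"hit on {self.protein_id}: invalid span [{self.start},{self.end})"
            )
        if self.score < 0:
            raise ParseError(f"hit on {self.protein_id}: negative score")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class GeneFeature:
    """One oriented gene on a contig, 0-based half-open nucleotide coordinates."""

    contig: str
    locus_id: str
    start: int
    end: int
    strand: str
    label: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ParseError(
                f"feature {self.locus_id}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ParseError(
                f"feature {self.locus_id}: unknown strand {self.strand!r}"
            )


# ---------------------------------------------------------------------------
# FASTA


def _as_handle(stream: str | Path | TextIO) -> TextIO:
    if isinstance(stream, str) and (
        stream == "" or stream.lstrip().startswith(">") or "\n" in stream
    ):
        return io.StringIO(stream)
    if isinstance(stream, (str, Path)):
        p = Path(stream)
        if p.is_file():
            return p.open()
        raise FileNotFoundError(stream)
    return stream


def parse_fasta(stream: str | Path | TextIO, source: str = "") -> list[ProteinRecord]:
    """Parse FASTA text into :class:`ProteinRecord` objects.

    Residues are upper-cased, '*' is stripped with a warning, and duplicate
    ids raise.  Text appearing before the first header is a parse error.
    """
    handle = _as_handle(stream)
    first = handle.read(1)
    if first == "":
        return []
    if first != ">":
        raise ParseError("FASTA parse error: line 1 does not start with '>'")
    handle_all = io.StringIO(">" + handle.read())
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(handle_all, "fasta"):
        if not rec.id:
            raise ParseError("FASTA parse error: header with empty id")
        if rec.id in seen:
            raise ParseError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if "*" in seq:
            logger.warning("record %s: stripped %d stop character(s)", rec.id, seq.count("*"))
            seq = seq.replace("*", "")
        records.append(ProteinRecord(id=rec.id, seq=seq, source=source))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path | TextIO) -> None:
    seqrecs = [
        SeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    if isinstance(path, (str, Path)):
        with open(path, "w") as fh:
            SeqIO.write(seqrecs, fh, "fasta")
    else:
        SeqIO.write(seqrecs, path, "fasta")


# ---------------------------------------------------------------------------
# gene feature tables


def _read_text(stream: str | Path | TextIO) -> str:
    if isinstance(stream, str) and (
        stream == "" or "\n" in stream or "\t" in stream
    ):
        return stream
    if isinstance(stream, (str, Path)):
        p = Path(stream)
        if p.is_file():
            return p.read_text()
        raise FileNotFoundError(stream)
    return stream.read()


def _feature_from_gff_fields(fields: list[str], line_no: int) -> GeneFeature:
    contig, _src, _ftype, start, end, _score, strand, _frame, attrs = fields
    attr: dict[str, str] = {}
    for chunk in attrs.strip().split(";"):
        if "=" in chunk:
            k, v = chunk.split("=", 1)
            attr[k.strip()] = v.strip()
    locus = attr.get("ID") or attr.get("locus") or f"feature_{line_no}"
    label = attr.get("label") or attr.get("gene") or attr.get("Name") or ""
    if not label:
        raise ParseError(f"GFF3 line {line_no}: no label/gene/Name attribute")
    return GeneFeature(
        contig=contig,
        locus_id=locus,
        start=int(start) - 1,  # 1-based inclusive -> 0-based half-open
        end=int(end),
        strand=strand,
        label=label,
    )


def parse_feature_table(
    stream: str | Path | TextIO, dialect: str = "gff3"
) -> list[GeneFeature]:
    """Parse a GFF3 (1-based inclusive) or simple TSV gene table.

    The TSV dialect has a header row ``contig locus start end strand label``
    with coordinates already 0-based half-open.  Output is sorted by
    (contig, start).
    """
    text = _read_text(stream)
    feats: list[GeneFeature] = []
    if dialect == "gff3":
        for i, line in enumerate(text.splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ParseError(f"GFF3 line {i}: expected 9 columns, got {len(fields)}")
            feats.append(_feature_from_gff_fields(fields, i))
    elif dialect == "tsv":
        reader = csv.DictReader(io.StringIO(text), delimiter="\t")
        required = {"contig", "locus", "start", "end", "strand", "label"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ParseError(f"feature TSV: header must contain {sorted(required)}")
        for row in reader:
            feats.append(
                GeneFeature(
                    contig=row["contig"],
                    locus_id=row["locus"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row["strand"],
                    label=row["label"],
                )
            )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    feats.sort(key=lambda f: (f.contig, f.start))
    return feats


def write_gff3(features: Iterable[GeneFeature], path: str | Path | TextIO) -> None:
    """Write features as GFF3; inverse of :func:`parse_feature_table`."""
    lines = ["##gff-version 3"]
    for f in features:
        lines.append(
            "\t".join(
                [
                    f.contig,
                    "hdrakit",
                    "gene",
                    str(f.start + 1),
                    str(f.end),
                    ".",
                    f.strand,
                    ".",
                    f"ID={f.locus_id};label={f.label}",
                ]
            )
        )
    text = "\n".join(lines) + "\n"
    if isinstance(path, (str, Path)):
        Path(path).write_text(text)
    else:
        path.write(text)


# ---------------------------------------------------------------------------
# domain-hit tables (CD-Search style, consumed not executed)


def _load_synonyms(name: str) -> dict[str, str]:
    table: dict[str, str] = {}
    data = resources.files("hdrakit.data").joinpath(name).read_text()
    for row in csv.reader(io.StringIO(data), delimiter="\t"):
        if not row or row[0].startswith("#"):
            continue
        table[row[0]] = row[1]
    return table


def domain_synonyms() -> dict[str, str]:
    """Bundled mapping from external domain accessions to the vocabulary."""
    return _load_synonyms("domain_synonyms.tsv")


def parse_domain_hits(stream: str | Path | TextIO) -> list[DomainHitRow]:
    """Parse a 5-column domain-hit TSV (1-based inclusive coordinates).

    Columns: protein_id, domain_label, from, to, score; header required.
    Labels are mapped to the controlled vocabulary through the bundled
    synonym table; unmappable rows are skipped with a warning.
    """
    text = _read_text(stream)
    reader = csv.DictReader(io.StringIO(text), delimiter="\t")
    required = {"protein_id", "domain_label", "from", "to", "score"}
    if reader.fieldnames is None:
        return []
    if not required.issubset(reader.fieldnames):
        raise ParseError(f"domain-hit TSV: header must contain {sorted(required)}")
    synonyms = domain_synonyms()
    known = set(DOMAIN_LABELS) | set(MOTIF_LABELS)
    hits: list[DomainHitRow] = []
    for row in reader:
        raw = row["domain_label"]
        label = raw if raw in known else synonyms.get(raw)
        if label is None:
            logger.warning("domain hit with unmappable label %r skipped", raw)
            continue
        score = float(row["score"])
        if score < 0:
            raise ParseError(f"hit on {row['protein_id']}: negative score {score}")
        hits.append(
            DomainHitRow(
                protein_id=row["protein_id"],
                domain_label=label,
                start=int(row["from"]) - 1,
                end=int(row["to"]),
                score=score,
                origin="external",
            )
        )
    return hits


def write_domain_hits(hits: Iterable[DomainHitRow], path: str | Path | TextIO) -> None:
    """Write hits in the same 5-column 1-based inclusive dialect."""
    rows = ["\t".join(["protein_id", "domain_label", "from", "to", "score"])]
    for h in hits:
        rows.append(
            "\t".join([h.protein_id, h.domain_label, str(h.start + 1), str(h.end), repr(h.score)])
        )
    text = "\n".join(rows) + "\n"
    if isinstance(path, (str, Path)):
        Path(path).write_text(text)
    else:
        path.write(text)
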