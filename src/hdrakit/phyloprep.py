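"""Preparation of HdrA sequences for phylogenetics.

The steps mirror a standard pre-phylogeny workflow for a redundant,
multi-domain protein family: greedy identity clustering to representative
sequences (80% cutoff, identity over the shorter sequence), splitting of
two-TRX proteins into N- and C-halves so each half carries one
thioredoxin reductase domain, excision of the inserted GltD domain, and
core-region extraction from a consumed multiple sequence alignment either
by per-column entropy/gap trimming or by a reference-coordinate segment
mask.  The trimmer is a deliberate simplification of BMGE-style block
trimming: pure Shannon-entropy and gap-fraction thresholds per column,
with no similarity-matrix smoothing and no block gathering.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np
from scipy.stats import entropy as shannon_entropy

from .io_formats import ParseError, ProteinRecord
from .residues import ScoringScheme, global_align

logger = logging.getLogger("hdrakit.phyloprep")


# ---------------------------------------------------------------------------
# identity clustering


@dataclass
class ClusterParams:
    """Greedy clustering parameters (identity over the shorter sequence)."""

    identity_cutoff: float = 0.80
    identity_denominator: str = "shorter_sequence"

    def __post_init__(self) -> None:
        if not (0 < self.identity_cutoff <= 1):
            raise ValueError("identity cutoff must be in (0, 1]")


@dataclass
class Cluster:
    representative: ProteinRecord
    members: list[ProteinRecord]


def pairwise_identity(
    a: str | ProteinRecord, b: str | ProteinRecord, s: ScoringScheme | None = None
) -> float:
    """Identical columns of the global alignment / length of the shorter."""
    sa = a.seq if isinstance(a, ProteinRecord) else a
    sb = b.seq if isinstance(b, ProteinRecord) else b
    return global_align(sa, sb, s).identity


def greedy_cluster(
    records: Sequence[ProteinRecord],
    p: ClusterParams | None = None,
    s: ScoringScheme | None = None,
) -> list[Cluster]:
    """Length-sorted greedy clustering, longest sequence founds first.

    Records are processed by decreasing length (ties by id, so the result
    is independent of input order); each joins the first-founded cluster
    whose representative it matches at or above the cutoff, else founds
    its own.
    """
    if not records:
        raise ValueError("no records to cluster")
    if p is None:
        p = ClusterParams()
    clusters: list[Cluster] = []
    for rec in sorted(records, key=lambda r: (-r.length, r.id)):
        placed = False
        for cl in clusters:
            if pairwise_identity(rec, cl.representative, s) >= p.identity_cutoff:
                cl.members.append(rec)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(representative=rec, members=[rec]))
    return clusters


# ---------------------------------------------------------------------------
# type II splitting and GltD excision


def split_type2(
    record: ProteinRecord, trx_spans: Sequence[tuple[int, int]]
) -> tuple[ProteinRecord, ProteinRecord]:
    """Split a two-TRX protein at the midpoint of the inter-domain linker.

    Returns the N-half (suffix ``_N``) and C-half (suffix ``_C``), each
    containing exactly one thioredoxin reductase span.
    """
    if len(trx_spans) != 2:
        raise ValueError(f"expected exactly two TRX spans, got {len(trx_spans)}")
    (s1, e1), (s2, e2) = sorted(trx_spans)
    if e1 > s2:
        raise ValueError("TRX spans overlap")
    if e2 > record.length:
        raise ValueError("TRX span beyond sequence end")
    split = (e1 + s2) // 2
    left = ProteinRecord(record.id + "_N", record.seq[:split], record.source)
    right = ProteinRecord(record.id + "_C", record.seq[split:], record.source)
    return left, right


def excise_gltd(record: ProteinRecord, gltd_span: tuple[int, int] | None) -> ProteinRecord:
    """Remove the inserted GltD span; the insertion must be internal."""
    if gltd_span is None:
        raise ValueError(f"{record.id}: no GltD span to excise")
    s, e = gltd_span
    if not (0 < s < e < record.length):
        raise ValueError(f"{record.id}: insertion expected internal, got [{s},{e})")
    return ProteinRecord(
        record.id + "_noGltD", record.seq[:s] + record.seq[e:], record.source
    )


# ---------------------------------------------------------------------------
# alignment containers and trimming


class Msa:
    """A multiple sequence alignment: equal-length gapped rows ('-')."""

    def __init__(self, ids: Sequence[str], rows: Sequence[str]):
        if len(ids) != len(rows):
            raise ValueError("ids and rows differ in length")
        if rows and len({len(r) for r in rows}) != 1:
            raise ValueError("alignment rows differ in length")
        self.ids = list(ids)
        self.rows = [r.upper() for r in rows]

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)

    def ungapped(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)].replace("-", "")

    def select_columns(self, mask: Sequence[bool]) -> "Msa":
        idx = [j for j, keep in enumerate(mask) if keep]
        return Msa(self.ids, ["".join(r[j] for j in idx) for r in self.rows])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Msa) and self.ids == other.ids and self.rows == other.rows
        )

    @classmethod
    def from_fasta(cls, stream: str | Path | TextIO) -> "Msa":
        from .io_formats import _as_handle  # aligned FASTA may contain '-'
        from Bio import SeqIO

        handle = _as_handle(stream)
        ids, rows = [], []
        for rec in SeqIO.parse(handle, "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(ids, rows)

    def to_fasta(self, path: str | Path | TextIO) -> None:
        text = "".join(f">{i}\n{r}\n" for i, r in zip(self.ids, self.rows))
        if isinstance(path, (str, Path)):
            Path(path).write_text(text)
        else:
            path.write(text)


@dataclass
class TrimParams:
    """Column-filter thresholds: entropy in bits over non-gap residues."""

    entropy_max: float = 1.5
    gap_fraction_max: float = 0.2

    def __post_init__(self) -> None:
        if self.entropy_max < 0:
            raise ValueError("entropy_max must be >= 0")
        if not (0 <= self.gap_fraction_max <= 1):
            raise ValueError("gap_fraction_max must be in [0, 1]")


def column_entropy(column: str) -> float:
    """Shannon entropy (bits) of the non-gap residues of one column."""
    residues = [c for c in column if c != "-"]
    if not residues:
        return float("inf")
    _, counts = np.unique(residues, return_counts=True)
    return float(shannon_entropy(counts, base=2))


def trim_columns(msa: Msa, p: TrimParams | None = None) -> tuple[list[bool], Msa]:
    """Keep columns with entropy <= entropy_max and gap fraction <= max.

    All-gap columns are always removed.  The mask preserves column order;
    applying the trimmer to its own output changes nothing (idempotent).
    """
    if p is None:
        p = TrimParams()
    mask: list[bool] = []
    for j in range(msa.n_cols):
        col = msa.column(j)
        gaps = col.count("-") / len(col)
        mask.append(gaps <= p.gap_fraction_max and column_entropy(col) <= p.entropy_max)
    trimmed = msa.select_columns(mask)
    if msa.n_cols and not any(mask):
        logger.warning("trimming removed every column")
    return mask, trimmed


@dataclass(frozen=True)
class SegmentMask:
    """Disjoint increasing [start, end) segments in reference coordinates."""

    reference: str
    segments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev = -1
        for (s, e) in self.segments:
            if not (prev <= s < e):
                raise ValueError("segments must be disjoint and increasing")
            prev = e

    @property
    def total_length(self) -> int:
        return sum(e - s for s, e in self.segments)

    def covers(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.segments)


def extract_segment_mask(msa: Msa, mask: SegmentMask) -> Msa:
    """Columns where the reference row is non-gap inside a mask segment.

    Reference coordinates are 0-based positions in the ungapped reference
    sequence; gap columns of the reference are never selected.
    """
    if mask.reference not in msa.ids:
        raise ValueError(f"reference {mask.reference!r} absent from alignment")
    ref_row = msa.rows[msa.ids.index(mask.reference)]
    keep = []
    ref_pos = -1
    for c in ref_row:
        if c != "-":
            ref_pos += 1
            keep.append(mask.covers(ref_pos))
        else:
            keep.append(False)
    return msa.select_columns(keep)
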