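"""Built-in motif scanning and architecture assembly for HdrA.

The conserved cofactor-binding sites of HdrA are recognisable from short
deterministic sequence fingerprints:

* ``FeS4``  — C-X2-C-X2-C-X3-C, a 4-cysteine [4Fe-4S] binding motif;
* ``FeS2``  — C-X2-C, half of a [2Fe-2S] site (MvhD carries two, 25-40
  residues apart);
* ``ROSS_NAD`` / ``ROSS_NADP`` — the glycine-rich Rossmann-fold
  fingerprints G-X-G-X-X-G and G-X-G-X-X-A, whose final position
  discriminates NAD(+) from NADP(+) preference.

Motif occurrences are assembled into an ordered domain architecture by a
small deterministic rule set (see :class:`AssemblyRules`).  These built-in
patterns are calibrated against the package's synthetic sequence
generator; on real survey data, externally computed conserved-domain
evidence (CD-Search-style hit tables) is the authoritative pathway and
overrides built-in calls on the same span.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .io_formats import (
    AMINO_ACIDS,
    DOMAIN_LABELS,
    DomainHitRow,
    ParseError,
    ProteinRecord,
)

logger = logging.getLogger("hdrakit.scan")


# ---------------------------------------------------------------------------
# motif definitions


@dataclass(frozen=True)
class MotifDefinition:
    """A deterministic amino-acid pattern with fixed and wildcard positions.

    ``pattern`` uses X for "any residue" and bracketed alternatives, e.g.
    ``C[ST]XC``.  ``context`` optionally restricts where on the protein a
    match may start: ``first:N`` (match must start within the first N
    residues) or ``last:N`` (match must end within the last N residues).
    """

    name: str
    pattern: str
    context: str = ""

    def __post_init__(self) -> None:
        if len(self.positions()) < 4:
            raise ValueError(f"motif {self.name}: pattern length < 4")

    def positions(self) -> tuple[frozenset[str] | None, ...]:
        """Parse the pattern into per-position allowed sets (None = any)."""
        out: list[frozenset[str] | None] = []
        i = 0
        p = self.pattern
        while i < len(p):
            c = p[i]
            if c == "X":
                out.append(None)
                i += 1
            elif c == "[":
                j = p.index("]", i)
                out.append(frozenset(p[i + 1 : j]))
                i = j + 1
            else:
                out.append(frozenset(c))
                i += 1
        return tuple(out)

    @property
    def fixed_count(self) -> int:
        """Number of constrained (non-wildcard) positions = match score."""
        return sum(1 for s in self.positions() if s is not None)


def default_motifs() -> list[MotifDefinition]:
    """The bundled motif set (editable TSV: name, pattern, context)."""
    data = resources.files("hdrakit.data").joinpath("motifs.tsv").read_text()
    motifs = []
    for row in csv.reader(io.StringIO(data), delimiter="\t"):
        if not row or row[0].startswith("#"):
            continue
        name, pattern = row[0], row[1]
        context = row[2] if len(row) > 2 and row[2] not in (".", "") else ""
        motifs.append(MotifDefinition(name, pattern, context))
    return motifs


def _context_ok(context: str, start: int, end: int, length: int) -> bool:
    if not context:
        return True
    kind, _, arg = context.partition(":")
    n = int(arg)
    if kind == "first":
        return start < n
    if kind == "last":
        return end > length - n
    raise ValueError(f"unknown motif context {context!r}")


def scan_motifs(
    record: ProteinRecord, motifs: Sequence[MotifDefinition] | None = None
) -> list[DomainHitRow]:
    """Report every occurrence of every motif on the sequence.

    All occurrences are reported, including overlapping ones of the same
    motif; resolution into domains happens in :func:`resolve_architecture`.
    Score = number of constrained positions (patterns are all-or-nothing).
    Selenocysteine is treated as cysteine for motif purposes.
    """
    if motifs is None:
        motifs = default_motifs()
    if not motifs:
        raise ValueError("motif set is empty")
    seq = record.seq.replace("U", "C")
    n = len(seq)
    hits: list[DomainHitRow] = []
    for m in motifs:
        pos = m.positions()
        plen = len(pos)
        score = float(m.fixed_count)
        for i in range(n - plen + 1):
            ok = True
            for j, allowed in enumerate(pos):
                if allowed is not None and seq[i + j] not in allowed:
                    ok = False
                    break
            if ok and _context_ok(m.context, i, i + plen, n):
                hits.append(
                    DomainHitRow(record.id, m.name, i, i + plen, score, "builtin")
                )
    hits.sort(key=lambda h: (h.start, h.domain_label))
    return hits


def call_rossmann(window: str) -> str:
    """Classify a Rossmann-fold fingerprint in a sequence window.

    The first occurrence of G-X-G-X-X-G signals NAD(+) preference, of
    G-X-G-X-X-A NADP(+) preference; at any single position the two are
    mutually exclusive (the last position cannot be both G and A).
    """
    if len(window) < 6:
        raise ValueError("window shorter than the 6-residue fingerprint")
    w = window.upper()
    for i in range(len(w) - 5):
        if w[i] == "G" and w[i + 2] == "G":
            if w[i + 5] == "G":
                return "NAD"
            if w[i + 5] == "A":
                return "NADP"
    return "none"


# ---------------------------------------------------------------------------
# architecture assembly


@dataclass(frozen=True)
class Architecture:
    """Ordered, non-overlapping conserved domains on one protein."""

    protein_id: str
    domains: tuple[str, ...]
    spans: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.domains) != len(self.spans):
            raise ValueError("domains and spans differ in length")
        prev_end = -1
        for (s, e) in self.spans:
            if s < prev_end:
                raise ValueError("architecture spans overlap or are unordered")
            prev_end = e

    def __len__(self) -> int:
        return len(self.domains)


@dataclass(frozen=True)
class AssemblyRules:
    """Thresholds turning motif occurrences into domain calls.

    Distances are in residues.  Defaults match the span scale of the
    synthetic domain templates and are configurable for other data.
    """

    fd_pair_max_sep: int = 60  # two FeS4 starts this close -> one Fd domain
    fes_n_window: int = 80  # lone FeS4 starting here, before any TRX -> FeS_N
    trx_fes_max_gap: int = 90  # lone FeS4 this close after TRX_FAD -> TRX_FeS
    fd_ins_max_gap: int = 160  # lone Fd this close after previous domain -> Fd_ins
    ross_pair_min: int = 80  # two Rossmann fingerprints this far apart ...
    ross_pair_max: int = 400  # ... (and no FeS4 between) -> one TRX_FAD
    fes2_pair_min: int = 25  # paired C-X2-C separation bounds -> MvhD
    fes2_pair_max: int = 40


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _dedupe(hits: list[DomainHitRow]) -> list[DomainHitRow]:
    """Resolve overlapping same-label hits by (score, span length, leftmost)."""
    kept: list[DomainHitRow] = []
    for h in sorted(
        hits, key=lambda h: (-h.score, -(h.end - h.start), h.start)
    ):
        if not any(_overlaps(h.span, k.span) for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: h.start)
    return kept


@dataclass
class _Call:
    label: str
    start: int
    end: int
    score: float
    origin: str = "builtin"


def resolve_architecture(
    hits: Iterable[DomainHitRow],
    record: ProteinRecord,
    rules: AssemblyRules | None = None,
) -> Architecture:
    """Group motif evidence into an ordered domain architecture.

    Assembly, in order: paired Rossmann fingerprints become a thioredoxin
    reductase FAD domain (TRX_FAD); a leftover Rossmann flanked by
    iron-sulfur motifs on both sides is an inserted GltD; FeS4 pairs become
    ferredoxin (Fd) domains; paired C-X2-C half-sites become MvhD; lone
    FeS4 motifs are labelled FeS_N / TRX_FeS / FeS_extra by position.
    External evidence carrying a vocabulary label is taken as a direct
    domain call and wins over built-in calls on the same span.
    """
    if rules is None:
        rules = AssemblyRules()
    hits = [h for h in hits if h.protein_id == record.id]
    direct = [h for h in hits if h.domain_label in DOMAIN_LABELS]
    fes4 = _dedupe([h for h in hits if h.domain_label == "FeS4"])
    ross = _dedupe(
        [h for h in hits if h.domain_label in ("ROSS_NAD", "ROSS_NADP")]
    )
    fes2 = [
        h
        for h in hits
        if h.domain_label == "FeS2"
        and not any(_overlaps(h.span, f.span) for f in fes4)
    ]
    fes2 = _dedupe(fes2)

    calls: list[_Call] = []

    # Rossmann pairing -> TRX_FAD
    used = [False] * len(ross)
    for i in range(len(ross)):
        if used[i]:
            continue
        for j in range(i + 1, len(ross)):
            if used[j]:
                continue
            sep = ross[j].start - ross[i].start
            if sep > rules.ross_pair_max:
                break
            if sep < rules.ross_pair_min:
                continue
            if any(ross[i].end <= f.start < ross[j].start for f in fes4):
                continue
            calls.append(
                _Call(
                    "TRX_FAD",
                    ross[i].start,
                    ross[j].end,
                    ross[i].score + ross[j].score,
                )
            )
            used[i] = used[j] = True
            break

    trx_spans = [(c.start, c.end) for c in calls]

    # leftover Rossmann flanked by FeS4 on both sides -> inserted GltD
    for i, r in enumerate(ross):
        if used[i]:
            continue
        before = any(f.end <= r.start for f in fes4)
        after = any(f.start >= r.end for f in fes4)
        inside_trx = any(s <= r.start and r.end <= e for (s, e) in trx_spans)
        if before and after and not inside_trx:
            calls.append(_Call("GltD", r.start, r.end, r.score))

    # FeS4 pairing -> Fd domains; leftovers stay lone
    i = 0
    lone_fes4: list[DomainHitRow] = []
    while i < len(fes4):
        if (
            i + 1 < len(fes4)
            and fes4[i + 1].start - fes4[i].start <= rules.fd_pair_max_sep
        ):
            calls.append(
                _Call(
                    "Fd",
                    fes4[i].start,
                    fes4[i + 1].end,
                    fes4[i].score + fes4[i + 1].score,
                )
            )
            i += 2
        else:
            lone_fes4.append(fes4[i])
            i += 1
    for h in lone_fes4:
        calls.append(_Call("FeS4_lone", h.start, h.end, h.score))

    # paired C-X2-C half-sites -> MvhD
    i = 0
    while i < len(fes2):
        if i + 1 < len(fes2) and (
            rules.fes2_pair_min
            <= fes2[i + 1].start - fes2[i].start
            <= rules.fes2_pair_max
        ):
            calls.append(
                _Call(
                    "MvhD",
                    fes2[i].start,
                    fes2[i + 1].end,
                    fes2[i].score + fes2[i + 1].score,
                )
            )
            i += 2
        else:
            i += 1

    # merge with external direct calls; external wins over builtin on overlap
    for h in direct:
        overlapping = [
            c
            for c in calls
            if c.origin == "builtin" and _overlaps((h.start, h.end), (c.start, c.end))
        ]
        for c in overlapping:
            logger.info(
                "record %s: external %s evidence overrides builtin %s at [%d,%d)",
                record.id,
                h.domain_label,
                c.label,
                c.start,
                c.end,
            )
            calls.remove(c)
        calls.append(_Call(h.domain_label, h.start, h.end, h.score, "external"))

    # final overlap resolution by (score, span length, leftmost)
    resolved: list[_Call] = []
    for c in sorted(calls, key=lambda c: (-c.score, -(c.end - c.start), c.start)):
        if not any(_overlaps((c.start, c.end), (k.start, k.end)) for k in resolved):
            resolved.append(c)
    resolved.sort(key=lambda c: c.start)

    # positional labelling of lone FeS4 calls and Fd_ins / Fd_C split
    n_fd = sum(1 for c in resolved if c.label == "Fd")
    fd_seen = 0
    labels: list[str] = []
    spans: list[tuple[int, int]] = []
    prev: _Call | None = None
    seen_trx = False
    for c in resolved:
        label = c.label
        if label == "FeS4_lone":
            if (
                prev is not None
                and prev.label == "TRX_FAD"
                and c.start - prev.end <= rules.trx_fes_max_gap
            ):
                label = "TRX_FeS"
            elif not seen_trx and c.start < rules.fes_n_window:
                label = "FeS_N"
            else:
                label = "FeS_extra"
        elif label == "Fd":
            fd_seen += 1
            if n_fd >= 2:
                label = "Fd_C" if fd_seen == n_fd else "Fd_ins"
            else:
                gap = c.start - prev.end if prev is not None else 0
                label = "Fd_ins" if gap <= rules.fd_ins_max_gap else "Fd_C"
        if label == "TRX_FAD":
            seen_trx = True
        labels.append(label)
        spans.append((c.start, c.end))
        prev = c

    return Architecture(record.id, tuple(labels), tuple(spans))
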