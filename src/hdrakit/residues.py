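"""Reference-anchored key-residue calling.

Two residue frames matter for HdrA biology.  On HdrA itself, a lysine and
a glutamate near the FAD (positions 409 and 356 in the reference frame of
a characterised methanogen HdrA) stabilise the flavin semiquinone; their
joint presence is the proposed hallmark of bifurcation-competent
proteins.  On molybdopterin-family (Molybdop) proteins found in hdrA gene
clusters, the active-site frame is a coordinating cysteine (118) plus a
proline/phenylalanine pair (234/235) whose side chains, when present
together with a missing cysteine, occlude the Mo/W-bisPGD cofactor site
and mark the protein as a non-catalytic structural subunit.

Residues are located by optimal global alignment of the query to the
reference sequence ("corresponding residues"), not by absolute position,
so terminal extensions and indels in the query do not shift the calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import AMINO_ACIDS, ProteinRecord

ALIGN_ALPHABET = AMINO_ACIDS + "UX"

#: below this alignment identity, positional equivalence is meaningless
IDENTITY_FLOOR = 0.15


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap alignment scoring.

    ``gap_open`` is the penalty charged for the first residue of a gap,
    ``gap_extend`` for each subsequent one.  With ``matrix_name='simple'``
    the ``match``/``mismatch`` scores are used instead of a substitution
    matrix.  Selenocysteine (U) scores as cysteine; X scores 0 against
    everything.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    match: float = 1.0
    mismatch: float = -1.0

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError("require gap_open >= gap_extend >= 0")


@dataclass(frozen=True)
class ReferenceAnchor:
    """A reference sequence with expected residues at 1-based positions."""

    ref_id: str
    ref_seq: str
    anchored: Mapping[int, str]

    def __post_init__(self) -> None:
        for pos, res in self.anchored.items():
            if not (1 <= pos <= len(self.ref_seq)):
                raise ValueError(f"anchored position {pos} beyond reference length")
            if len(res) != 1:
                raise ValueError(f"expected residue at {pos} must be one letter")


@dataclass(frozen=True)
class ResidueCall:
    """Observed query residues at the anchored reference positions."""

    protein_id: str
    observed: Mapping[int, str | None]  # residue, '-' for gap, None undetermined
    matches: Mapping[int, bool | None]
    status: str = "ok"  # ok | unalignable


@dataclass(frozen=True)
class GlobalAlignment:
    aligned_a: str
    aligned_b: str
    score: float

    @property
    def identity(self) -> float:
        """Identical columns over the length of the shorter sequence."""
        ident = sum(
            1 for x, y in zip(self.aligned_a, self.aligned_b) if x == y and x != "-"
        )
        la = len(self.aligned_a.replace("-", ""))
        lb = len(self.aligned_b.replace("-", ""))
        return ident / min(la, lb)


@lru_cache(maxsize=8)
def _matrix(name: str, match: float, mismatch: float):
    alphabet = ALIGN_ALPHABET
    arr = substitution_matrices.Array(alphabet=alphabet, dims=2)
    if name == "simple":
        for a in alphabet:
            for b in alphabet:
                if "X" in (a, b):
                    arr[a, b] = 0.0
                else:
                    arr[a, b] = match if a == b else mismatch
        return arr
    base = substitution_matrices.load(name)

    def canonical(c: str) -> str:
        return "C" if c == "U" else c

    for a in alphabet:
        for b in alphabet:
            if "X" in (a, b):
                arr[a, b] = 0.0
            else:
                arr[a, b] = base[canonical(a), canonical(b)]
    return arr


def _aligner(s: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _matrix(s.matrix_name, s.match, s.mismatch)
    aligner.open_gap_score = -s.gap_open
    aligner.extend_gap_score = -s.gap_extend
    return aligner


def _check_seq(seq: str, label: str) -> None:
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    bad = set(seq) - set(ALIGN_ALPHABET)
    if bad:
        raise ValueError(f"{label}: non-residue characters {sorted(bad)!r}")


def global_align(a: str, b: str, s: ScoringScheme | None = None) -> GlobalAlignment:
    """Optimal global alignment of two sequences under affine-gap scoring."""
    if s is None:
        s = ScoringScheme()
    _check_seq(a, "first sequence")
    _check_seq(b, "second sequence")
    aln = _aligner(s).align(a, b)[0]
    return GlobalAlignment(str(aln[0]), str(aln[1]), float(aln.score))


def call_anchored_residues(
    query: ProteinRecord | str,
    anchor: ReferenceAnchor,
    s: ScoringScheme | None = None,
) -> ResidueCall:
    """Report the query residue aligned to each anchored reference column.

    A query whose alignment identity to the reference falls below the
    15% floor is called "unalignable" with all positions undetermined.
    """
    qid = query.id if isinstance(query, ProteinRecord) else "query"
    qseq = query.seq if isinstance(query, ProteinRecord) else query
    aln = global_align(anchor.ref_seq, qseq, s)
    if aln.identity < IDENTITY_FLOOR:
        observed = {p: None for p in anchor.anchored}
        matches = {p: None for p in anchor.anchored}
        return ResidueCall(qid, observed, matches, status="unalignable")
    observed: dict[int, str | None] = {}
    ref_pos = 0  # 1-based position of the last consumed reference residue
    wanted = set(anchor.anchored)
    for rc, qc in zip(aln.aligned_a, aln.aligned_b):
        if rc != "-":
            ref_pos += 1
            if ref_pos in wanted:
                observed[ref_pos] = qc if qc != "-" else "-"
    matches = {
        p: (observed[p] == anchor.anchored[p]) if observed[p] not in (None, "-") else False
        for p in anchor.anchored
    }
    return ResidueCall(qid, observed, matches, status="ok")


def bifurcation_competence(call: ResidueCall) -> str:
    """Summarise the FAD-stabilising residue pair into a competence status.

    Both anchored residues present -> "competent"; exactly one ->
    "partial"; neither -> "absent".  The individual flags remain in the
    call; undetermined positions yield "unknown".
    """
    if call.status != "ok" or any(v is None for v in call.matches.values()):
        return "unknown"
    flags = list(call.matches.values())
    if len(flags) < 2:
        raise ValueError("competence requires at least the two anchored positions")
    n = sum(bool(f) for f in flags)
    if n == len(flags):
        return "competent"
    if n > 0:
        return "partial"
    return "absent"


def molybdop_site_check(
    query: ProteinRecord | str,
    anchor: ReferenceAnchor,
    s: ScoringScheme | None = None,
) -> str:
    """Active-site status of a Molybdop-family protein.

    The anchor frame must carry expected residues C (coordinating
    cysteine), P and F (the occluding pair).  Cysteine present ->
    "catalytic"; serine in its place -> "serine_substituted"; cysteine
    absent with the proline or phenylalanine present ->
    "cofactor_blocked"; anything else (including an unalignable query)
    -> "ambiguous".
    """
    by_expected = {res: pos for pos, res in anchor.anchored.items()}
    if not {"C", "P", "F"}.issubset(by_expected):
        raise ValueError("Molybdop anchor must carry expected residues C, P and F")
    call = call_anchored_residues(query, anchor, s)
    if call.status != "ok":
        return "ambiguous"
    obs_c = call.observed[by_expected["C"]]
    obs_p = call.observed[by_expected["P"]]
    obs_f = call.observed[by_expected["F"]]
    if obs_c == "C":
        return "catalytic"
    if obs_c == "S":
        return "serine_substituted"
    if obs_p == "P" or obs_f == "F":
        return "cofactor_blocked"
    return "ambiguous"
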