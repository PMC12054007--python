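"""Synthetic inputs with known ground truth for every pipeline stage.

Proteins are built by concatenating per-domain template instances joined
by random linkers, so each record carries a planted class architecture,
planted (or ablated) FAD-stabilising residues, and a known truth row.
The domain templates are packaged synthetic consensus strings — NOT real
HdrA segments — that contain the scanner's motif patterns at fixed
internal offsets:

==========  ======  =================================================
template    length  embedded fingerprints (0-based offsets)
==========  ======  =================================================
FeS_N           70  FeS4 at 10
TRX_FAD        320  Rossmann G-X-G-X-X-G at 5 and 310; E at 255,
                    K at 308 (the FAD-stabilising pair)
TRX_FeS         70  FeS4 at 10
Fd              80  FeS4 at 5 and 35 (two [4Fe-4S] clusters)
MvhD            70  C-X2-C at 10 and 42 ([2Fe-2S] half-sites)
GltD            60  Rossmann G-X-G-X-X-G at 25
FeS_extra       70  FeS4 at 10
==========  ======  =================================================

Filler and linker residues are drawn from an alphabet without C and G,
and substitutions avoid C and G as well, so point noise cannot fabricate
iron-sulfur or Rossmann fingerprints; motif-critical positions are only
ever touched when ``corrupt_motifs`` is set.  In the canonical reference
layout (class A1, fixed 30-residue linkers) the planted lysine and
glutamate fall at 1-based positions 409 and 356, mirroring the reference
frame used for bifurcation-competence calls.

All generators are fully deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .classify import ClassCatalog, load_catalog
from .io_formats import GeneFeature, ProteinRecord
from .neighborhood import ClusteringRule
from .phyloprep import Msa
from .residues import ReferenceAnchor

#: linker/filler alphabet: no cysteine, no glycine (cannot seed motifs)
FILLER_ALPHABET = "ADEFHIKLMNPQRSTVWY"
AA20 = "ACDEFGHIKLMNPQRSTVWY"

_TEMPLATE_SEED = 271828  # fixed: templates are part of the package contract

LINKER_RANGE = (20, 60)  # residues, inclusive
#: spacer replacing a deleted Fd_ins when Fd_C follows the TRX module directly
ORPHAN_FD_C_SPACER = (150, 190)

K_OFFSET = 308  # within TRX_FAD, 0-based
E_OFFSET = 255


@dataclass(frozen=True)
class DomainTemplate:
    label: str
    seq: str
    fixed: frozenset[int]  # motif-critical positions, never substituted

    @property
    def length(self) -> int:
        return len(self.seq)


def _motif_chars(pattern: str) -> list[tuple[int, str]]:
    return [(i, c) for i, c in enumerate(pattern) if c != "X"]


def _build_templates() -> dict[str, DomainTemplate]:
    rng = np.random.default_rng(_TEMPLATE_SEED)

    def filler(n: int) -> list[str]:
        return list(rng.choice(list(FILLER_ALPHABET), size=n))

    def place(seq: list[str], fixed: set[int], offset: int, pattern: str) -> None:
        for i, c in _motif_chars(pattern):
            seq[offset + i] = c
            fixed.add(offset + i)

    FES4 = "CXXCXXCXXXC"
    ROSS = "GXGXXG"
    CX2C = "CXXC"

    out: dict[str, DomainTemplate] = {}

    for label in ("FeS_N", "TRX_FeS", "FeS_extra"):
        seq, fixed = filler(70), set()
        place(seq, fixed, 10, FES4)
        out[label] = DomainTemplate(label, "".join(seq), frozenset(fixed))

    seq, fixed = filler(320), set()
    place(seq, fixed, 5, ROSS)
    place(seq, fixed, 310, ROSS)
    seq[E_OFFSET] = "E"
    seq[K_OFFSET] = "K"
    fixed |= {E_OFFSET, K_OFFSET}
    out["TRX_FAD"] = DomainTemplate("TRX_FAD", "".join(seq), frozenset(fixed))

    seq, fixed = filler(80), set()
    place(seq, fixed, 5, FES4)
    place(seq, fixed, 35, FES4)
    out["Fd"] = DomainTemplate("Fd", "".join(seq), frozenset(fixed))

    seq, fixed = filler(70), set()
    place(seq, fixed, 10, CX2C)
    place(seq, fixed, 42, CX2C)
    out["MvhD"] = DomainTemplate("MvhD", "".join(seq), frozenset(fixed))

    seq, fixed = filler(60), set()
    place(seq, fixed, 25, ROSS)
    out["GltD"] = DomainTemplate("GltD", "".join(seq), frozenset(fixed))

    return out


DOMAIN_TEMPLATES: dict[str, DomainTemplate] = _build_templates()

_TOKEN_TEMPLATE = {
    "FeS_N": "FeS_N",
    "TRX_FAD": "TRX_FAD",
    "TRX_FeS": "TRX_FeS",
    "Fd_ins": "Fd",
    "Fd_C": "Fd",
    "MvhD": "MvhD",
    "GltD": "GltD",
    "FeS_extra": "FeS_extra",
}


@dataclass
class ProteinSpec:
    """What to generate: class, count, noise and planted-residue flags."""

    class_name: str
    n: int = 1
    substitution_rate: float = 0.0
    plant_K409: bool = True
    plant_E356: bool = True
    corrupt_motifs: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.substitution_rate < 1):
            raise ValueError("substitution_rate must be in [0, 1)")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass(frozen=True)
class ProteinTruth:
    """Ground truth for one generated protein."""

    id: str
    class_name: str
    major_type: str
    k409_present: bool
    e356_present: bool
    k_pos: int  # global 1-based position of the K-equivalent (first TRX_FAD)
    e_pos: int
    domains: tuple[tuple[str, int, int], ...]  # (token, start, end) extents


def _mandatory_tokens(template: Sequence[str]) -> list[str]:
    return [t[:-1] if t.endswith("?") else t for t in template if not t.endswith("?")]


def generate_proteins(
    spec: ProteinSpec, catalog: ClassCatalog | None = None
) -> tuple[list[ProteinRecord], list[ProteinTruth]]:
    """Generate ``spec.n`` proteins of the planted class with ground truth."""
    if catalog is None:
        catalog = load_catalog()
    if spec.class_name not in catalog.by_name:
        raise ValueError(f"unknown class {spec.class_name!r}")
    entry = catalog.by_name[spec.class_name]
    tokens = _mandatory_tokens(entry.template)
    rng = np.random.default_rng(spec.seed)
    records, truths = [], []
    safe_name = spec.class_name.replace("+", "p").replace("-", "_")
    for i in range(spec.n):
        seq_parts: list[str] = []
        pos = 0
        extents: list[tuple[str, int, int]] = []
        k_pos = e_pos = -1
        for j, tok in enumerate(tokens):
            if j > 0:
                if tok == "Fd_C" and "Fd_ins" not in tokens[:j]:
                    lo, hi = ORPHAN_FD_C_SPACER
                else:
                    lo, hi = LINKER_RANGE
                linker_len = int(rng.integers(lo, hi + 1))
                seq_parts.append(
                    "".join(rng.choice(list(FILLER_ALPHABET), size=linker_len))
                )
                pos += linker_len
            tmpl = DOMAIN_TEMPLATES[_TOKEN_TEMPLATE[tok]]
            chars = list(tmpl.seq)
            if spec.substitution_rate > 0:
                hitmask = rng.random(len(chars)) < spec.substitution_rate
                for p in np.nonzero(hitmask)[0]:
                    if p in tmpl.fixed and not spec.corrupt_motifs:
                        continue
                    choices = [c for c in FILLER_ALPHABET if c != chars[p]]
                    chars[p] = str(rng.choice(choices))
            if tok == "TRX_FAD":
                if not spec.plant_K409:
                    chars[K_OFFSET] = "A"
                if not spec.plant_E356:
                    chars[E_OFFSET] = "A"
                if k_pos < 0:
                    k_pos = pos + K_OFFSET + 1
                    e_pos = pos + E_OFFSET + 1
            seq_parts.append("".join(chars))
            extents.append((tok, pos, pos + tmpl.length))
            pos += tmpl.length
        rid = f"{safe_name}_{spec.seed}_{i:03d}"
        records.append(ProteinRecord(rid, "".join(seq_parts), source="synthetic"))
        truths.append(
            ProteinTruth(
                id=rid,
                class_name=spec.class_name,
                major_type=entry.major_type,
                k409_present=spec.plant_K409,
                e356_present=spec.plant_E356,
                k_pos=k_pos,
                e_pos=e_pos,
                domains=tuple(extents),
            )
        )
    return records, truths


# ---------------------------------------------------------------------------
# reference anchors (synthetic stand-ins; no accession downloads)


def reference_protein() -> ProteinRecord:
    """The canonical synthetic A1 reference: fixed 30-residue linkers.

    In this layout the FAD-stabilising lysine and glutamate fall exactly
    at 1-based positions 409 and 356.
    """
    tokens = ["FeS_N", "TRX_FAD", "TRX_FeS", "Fd_ins", "Fd_C"]
    rng = np.random.default_rng(_TEMPLATE_SEED + 1)
    parts = []
    for j, tok in enumerate(tokens):
        if j > 0:
            parts.append("".join(rng.choice(list(FILLER_ALPHABET), size=30)))
        parts.append(DOMAIN_TEMPLATES[_TOKEN_TEMPLATE[tok]].seq)
    return ProteinRecord("synthetic_hdrA_ref", "".join(parts), source="synthetic")


def synthetic_reference_anchor() -> ReferenceAnchor:
    """Synthetic HdrA anchor: K expected at 409, E at 356."""
    ref = reference_protein()
    assert ref.seq[408] == "K" and ref.seq[355] == "E"
    return ReferenceAnchor(ref.id, ref.seq, {409: "K", 356: "E"})


_MOLYBDOP_LEN = 400
_MOLYBDOP_SITES = {117: "C", 233: "P", 234: "F"}  # 0-based frame positions


def _molybdop_base() -> list[str]:
    rng = np.random.default_rng(_TEMPLATE_SEED + 2)
    return list(rng.choice(list(FILLER_ALPHABET), size=_MOLYBDOP_LEN))


def synthetic_molybdop_anchor() -> ReferenceAnchor:
    """Synthetic Molybdop active-site frame: C118, P234, F235 (1-based)."""
    chars = _molybdop_base()
    for p, res in _MOLYBDOP_SITES.items():
        chars[p] = res
    return ReferenceAnchor(
        "synthetic_molybdop_frame",
        "".join(chars),
        {p + 1: res for p, res in _MOLYBDOP_SITES.items()},
    )


def generate_molybdop(variant: str, seed: int = 0) -> ProteinRecord:
    """A synthetic Molybdop-family protein of a given active-site variant.

    Variants: "catalytic" (Cys present, occluding pair absent), "serine"
    (Ser replaces the cysteine), "blocked" (no Cys; Pro and Phe present).
    """
    site = {
        "catalytic": {117: "C", 233: "A", 234: "L"},
        "serine": {117: "S", 233: "A", 234: "L"},
        "blocked": {117: "A", 233: "P", 234: "F"},
    }
    if variant not in site:
        raise ValueError(f"unknown variant {variant!r}")
    chars = _molybdop_base()
    for p, res in site[variant].items():
        chars[p] = res
    return ProteinRecord(
        f"molybdop_{variant}_{seed}", "".join(chars), source="synthetic"
    )


# ---------------------------------------------------------------------------
# gene neighborhoods


def generate_neighborhood(
    layout: Sequence[tuple[str, str, int]],
    seed: int = 0,
    rule: ClusteringRule | None = None,
    contig: str = "synthetic_contig_1",
) -> tuple[list[GeneFeature], list[int]]:
    """Place oriented genes left to right with specified strands and gaps.

    ``layout`` rows are (label, strand, gap-to-previous-gene); the gap of
    the first gene is ignored.  Gene lengths are drawn 600-2400 nt under
    the seed.  Returns the features and the planted partition: for each
    gene, the index of the cluster it belongs to under ``rule`` (default
    rule: same strand, gap <= 200).
    """
    if rule is None:
        rule = ClusteringRule()
    rng = np.random.default_rng(seed)
    features: list[GeneFeature] = []
    truth: list[int] = []
    pos = 0
    cluster_idx = 0
    prev_strand: str | None = None
    for i, (label, strand, gap) in enumerate(layout):
        if i > 0:
            if gap < 0:
                raise ValueError("negative intergenic gap")
            pos += gap
            if strand != prev_strand and rule.same_strand_required or gap > rule.max_gap:
                cluster_idx += 1
        length = int(rng.integers(600, 2401))
        features.append(
            GeneFeature(
                contig=contig,
                locus_id=f"gene_{seed}_{i:03d}",
                start=pos,
                end=pos + length,
                strand=strand,
                label=label,
            )
        )
        truth.append(cluster_idx)
        pos += length
        prev_strand = strand
    return features, truth


# ---------------------------------------------------------------------------
# MSA fixture for the trimmer


def generate_msa_fixture(
    n_rows: int, core_cols: int, insert_cols: int, seed: int = 0
) -> tuple[Msa, list[str]]:
    """An alignment of near-conserved core columns and noisy insert columns.

    Core columns have one dominant residue at >=90% frequency and no
    gaps; insert columns are uniform over the 20 residues with 30% gaps.
    Columns are interleaved at random.  Returns the alignment and the
    per-column truth labels ("core" / "insert").
    """
    if min(n_rows, core_cols, insert_cols) < 1:
        raise ValueError("all counts must be >= 1")
    rng = np.random.default_rng(seed)
    labels = ["core"] * core_cols + ["insert"] * insert_cols
    order = rng.permutation(len(labels))
    labels = [labels[i] for i in order]
    columns: list[str] = []
    for lab in labels:
        if lab == "core":
            dom = str(rng.choice(list(AA20)))
            col = [
                dom if rng.random() < 0.92 else str(rng.choice(list(AA20.replace(dom, ""))))
                for _ in range(n_rows)
            ]
        else:
            col = [
                "-" if rng.random() < 0.30 else str(rng.choice(list(AA20)))
                for _ in range(n_rows)
            ]
        columns.append("".join(col))
    rows = ["".join(columns[j][i] for j in range(len(columns))) for i in range(n_rows)]
    ids = [f"row_{i:02d}" for i in range(n_rows)]
    return Msa(ids, rows), labels
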