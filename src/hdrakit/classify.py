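"""Assignment of HdrA architectures to 28 classes and 4 major types.

The classification scheme groups HdrA proteins by their ordered conserved
domains.  The four major types are decided by the thioredoxin reductase
(TRX_FAD) domains and the characteristic fusions/insertions:

* type II  — two TRX_FAD domains (decided first);
* type III — an inserted GltD domain;
* type Ia  — a C-terminal MvhD fusion;
* type I   — everything else with a single TRX_FAD.

Within a type, the class is the exact ordered match of the domain string
against the catalog templates.  Proteins shorter than 300 residues are
filtered out beforehand as low quality or incomplete (the shortest
characterised homolog is 341 residues; the survey minimum is 302).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .domain_scan import Architecture
from .io_formats import DOMAIN_LABELS, ProteinRecord

MAJOR_TYPES = ("I", "Ia", "II", "III")
#: classes per major type stated by the survey
EXPECTED_TYPE_COUNTS = {"I": 13, "Ia": 5, "II": 7, "III": 3}
N_CLASSES = 28


class CatalogError(ValueError):
    """The class catalog violates one of its structural constraints."""


class UnassignableCombinationError(ValueError):
    """A domain combination outside the closed classification scheme."""


@dataclass(frozen=True)
class ClassCatalogEntry:
    class_name: str
    major_type: str
    template: tuple[str, ...]  # tokens; trailing '?' marks an optional slot

    @property
    def n_domains(self) -> int:
        return len(self.template)


@dataclass
class FilterParams:
    """Minimum-length quality filter; default 300 residues."""

    min_length: int = 300

    def __post_init__(self) -> None:
        if self.min_length <= 0:
            raise ValueError("min_length must be positive")


@dataclass(frozen=True)
class ClassificationResult:
    protein_id: str
    class_name: str  # class name or "unassigned"
    major_type: str  # type or "not-hdrA"
    evidence: str  # matched (or nearest) template as a token string
    filter_status: str = "passed"  # passed | too_short


class ClassCatalog:
    """Validated collection of the 28 class templates."""

    def __init__(self, entries: Sequence[ClassCatalogEntry], validate: bool = True):
        self.entries = list(entries)
        self.by_name = {e.class_name: e for e in self.entries}
        if validate:
            self.validate()

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def validate(self) -> None:
        if len(self.entries) != N_CLASSES:
            raise CatalogError(
                f"catalog must contain exactly {N_CLASSES} classes, got {len(self.entries)}"
            )
        counts = {t: 0 for t in MAJOR_TYPES}
        for e in self.entries:
            if e.major_type not in MAJOR_TYPES:
                raise CatalogError(f"{e.class_name}: unknown major type {e.major_type}")
            counts[e.major_type] += 1
            if not (2 <= e.n_domains <= 8):
                raise CatalogError(
                    f"{e.class_name}: {e.n_domains} domains outside the 2-8 range"
                )
            for tok in e.template:
                base = tok[:-1] if tok.endswith("?") else tok
                if base not in DOMAIN_LABELS:
                    raise CatalogError(f"{e.class_name}: unknown domain token {tok!r}")
            declared = assign_type(_mandatory(e.template))
            if declared != e.major_type:
                raise CatalogError(
                    f"{e.class_name}: template implies type {declared}, "
                    f"catalog says {e.major_type}"
                )
        if counts != EXPECTED_TYPE_COUNTS:
            raise CatalogError(
                f"per-type class counts {counts} != expected {EXPECTED_TYPE_COUNTS}"
            )
        templates = [e.template for e in self.entries]
        if len(set(templates)) != len(templates):
            raise CatalogError("catalog templates are not pairwise distinct")
        if len(self.by_name) != len(self.entries):
            raise CatalogError("duplicate class names in catalog")


def _mandatory(template: tuple[str, ...]) -> tuple[str, ...]:
    return tuple(t for t in template if not t.endswith("?"))


def load_catalog(path: str | Path | None = None) -> ClassCatalog:
    """Load and validate a catalog TSV (class_name, major_type, template).

    Template tokens are space-separated; a token suffixed ``?`` marks a
    wildcard slot that may be absent (used for variable extra iron-sulfur
    clusters within a class).  Without a path the packaged catalog is used.
    """
    if path is None:
        text = resources.files("hdrakit.data").joinpath("class_catalog.tsv").read_text()
    else:
        text = Path(path).read_text()
    entries = []
    for row in csv.reader(io.StringIO(text), delimiter="\t"):
        if not row or row[0].startswith("#") or row[0] == "class_name":
            continue
        if len(row) != 3:
            raise CatalogError(f"catalog row {row!r}: expected 3 columns")
        entries.append(
            ClassCatalogEntry(row[0], row[1], tuple(row[2].split()))
        )
    return ClassCatalog(entries)


def length_filter(
    records: Iterable[ProteinRecord], params: FilterParams | None = None
) -> tuple[list[ProteinRecord], list[tuple[ProteinRecord, str]]]:
    """Split records into (kept, rejected-with-reason) by minimum length."""
    if params is None:
        params = FilterParams()
    kept, rejected = [], []
    for r in records:
        if r.length >= params.min_length:
            kept.append(r)
        else:
            rejected.append((r, "too_short"))
    return kept, rejected


def assign_type(arch: Architecture | Sequence[str]) -> str:
    """Decide the major type of a domain string.

    Precedence: type II first (two TRX_FAD), then III (GltD), then Ia
    (terminal MvhD), then I.  No TRX_FAD at all means the protein is not
    an HdrA.  Combinations outside the closed scheme (GltD together with
    two TRX_FAD, or GltD plus a terminal MvhD) raise
    :class:`UnassignableCombinationError`.
    """
    domains = tuple(arch.domains) if isinstance(arch, Architecture) else tuple(arch)
    n_trx = domains.count("TRX_FAD")
    has_gltd = "GltD" in domains
    mvhd_last = bool(domains) and domains[-1] == "MvhD"
    if n_trx == 0:
        return "not-hdrA"
    if n_trx >= 2:
        if has_gltd:
            raise UnassignableCombinationError(
                "two TRX_FAD domains together with GltD are outside the scheme"
            )
        return "II"
    if has_gltd:
        if mvhd_last:
            raise UnassignableCombinationError(
                "GltD together with a terminal MvhD is outside the scheme"
            )
        return "III"
    if mvhd_last:
        return "Ia"
    return "I"


def _template_matches(template: tuple[str, ...], domains: tuple[str, ...]) -> bool:
    """Ordered match; tokens suffixed '?' may be skipped."""

    def rec(ti: int, di: int) -> bool:
        if ti == len(template):
            return di == len(domains)
        tok = template[ti]
        optional = tok.endswith("?")
        base = tok[:-1] if optional else tok
        if di < len(domains) and domains[di] == base and rec(ti + 1, di + 1):
            return True
        if optional and rec(ti + 1, di):
            return True
        return False

    return rec(0, 0)


def _token_edit_distance(a: Sequence[str], b: Sequence[str]) -> int:
    m, n = len(a), len(b)
    dp = list(range(n + 1))
    for i in range(1, m + 1):
        prev = dp[0]
        dp[0] = i
        for j in range(1, n + 1):
            cur = dp[j]
            dp[j] = min(dp[j] + 1, dp[j - 1] + 1, prev + (a[i - 1] != b[j - 1]))
            prev = cur
    return dp[n]


def assign_class(
    arch: Architecture, catalog: ClassCatalog | None = None
) -> ClassificationResult:
    """Assign an architecture to its class via exact ordered template match.

    A protein whose type is decidable but whose domain string matches no
    template of that type is reported "unassigned" with the nearest
    template (minimum token edit distance over the whole catalog) as
    evidence — the scheme is closed but real data need not be.
    """
    if catalog is None:
        catalog = load_catalog()
    domains = tuple(arch.domains)
    try:
        major = assign_type(domains)
    except UnassignableCombinationError:
        nearest = min(
            catalog,
            key=lambda e: _token_edit_distance(_mandatory(e.template), domains),
        )
        return ClassificationResult(
            arch.protein_id, "unassigned", "not-hdrA", " ".join(nearest.template)
        )
    if major == "not-hdrA":
        return ClassificationResult(arch.protein_id, "unassigned", "not-hdrA", "")
    for e in catalog:
        if e.major_type == major and _template_matches(e.template, domains):
            return ClassificationResult(
                arch.protein_id, e.class_name, major, " ".join(e.template)
            )
    nearest = min(
        catalog,
        key=lambda e: _token_edit_distance(_mandatory(e.template), domains),
    )
    return ClassificationResult(
        arch.protein_id, "unassigned", major, " ".join(nearest.template)
    )
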