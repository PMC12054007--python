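"""Gene-cluster detection around hdrA and FBEB/FBEC function inference.

A gene cluster is a run of co-oriented, closely spaced genes on one
contig, used as a proxy for a co-functioning protein complex.  The manual
criterion of transcription direction plus intergenic gap is
operationalised as: same contig, same strand (configurable) and gap
<= 200 nt (configurable).

Cluster composition, together with the HdrA types present, feeds a
most-specific-first rulebook that predicts the mid-potential electron
carrier (H2 via MvhAG, F420H2 via FdhB with a non-catalytic Molybdop,
formate via FdhA/FdhB, NADH via the type III GltD insertion), the
high-potential arm (heterodisulfide reduction via HdrBC or HdrD) and the
low-potential arm (Fd reduction, CO2 -> formyl-methanofuran via Fwd/Fmd,
or H2 evolution).  Rows are data (an editable TSV), and each prediction
cites the rows that fired.
"""

from __future__ import annotations

import csv
import io
import logging
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io_formats import GeneFeature, _load_synonyms

logger = logging.getLogger("hdrakit.neighborhood")

MID_CARRIERS = ("H2", "F420H2", "formate", "NADH", "unknown")
HIGH_ARMS = ("CoM-S-S-CoB via HdrBC", "CoM-S-S-CoB via HdrD", "none-detected")
LOW_ARMS = ("Fd", "CO2->formyl-MFR", "H2-evolution", "none")


@dataclass
class ClusteringRule:
    """Strand/gap contiguity rule; defaults stated in every output header."""

    max_gap: int = 200
    same_strand_required: bool = True
    same_contig_required: bool = True

    def __post_init__(self) -> None:
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")


@dataclass
class GeneCluster:
    contig: str
    members: list[GeneFeature]

    @property
    def composition(self) -> Counter:
        syn = gene_synonyms()
        return Counter(normalize_label(m.label, syn) for m in self.members)

    @property
    def contains_hdrA(self) -> bool:
        return "hdrA" in self.composition

    @property
    def span(self) -> tuple[int, int]:
        return (self.members[0].start, self.members[-1].end)


def gene_synonyms() -> dict[str, str]:
    """Bundled gene-label normalisation table (mvh/vhu, fwd/fmd expansion)."""
    return _load_synonyms("gene_synonyms.tsv")


def normalize_label(label: str, synonyms: Mapping[str, str] | None = None) -> str:
    if synonyms is None:
        synonyms = gene_synonyms()
    return synonyms.get(label, label)


def detect_clusters(
    features: Sequence[GeneFeature], rule: ClusteringRule | None = None
) -> list[GeneCluster]:
    """Partition features into strand/gap-contiguous clusters.

    Features must be sorted by (contig, start).  A feature joins the open
    cluster iff it shares the contig, shares the strand (when required)
    and starts within ``max_gap`` nt of the previous feature's end.
    Overlapping features are both kept with the gap treated as 0 (with a
    warning).  The output is a partition: every feature appears in
    exactly one cluster, member order preserved.
    """
    if rule is None:
        rule = ClusteringRule()
    clusters: list[GeneCluster] = []
    current: list[GeneFeature] = []
    for f in features:
        if current:
            prev = current[-1]
            gap = f.start - prev.end
            if gap < 0:
                logger.warning(
                    "overlapping features %s and %s; gap treated as 0",
                    prev.locus_id,
                    f.locus_id,
                )
                gap = 0
            same_contig = f.contig == prev.contig
            same_strand = f.strand == prev.strand
            joins = (
                (same_contig or not rule.same_contig_required)
                and same_contig  # different contigs never share a cluster
                and (same_strand or not rule.same_strand_required)
                and gap <= rule.max_gap
            )
            if not joins:
                clusters.append(GeneCluster(current[0].contig, current))
                current = []
        current.append(f)
    if current:
        clusters.append(GeneCluster(current[0].contig, current))
    return clusters


def hdra_clusters(clusters: Iterable[GeneCluster]) -> list[GeneCluster]:
    """The default report: only clusters containing an hdrA gene."""
    return [c for c in clusters if c.contains_hdrA]


# ---------------------------------------------------------------------------
# function inference


@dataclass(frozen=True)
class RulebookRow:
    rule_id: str
    fieldname: str  # mid | high | low | flag
    requires: tuple[str, ...]
    value: str
    confidence: str  # validated | predicted
    note: str = ""


@dataclass(frozen=True)
class FunctionPrediction:
    cluster_id: str
    hdrA_types: tuple[str, ...]
    mid_potential_carrier: str
    high_potential_arm: str
    low_potential_arm: str
    confidence: str
    notes: str
    fired_rules: tuple[str, ...]


def load_rulebook(path: str | Path | None = None) -> list[RulebookRow]:
    """Load the composition -> prediction rulebook (most-specific-first)."""
    if path is None:
        text = resources.files("hdrakit.data").joinpath("rulebook.tsv").read_text()
    else:
        text = Path(path).read_text()
    rows = []
    for row in csv.reader(io.StringIO(text), delimiter="\t"):
        if not row or row[0].startswith("#") or row[0] == "rule_id":
            continue
        rule_id, fieldname, requires, value, confidence = row[:5]
        note = row[5] if len(row) > 5 else ""
        rows.append(
            RulebookRow(
                rule_id,
                fieldname,
                tuple(t.strip() for t in requires.split(",") if t.strip()),
                value,
                confidence,
                note,
            )
        )
    return rows


def _token_satisfied(
    token: str,
    composition: Counter,
    hdra_type_set: set[str],
    n_hdra: int,
    molybdop_statuses: set[str],
) -> bool:
    if "=" in token:
        key, val = token.split("=", 1)
        if key == "hdrA":
            return val in hdra_type_set
        if key == "hdrA2":
            return n_hdra >= 2 and val in hdra_type_set
        if key == "molybdop":
            return val in molybdop_statuses
        raise ValueError(f"unknown rule token {token!r}")
    return composition[token] > 0


def infer_function(
    cluster: GeneCluster,
    hdrA_types: Mapping[str, str],
    rulebook: Sequence[RulebookRow] | None = None,
    molybdop_status: Mapping[str, str] | None = None,
) -> FunctionPrediction:
    """Infer the FBEB/FBEC reaction of the complex a cluster encodes.

    ``hdrA_types`` maps hdrA locus ids to their major type; optional
    ``molybdop_status`` maps Molybdop locus ids to their active-site
    status.  For each prediction field the first matching rulebook row
    wins; overall confidence is "validated" only when the mid-potential
    carrier row that fired is experimentally validated.
    """
    if rulebook is None:
        rulebook = load_rulebook()
    composition = cluster.composition
    if composition["hdrA"] == 0:
        raise ValueError("cluster contains no hdrA gene")
    hdra_members = [
        m for m in cluster.members if normalize_label(m.label) == "hdrA"
    ]
    types = tuple(
        sorted(hdrA_types[m.locus_id] for m in hdra_members if m.locus_id in hdrA_types)
    )
    type_set = set(types)
    mstat = set()
    if molybdop_status:
        mstat = {
            molybdop_status[m.locus_id]
            for m in cluster.members
            if normalize_label(m.label) == "molybdop" and m.locus_id in molybdop_status
        }
    fired: list[str] = []
    values = {"mid": "unknown", "high": "none-detected", "low": "none"}
    conf = "predicted"
    flags: list[str] = []
    picked: dict[str, RulebookRow] = {}
    for row in rulebook:
        if row.fieldname in values and row.fieldname in picked:
            continue
        ok = all(
            _token_satisfied(t, composition, type_set, len(hdra_members), mstat)
            for t in row.requires
        )
        if not ok:
            continue
        if row.fieldname == "flag":
            flags.append(row.value)
            fired.append(row.rule_id)
        else:
            values[row.fieldname] = row.value
            picked[row.fieldname] = row
            fired.append(row.rule_id)
    mid_row = picked.get("mid")
    if mid_row is not None and mid_row.confidence == "validated":
        conf = "validated"
    cluster_id = f"{cluster.contig}:{cluster.span[0]}-{cluster.span[1]}"
    notes = "; ".join(flags)
    return FunctionPrediction(
        cluster_id=cluster_id,
        hdrA_types=types,
        mid_potential_carrier=values["mid"],
        high_potential_arm=values["high"],
        low_potential_arm=values["low"],
        confidence=conf,
        notes=notes,
        fired_rules=tuple(fired),
    )
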