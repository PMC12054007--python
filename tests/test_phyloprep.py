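"""Clustering, splitting/excision, and alignment-column trimming."""

import math

import pytest

from hdrakit.domain_scan import resolve_architecture, scan_motifs
from hdrakit.io_formats import ProteinRecord
from hdrakit.phyloprep import (
    ClusterParams,
    Msa,
    SegmentMask,
    TrimParams,
    column_entropy,
    excise_gltd,
    extract_segment_mask,
    greedy_cluster,
    pairwise_identity,
    split_type2,
    trim_columns,
)
from hdrakit.residues import ScoringScheme
from hdrakit.synth import ProteinSpec, generate_msa_fixture, generate_proteins

SIMPLE = ScoringScheme(matrix_name="simple", gap_open=1.0, gap_extend=1.0)


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("MKVL", "MKVL", SIMPLE) == 1.0

    def test_disjoint(self):
        assert pairwise_identity("AAAA", "TTTT", SIMPLE) == 0.0

    def test_shorter_sequence_denominator(self):
        assert pairwise_identity("AAAA", "AAAT", SIMPLE) == pytest.approx(0.75)
        # shorter length is the denominator, not the alignment length
        assert pairwise_identity("AAAA", "AAAAAAAA", SIMPLE) == 1.0


class TestGreedyCluster:
    def test_two_clusters_at_80pct(self):
        recs = [
            ProteinRecord("a1", "AAAAAAAAAA"),
            ProteinRecord("a2", "AAAAAAAAAV"),
            ProteinRecord("t1", "TTTTTTTTTT"),
        ]
        clusters = greedy_cluster(recs, ClusterParams(0.8), SIMPLE)
        assert len(clusters) == 2
        sizes = sorted(len(c.members) for c in clusters)
        assert sizes == [1, 2]

    def test_all_singletons_below_cutoff(self):
        recs = [
            ProteinRecord("a", "AAAAA"),
            ProteinRecord("c", "CCCCC"),
            ProteinRecord("d", "DDDDD"),
        ]
        clusters = greedy_cluster(recs, ClusterParams(0.8), SIMPLE)
        assert len(clusters) == 3

    def test_order_free_by_length_sort(self):
        recs = [
            ProteinRecord("a1", "AAAAAAAAAA"),
            ProteinRecord("a2", "AAAAAAAAV"),
            ProteinRecord("t1", "TTTTTTTTTT"),
        ]
        c_fwd = greedy_cluster(recs, ClusterParams(0.8), SIMPLE)
        c_rev = greedy_cluster(list(reversed(recs)), ClusterParams(0.8), SIMPLE)
        as_sets = lambda cs: {
            (c.representative.id, frozenset(m.id for m in c.members)) for c in cs
        }
        assert as_sets(c_fwd) == as_sets(c_rev)

    def test_members_meet_cutoff_and_partition(self):
        recs = [ProteinRecord(f"r{i}", "AAAAAAAAA" + "AV"[i % 2]) for i in range(6)]
        params = ClusterParams(0.8)
        clusters = greedy_cluster(recs, params, SIMPLE)
        seen = []
        for c in clusters:
            for m in c.members:
                seen.append(m.id)
                assert pairwise_identity(m, c.representative, SIMPLE) >= params.identity_cutoff
        assert sorted(seen) == sorted(r.id for r in recs)

    def test_cluster_count_nonincreasing_in_cutoff(self):
        recs = [
            ProteinRecord("a", "AAAAAAAAAA"),
            ProteinRecord("b", "AAAAAAAVVV"),
            ProteinRecord("c", "AAAAVVVVVV"),
            ProteinRecord("d", "VVVVVVVVVV"),
        ]
        counts = [
            len(greedy_cluster(recs, ClusterParams(cut), SIMPLE))
            for cut in (0.9, 0.7, 0.5, 0.3)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            greedy_cluster([])


class TestSplitType2:
    def test_midpoint_of_linker(self):
        rec = ProteinRecord("x", "M" * 700)
        left, right = split_type2(rec, [(50, 200), (400, 560)])
        assert (left.id, right.id) == ("x_N", "x_C")
        assert (left.length, right.length) == (300, 400)

    def test_adjacent_spans_split_at_junction(self):
        rec = ProteinRecord("x", "M" * 400)
        left, right = split_type2(rec, [(50, 200), (200, 350)])
        assert left.length == 200

    def test_parts_reassemble(self):
        rec = ProteinRecord("x", "MKVL" * 100)
        left, right = split_type2(rec, [(20, 120), (250, 380)])
        assert left.seq + right.seq == rec.seq

    def test_single_span_error(self):
        with pytest.raises(ValueError, match="two TRX"):
            split_type2(ProteinRecord("x", "M" * 400), [(50, 200)])

    def test_overlapping_spans_error(self):
        with pytest.raises(ValueError, match="overlap"):
            split_type2(ProteinRecord("x", "M" * 400), [(50, 220), (200, 350)])


class TestExciseGltd:
    def test_length_arithmetic(self):
        rec = ProteinRecord("x", "M" * 600)
        out = excise_gltd(rec, (300, 450))
        assert out.length == 450 and out.id == "x_noGltD"

    def test_terminal_span_error(self):
        with pytest.raises(ValueError, match="internal"):
            excise_gltd(ProteinRecord("x", "M" * 600), (0, 100))

    def test_missing_span_error(self):
        with pytest.raises(ValueError):
            excise_gltd(ProteinRecord("x", "M" * 600), None)

    def test_rescan_no_longer_detects_gltd(self, catalog):
        (rec,), _ = generate_proteins(ProteinSpec("A10", seed=3), catalog)
        arch = resolve_architecture(scan_motifs(rec), rec)
        assert "GltD" in arch.domains
        span = arch.spans[arch.domains.index("GltD")]
        out = excise_gltd(rec, span)
        arch2 = resolve_architecture(scan_motifs(out), out)
        assert "GltD" not in arch2.domains
        # flanking architecture unchanged
        expected = tuple(d for d in arch.domains if d != "GltD")
        assert arch2.domains == expected


class TestTrimColumns:
    def test_conserved_column_kept(self):
        msa = Msa(["a", "b", "c", "d"], ["A", "A", "A", "A"])
        mask, trimmed = trim_columns(msa)
        assert mask == [True] and trimmed.n_cols == 1

    def test_high_entropy_column_removed(self):
        # four distinct residues over four rows: entropy = 2 bits > 1.5
        assert column_entropy("ACDE") == pytest.approx(2.0)
        msa = Msa(["a", "b", "c", "d"], ["A", "C", "D", "E"])
        mask, trimmed = trim_columns(msa)
        assert mask == [False] and trimmed.n_cols == 0

    def test_gappy_column_removed(self):
        # gap fraction 1/4 > 0.2 even though entropy is 0
        msa = Msa(["a", "b", "c", "d"], ["A", "A", "A", "-"])
        mask, _ = trim_columns(msa)
        assert mask == [False]

    def test_all_gap_column_always_removed(self):
        msa = Msa(["a", "b"], ["-A", "-A"])
        mask, _ = trim_columns(msa)
        assert mask == [False, True]

    def test_idempotent(self):
        msa, _ = generate_msa_fixture(8, 40, 20, seed=5)
        _, once = trim_columns(msa)
        mask2, twice = trim_columns(once)
        assert twice == once and all(mask2)

    def test_fixture_core_retained_inserts_removed(self):
        msa, labels = generate_msa_fixture(10, 100, 50, seed=1)
        mask, _ = trim_columns(msa)
        core_kept = sum(1 for m, l in zip(mask, labels) if m and l == "core")
        insert_removed = sum(1 for m, l in zip(mask, labels) if not m and l == "insert")
        assert core_kept >= 90
        assert insert_removed >= 45


class TestSegmentMask:
    def _msa(self):
        return Msa(
            ["ref", "q1"],
            ["ACDEFGHIKL", "ACDEF-HIKL"],
        )

    def test_segment_extraction(self):
        out = extract_segment_mask(self._msa(), SegmentMask("ref", ((0, 3), (7, 9))))
        assert out.rows[0] == "ACDIK"

    def test_reference_gap_columns_excluded(self):
        msa = Msa(["ref", "q1"], ["AC--DE", "ACGGDE"])
        out = extract_segment_mask(msa, SegmentMask("ref", ((0, 4),)))
        assert out.rows[0] == "ACDE" and out.rows[1] == "ACDE"

    def test_gap_free_reference_yields_mask_length(self):
        mask = SegmentMask("ref", ((1, 4), (6, 8)))
        out = extract_segment_mask(self._msa(), mask)
        assert out.n_cols == mask.total_length == 5

    def test_empty_mask_empty_alignment(self):
        out = extract_segment_mask(self._msa(), SegmentMask("ref", ()))
        assert out.n_cols == 0

    def test_missing_reference_error(self):
        with pytest.raises(ValueError, match="absent"):
            extract_segment_mask(self._msa(), SegmentMask("nope", ((0, 2),)))

    def test_invalid_segments(self):
        with pytest.raises(ValueError):
            SegmentMask("ref", ((5, 3),))
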