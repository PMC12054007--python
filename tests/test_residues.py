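"""Global alignment vs an independent recursion oracle; residue calling."""

from functools import lru_cache
from itertools import product

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdrakit.io_formats import ProteinRecord
from hdrakit.residues import (
    ReferenceAnchor,
    ScoringScheme,
    bifurcation_competence,
    call_anchored_residues,
    global_align,
    molybdop_site_check,
)
from hdrakit.synth import generate_molybdop, generate_proteins, ProteinSpec

SIMPLE = ScoringScheme(matrix_name="simple", gap_open=1.0, gap_extend=1.0)


def oracle_best_score(a: str, b: str, s: ScoringScheme) -> float:
    """Independent affine-gap alignment oracle.

    Plain recursion over the scoring definition: the first residue of a
    gap costs gap_open, each further residue gap_extend.  Memoised on the
    (i, j, last-operation) state; shares no code with the aligner.
    """

    def sub(x: str, y: str) -> float:
        if "X" in (x, y):
            return 0.0
        if s.matrix_name == "simple":
            return s.match if x == y else s.mismatch
        from Bio.Align import substitution_matrices

        m = substitution_matrices.load(s.matrix_name)
        cx = "C" if x == "U" else x
        cy = "C" if y == "U" else y
        return float(m[cx, cy])

    NEG = float("-inf")

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, state: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = NEG
        if i < len(a) and j < len(b):
            best = max(best, sub(a[i], b[j]) + rec(i + 1, j + 1, 0))
        if i < len(a):
            pen = s.gap_extend if state == 1 else s.gap_open
            best = max(best, -pen + rec(i + 1, j, 1))
        if j < len(b):
            pen = s.gap_extend if state == 2 else s.gap_open
            best = max(best, -pen + rec(i, j + 1, 2))
        return best

    return rec(0, 0, 0)


class TestGlobalAlign:
    def test_identical_sequences_identity_alignment(self):
        aln = global_align("MKVL", "MKVL", SIMPLE)
        assert aln.aligned_a == aln.aligned_b == "MKVL"
        assert aln.score == 4 * SIMPLE.match
        assert aln.identity == 1.0

    def test_spec_small_example_matches_oracle(self):
        aln = global_align("ACD", "AD", SIMPLE)
        assert aln.score == oracle_best_score("ACD", "AD", SIMPLE)

    def test_empty_sequence_error(self):
        with pytest.raises(ValueError, match="empty"):
            global_align("", "A")

    def test_non_residue_characters_error(self):
        with pytest.raises(ValueError, match="non-residue"):
            global_align("MKB1", "MK")

    def test_exhaustive_short_pairs_match_oracle(self):
        alphabet = "ACGT"
        pairs = [
            (a, b)
            for la in (1, 2, 3)
            for lb in (1, 2, 3)
            for a in map("".join, product(alphabet, repeat=la))
            for b in map("".join, product(alphabet, repeat=lb))
        ]
        for a, b in pairs:
            assert global_align(a, b, SIMPLE).score == pytest.approx(
                oracle_best_score(a, b, SIMPLE)
            ), (a, b)

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(
        st.text(alphabet="ACGT", min_size=1, max_size=8),
        st.text(alphabet="ACGT", min_size=1, max_size=8),
    )
    def test_random_pairs_match_oracle(self, a, b):
        assert global_align(a, b, SIMPLE).score == pytest.approx(
            oracle_best_score(a, b, SIMPLE)
        )

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        st.text(alphabet="ACDEFGHIKLMNPQRSTVWYUX", min_size=1, max_size=8),
        st.text(alphabet="ACDEFGHIKLMNPQRSTVWYUX", min_size=1, max_size=8),
    )
    def test_blosum_scoring_matches_oracle(self, a, b):
        s = ScoringScheme()  # BLOSUM62, open 10, extend 0.5
        assert global_align(a, b, s).score == pytest.approx(oracle_best_score(a, b, s))

    def test_invalid_gap_penalties(self):
        with pytest.raises(ValueError):
            ScoringScheme(gap_open=0.5, gap_extend=1.0)


TOY_REF = "MKVLEDAKRHWFECNQYITS"
TOY_ANCHOR = ReferenceAnchor("toy", TOY_REF, {5: "E", 9: "R"})


class TestCallAnchoredResidues:
    def test_self_alignment_all_match(self, hdra_anchor):
        call = call_anchored_residues(hdra_anchor.ref_seq, hdra_anchor)
        assert call.observed == {409: "K", 356: "E"}
        assert all(call.matches.values())

    def test_substituted_position_reported(self):
        query = TOY_REF[:4] + "A" + TOY_REF[5:]  # E5 -> A
        call = call_anchored_residues(query, TOY_ANCHOR)
        assert call.observed[5] == "A" and call.matches[5] is False
        assert call.matches[9] is True

    def test_nterminal_deletion_does_not_shift_calls(self, hdra_anchor):
        full = call_anchored_residues(hdra_anchor.ref_seq, hdra_anchor)
        trunc = call_anchored_residues(hdra_anchor.ref_seq[10:], hdra_anchor)
        assert trunc.observed == full.observed

    def test_terminal_padding_invariance(self, hdra_anchor):
        padded = "MSTA" * 5 + hdra_anchor.ref_seq + "HHHH"
        call = call_anchored_residues(padded, hdra_anchor)
        assert call.observed == {409: "K", 356: "E"}

    def test_unalignable_below_identity_floor(self):
        anchor = ReferenceAnchor("r", "W" * 50, {10: "W"})
        call = call_anchored_residues("P" * 50, anchor)
        assert call.status == "unalignable"
        assert call.observed[10] is None


class TestBifurcationCompetence:
    def _call(self, k, e, status="ok"):
        from hdrakit.residues import ResidueCall

        return ResidueCall(
            "p",
            {409: "K" if k else "A", 356: "E" if e else "A"},
            {409: k, 356: e},
            status=status,
        )

    @pytest.mark.parametrize(
        "k, e, expected",
        [
            (True, True, "competent"),
            (True, False, "partial"),
            (False, True, "partial"),
            (False, False, "absent"),
        ],
    )
    def test_status_mapping(self, k, e, expected):
        assert bifurcation_competence(self._call(k, e)) == expected

    def test_unalignable_is_unknown(self):
        assert bifurcation_competence(self._call(True, True, "unalignable")) == "unknown"

    def test_monotone_losing_a_residue_never_upgrades(self):
        rank = {"absent": 0, "partial": 1, "competent": 2}
        assert (
            rank[bifurcation_competence(self._call(True, False))]
            <= rank[bifurcation_competence(self._call(True, True))]
        )
        assert (
            rank[bifurcation_competence(self._call(False, False))]
            <= rank[bifurcation_competence(self._call(True, False))]
        )

    def test_planted_and_ablated_flags_recovered(self, hdra_anchor, catalog):
        for k, e, expected in [
            (True, True, "competent"),
            (True, False, "partial"),
            (False, False, "absent"),
        ]:
            recs, _ = generate_proteins(
                ProteinSpec("A1", n=2, plant_K409=k, plant_E356=e, seed=11), catalog
            )
            for r in recs:
                call = call_anchored_residues(r, hdra_anchor)
                assert bifurcation_competence(call) == expected


class TestMolybdopSiteCheck:
    @pytest.mark.parametrize(
        "variant, expected",
        [
            ("catalytic", "catalytic"),
            ("serine", "serine_substituted"),
            ("blocked", "cofactor_blocked"),
        ],
    )
    def test_variant_statuses(self, molybdop_anchor, variant, expected):
        assert molybdop_site_check(generate_molybdop(variant), molybdop_anchor) == expected

    def test_unalignable_is_ambiguous(self, molybdop_anchor):
        assert molybdop_site_check("W" * 120, molybdop_anchor) == "ambiguous"

    def test_anchor_frame_must_carry_cpf(self):
        with pytest.raises(ValueError, match="C, P and F"):
            molybdop_site_check("MKV", ReferenceAnchor("r", "MKV", {1: "M"}))
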