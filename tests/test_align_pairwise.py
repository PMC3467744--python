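"""Pairwise alignment: matrix I/O, global/local affine DP against
brute-force oracles, and the linear-memory anchored aligner."""

import io

import pytest
from Bio.Align import substitution_matrices

from seqforge.errors import AnchorError, FormatError, ScoringError
from seqforge.align import (
    GapPenalty,
    align_global,
    align_global_linear,
    align_local,
    linear_global_score,
    load_matrix,
    read_substitution_matrix,
    score_alignment,
)

from conftest import random_dna
from _oracles import (
    anchored_bruteforce_score,
    brute_local_score,
    dp_global_score,
    exhaustive_global_score,
)


class TestSubstitutionMatrixIO:
    def test_bundled_blosum62_values(self):
        m = load_matrix("blosum62")
        assert m.score("W", "W") == 11
        assert m.score("A", "A") == 4

    @pytest.mark.parametrize("name", ["blosum62", "nuc.4.4"])
    def test_bundled_matrices_match_reference_copies(self, name):
        ours = load_matrix(name)
        ref = substitution_matrices.load(name.upper())
        for a in ours.symbols:
            for b in ours.symbols:
                assert ours.score(a, b) == int(ref[a][b]), (a, b)

    def test_toy_matrix_parses(self):
        text = "# toy\n   A  B\nA  1 -1\nB -1  2\n"
        m = read_substitution_matrix(io.StringIO(text))
        assert m.score("A", "B") == -1 and m.score("B", "B") == 2

    def test_asymmetric_matrix_rejected(self):
        text = "   A  B\nA  1 -1\nB -2  2\n"
        with pytest.raises(FormatError, match="symmetric|asymmetric"):
            read_substitution_matrix(io.StringIO(text))

    def test_missing_symbol_raises_scoring_error(self, unit_matrix, default_gap):
        with pytest.raises(ScoringError, match="'N'"):
            align_global("ACGN", "ACG", unit_matrix, default_gap)


class TestAlignGlobal:
    def test_identical_sequences_align_without_gaps(self, unit_matrix):
        aln = align_global("ACGT", "ACGT", unit_matrix, GapPenalty(-3, -1))
        assert aln.score == 4
        assert aln.rows == ("ACGT", "ACGT")

    def test_empty_against_single_residue(self, unit_matrix):
        aln = align_global("A", "", unit_matrix, GapPenalty(-3, -1))
        assert aln.score == -4
        assert aln.rows == ("A", "-")

    def test_known_gapped_optimum(self, unit_matrix):
        # exhaustive enumeration of all global alignments gives 0
        aln = align_global("ACGT", "AGT", unit_matrix, GapPenalty(-2, -1))
        assert aln.score == 0
        assert exhaustive_global_score(
            "ACGT", "AGT", unit_matrix.score, -2, -1
        ) == 0

    def test_score_matches_explicit_enumeration(self, rng, unit_matrix):
        """Optimal affine score equals the maximum over every explicitly
        enumerated alignment, for random short pairs."""
        for _ in range(150):
            a = random_dna(rng, rng.randint(0, 5))
            b = random_dna(rng, rng.randint(0, 5))
            go, ge = rng.choice([(-2, -1), (-3, -1), (-1, -1)])
            gap = GapPenalty(go, ge)
            got = align_global(a, b, unit_matrix, gap)
            expected = exhaustive_global_score(a, b, unit_matrix.score, go, ge)
            assert got.score == expected, (a, b, go, ge)
            assert score_alignment(*got.rows, unit_matrix, gap) == got.score

    def test_rows_degap_to_inputs_and_score_is_consistent(self, rng, unit_matrix, default_gap):
        for _ in range(50):
            a = random_dna(rng, rng.randint(0, 30))
            b = random_dna(rng, rng.randint(0, 30))
            aln = align_global(a, b, unit_matrix, default_gap)
            assert aln.degap(0) == a and aln.degap(1) == b
            if len(aln):
                assert score_alignment(*aln.rows, unit_matrix, default_gap) == aln.score

    def test_score_symmetry(self, rng, unit_matrix, default_gap):
        for _ in range(30):
            a = random_dna(rng, rng.randint(0, 25))
            b = random_dna(rng, rng.randint(0, 25))
            assert (
                align_global(a, b, unit_matrix, default_gap).score
                == align_global(b, a, unit_matrix, default_gap).score
            )


class TestAlignLocal:
    def test_no_positive_pair_gives_empty_alignment(self, unit_matrix):
        aln = align_local("AAA", "TTT", unit_matrix, GapPenalty(-2, -1))
        assert aln.score == 0 and aln.rows == ("", "")

    def test_substring_match(self, unit_matrix):
        aln = align_local("TACGT", "CG", unit_matrix, GapPenalty(-2, -1))
        assert aln.score == 2
        assert aln.rows == ("CG", "CG")
        assert aln.starts == (2, 0)

    def test_empty_input(self, unit_matrix, default_gap):
        assert align_local("", "ACGT", unit_matrix, default_gap).score == 0

    def test_score_matches_substring_bruteforce(self, rng, unit_matrix):
        for _ in range(120):
            a = random_dna(rng, rng.randint(0, 6))
            b = random_dna(rng, rng.randint(0, 6))
            go, ge = rng.choice([(-2, -1), (-1, -1)])
            got = align_local(a, b, unit_matrix, GapPenalty(go, ge))
            assert got.score == brute_local_score(a, b, unit_matrix.score, go, ge)

    def test_local_dominates_global(self, rng, unit_matrix, default_gap):
        for _ in range(40):
            a = random_dna(rng, rng.randint(1, 20))
            b = random_dna(rng, rng.randint(1, 20))
            g = align_global(a, b, unit_matrix, default_gap).score
            l = align_local(a, b, unit_matrix, default_gap).score
            assert l >= max(0, g)

    def test_rows_are_substrings_at_reported_offsets(self, rng, unit_matrix, default_gap):
        for _ in range(30):
            a = random_dna(rng, rng.randint(0, 25))
            b = random_dna(rng, rng.randint(0, 25))
            aln = align_local(a, b, unit_matrix, default_gap)
            sa, sb = aln.starts
            assert a[sa : sa + len(aln.degap(0))] == aln.degap(0)
            assert b[sb : sb + len(aln.degap(1))] == aln.degap(1)


class TestLinearMemoryAligner:
    def test_matches_quadratic_on_random_pairs(self, rng, unit_matrix):
        for _ in range(60):
            a = random_dna(rng, rng.randint(0, 80))
            b = random_dna(rng, rng.randint(0, 80))
            for go, ge in ((-10, -1), (-2, -1), (-5, -3)):
                gap = GapPenalty(go, ge)
                expected = align_global(a, b, unit_matrix, gap).score
                aln = align_global_linear(a, b, unit_matrix, gap)
                assert aln.score == expected
                assert linear_global_score(a, b, unit_matrix, gap) == expected
                assert aln.degap(0) == a and aln.degap(1) == b

    def test_anchor_on_optimal_path_preserves_score(self, unit_matrix):
        gap = GapPenalty(-3, -1)
        assert (
            align_global_linear("ACGT", "ACGT", unit_matrix, gap, [(0, 0)]).score
            == 4
        )

    def test_anchored_score_matches_bruteforce(self, rng, unit_matrix):
        for _ in range(40):
            a = random_dna(rng, rng.randint(1, 5))
            b = random_dna(rng, rng.randint(1, 5))
            i = rng.randrange(len(a))
            j = rng.randrange(len(b))
            gap = GapPenalty(-2, -1)
            got = align_global_linear(a, b, unit_matrix, gap, [(i, j)])
            expected = anchored_bruteforce_score(
                a, b, [(i, j)], unit_matrix.score, -2, -1
            )
            assert got.score == expected, (a, b, i, j)
            # the anchored column really pairs a[i] with b[j]
            cols = list(zip(got.column_map(0), got.column_map(1)))
            assert (i, j) in cols

    def test_anchored_never_beats_unanchored(self, rng, unit_matrix, default_gap):
        for _ in range(40):
            a = random_dna(rng, rng.randint(2, 30))
            b = random_dna(rng, rng.randint(2, 30))
            i = rng.randrange(len(a))
            j = rng.randrange(len(b))
            free = align_global(a, b, unit_matrix, default_gap).score
            anchored = align_global_linear(
                a, b, unit_matrix, default_gap, [(i, j)]
            ).score
            assert anchored <= free

    def test_crossing_and_out_of_range_anchors_rejected(self, unit_matrix, default_gap):
        with pytest.raises(AnchorError):
            align_global_linear(
                "ACGTACGT", "ACGTACGT", unit_matrix, default_gap, [(3, 3), (4, 2)]
            )
        with pytest.raises(AnchorError):
            align_global_linear("ACG", "ACG", unit_matrix, default_gap, [(3, 0)])


class TestOracleAgreement:
    def test_dp_oracle_agrees_with_enumeration(self, rng, unit_matrix):
        """The fast last-op-state oracle used elsewhere is itself checked
        against explicit enumeration on tiny cases."""
        for _ in range(60):
            a = random_dna(rng, rng.randint(0, 4))
            b = random_dna(rng, rng.randint(0, 4))
            assert dp_global_score(a, b, unit_matrix.score, -2, -1) == (
                exhaustive_global_score(a, b, unit_matrix.score, -2, -1)
            )
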