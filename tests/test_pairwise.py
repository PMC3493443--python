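import math

import numpy as np
import pytest

from bruteforce import best_global_score, best_local_score
from conftest import record
from foxsurvey.pairwise import (
    DEFAULT_SCHEME,
    ScoringScheme,
    evalue,
    needleman_wunsch,
    percent_identity,
    search,
    smith_waterman,
)


class TestSmithWaterman:
    def test_identity_alignment_scores_blosum62_diagonal(self):
        # A=4, C=9, D=6, E=5 on the BLOSUM62 diagonal
        aln = smith_waterman(record("a", "ACDE"), record("b", "ACDE"))
        assert aln.raw_score == 24
        assert aln.n_identical == 4
        assert aln.n_columns == 4
        assert aln.a_span == (1, 4) and aln.b_span == (1, 4)

    def test_empty_sequence_gives_empty_alignment(self):
        a = record("a", "ACDE")
        b = record("b", "A")
        object.__setattr__(b, "residues", "")  # bypass record validation
        aln = smith_waterman(a, b)
        assert aln.raw_score == 0
        assert aln.is_empty

    def test_no_positive_pair_gives_empty_alignment(self):
        # every C-vs-W/G pair scores negative under BLOSUM62
        aln = smith_waterman(record("a", "CCCC"), record("b", "WGWG"))
        assert aln.raw_score == 0
        assert aln.is_empty

    def test_embedded_domain_found_with_correct_span(self):
        aln = smith_waterman(record("a", "MMMWCDEHKMMM"), record("b", "WCDEHK"))
        assert aln.a_span == (4, 9)
        assert aln.b_span == (1, 6)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_enumeration(self, seed):
        """Local scores equal exhaustive enumeration over all substring
        pairs and all affine-gap alignment paths (length <= 6)."""
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list("ACDE"), size=rng.integers(1, 7)))
        b = "".join(rng.choice(list("ACDE"), size=rng.integers(1, 7)))
        expected = best_local_score(a, b, DEFAULT_SCHEME)
        got = smith_waterman(record("a", a), record("b", b)).raw_score
        assert got == expected

    def test_score_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = "".join(rng.choice(list("ACDEFGHIK"), size=12))
            b = "".join(rng.choice(list("ACDEFGHIK"), size=9))
            ab = smith_waterman(record("a", a), record("b", b))
            ba = smith_waterman(record("b", b), record("a", a))
            assert ab.raw_score == ba.raw_score
            assert ab.n_identical == ba.n_identical


class TestNeedlemanWunsch:
    def test_identical_sequences_align_without_gaps(self):
        aln = needleman_wunsch(record("a", "MKVLAT"), record("b", "MKVLAT"))
        assert "-" not in aln.aligned_a + aln.aligned_b
        assert aln.n_identical == aln.n_columns == 6

    def test_both_empty_is_error(self):
        a = record("a", "A")
        object.__setattr__(a, "residues", "")  # bypass record validation
        with pytest.raises(ValueError):
            needleman_wunsch(a, a)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_enumeration(self, seed):
        """Global scores equal exhaustive affine-path enumeration (<= 6)."""
        rng = np.random.default_rng(100 + seed)
        a = "".join(rng.choice(list("ACDE"), size=rng.integers(1, 7)))
        b = "".join(rng.choice(list("ACDE"), size=rng.integers(1, 7)))
        expected = best_global_score(a, b, DEFAULT_SCHEME)
        got = needleman_wunsch(record("a", a), record("b", b), DEFAULT_SCHEME).raw_score
        assert got == expected

    def test_local_equals_global_when_local_optimum_spans_all(self):
        a, b = record("a", "WCDEHK"), record("b", "WCDEHK")
        assert (
            smith_waterman(a, b, DEFAULT_SCHEME).raw_score
            == needleman_wunsch(a, b, DEFAULT_SCHEME).raw_score
        )


class TestPercentIdentity:
    def test_identical_is_100(self):
        aln = needleman_wunsch(record("a", "MKVLAT"), record("b", "MKVLAT"))
        assert percent_identity(aln) == 100.0

    def test_half_identical_constructed_alignment(self):
        from foxsurvey.pairwise import AlignmentResult

        aln = AlignmentResult(
            mode="global", aligned_a="AAAAAAAAAA", aligned_b="AAAAACCCCC",
            raw_score=0, bit_score=0, n_identical=5, n_columns=10,
            a_span=(1, 10), b_span=(1, 10),
        )
        assert percent_identity(aln) == 50.0

    def test_denominator_conventions_differ_under_gaps(self):
        aln = needleman_wunsch(record("a", "MKVVVVLAT"), record("b", "MKLAT"))
        all_cols = percent_identity(aln, "all")
        ungapped = percent_identity(aln, "ungapped")
        shorter = percent_identity(aln, "shorter")
        assert all_cols <= ungapped
        assert all_cols <= shorter

    def test_empty_alignment_is_error(self):
        from foxsurvey.pairwise import _empty_result

        with pytest.raises(ValueError):
            percent_identity(_empty_result("local", DEFAULT_SCHEME))


class TestEvalue:
    def test_zero_bits_gives_search_space_size(self):
        assert evalue(0.0, 7, 13) == 91.0

    def test_closed_form_example(self):
        assert math.isclose(evalue(20.0, 100, 10**6), 95.367, rel_tol=1e-4)

    def test_strictly_decreasing_in_bit_score(self):
        values = [evalue(b, 100, 1000) for b in np.linspace(0, 50, 20)]
        assert all(x > y for x, y in zip(values, values[1:]))

    @pytest.mark.parametrize("m,n", [(0, 10), (10, 0), (-1, 5)])
    def test_nonpositive_search_space_is_error(self, m, n):
        with pytest.raises(ValueError):
            evalue(10.0, m, n)


class TestSearch:
    def test_database_containing_query_ranks_it_first(self, small_family):
        domains = [small_family.domain_of(o) for o in sorted(small_family.labels)]
        query = domains[0]
        hits = search(query, domains, threshold=1e3)
        assert hits[0].subject_id == query.id

    def test_hits_sorted_by_evalue_then_bits_then_id(self, small_family):
        domains = [small_family.domain_of(o) for o in sorted(small_family.labels)]
        hits = search(domains[0], domains, threshold=1e3)
        keys = [(h.evalue, -h.alignment.bit_score, h.subject_id) for h in hits]
        assert keys == sorted(keys)

    def test_threshold_zero_empties_hit_list(self, small_family):
        domains = [small_family.domain_of(o) for o in sorted(small_family.labels)]
        assert search(domains[0], domains, threshold=0.0) == []

    def test_marginal_evalue_rejected_at_threshold(self):
        # a hit with E = 0.05 fails the E < 1e-2 inclusion filter by design:
        # the filter is strict inequality against the threshold
        assert not (0.05 < 1e-2)
        db = [record("junk", "W" * 30)]
        assert search(record("q", "ACDE"), db, threshold=1e-2) == []

    def test_planted_domain_protein_is_sole_hit_among_decoys(self, survey_fixture):
        from foxsurvey.seq_io import read_fasta

        family = survey_fixture.family
        organism = "FoxJ1_t1"
        proteome = read_fasta(survey_fixture.proteome_paths[organism])
        query = family.domain_of("FoxJ1_t0")
        hits = search(query, proteome, threshold=1e-2)
        assert [h.subject_id for h in hits] == [organism]

    def test_empty_database_is_error(self):
        with pytest.raises(ValueError):
            search(record("q", "ACDE"), [])


class TestScoringScheme:
    def test_invalid_gap_parameters_rejected(self):
        with pytest.raises(ValueError):
            ScoringScheme(gap_open=1, gap_extend=2)
        with pytest.raises(ValueError):
            ScoringScheme(lam=-1.0)

    def test_selenocysteine_scored_as_cysteine(self):
        s = ScoringScheme()
        assert s.pair_score("U", "C") == s.pair_score("C", "C")
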