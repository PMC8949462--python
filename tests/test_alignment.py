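"""Alignment kernel, seeding and E-value statistics."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from acaryopan.alignment import (LocalAlignment, ScoringScheme, _align_encoded,
                                 _kmer_index, _kmer_keys, _seed_windows,
                                 bit_score, evalue, iter_local_hits,
                                 raw_for_bits, smith_waterman)

from conftest import random_dna, random_protein

DNA = st.text(alphabet="ACGT", min_size=0, max_size=12)


def brute_force_best_local(a: str, b: str, s: ScoringScheme) -> int:
    """Best affine-gap local alignment score by exhaustive enumeration.

    Enumerates every pair of subsequences expressed as global alignments of
    every substring pair via NW with affine gaps (O(n^2 m^2 * nm)); only
    feasible for very short strings, which is the point of an oracle.
    """
    best = 0
    for qa in range(len(a) + 1):
        for qb in range(qa, len(a) + 1):
            for ta in range(len(b) + 1):
                for tb in range(ta, len(b) + 1):
                    best = max(best, _nw_affine(a[qa:qb], b[ta:tb], s))
    return best


def _nw_affine(x: str, y: str, s: ScoringScheme) -> int:
    """Global affine-gap alignment score (end gaps penalized)."""
    m, n = len(x), len(y)
    if m == 0 and n == 0:
        return 0
    NEG = -10 ** 9
    mat = s.matrix
    enc = s.encode
    xe, ye = enc(x), enc(y)
    H = [[NEG] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    H[0][0] = 0
    for i in range(1, m + 1):
        F[i][0] = s.gap_open + (i - 1) * s.gap_extend
        H[i][0] = F[i][0]
    for j in range(1, n + 1):
        E[0][j] = s.gap_open + (j - 1) * s.gap_extend
        H[0][j] = E[0][j]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] + s.gap_open, E[i][j - 1] + s.gap_extend)
            F[i][j] = max(H[i - 1][j] + s.gap_open, F[i - 1][j] + s.gap_extend)
            diag = H[i - 1][j - 1] + mat[xe[i - 1], ye[j - 1]]
            H[i][j] = max(diag, E[i][j], F[i][j])
    return H[m][n]


class TestSmithWaterman:
    def test_identical_sequences(self, nt_scheme):
        aln = smith_waterman("ACGTACGT", "ACGTACGT", nt_scheme)
        assert aln.score == 16
        assert aln.query_span == (0, 8) and aln.target_span == (0, 8)
        assert aln.pct_identity == 100.0

    def test_empty_sequence(self, nt_scheme):
        assert smith_waterman("", "ACGT", nt_scheme).score == 0
        assert smith_waterman("ACGT", "", nt_scheme).score == 0

    def test_no_positive_alignment(self, nt_scheme):
        assert smith_waterman("AAAA", "TTTT", nt_scheme).score == 0

    def test_gap_cost_convention(self, nt_scheme):
        # 10 matches interrupted by a 2-nt deletion: 20 - (5 + 2) = 13
        q = "AAAACCGGTT"
        t = "AAAACCXXGGTT".replace("X", "T")  # insert 2 target bases
        aln = smith_waterman(q, "AAAACCTTGGTT", nt_scheme)
        assert aln.score == 20 - 7

    def test_brute_force_oracle_nt(self, nt_scheme):
        rng = np.random.default_rng(101)
        for _ in range(40):
            a = random_dna(rng, int(rng.integers(0, 13)))
            b = random_dna(rng, int(rng.integers(0, 13)))
            got = smith_waterman(a, b, nt_scheme).score
            want = brute_force_best_local(a, b, nt_scheme)
            assert got == want, (a, b)

    def test_biopython_oracle_nt(self, nt_scheme):
        from Bio import Align
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = 2
        aligner.mismatch_score = -3
        aligner.open_gap_score = -5
        aligner.extend_gap_score = -2
        rng = np.random.default_rng(5)
        for _ in range(60):
            a = random_dna(rng, int(rng.integers(1, 120)))
            b = random_dna(rng, int(rng.integers(1, 250)))
            assert smith_waterman(a, b, nt_scheme).score == \
                max(aligner.score(a, b), 0)

    def test_biopython_oracle_protein(self, prot_scheme):
        from Bio import Align
        from Bio.Align import substitution_matrices
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
        rng = np.random.default_rng(17)
        for _ in range(40):
            a = random_protein(rng, int(rng.integers(1, 60)))
            b = random_protein(rng, int(rng.integers(1, 120)))
            assert smith_waterman(a, b, prot_scheme).score == \
                max(aligner.score(a, b), 0)

    @given(DNA, DNA)
    def test_symmetry_of_score(self, a, b):
        s = ScoringScheme.nucleotide()
        assert smith_waterman(a, b, s).score == smith_waterman(b, a, s).score

    @given(DNA)
    def test_self_alignment_is_perfect(self, a):
        s = ScoringScheme.nucleotide()
        aln = smith_waterman(a, a, s)
        assert aln.score == 2 * len(a)
        if a:
            assert aln.pct_identity == 100.0

    def test_identity_and_columns_consistent(self, nt_scheme):
        rng = np.random.default_rng(3)
        for _ in range(30):
            a = random_dna(rng, 50)
            b = random_dna(rng, 80)
            aln = smith_waterman(a, b, nt_scheme)
            if aln.score > 0:
                assert 0 < aln.n_identical <= aln.n_columns
                qs, qe = aln.query_span
                ts, te = aln.target_span
                assert aln.n_columns >= max(qe - qs, te - ts)

    def test_banded_equals_full_when_band_covers(self, nt_scheme):
        rng = np.random.default_rng(11)
        for _ in range(25):
            q = nt_scheme.encode(random_dna(rng, 40))
            t = nt_scheme.encode(random_dna(rng, 120))
            full = _align_encoded(q, t, nt_scheme)
            band = _align_encoded(q, t, nt_scheme, -len(q), len(t))
            assert full == band

    def test_band_restricts_offdiagonal_alignment(self, nt_scheme):
        q = nt_scheme.encode("ACGTACGTACGT")
        t = nt_scheme.encode("TTTTTTTTTTTTTTTTTTTTACGTACGTACGT")
        # planted copy starts at diagonal +20; a band around diagonal 0
        # excludes it
        on = _align_encoded(q, t, nt_scheme, 20 - 2, 20 + 2)
        off = _align_encoded(q, t, nt_scheme, -5, 5)
        assert on.score == 24
        assert off.score < 24


class TestKarlinAltschul:
    def test_worked_example(self, prot_scheme):
        # lambda=0.267, K=0.041, m=100, n=10000, S=40
        e = evalue(40, 100, 10000, prot_scheme)
        assert e == pytest.approx(0.041 * 1e6 * math.exp(-0.267 * 40))
        assert e == pytest.approx(0.9430, abs=2e-4)

    def test_evalue_monotonic_in_score(self, nt_scheme):
        es = [evalue(sc, 100, 1000, nt_scheme) for sc in range(10, 60, 5)]
        assert all(a > b for a, b in zip(es, es[1:]))

    def test_evalue_positive_even_for_huge_scores(self, nt_scheme):
        assert evalue(10 ** 6, 10, 10, nt_scheme) > 0

    def test_bit_score_roundtrip(self, nt_scheme):
        raw = 40
        bits = bit_score(raw, nt_scheme)
        assert raw_for_bits(bits, nt_scheme) == raw

    def test_invalid_space(self, nt_scheme):
        with pytest.raises(ValueError):
            evalue(10, 0, 100, nt_scheme)


class TestScoringScheme:
    def test_encode_rejects_bad_chars(self, nt_scheme):
        with pytest.raises(ValueError):
            nt_scheme.encode("ACGU")

    def test_encode_case_insensitive(self, nt_scheme):
        assert np.array_equal(nt_scheme.encode("acgt"), nt_scheme.encode("ACGT"))

    def test_gap_penalties_validated(self):
        with pytest.raises(ValueError):
            ScoringScheme.nucleotide(gap_open=5)

    def test_blosum62_diagonal_positive(self, prot_scheme):
        for i in range(20):
            assert prot_scheme.matrix[i, i] > 0


class TestKmerIndex:
    def test_index_matches_naive(self, nt_scheme):
        rng = np.random.default_rng(2)
        codes = nt_scheme.encode(random_dna(rng, 300))
        k = 5
        idx = _kmer_index(codes, k)
        keys = _kmer_keys(codes, k)
        naive = {}
        for i in range(len(codes) - k + 1):
            naive.setdefault(int(keys[i]), []).append(i)
        assert {k_: list(v) for k_, v in idx.items()} == naive

    def test_keys_injective_for_short_words(self, nt_scheme):
        rng = np.random.default_rng(9)
        codes = nt_scheme.encode(random_dna(rng, 64))
        keys = _kmer_keys(codes, 3)
        words = [codes[i:i + 3].tobytes() for i in range(len(codes) - 2)]
        for i, j in itertools.combinations(range(len(words)), 2):
            assert (keys[i] == keys[j]) == (words[i] == words[j])

    def test_short_sequence_empty_index(self, nt_scheme):
        assert _kmer_index(nt_scheme.encode("ACG"), 11) == {}


class TestSeedingAndHits:
    def test_planted_hit_window_found(self, nt_scheme):
        rng = np.random.default_rng(21)
        gene = random_dna(rng, 150)
        t = random_dna(rng, 2000) + gene + random_dna(rng, 2000)
        q = nt_scheme.encode(gene)
        tc = nt_scheme.encode(t)
        idx = _kmer_index(tc, nt_scheme.word_size)
        wins = _seed_windows(q, tc, idx, nt_scheme, 40)
        assert any(lo <= 2000 and hi >= 2150 for lo, hi, _, _ in wins)

    def test_seeded_hits_equal_exhaustive_on_planted(self, nt_scheme):
        rng = np.random.default_rng(22)
        gene = random_dna(rng, 120)
        t = random_dna(rng, 1500) + gene + random_dna(rng, 1500)
        q = nt_scheme.encode(gene)
        tc = nt_scheme.encode(t)
        exhaustive = iter_local_hits(q, tc, nt_scheme, 60)
        idx = _kmer_index(tc, nt_scheme.word_size)
        seeded = []
        for lo, hi, dlo, dhi in _seed_windows(q, tc, idx, nt_scheme, 60):
            for aln in iter_local_hits(q, tc[lo:hi], nt_scheme, 60,
                                       dlo - lo, dhi - lo):
                ts, te = aln.target_span
                seeded.append(LocalAlignment(aln.score, aln.query_span,
                                             (ts + lo, te + lo),
                                             aln.n_identical, aln.n_columns))
        assert [(a.score, a.target_span) for a in seeded] == \
            [(a.score, a.target_span) for a in exhaustive]

    def test_iter_local_hits_disjoint_and_sorted(self, nt_scheme):
        rng = np.random.default_rng(23)
        gene = random_dna(rng, 100)
        t = gene + random_dna(rng, 400) + gene
        q = nt_scheme.encode(gene)
        hits = iter_local_hits(q, nt_scheme.encode(t), nt_scheme, 100)
        assert len(hits) == 2
        spans = sorted(h.target_span for h in hits)
        assert spans[0][1] <= spans[1][0]  # disjoint
        assert hits[0].score >= hits[1].score  # sorted by score

    def test_min_score_validation(self, nt_scheme):
        with pytest.raises(ValueError):
            iter_local_hits(nt_scheme.encode("ACGT"),
                            nt_scheme.encode("ACGT"), nt_scheme, 0)
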