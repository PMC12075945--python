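"""Affine-gap alignment: enumeration and Biopython oracles, identity
properties, suboptimal local alignments, identity matrices."""

import numpy as np
import pytest
from Bio import Align
from hypothesis import given, settings
from hypothesis import strategies as st

from oracle_helpers import enumerate_global_score, enumerate_local_score
from trirec.io_formats import NucleotideSequence, UsageError
from trirec.pairwise_alignment import (
    ScoringScheme,
    align_global,
    align_local,
    identity_matrix,
)

S = ScoringScheme()


def seq(label, residues):
    return NucleotideSequence(label, residues)


def rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def biopython_aligner(s: ScoringScheme, mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    al.match_score = s.match
    al.mismatch_score = s.mismatch
    al.open_gap_score = -s.gap_open
    al.extend_gap_score = -s.gap_extend
    return al


class TestGlobal:
    def test_identical(self):
        a = align_global(seq("a", "ACGT"), seq("b", "ACGT"), S)
        assert (a.matches, a.columns, a.pct_identity) == (4, 4, 100.0)
        assert a.score == 4 * S.match

    def test_single_substitution(self):
        a = align_global(seq("a", "ACGT"), seq("b", "ACGA"), S)
        assert (a.matches, a.pct_identity) == (3, 75.0)

    def test_empty_rejected(self):
        with pytest.raises(UsageError):
            align_global(seq("a", ""), seq("b", "ACGT"), S)

    @pytest.mark.parametrize("scheme", [
        ScoringScheme(),
        ScoringScheme(match=1, mismatch=-1, gap_open=2, gap_extend=1),
        ScoringScheme(match=3, mismatch=0, gap_open=5, gap_extend=2),
    ])
    def test_score_equals_enumeration_oracle(self, scheme):
        rng = np.random.default_rng(42)
        for _ in range(40):
            a = rand_seq(rng, int(rng.integers(1, 9)))
            b = rand_seq(rng, int(rng.integers(1, 9)))
            got = align_global(seq("a", a), seq("b", b), scheme).score
            want = enumerate_global_score(a, b, scheme.match, scheme.mismatch,
                                          scheme.gap_open, scheme.gap_extend)
            assert got == want, (a, b)

    def test_score_equals_biopython_on_long_pairs(self):
        rng = np.random.default_rng(7)
        al = biopython_aligner(S, "global")
        for _ in range(15):
            a = rand_seq(rng, int(rng.integers(50, 200)))
            b = rand_seq(rng, int(rng.integers(50, 200)))
            assert align_global(seq("a", a), seq("b", b), S).score == \
                al.score(a, b)

    @settings(derandomize=True, max_examples=60)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=40),
           st.text(alphabet="ACGT", min_size=1, max_size=40))
    def test_degapped_rows_reproduce_inputs(self, a, b):
        aln = align_global(seq("a", a), seq("b", b), S)
        assert aln.aligned_a.replace("-", "") == a
        assert aln.aligned_b.replace("-", "") == b
        assert len(aln.aligned_a) == len(aln.aligned_b)
        assert not any(x == y == "-" for x, y in
                       zip(aln.aligned_a, aln.aligned_b))

    def test_n_never_counts_as_match(self):
        aln = align_global(seq("a", "ANNA"), seq("b", "ANNA"), S)
        assert aln.matches == 2

    def test_symmetry_of_identity(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a, b = rand_seq(rng, 30), rand_seq(rng, 33)
            ab = align_global(seq("a", a), seq("b", b), S).pct_identity
            ba = align_global(seq("b", b), seq("a", a), S).pct_identity
            assert ab == pytest.approx(ba)


class TestLocal:
    def test_identical_full_cover(self):
        rng = np.random.default_rng(0)
        s50 = rand_seq(rng, 50)
        (best, *_rest) = align_local(seq("a", s50), seq("b", s50), S,
                                     max_alternatives=1)
        assert best.pct_identity == 100.0
        assert best.aligned_a == s50

    def test_planted_duplication_gives_alternatives(self):
        rng = np.random.default_rng(1)
        motif = rand_seq(rng, 30)
        query = rand_seq(rng, 40) + motif + rand_seq(rng, 50) + motif + \
            rand_seq(rng, 40)
        alts = align_local(seq("q", query), seq("m", motif), S,
                           max_alternatives=20)
        full = [a for a in alts if a.aligned_b.replace("-", "") == motif
                and a.pct_identity == 100.0]
        assert len(full) >= 2

    def test_no_positive_alignment(self):
        assert align_local(seq("a", "AAAA"), seq("b", "TTTT"), S) == []

    def test_score_equals_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            a = rand_seq(rng, int(rng.integers(2, 7)))
            b = rand_seq(rng, int(rng.integers(2, 7)))
            hits = align_local(seq("a", a), seq("b", b), S)
            got = hits[0].score if hits else 0
            assert got == enumerate_local_score(
                a, b, S.match, S.mismatch, S.gap_open, S.gap_extend), (a, b)

    def test_score_equals_biopython_on_long_pairs(self):
        rng = np.random.default_rng(13)
        al = biopython_aligner(S, "local")
        for _ in range(10):
            a, b = rand_seq(rng, 120), rand_seq(rng, 150)
            hits = align_local(seq("a", a), seq("b", b), S)
            got = hits[0].score if hits else 0
            assert got == al.score(a, b)

    def test_aligned_substrings_come_from_inputs(self):
        rng = np.random.default_rng(21)
        a, b = rand_seq(rng, 80), rand_seq(rng, 90)
        for aln in align_local(seq("a", a), seq("b", b), S, max_alternatives=5):
            assert aln.aligned_a.replace("-", "") == \
                a[aln.a_start - 1:aln.a_end]
            assert aln.aligned_b.replace("-", "") == \
                b[aln.b_start - 1:aln.b_end]


class TestIdentityMatrix:
    def test_identical_pair(self):
        m = identity_matrix([seq("a", "ACGTACGT"), seq("b", "ACGTACGT")], "global", S)
        assert np.allclose(m.values, 100.0)

    def test_symmetric_unit_diagonal(self, small_scenario):
        from trirec.genomic_context import extract_region

        regions = []
        for i, t in enumerate(small_scenario.truth["clusters"][:6]):
            r = extract_region(small_scenario.genome_a, t["chrom"],
                               t["span_start"], t["span_end"], t["orientation"])
            r.id = f"r{i}"
            regions.append(r)
        m = identity_matrix(regions, "global", S)
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 100.0)
        assert m.values.min() >= 0 and m.values.max() <= 100

    def test_duplicate_labels_rejected(self):
        with pytest.raises(UsageError):
            identity_matrix([seq("a", "ACGT"), seq("a", "ACGT")], "global", S)

    def test_planted_outlier_argmin(self):
        rng = np.random.default_rng(2)
        base = rand_seq(rng, 120)
        seqs = [seq(f"s{i}", base) for i in range(4)]
        seqs.append(seq("outlier", rand_seq(rng, 120)))
        m = identity_matrix(seqs, "global", S)
        assert "outlier" in m.argmin_pair
        assert m.max_offdiag == 100.0

    def test_mean_identity_matches_mutation_mask_oracle(self):
        """30 sequences mutated from one ancestor at rate 0.05: the matrix
        mean must sit within 2 points of the identity computed directly
        from the planted substitutions (no alignment involved)."""
        rng = np.random.default_rng(8)
        anc = rand_seq(rng, 400)
        seqs = []
        for i in range(30):
            arr = np.array(list(anc))
            mask = rng.random(len(anc)) < 0.05
            bases = np.array(list("ACGT"))
            repl = bases[(np.searchsorted(bases, arr[mask])
                          + rng.integers(1, 4, mask.sum())) % 4]
            arr[mask] = repl
            seqs.append(seq(f"s{i:02d}", "".join(arr)))
        direct = []
        for i in range(30):
            for j in range(i + 1, 30):
                d = sum(x != y for x, y in
                        zip(seqs[i].residues, seqs[j].residues))
                direct.append(100.0 * (400 - d) / 400)
        m = identity_matrix(seqs, "global", S)
        off = m.values[~np.eye(30, dtype=bool)]
        assert abs(off.mean() - np.mean(direct)) < 2.0

    def test_identity_decreases_with_divergence(self):
        rng = np.random.default_rng(12)
        anc = rand_seq(rng, 600)
        means = []
        bases = np.array(list("ACGT"))
        for mu in (0.01, 0.05, 0.1, 0.2):
            seqs = []
            for i in range(6):
                arr = np.array(list(anc))
                idx = np.flatnonzero(rng.random(len(anc)) < mu)
                old = np.searchsorted(bases, arr[idx])
                arr[idx] = bases[(old + rng.integers(1, 4, idx.size)) % 4]
                seqs.append(seq(f"m{i}", "".join(arr)))
            m = identity_matrix(seqs, "global", S)
            means.append(m.values[~np.eye(6, dtype=bool)].mean())
        assert all(x > y for x, y in zip(means, means[1:]))
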