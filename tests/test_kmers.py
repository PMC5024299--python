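"""k-mer counting, the three per-cycle scores, the Markov background and
reverse-complement aggregation."""

import math
import random
from collections import Counter

import numpy as np
import pytest

import selexmer as sx
from selexmer._encoding import code_to_kmer, kmer_to_code, revcomp

from conftest import filtered_from_collection


def naive_count(inserts, k):
    """Brute-force sliding-window oracle."""
    c = Counter()
    for s in inserts:
        for i in range(len(s) - k + 1):
            c[s[i : i + k]] += 1
    return c


class TestCountKmers:
    def test_homopolymer(self):
        t = sx.count_kmers(["AAAAAAAAAAAA"], 6)
        assert t["AAAAAA"] == 7 and t.total_windows == 7
        assert t.counts.sum() == 7

    def test_small_example_matches_oracle(self):
        t = sx.count_kmers(["ACGTACGTACGT"], 6)
        oracle = naive_count(["ACGTACGTACGT"], 6)
        assert t["ACGTAC"] == oracle["ACGTAC"] == 2
        assert t.nonzero_items() == dict(oracle)

    @pytest.mark.parametrize("k", [1, 6, 8, 10, 12])
    def test_random_inserts_match_oracle(self, k):
        rnd = random.Random(100 + k)
        inserts = ["".join(rnd.choice("ACGT") for _ in range(12)) for _ in range(100)]
        t = sx.count_kmers(inserts, k)
        assert t.nonzero_items() == dict(naive_count(inserts, k))
        assert t.total_windows == 100 * (12 - k + 1)

    def test_total_windows_arithmetic(self, design):
        pool = sx.generate_initial_library(design, 1000, rng_seed=2)
        assert sx.count_kmers(pool, 6).total_windows == 7000

    def test_read_multiplicity_weighting(self, design):
        fs = sx.FilteredReadSet(0, design.barcodes[0], 12, Counter({"A" * 12: 3}))
        t = sx.count_kmers(fs, 6)
        assert t["AAAAAA"] == 21 and t.total_windows == 21

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="k"):
            sx.count_kmers(["ACGTACGTACGT"], 13)
        with pytest.raises(ValueError, match="k"):
            sx.count_kmers(["ACGTACGTACGT"], 0)


class TestComputeScores:
    def _tables(self, insert_lists):
        out = []
        for r, inserts in enumerate(insert_lists):
            t = sx.count_kmers(inserts, 6)
            t.round_index = r
            out.append(t)
        return out

    def test_hand_tallied_two_round_fixture(self):
        """Frequencies and ratios equal a by-hand tally on a tiny corpus."""
        r0 = ["AAAAAACACGTG", "ACGTACGTACGT"]
        r1 = ["AAAAAACACGTG", "AAAAAACACGTG", "ACGTACGTACGT"]
        scores = sx.compute_scores(self._tables([r0, r1]))
        # AAAAAA occurs once per AAAAAACACGTG read: 1/14 windows in round 0, 2/21 in round 1
        assert scores[0].score("AAAAAA", "f") == pytest.approx(1 / 14)
        assert scores[1].score("AAAAAA", "f") == pytest.approx(2 / 21)
        assert scores[1].score("AAAAAA", "r") == pytest.approx((2 / 21) / (1 / 14))
        assert scores[1].score("AAAAAA", "r0") == scores[1].score("AAAAAA", "r")
        # CACGTG: once per AAAAAACACGTG read, same tally
        assert scores[1].score("CACGTG", "r") == pytest.approx((2 / 21) / (1 / 14))
        assert np.isnan(scores[0].r).all()

    def test_identical_rounds_have_unit_ratio(self):
        reads = ["ACGTACGTACGT", "CACGTGCACGTG"]
        scores = sx.compute_scores(self._tables([reads, reads]))
        observed = scores[1].f > 0
        assert np.allclose(scores[1].r[observed], 1.0)
        assert np.allclose(scores[1].r0[observed], 1.0)

    def test_frequency_normalization_and_rank_permutation(self, small_run_tables):
        for s in sx.compute_scores(small_run_tables):
            assert s.f.sum() == pytest.approx(1.0, abs=1e-9)
            assert sorted(s.rank) == list(range(1, 4**6 + 1))
            assert (s.f >= 0).all() and (s.r0 >= 0).all()

    def test_rank_ties_break_lexicographically(self):
        scores = sx.compute_scores(self._tables([["ACGTACGTACGT"]]))
        s = scores[0]
        # windows: ACGTAC x2, CGTACG x2, GTACGT x2, TACGTA x1 — the count-2
        # tie resolves lexicographically into ranks 1..3
        top4 = [code_to_kmer(int(c), 6) for c in np.argsort(s.rank)[:4]]
        assert top4 == ["ACGTAC", "CGTACG", "GTACGT", "TACGTA"]
        assert s.score("TACGTA", "rank") == 4

    def test_zero_denominator_pseudocount_flagged(self):
        r0 = ["AAAAAAAAAAAA"]
        r1 = ["AAAAAAAAAAAA", "CACGTGCACGTG"]
        scores = sx.compute_scores(self._tables([r0, r1]))
        code = kmer_to_code("CACGTG")
        assert scores[1].denominator_imputed[code]
        assert not scores[1].denominator_imputed[kmer_to_code("AAAAAA")]
        # denominator = pseudocount 1 / 7 windows
        assert scores[1].score("CACGTG", "r") == pytest.approx((2 / 14) / (1 / 7))
        assert np.isfinite(scores[1].r).all()

    def test_missing_round0_requires_background(self, small_run_tables):
        with pytest.raises(ValueError, match="round 0"):
            sx.compute_scores(small_run_tables[1:])

    def test_background_replaces_round0_denominator(self, design):
        pool = sx.generate_initial_library(design, 3000, rng_seed=4)
        fs = filtered_from_collection(pool)
        bg = sx.fit_markov_background(fs, order=3)
        tables = self._tables([pool.insert_strings(), pool.insert_strings()])
        scores = sx.compute_scores(tables, background=bg)
        probs = bg.all_word_probs(6)
        code = kmer_to_code("CACGTG")
        assert scores[1].r0[code] == pytest.approx(scores[1].f[code] / probs[code])
        assert not scores[1].round0_imputed.any()


class TestMarkovBackground:
    def test_uniform_corpus_estimates_uniform(self, design):
        """On an i.i.d. uniform corpus every 10-mer estimate sits near 4^-10.

        Repeated-context words (e.g. homopolymers) reuse one estimated
        conditional several times, so their sampling error compounds; the
        per-word check uses random words and the global check bounds the
        dispersion of the full estimate vector."""
        pool = sx.generate_initial_library(
            design, 30_000, composition_bias=(0.25,) * 4, rng_seed=8
        )
        bg = sx.fit_markov_background(filtered_from_collection(pool), order=5)
        rnd = random.Random(77)
        for _ in range(20):
            word = "".join(rnd.choice("ACGT") for _ in range(10))
            assert bg.estimate(word) == pytest.approx(4.0**-10, rel=0.5)
        probs = bg.all_word_probs(10)
        assert probs.mean() == pytest.approx(4.0**-10)
        assert probs.std() / probs.mean() < 0.5

    def test_tiny_corpus_matches_hand_computed_chain(self):
        """Order-1 chain on three inserts, checked against count-and-divide by hand."""
        corpus = ["AACCAACCAACC", "ACACACACACAC", "AAAACCCCAAAA"]
        bg = sx.fit_markov_background(corpus, order=1, pseudocount=0.0)
        # 1-mer windows: 36 total; A: 20, C: 16
        assert bg.initial[kmer_to_code("A")] == pytest.approx(20 / 36)
        # transitions out of A (19 total): A->A 9, A->C 10
        assert bg.conditional[kmer_to_code("A"), kmer_to_code("C")] == pytest.approx(10 / 19)
        # estimate("AAC") = p(A) p(A|A) p(C|A)
        assert bg.estimate("AAC") == pytest.approx((20 / 36) * (9 / 19) * (10 / 19))

    def test_total_probability_telescopes_to_one(self, design):
        pool = sx.generate_initial_library(design, 2000, rng_seed=6)
        bg = sx.fit_markov_background(filtered_from_collection(pool), order=5)
        assert bg.all_word_probs(7).sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(bg.conditional.sum(axis=1), 1.0)

    def test_order_bounds(self, design):
        pool = sx.generate_initial_library(design, 10, rng_seed=1)
        fs = filtered_from_collection(pool)
        with pytest.raises(ValueError, match="order"):
            sx.fit_markov_background(fs, order=12)
        with pytest.raises(ValueError, match="order"):
            sx.fit_markov_background(fs, order=0)
        with pytest.raises(ValueError, match="non-empty"):
            sx.fit_markov_background([], order=2)


class TestRevcompAggregation:
    def test_class_count_is_32896(self):
        assert sx.n_revcomp_classes(8) == 32896

    def test_singleton_oligo(self):
        agg = sx.aggregate_kmer_scores({"AAAACACGTGAA": 2.5}, k=8)
        assert agg[sx.canonical_kmer("AAAACACG")] == 2.5

    def test_shared_class_weighted_mean(self):
        """Two oligos (scores 1 and 3) sharing an 8-mer average to 2 at equal counts."""
        shared = "ACGTACGT"
        a, b = shared + "AAAA", "TTTT" + revcomp(shared)  # opposite orientations
        agg = sx.aggregate_kmer_scores({a: 1.0, b: 3.0}, k=8)
        assert agg[sx.canonical_kmer(shared)] == pytest.approx(2.0)

    def test_count_weighting_vs_unique(self):
        oligos = {"ACGTACGTAAAA": 1.0, "ACGTACGTCCCC": 3.0}
        counts = {"ACGTACGTAAAA": 3, "ACGTACGTCCCC": 1}
        cls = sx.canonical_kmer("ACGTACGT")
        weighted = sx.aggregate_kmer_scores(oligos, k=8, counts=counts)
        unique = sx.aggregate_kmer_scores(oligos, k=8, counts=counts, unique=True)
        assert weighted[cls] == pytest.approx(1.5)
        assert unique[cls] == pytest.approx(2.0)

    def test_absent_classes_are_absent(self):
        agg = sx.aggregate_kmer_scores({"A" * 12: 1.0}, k=8)
        assert list(agg) == ["AAAAAAAA"]
        with pytest.raises(ValueError, match="non-empty"):
            sx.aggregate_kmer_scores({}, k=8)
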