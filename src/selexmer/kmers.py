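"""k-mer counting, per-cycle affinity scores and the Markov background.

For each k-mer w and enrichment cycle i three scores are produced from
overlapping forward-strand windows of the retained inserts:

    f_i(w)   frequency of w among all insert windows of cycle i
    r_i(w)   f_i(w) / f_{i-1}(w)       enrichment over the previous cycle
    r_i0(w)  f_i(w) / f_0(w)           enrichment over the unselected library

For long words (k = 10) the round-0 frequencies are too undersampled to
divide by, so they are replaced by an order-m Markov chain estimate fitted
on the round-0 inserts (order 5 by default): the probability of a word is
the probability of its first m bases times the product of conditional
next-base probabilities given the preceding m bases.

Reverse-complement collapsing happens only in the 8-mer aggregation used for
cross-platform comparison; f/r/r0 are strand-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._encoding import (
    code_to_kmer,
    encode_seqs,
    kmer_to_code,
    revcomp,
    revcomp_codes,
    window_codes,
)
from .design import ReadCollection
from .filtering import FilteredReadSet


def _insert_matrix_and_weights(source) -> tuple[np.ndarray, np.ndarray, int]:
    """Normalize a read source to (unique-insert matrix, per-row read counts, round)."""
    round_index = 0
    if isinstance(source, FilteredReadSet):
        round_index = source.round_index
        uniq = sorted(source.inserts)
        weights = np.array([source.inserts[u] for u in uniq], dtype=np.int64)
        mat = encode_seqs(uniq, source.insert_length)
    elif isinstance(source, ReadCollection):
        mat = source.inserts
        weights = np.ones(len(mat), dtype=np.int64)
    else:  # sequence of strings
        seqs = list(source)
        mat = encode_seqs(seqs)
        weights = np.ones(len(mat), dtype=np.int64)
    return mat, weights, round_index


@dataclass
class KmerCountTable:
    """Dense counts of every length-k word over the insert windows of one cycle."""

    k: int
    round_index: int
    counts: np.ndarray  # int64, length 4**k
    total_windows: int

    def __getitem__(self, kmer: str) -> int:
        return int(self.counts[kmer_to_code(kmer)])

    def frequencies(self) -> np.ndarray:
        if self.total_windows == 0:
            return np.zeros_like(self.counts, dtype=np.float64)
        return self.counts / self.total_windows

    def nonzero_items(self) -> dict[str, int]:
        idx = np.nonzero(self.counts)[0]
        return {code_to_kmer(int(c), self.k): int(self.counts[c]) for c in idx}

    def to_frame(self, nonzero_only: bool = False) -> pd.DataFrame:
        codes = np.nonzero(self.counts)[0] if nonzero_only else np.arange(4**self.k)
        return pd.DataFrame(
            {
                "kmer": [code_to_kmer(int(c), self.k) for c in codes],
                "count": self.counts[codes],
            }
        )


def count_kmers(source, k: int, insert_length: int | None = None) -> KmerCountTable:
    """Count all overlapping k-windows on the forward strand of the inserts.

    ``source`` may be a :class:`FilteredReadSet` (read-multiplicity weighted),
    a :class:`ReadCollection`, or a sequence of insert strings. Adapters and
    barcode never enter the counts — only inserts are seen here.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    mat, weights, round_index = _insert_matrix_and_weights(source)
    L = mat.shape[1] if mat.size or mat.shape[1] else (insert_length or 0)
    if mat.shape[0] == 0:
        if insert_length is not None and k > insert_length:
            raise ValueError(f"k={k} exceeds insert length {insert_length}")
        return KmerCountTable(k, round_index, np.zeros(4**k, dtype=np.int64), 0)
    if k > L:
        raise ValueError(f"k={k} exceeds insert length {L}")
    codes = window_codes(mat, k)  # (n, L-k+1)
    n_win = codes.shape[1]
    w = np.repeat(weights, n_win)
    counts = np.bincount(codes.ravel(), weights=w, minlength=4**k)
    counts = np.rint(counts).astype(np.int64)
    total = int(weights.sum()) * n_win
    return KmerCountTable(k, round_index, counts, total)


@dataclass
class MarkovBackground:
    """Order-m conditional word model of the unselected library.

    ``initial`` is the pseudocounted distribution of length-m words over all
    insert windows; ``conditional[c, b]`` is P(next base = b | preceding m
    bases have code c). Both are normalized, so the estimated probabilities
    of all length-L words sum to 1 for any L > m by telescoping.
    """

    order: int
    initial: np.ndarray  # (4**m,)
    conditional: np.ndarray  # (4**m, 4)
    pseudocount: float = 1.0

    def estimate(self, word: str) -> float:
        """Estimated probability of one word of length > order."""
        m = self.order
        if len(word) <= m:
            raise ValueError(f"word length must exceed the model order {m}")
        code = kmer_to_code(word[:m])
        p = float(self.initial[code])
        mask = 4**m
        for c in word[m:]:
            b = kmer_to_code(c)
            p *= float(self.conditional[code, b])
            code = (code * 4 + b) % mask
        return p

    def all_word_probs(self, length: int) -> np.ndarray:
        """Estimated probabilities of all 4**length words (length > order)."""
        m = self.order
        if length <= m:
            raise ValueError(f"length must exceed the model order {m}")
        probs = self.initial.astype(np.float64)
        for ell in range(m, length):
            ctx = np.arange(4**ell, dtype=np.int64) % (4**m)
            probs = (probs[:, None] * self.conditional[ctx]).ravel()
        return probs


def fit_markov_background(
    round0, order: int = 5, pseudocount: float = 1.0
) -> MarkovBackground:
    """Fit the background chain on round-0 inserts.

    Context and extension counts are taken over all overlapping windows;
    ``pseudocount`` (default 1) is added per (context, base) cell and per
    initial word so every conditional is strictly positive.
    """
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    mat, weights, _ = _insert_matrix_and_weights(round0)
    if mat.shape[0] == 0:
        raise ValueError("round0 must be non-empty")
    L = mat.shape[1]
    if order >= L:
        raise ValueError(f"order {order} must be smaller than insert length {L}")
    ext = count_kmers(round0, order + 1).counts.reshape(4**order, 4).astype(np.float64)
    ctx_counts = count_kmers(round0, order).counts.astype(np.float64)
    num = ext + pseudocount
    rowsum = num.sum(axis=1, keepdims=True)
    # a context never observed (possible only at pseudocount 0) gets a
    # uniform conditional so normalization still telescopes
    cond = np.where(rowsum > 0, num / np.where(rowsum > 0, rowsum, 1.0), 0.25)
    initial = (ctx_counts + pseudocount) / (ctx_counts + pseudocount).sum()
    return MarkovBackground(order, initial, cond, pseudocount)


@dataclass
class KmerScoreTable:
    """Per-k-mer scores for one cycle: f, r, r0 and frequency rank.

    ``r`` is NaN for round 0 (no previous cycle). ``denominator_imputed``
    marks k-mers whose previous-round count was zero and was replaced by a
    single pseudocount to keep the ratio finite; ``round0_imputed`` marks the
    same for the round-0 denominator of r0 (always all-False when a Markov
    background supplies round-0 frequencies).
    """

    k: int
    round_index: int
    f: np.ndarray
    r: np.ndarray
    r0: np.ndarray
    rank: np.ndarray  # 1..4**k, ties broken lexicographically
    denominator_imputed: np.ndarray = field(default=None)  # type: ignore[assignment]
    round0_imputed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def score(self, kmer: str, which: str = "r0") -> float:
        arr = {"f": self.f, "r": self.r, "r0": self.r0, "rank": self.rank}[which]
        return float(arr[kmer_to_code(kmer)])

    def top_kmer(self) -> str:
        return code_to_kmer(int(np.argmax(self.f)), self.k)

    def to_frame(self, nonzero_only: bool = False) -> pd.DataFrame:
        codes = np.nonzero(self.f)[0] if nonzero_only else np.arange(4**self.k)
        return pd.DataFrame(
            {
                "kmer": [code_to_kmer(int(c), self.k) for c in codes],
                "f": self.f[codes],
                "r": self.r[codes],
                "r0": self.r0[codes],
                "rank": self.rank[codes],
            }
        )


def _rank_by_frequency(f: np.ndarray) -> np.ndarray:
    # stable argsort on -f keeps ascending code order within ties, i.e.
    # lexicographic tie-breaking
    order = np.argsort(-f, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(1, len(f) + 1)
    return rank


def _denominator(counts: np.ndarray, total: int, pseudocount: float) -> tuple[np.ndarray, np.ndarray]:
    """Frequency denominator with zero counts lifted by ``pseudocount``."""
    imputed = counts == 0
    adj = counts + imputed * pseudocount
    return adj / total, imputed


def compute_scores(
    tables: Sequence[KmerCountTable],
    background: MarkovBackground | None = None,
    zero_pseudocount: float = 1.0,
) -> list[KmerScoreTable]:
    """Turn per-cycle count tables into f / r / r0 score tables.

    ``tables`` must share k and have consecutive round indices starting at 0
    (or at 1 when a ``background`` stands in for the unselected library).
    When a background is given it replaces the round-0 frequencies in every
    r0 denominator, the standard treatment for undersampled long words.
    """
    if not tables:
        raise ValueError("tables must be non-empty")
    k = tables[0].k
    if any(t.k != k for t in tables):
        raise ValueError("all count tables must share the same k")
    rounds = [t.round_index for t in tables]
    first = rounds[0]
    if rounds != list(range(first, first + len(rounds))):
        raise ValueError(f"round indices must be consecutive, got {rounds}")
    if first not in (0, 1) or (first == 1 and background is None):
        raise ValueError("round 0 is required unless a Markov background is supplied")

    if background is not None:
        f0 = background.all_word_probs(k)
        f0_imputed = np.zeros(4**k, dtype=bool)
    else:
        f0, f0_imputed = _denominator(tables[0].counts, tables[0].total_windows, zero_pseudocount)

    out: list[KmerScoreTable] = []
    prev_denom: np.ndarray | None = f0 if first == 1 else None
    prev_imputed: np.ndarray | None = f0_imputed if first == 1 else None
    for t in tables:
        f = t.frequencies()
        if t.round_index == 0:
            r = np.full_like(f, np.nan)
            r_imp = np.zeros(4**k, dtype=bool)
        else:
            r = f / prev_denom
            r_imp = prev_imputed
        r0 = f / f0
        out.append(
            KmerScoreTable(
                k=k,
                round_index=t.round_index,
                f=f,
                r=r,
                r0=r0,
                rank=_rank_by_frequency(f),
                denominator_imputed=r_imp,
                round0_imputed=f0_imputed.copy(),
            )
        )
        prev_denom, prev_imputed = _denominator(t.counts, t.total_windows, zero_pseudocount)
    return out


def canonical_kmer(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return min(kmer.upper(), rc)


def n_revcomp_classes(k: int) -> int:
    """Number of {w, revcomp(w)} classes over all 4**k words (palindromes are singletons)."""
    codes = np.arange(4**k, dtype=np.int64)
    return int((codes <= revcomp_codes(codes, k)).sum())


def aggregate_kmer_scores(
    oligo_scores: Mapping[str, float],
    k: int = 8,
    counts: Mapping[str, int] | None = None,
    unique: bool = False,
) -> dict[str, float]:
    """Average per-oligo scores over the k-mer classes the oligos contain.

    Every k-mer is identified with its reverse complement; a class's score
    is the count-weighted mean score of all retained oligo inserts containing
    either orientation (each insert contributes once per class it contains,
    however many windows match). ``counts`` gives read multiplicities
    (default 1 per insert); ``unique=True`` forces unweighted averaging over
    unique inserts. Classes contained in no oligo are absent from the result.
    """
    if not oligo_scores:
        raise ValueError("oligo_scores must be non-empty")
    acc: dict[str, float] = {}
    wt: dict[str, float] = {}
    for insert, score in oligo_scores.items():
        w = 1.0 if unique or counts is None else float(counts.get(insert, 1))
        if w <= 0:
            continue
        classes = {
            canonical_kmer(insert[i : i + k]) for i in range(len(insert) - k + 1)
        }
        for cls in classes:
            acc[cls] = acc.get(cls, 0.0) + w * score
            wt[cls] = wt.get(cls, 0.0) + w
    return {cls: acc[cls] / wt[cls] for cls in acc}
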