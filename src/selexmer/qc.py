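"""Library-uniformity QC: Kullback-Leibler divergence from uniform.

A fresh random-insert library should use all 4^k words of a given length
about equally. The QC score is the KL divergence (in bits) of the observed
k-mer frequencies from the uniform distribution, divided by k so the score
is per position: 0 for a perfectly uniform library, 2 for the degenerate
library concentrated on a single k-mer (the per-position maximum, since a
point mass attains KL = log2(4^k) = 2k bits).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kmers import KmerCountTable


@dataclass(frozen=True)
class KLDReport:
    label: str
    k: int
    kld: float
    n_windows: int


def kld_score(freqs, k: int | None = None, per_position: bool = True) -> float:
    """KL divergence of ``freqs`` from uniform, in bits (per position by default).

    ``freqs`` is a length-4^k vector of k-mer frequencies (dict keyed by
    k-mer also accepted, missing words at 0). Computes
    (1/k) * sum_w f(w) * log2(f(w) * 4^k) with 0*log(0) = 0; set
    ``per_position=False`` for the raw divergence in bits.
    """
    if isinstance(freqs, dict):
        if k is None:
            k = len(next(iter(freqs)))
        vec = np.zeros(4**k)
        from ._encoding import kmer_to_code

        for kmer, f in freqs.items():
            vec[kmer_to_code(kmer)] = f
        freqs = vec
    f = np.asarray(freqs, dtype=np.float64)
    if k is None:
        k = round(np.log2(len(f)) / 2)
    if len(f) != 4**k:
        raise ValueError(f"expected 4^{k} = {4**k} frequencies, got {len(f)}")
    if (f < 0).any():
        raise ValueError("frequencies must be non-negative")
    total = f.sum()
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"frequencies must sum to 1 within 1e-9, observed sum {total!r}")
    nz = f > 0
    kld = float(np.sum(f[nz] * np.log2(f[nz] * 4**k)))
    if -1e-9 < kld < 0:  # rounding in near-uniform inputs
        kld = 0.0
    return kld / k if per_position else kld


def kld_report(counts: KmerCountTable, label: str = "") -> KLDReport:
    """QC one cycle's count table (normally round 0)."""
    if counts.total_windows == 0:
        raise ValueError("count table has no windows to score")
    return KLDReport(label, counts.k, kld_score(counts.frequencies(), counts.k), counts.total_windows)
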