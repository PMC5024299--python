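"""Seed-anchored position weight matrices from k-mer counts.

The PWM summarizes the affinity landscape around its strongest site: the
top-ranking k-mer of the last cycle is the seed, every k-mer within Hamming
distance 1 of it that occurs in the data is collected and aligned (no gaps
— all neighbours share the seed's frame), per-column base counts are
accumulated and normalized to probabilities. At most 1 + 3k words can
contribute. Forward-strand counts only, matching the scoring convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._encoding import BASES, encode_seq, kmer_to_code
from .kmers import KmerCountTable, KmerScoreTable


class EmptyNeighborhoodError(ValueError):
    """Neither the seed nor any single-mismatch neighbour occurs in the data."""


@dataclass
class PWM:
    seed: str
    matrix: np.ndarray  # (L, 4) probabilities, columns indexed A,C,G,T
    round_index: int = -1

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def consensus(self) -> str:
        """Per-column argmax string (ties to the alphabetically first base)."""
        return "".join(BASES[int(i)] for i in self.matrix.argmax(axis=1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=list(BASES)).rename_axis("position")


def pick_seed(scores: KmerScoreTable) -> str:
    """The k-mer with maximal frequency; ties go to the lexicographic smallest."""
    # argmax returns the first maximal index == smallest code == lexicographic min
    return scores.top_kmer()


def hamming_neighbors(seed: str) -> list[str]:
    """The seed plus its 3k single-mismatch variants."""
    out = [seed]
    for i, orig in enumerate(seed):
        for b in BASES:
            if b != orig:
                out.append(seed[:i] + b + seed[i + 1 :])
    return out


def pwm_from_seed(
    counts: KmerCountTable, seed: str, weighted: bool = True
) -> PWM:
    """Build a PWM from the seed's Hamming-distance-<=1 neighbourhood.

    Contributions are weighted by observed counts (``weighted=False`` uses
    presence/absence instead). Raises :class:`EmptyNeighborhoodError` when
    no neighbourhood member occurs in the data.
    """
    seed = seed.upper()
    if len(seed) != counts.k:
        raise ValueError(f"seed length {len(seed)} != count table k={counts.k}")
    encode_seq(seed)
    L = len(seed)
    matrix = np.zeros((L, 4), dtype=np.float64)
    n_contributing = 0
    for neighbor in hamming_neighbors(seed):
        c = counts.counts[kmer_to_code(neighbor)]
        if c <= 0:
            continue
        n_contributing += 1
        w = float(c) if weighted else 1.0
        for j, base in enumerate(neighbor):
            matrix[j, BASES.index(base)] += w
    if n_contributing == 0:
        raise EmptyNeighborhoodError(
            f"seed {seed} and all {3 * L} single-mismatch neighbours are absent from the data"
        )
    matrix /= matrix.sum(axis=1, keepdims=True)
    return PWM(seed=seed, matrix=matrix, round_index=counts.round_index)


def write_meme(pwms, path, background=None) -> Path:
    """Write PWMs in MEME minimal motif format."""
    if isinstance(pwms, PWM):
        pwms = [pwms]
    bg = background if background is not None else [0.25] * 4
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: +\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A %.5f C %.5f G %.5f T %.5f\n\n" % tuple(bg))
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.seed}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.length} nsites= 20 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" %.6f %.6f %.6f %.6f\n" % tuple(row))
            fh.write("\n")
    return path


def write_tabular(pwm: PWM, path) -> Path:
    path = Path(path)
    pwm.to_frame().to_csv(path, sep="\t", float_format="%.6f")
    return path
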