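"""Multi-round SELEX enrichment simulator.

A synthetic transcription factor is modelled as a consensus site with a
per-mismatch multiplicative affinity penalty: a window w of length k_c has
affinity a(w) = lambda^(-HammingDistance(w, consensus)) and an oligo binds
with the affinity of its best insert window. One selection round samples
reads multinomially with probability proportional to pool frequency times
oligo affinity, collapsing capture, amplification and sequencing into a
single sampling step. Round 0 is the unselected library, drawn i.i.d. from
a per-base composition vector (slightly skewed by default, as real oligo
syntheses are).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._encoding import encode_seq
from .design import OligoDesign, ReadCollection

#: Mild A/G-rich synthesis skew so the simulated round-0 library has a small
#: but nonzero divergence from uniform, like real libraries. Order: A, C, G, T.
DEFAULT_COMPOSITION_BIAS = (0.27, 0.23, 0.27, 0.23)


@dataclass(frozen=True)
class BindingModel:
    """Mismatch-penalty affinity model for a synthetic TF.

    ``mismatch_factor`` (lambda) is the multiplicative affinity loss per
    mismatching base; the consensus has affinity 1 and every window affinity
    lies in (0, 1]. ``math.inf`` is accepted and gives all-or-none binding.
    """

    consensus: str
    mismatch_factor: float = 5.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "consensus", self.consensus.upper())
        encode_seq(self.consensus)  # validates alphabet
        if not self.mismatch_factor > 1:
            raise ValueError(f"mismatch_factor must be > 1, got {self.mismatch_factor}")

    @property
    def k(self) -> int:
        return len(self.consensus)

    def window_affinity(self, window: str) -> float:
        """a(w) = lambda^(-Hamming distance to consensus)."""
        if len(window) != self.k:
            raise ValueError(f"window length {len(window)} != consensus length {self.k}")
        d = sum(a != b for a, b in zip(window.upper(), self.consensus))
        return float(self.mismatch_factor ** -d)

    def oligo_affinities(self, inserts: np.ndarray) -> np.ndarray:
        """Best-window affinity A(s) for each row of an encoded insert matrix."""
        if inserts.shape[1] < self.k:
            raise ValueError(
                f"consensus length {self.k} exceeds insert length {inserts.shape[1]}"
            )
        cons = encode_seq(self.consensus)
        win = np.lib.stride_tricks.sliding_window_view(inserts, self.k, axis=1)
        mismatches = (win != cons).sum(axis=2)
        min_d = mismatches.min(axis=1)
        return np.asarray(self.mismatch_factor, dtype=np.float64) ** -min_d

    def affinity(self, insert: str) -> float:
        """A(s): best-window affinity of a single insert string."""
        mat = encode_seq(insert)[None, :]
        return float(self.oligo_affinities(mat)[0])


def _validate_bias(composition_bias) -> np.ndarray:
    bias = np.asarray(composition_bias, dtype=np.float64)
    if bias.shape != (4,):
        raise ValueError(f"composition_bias must have 4 entries (A,C,G,T), got shape {bias.shape}")
    if (bias < 0).any():
        raise ValueError("composition_bias entries must be non-negative")
    if abs(bias.sum() - 1.0) > 1e-9:
        raise ValueError(f"composition_bias must sum to 1 within 1e-9, got {bias.sum()!r}")
    return bias


def generate_initial_library(
    design: OligoDesign,
    n_reads: int,
    composition_bias=DEFAULT_COMPOSITION_BIAS,
    rng_seed: int = 0,
    barcode: str | None = None,
) -> ReadCollection:
    """Draw the unselected round-0 library.

    Insert bases are i.i.d. from ``composition_bias`` (A, C, G, T order);
    every read carries the full template with the given barcode.
    """
    if n_reads < 0:
        raise ValueError(f"n_reads must be non-negative, got {n_reads}")
    bias = _validate_bias(composition_bias)
    bc = design.barcodes[0] if barcode is None else barcode.upper()
    if bc not in design.barcodes:
        raise ValueError(f"barcode {bc!r} is not one of the design barcodes")
    rng = np.random.default_rng(rng_seed)
    inserts = rng.choice(4, size=(n_reads, design.insert_length), p=bias).astype(np.uint8)
    idx = np.full(n_reads, design.barcodes.index(bc), dtype=np.int64)
    return ReadCollection(design, inserts, idx)


def simulate_selection_round(
    pool: ReadCollection,
    model: BindingModel,
    n_reads: int,
    rng_seed: int = 0,
) -> ReadCollection:
    """One capture + amplification + sequencing cycle.

    Each output read is drawn with replacement from the pool with probability
    proportional to (pool frequency x best-window affinity); sequences never
    enter that were absent from the pool.
    """
    if len(pool) == 0:
        raise ValueError("pool must be non-empty")
    if n_reads < 0:
        raise ValueError(f"n_reads must be non-negative, got {n_reads}")
    if model.k > pool.design.insert_length:
        raise ValueError(
            f"consensus length {model.k} exceeds insert length {pool.design.insert_length}"
        )
    aff = model.oligo_affinities(pool.inserts)
    total = aff.sum()
    if not total > 0:
        raise ValueError("all pool affinities are zero; nothing can be selected")
    rng = np.random.default_rng(rng_seed)
    counts = rng.multinomial(n_reads, aff / total)
    picked = np.repeat(np.arange(len(pool)), counts)
    return ReadCollection(pool.design, pool.inserts[picked], pool.barcode_index[picked])


@dataclass
class SimulatedRoundSet:
    """Rounds 0..R of one simulated enrichment experiment."""

    design: OligoDesign
    rounds: list[ReadCollection]
    reads_per_round: int
    rng_seed: int
    composition_bias: tuple[float, ...] = DEFAULT_COMPOSITION_BIAS
    model: BindingModel | None = None

    def __post_init__(self) -> None:
        if not self.rounds:
            raise ValueError("rounds must be non-empty")


def simulate_rounds(
    design: OligoDesign,
    model: BindingModel,
    n_rounds: int,
    reads_per_round: int,
    composition_bias=DEFAULT_COMPOSITION_BIAS,
    rng_seed: int = 0,
    barcode: str | None = None,
) -> SimulatedRoundSet:
    """Round 0 plus ``n_rounds`` selection cycles, each re-seeded deterministically."""
    if n_rounds < 0:
        raise ValueError(f"n_rounds must be non-negative, got {n_rounds}")
    seeds = np.random.SeedSequence(rng_seed).generate_state(n_rounds + 1)
    pool = generate_initial_library(
        design, reads_per_round, composition_bias, rng_seed=int(seeds[0]), barcode=barcode
    )
    rounds = [pool]
    for i in range(n_rounds):
        pool = simulate_selection_round(pool, model, reads_per_round, rng_seed=int(seeds[i + 1]))
        rounds.append(pool)
    return SimulatedRoundSet(
        design, rounds, reads_per_round, rng_seed, tuple(np.asarray(composition_bias)), model
    )


def write_fastq(rounds: SimulatedRoundSet, path_prefix) -> list[Path]:
    """Write one FASTQ per round (``<prefix>_round<i>.fastq``).

    Quality is a constant dummy line (Sanger 'I' = Q40); read IDs encode the
    round and serial number so reads stay traceable to their cycle.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = []
    for r, coll in enumerate(rounds.rounds):
        path = prefix.parent / f"{prefix.name}_round{r}.fastq"
        qual = "I" * rounds.design.total_length
        with open(path, "w") as fh:
            for i, seq in enumerate(coll.sequences()):
                fh.write(f"@sim_round{r}_read{i}\n{seq}\n+\n{qual}\n")
        paths.append(path)
    return paths


def consensus_frequency(pool: ReadCollection, consensus: str) -> float:
    """Fraction of reads whose insert contains ``consensus`` exactly."""
    if len(pool) == 0:
        return 0.0
    cons = encode_seq(consensus)
    win = np.lib.stride_tricks.sliding_window_view(pool.inserts, len(cons), axis=1)
    has = ((win == cons).all(axis=2)).any(axis=1)
    return float(has.mean())
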