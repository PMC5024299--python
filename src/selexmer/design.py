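"""The five-segment oligomer template and in-memory read collections.

Each library oligo is adapter A (with the sequencing 'key' at its 3' end),
a library-identifying barcode, a random insert exposed to the transcription
factor, and the trP1 adapter:

    [ adapter A + key | barcode | random insert | trP1 ]

Only the insert varies between molecules; the flanks are fixed per library.
The default geometry (30 + 6 + 12 + 23 nt) yields a 71-nt template with a
12-nt random insert.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from ._encoding import decode, encode_seqs, is_dna

# Ion Torrent A (incl. key) and trP1 adapters, the platform defaults for
# this template geometry.
DEFAULT_ADAPTER_A = "CCATCTCATCCCTGCGTGTCTCCGACTCAG"
DEFAULT_ADAPTER_TRP1 = "CCTCTCTATGGGCAGTCGGTGAT"
DEFAULT_BARCODES = ("CGTGAT", "ACATCG")


@dataclass(frozen=True)
class OligoDesign:
    """Template geometry of a SELEX oligomer library.

    Parameters
    ----------
    adapter_a : 5' adapter, key included at its 3' end.
    barcodes : one barcode per sub-library; equal length, pairwise distinct.
    insert_length : length of the random insert in nt.
    adapter_trp1 : 3' adapter.
    """

    adapter_a: str = DEFAULT_ADAPTER_A
    barcodes: tuple[str, ...] = DEFAULT_BARCODES
    insert_length: int = 12
    adapter_trp1: str = DEFAULT_ADAPTER_TRP1

    def __post_init__(self) -> None:
        object.__setattr__(self, "barcodes", tuple(b.upper() for b in self.barcodes))
        object.__setattr__(self, "adapter_a", self.adapter_a.upper())
        object.__setattr__(self, "adapter_trp1", self.adapter_trp1.upper())
        if not is_dna(self.adapter_a):
            raise ValueError("adapter_a must be a non-empty A/C/G/T string")
        if not is_dna(self.adapter_trp1):
            raise ValueError("adapter_trp1 must be a non-empty A/C/G/T string")
        if not self.barcodes:
            raise ValueError("barcodes: at least one barcode is required")
        for b in self.barcodes:
            if not is_dna(b):
                raise ValueError(f"barcodes: {b!r} is not an A/C/G/T string")
        lengths = {len(b) for b in self.barcodes}
        if len(lengths) != 1:
            raise ValueError(f"barcodes must share one length, got lengths {sorted(lengths)}")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcodes must be pairwise distinct")
        if self.insert_length <= 0:
            raise ValueError(f"insert_length must be positive, got {self.insert_length}")

    @property
    def barcode_length(self) -> int:
        return len(self.barcodes[0])

    @property
    def insert_start(self) -> int:
        """0-based position of the first insert base in a full read."""
        return len(self.adapter_a) + self.barcode_length

    @property
    def total_length(self) -> int:
        return len(self.adapter_a) + self.barcode_length + self.insert_length + len(self.adapter_trp1)

    def assemble(self, barcode: str, insert: str) -> str:
        """Full template sequence for one molecule."""
        return f"{self.adapter_a}{barcode}{insert}{self.adapter_trp1}"


@dataclass
class ReadCollection:
    """Reads of one library round, stored as encoded inserts.

    The fixed flanks are implied by ``design``; ``barcode_index`` gives each
    read's barcode (index into ``design.barcodes``).
    """

    design: OligoDesign
    inserts: np.ndarray  # (n, insert_length) uint8
    barcode_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.inserts = np.asarray(self.inserts, dtype=np.uint8)
        if self.inserts.ndim != 2 or self.inserts.shape[1] != self.design.insert_length:
            raise ValueError(
                f"inserts must be (n, {self.design.insert_length}), got {self.inserts.shape}"
            )
        if self.barcode_index is None:
            self.barcode_index = np.zeros(len(self.inserts), dtype=np.int64)
        self.barcode_index = np.asarray(self.barcode_index, dtype=np.int64)
        if len(self.barcode_index) != len(self.inserts):
            raise ValueError("barcode_index length must match number of reads")

    def __len__(self) -> int:
        return len(self.inserts)

    def insert_strings(self) -> list[str]:
        return [decode(row) for row in self.inserts]

    def sequences(self) -> Iterator[str]:
        """Full 71-nt (by default) template sequences, in order."""
        for bc_idx, row in zip(self.barcode_index, self.inserts):
            yield self.design.assemble(self.design.barcodes[int(bc_idx)], decode(row))

    @classmethod
    def from_inserts(
        cls, design: OligoDesign, inserts: Sequence[str], barcode: str | None = None
    ) -> "ReadCollection":
        bc = design.barcodes[0] if barcode is None else barcode.upper()
        if bc not in design.barcodes:
            raise ValueError(f"barcode {bc!r} is not one of the design barcodes")
        idx = design.barcodes.index(bc)
        mat = encode_seqs(inserts, design.insert_length)
        return cls(design, mat, np.full(len(mat), idx, dtype=np.int64))
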