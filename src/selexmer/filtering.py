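"""FASTQ ingestion, barcode demultiplexing and read filtering.

Reads are screened in a fixed order — missing barcode, ambiguous base 'N',
wrong total length — and each read is charged to the first filter it fails,
so the category counts always partition the input. Retained reads contribute
the ``insert_length`` bases immediately following the barcode. The barcode
is matched at its fixed template position (immediately after adapter A);
exact match by default, with an optional mismatch allowance. Quality scores
are parsed but never used for filtering.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

from .design import OligoDesign


@dataclass
class FilteredReadSet:
    """Retained inserts plus filter accounting for one (round, barcode) set."""

    round_index: int
    barcode: str
    insert_length: int
    inserts: Counter = dc_field(default_factory=Counter)
    n_input: int = 0
    n_no_barcode: int = 0
    n_has_n: int = 0
    n_wrong_length: int = 0
    n_malformed: int = 0

    @property
    def n_retained(self) -> int:
        return sum(self.inserts.values())

    def check_partition(self) -> bool:
        return (
            self.n_input
            == self.n_no_barcode + self.n_has_n + self.n_wrong_length
            + self.n_malformed + self.n_retained
        )

    def insert_list(self) -> list[str]:
        """Retained inserts expanded to one entry per read (multiset order: lexicographic)."""
        out: list[str] = []
        for ins in sorted(self.inserts):
            out.extend([ins] * self.inserts[ins])
        return out


@dataclass
class DemuxResult:
    """Per-barcode filtered sets plus reads no barcode (or several) claimed."""

    by_barcode: dict[str, FilteredReadSet]
    n_input: int = 0
    n_no_barcode: int = 0
    n_ambiguous: int = 0
    n_malformed: int = 0


def read_fastq(path) -> Iterator[str]:
    """Yield read sequences (uppercase) from a FASTQ file, gzip-aware."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield str(rec.seq).upper()


def _as_sequences(records) -> Iterator[str]:
    if isinstance(records, (str, Path)):
        yield from read_fastq(records)
        return
    for rec in records:
        if isinstance(rec, str):
            yield rec.upper()
        else:  # Bio.SeqRecord
            yield str(rec.seq).upper()


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _match_barcodes(
    seq: str, design: OligoDesign, barcodes: tuple[str, ...], mismatches: int
) -> list[str]:
    start = len(design.adapter_a)
    end = start + design.barcode_length
    if len(seq) < end:
        return []
    observed = seq[start:end]
    if mismatches == 0:
        return [observed] if observed in barcodes else []
    return [bc for bc in barcodes if _hamming(observed, bc) <= mismatches]


def _classify(
    seq: str, design: OligoDesign, fs: FilteredReadSet
) -> None:
    """Apply the N and length filters and record the insert. Barcode already matched."""
    if "N" in seq:
        fs.n_has_n += 1
    elif len(seq) != design.total_length:
        fs.n_wrong_length += 1
    else:
        start = design.insert_start
        insert = seq[start : start + design.insert_length]
        if set(insert) <= set("ACGT"):
            fs.inserts[insert] += 1
        else:
            fs.n_malformed += 1


def filter_reads(
    records,
    design: OligoDesign,
    barcode: str,
    round_index: int = 0,
    barcode_mismatches: int = 0,
) -> FilteredReadSet:
    """Filter one round's reads for a single barcode.

    ``records`` may be a FASTQ path, an iterable of sequence strings, or an
    iterable of Biopython ``SeqRecord`` objects.
    """
    barcode = barcode.upper()
    if barcode not in design.barcodes:
        raise ValueError(f"barcode {barcode!r} is not one of the design barcodes")
    fs = FilteredReadSet(round_index, barcode, design.insert_length)
    for seq in _as_sequences(records):
        fs.n_input += 1
        matched = _match_barcodes(seq, design, (barcode,), barcode_mismatches)
        if not matched:
            fs.n_no_barcode += 1
            continue
        _classify(seq, design, fs)
    return fs


def demultiplex(
    records,
    design: OligoDesign,
    round_index: int = 0,
    barcode_mismatches: int = 0,
) -> DemuxResult:
    """Assign each read to at most one barcode and filter per sub-library.

    A read whose barcode position matches several design barcodes (possible
    only with ``barcode_mismatches > 0``) is counted as ambiguous and
    excluded from every sub-library.
    """
    result = DemuxResult(
        by_barcode={
            bc: FilteredReadSet(round_index, bc, design.insert_length)
            for bc in design.barcodes
        }
    )
    for seq in _as_sequences(records):
        result.n_input += 1
        matched = _match_barcodes(seq, design, design.barcodes, barcode_mismatches)
        if not matched:
            result.n_no_barcode += 1
        elif len(matched) > 1:
            result.n_ambiguous += 1
        else:
            fs = result.by_barcode[matched[0]]
            fs.n_input += 1
            _classify(seq, design, fs)
    return result


def filter_report(sets: Iterable[FilteredReadSet]) -> pd.DataFrame:
    """Tabular per-(round, barcode) filter accounting."""
    rows = []
    for fs in sets:
        rows.append(
            {
                "round": fs.round_index,
                "barcode": fs.barcode,
                "n_input": fs.n_input,
                "n_no_barcode": fs.n_no_barcode,
                "n_has_N": fs.n_has_n,
                "n_wrong_length": fs.n_wrong_length,
                "n_malformed": fs.n_malformed,
                "n_retained": fs.n_retained,
            }
        )
    return pd.DataFrame(rows)
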