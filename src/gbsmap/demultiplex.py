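"""Barcode demultiplexing and read standardisation.

Raw GBS reads carry an inline sample barcode (4-8 nt) immediately followed by
the PstI overhang TGCAG.  A read is assigned to a sample iff a barcode
matches its 5' end exactly, the overhang follows, and the barcode-stripped
read contains no undetermined base.  Assigned reads are quality-trimmed from
the 3' end (trailing bases below Phred 20 removed) and standardised to 64 bp;
anything shorter is discarded.  Rejected reads are classified so that every
input read lands in exactly one output class.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import ConfigurationError

OVERHANG = "TGCAG"

REJECT_NO_BARCODE = "no-barcode"
REJECT_BAD_OVERHANG = "bad-overhang"
REJECT_CONTAINS_N = "contains-N"
REJECT_TOO_SHORT = "too-short"
REJECT_REASONS = (
    REJECT_NO_BARCODE,
    REJECT_BAD_OVERHANG,
    REJECT_CONTAINS_N,
    REJECT_TOO_SHORT,
)


class BarcodeSet:
    """Validated sample barcodes with longest-match-first assignment.

    The loader rejects sets where one ``barcode + TGCAG`` string is a prefix
    of another, which is the exact condition under which longest-match
    assignment could be ambiguous.
    """

    def __init__(self, entries: Sequence[tuple[str, str]], overhang: str = OVERHANG):
        if not entries:
            raise ConfigurationError("barcode set is empty")
        self.overhang = overhang
        self.entries = [(s, b.upper()) for s, b in entries]
        barcodes = [b for _, b in self.entries]
        if len(set(barcodes)) != len(barcodes):
            raise ConfigurationError("barcodes are not unique")
        samples = [s for s, _ in self.entries]
        if len(set(samples)) != len(samples):
            raise ConfigurationError("sample ids are not unique")
        for _, b in self.entries:
            if not (4 <= len(b) <= 8):
                raise ConfigurationError(f"barcode {b} outside 4-8 nt")
            if set(b) - set("ACGT"):
                raise ConfigurationError(f"barcode {b} contains non-ACGT characters")
        keyed = sorted(b + overhang for b in barcodes)
        for a, b in zip(keyed, keyed[1:]):
            if b.startswith(a):
                raise ConfigurationError(
                    f"ambiguous barcode design: {a} is a prefix of {b}"
                )
        self._by_length: list[tuple[int, dict[str, str]]] = []
        lengths = sorted({len(b) for b in barcodes}, reverse=True)
        for L in lengths:
            table = {b: s for s, b in self.entries if len(b) == L}
            self._by_length.append((L, table))
        # joint barcode+overhang keys: prefix-free by the validation above,
        # so matching on them is unambiguous even for nested barcodes
        self._keyed: list[tuple[int, dict[str, tuple[str, str]]]] = []
        for L in lengths:
            table = {
                b + overhang: (s, b) for s, b in self.entries if len(b) == L
            }
            self._keyed.append((L + len(overhang), table))

    def __len__(self) -> int:
        return len(self.entries)

    def match(self, seq: str) -> tuple[str, str] | None:
        """Exact joint (barcode + overhang) prefix match; returns
        (sample_id, barcode).  Joint matching keeps nested barcodes
        decodable: a shorter barcode whose overhang overlaps a longer
        barcode's spelling is still routed correctly."""
        for L, table in self._keyed:
            hit = table.get(seq[:L])
            if hit is not None:
                return hit
        return None

    def match_barcode_only(self, seq: str) -> tuple[str, str] | None:
        """Longest-first barcode match, ignoring the overhang (used to
        distinguish bad-overhang from no-barcode rejections)."""
        for L, table in self._by_length:
            sample = table.get(seq[:L])
            if sample is not None:
                return sample, seq[:L]
        return None

    @classmethod
    def from_tsv(cls, path, overhang: str = OVERHANG) -> "BarcodeSet":
        entries = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if fields[0].lower() in ("sample", "sample_id"):
                    continue
                entries.append((fields[0], fields[1]))
        return cls(entries, overhang)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tbarcode\n")
            for s, b in self.entries:
                fh.write(f"{s}\t{b}\n")


@dataclass
class DemuxedRead:
    """A sample-assigned, trimmed, standard-length read."""

    sample_id: str
    read_id: str
    sequence: str
    quality_string: str  # phred+33

    @property
    def qualities(self) -> np.ndarray:
        return (
            np.frombuffer(self.quality_string.encode("ascii"), dtype=np.uint8) - 33
        ).astype(np.int64)


@dataclass
class Rejection:
    read_id: str
    reason: str


def assign_read(
    seq: str, barcodes: BarcodeSet, overhang: str = OVERHANG
) -> tuple[str, int] | str:
    """Assign a raw read sequence to a sample.

    Returns ``(sample_id, barcode_length)`` on success or a rejection reason.
    The N-check applies to the whole barcode-stripped read, before trimming
    (strictest reading: a categorised read has no undetermined base at all).
    """
    hit = barcodes.match(seq)
    if hit is None:
        if barcodes.match_barcode_only(seq) is not None:
            return REJECT_BAD_OVERHANG
        return REJECT_NO_BARCODE
    sample_id, barcode = hit
    stripped = seq[len(barcode) :]
    if "N" in stripped:
        return REJECT_CONTAINS_N
    return sample_id, len(barcode)


def trim_and_standardise(
    seq: str, qual: str, min_q: int = 20, out_len: int = 64
) -> tuple[str, str] | str:
    """3'-trailing quality trim, then truncation to the standard length.

    Removes the maximal 3' suffix of bases below ``min_q``, truncates what
    remains to ``out_len`` from the 5' end, and rejects reads that end up
    shorter than that.
    """
    cutoff = chr(min_q + 33)
    end = len(qual)
    while end > 0 and qual[end - 1] < cutoff:
        end -= 1
    if end < out_len:
        return REJECT_TOO_SHORT
    return seq[:out_len], qual[:out_len]


def demultiplex(
    records: Iterable[tuple[str, str, str]],
    barcodes: BarcodeSet,
    overhang: str = OVERHANG,
    min_q: int = 20,
    out_len: int = 64,
) -> Iterator[DemuxedRead | Rejection]:
    """Stream (read_id, sequence, phred33-quality) triples through assignment
    and standardisation.  Every input read yields exactly one output item."""
    for read_id, seq, qual in records:
        seq = seq.upper()
        assigned = assign_read(seq, barcodes, overhang)
        if isinstance(assigned, str):
            yield Rejection(read_id, assigned)
            continue
        sample_id, blen = assigned
        trimmed = trim_and_standardise(seq[blen:], qual[blen:], min_q, out_len)
        if isinstance(trimmed, str):
            yield Rejection(read_id, trimmed)
            continue
        yield DemuxedRead(sample_id, read_id, trimmed[0], trimmed[1])


def iter_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Iterate a (gzip-aware) FASTQ file as (id, sequence, quality) triples."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "rt") as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq, qual


def demultiplex_fastq(path, barcodes: BarcodeSet, **kwargs):
    return demultiplex(iter_fastq(path), barcodes, **kwargs)


@dataclass
class DemuxStats:
    per_sample: dict
    rejections: dict
    total: int

    @property
    def assigned(self) -> int:
        return sum(self.per_sample.values())

    @property
    def categorised_fraction(self) -> float:
        return self.assigned / self.total if self.total else float("nan")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("class\tkey\tcount\n")
            for s, c in sorted(self.per_sample.items()):
                fh.write(f"assigned\t{s}\t{c}\n")
            for r, c in sorted(self.rejections.items()):
                fh.write(f"rejected\t{r}\t{c}\n")
            fh.write(f"total\t-\t{self.total}\n")


def demux_stats(items: Iterable[DemuxedRead | Rejection]) -> DemuxStats:
    """Per-sample read counts and rejection histogram for a demux stream."""
    per_sample: dict[str, int] = {}
    rejections: dict[str, int] = {r: 0 for r in REJECT_REASONS}
    total = 0
    for item in items:
        total += 1
        if isinstance(item, DemuxedRead):
            per_sample[item.sample_id] = per_sample.get(item.sample_id, 0) + 1
        else:
            rejections[item.reason] += 1
    return DemuxStats(per_sample, rejections, total)
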