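"""Read-to-tag mapping under the unique, best-stratum, <=1-mismatch contract.

Reads and reference tags are both 64 bp and strand-fixed by the protocol
(every read starts at the PstI overhang, and the reference already contains
both flank orientations), so mapping is ungapped, end-to-end Hamming
matching.  A read maps iff its best stratum (0 mismatches if any exact hit
exists, otherwise 1 mismatch) contains exactly one tag; ties are never
broken.

The 1-mismatch search uses the pigeonhole principle on the two 32-base read
halves: a single substitution leaves at least one half intact, so exact
lookups on the halves enumerate every candidate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .dna import hamming, mismatch_positions
from .ref_tags import ReferenceTag

MAPPED = "mapped"
AMBIGUOUS = "ambiguous"
UNMAPPED = "unmapped"


@dataclass(frozen=True)
class TagAlignment:
    tag_id: str
    mismatch_count: int
    mismatch_offset: int | None = None  # 0-based within the tag; None if exact


class TagIndex:
    """Exact + pigeonhole index over a set of equal-length reference tags.

    Duplicate tag sequences are recorded as an ambiguity class: any read
    matching them is inherently multi-mapped.
    """

    def __init__(self, tags: Sequence[ReferenceTag | tuple[str, str]]):
        pairs = [
            (t.tag_id, t.sequence) if isinstance(t, ReferenceTag) else t for t in tags
        ]
        if not pairs:
            raise ValueError("cannot build an index over an empty tag set")
        self.tag_len = len(pairs[0][1])
        for tid, seq in pairs:
            if len(seq) != self.tag_len:
                raise ValueError(
                    f"tag {tid} has length {len(seq)}, expected {self.tag_len}"
                )
        self.tag_ids = [tid for tid, _ in pairs]
        self.sequences = [seq for _, seq in pairs]
        self._exact: dict[str, list[int]] = {}
        for i, seq in enumerate(self.sequences):
            self._exact.setdefault(seq, []).append(i)
        half = self.tag_len // 2
        self._half = half
        self._left: dict[str, list[int]] = {}
        self._right: dict[str, list[int]] = {}
        for i, seq in enumerate(self.sequences):
            self._left.setdefault(seq[:half], []).append(i)
            self._right.setdefault(seq[half:], []).append(i)
        self._chunk_cache: dict[int, tuple[list[tuple[int, int]], dict]] = {}

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def duplicate_sequences(self) -> set[str]:
        return {s for s, idx in self._exact.items() if len(idx) > 1}

    def exact_hits(self, seq: str) -> list[int]:
        return self._exact.get(seq, [])

    def one_mismatch_hits(self, seq: str) -> list[int]:
        """Indices of tags at Hamming distance exactly 1 from ``seq``."""
        half = self._half
        candidates = set(self._left.get(seq[:half], ()))
        candidates.update(self._right.get(seq[half:], ()))
        return [
            i for i in candidates if hamming(seq, self.sequences[i], limit=1) == 1
        ]

    def _chunks(self, dmax: int):
        parts = dmax + 1
        if parts not in self._chunk_cache:
            base, extra = divmod(self.tag_len, parts)
            bounds = []
            start = 0
            for i in range(parts):
                size = base + (1 if i < extra else 0)
                bounds.append((start, start + size))
                start += size
            table: dict[tuple[int, str], list[int]] = {}
            for i, seq in enumerate(self.sequences):
                for j, (a, b) in enumerate(bounds):
                    table.setdefault((j, seq[a:b]), []).append(i)
            self._chunk_cache[parts] = (bounds, table)
        return self._chunk_cache[parts]

    def has_within(self, seq: str, dmax: int) -> bool:
        """True iff some tag lies within Hamming distance ``dmax`` of ``seq``."""
        if dmax < 0:
            return False
        if seq in self._exact:
            return True
        if dmax == 0:
            return False
        if dmax == 1:
            return bool(self.one_mismatch_hits(seq))
        bounds, table = self._chunks(dmax)
        seen: set[int] = set()
        for j, (a, b) in enumerate(bounds):
            for i in table.get((j, seq[a:b]), ()):
                if i in seen:
                    continue
                seen.add(i)
                if hamming(seq, self.sequences[i], limit=dmax) <= dmax:
                    return True
        return False


def map_read(seq: str, index: TagIndex):
    """Map one 64 bp read; returns (status, TagAlignment | None).

    Best-stratum semantics: 1-mismatch hits never compete with an exact hit.
    Uniqueness is required within the winning stratum; ties yield
    ``ambiguous``, an empty 1-mismatch stratum yields ``unmapped``.
    """
    if len(seq) != index.tag_len:
        raise ValueError(f"read length {len(seq)} != tag length {index.tag_len}")
    exact = index.exact_hits(seq)
    if exact:
        if len(exact) == 1:
            return MAPPED, TagAlignment(index.tag_ids[exact[0]], 0, None)
        return AMBIGUOUS, None
    hits = index.one_mismatch_hits(seq)
    if len(hits) == 1:
        i = hits[0]
        offset = mismatch_positions(seq, index.sequences[i])[0]
        return MAPPED, TagAlignment(index.tag_ids[i], 1, offset)
    if not hits:
        return UNMAPPED, None
    return AMBIGUOUS, None


def map_read_bruteforce(seq: str, tags: Sequence[tuple[str, str]]):
    """Exhaustive Hamming-distance oracle for the same strata/uniqueness rules.

    Independent of :class:`TagIndex`; used as the reference implementation in
    equivalence tests.
    """
    exact = [tid for tid, t in tags if t == seq]
    if exact:
        if len(exact) == 1:
            return MAPPED, TagAlignment(exact[0], 0, None)
        return AMBIGUOUS, None
    one = [(tid, t) for tid, t in tags if hamming(seq, t) == 1]
    if len(one) == 1:
        tid, t = one[0]
        return MAPPED, TagAlignment(tid, 1, mismatch_positions(seq, t)[0])
    if not one:
        return UNMAPPED, None
    return AMBIGUOUS, None


# ---------------------------------------------------------------------------
# pileups

_BASE_ORDER = "ACGT"


class TagPileup:
    """Per-sample base counts over one tag.

    Every mapped read covers all 64 positions, so per-offset depth equals the
    tag's mapped-read count; only non-reference observations need individual
    storage.  Quality sums are kept densely per offset so allele mean base
    qualities are exact.
    """

    __slots__ = ("tag_id", "ref_seq", "n_samples", "depth", "qualsum", "alt")

    def __init__(self, tag_id: str, ref_seq: str, n_samples: int):
        self.tag_id = tag_id
        self.ref_seq = ref_seq
        self.n_samples = n_samples
        self.depth = np.zeros(n_samples, dtype=np.int64)
        self.qualsum = np.zeros((len(ref_seq), n_samples), dtype=np.float64)
        # (offset, base) -> [counts per sample, quality sums per sample]
        self.alt: dict[tuple[int, str], list[np.ndarray]] = {}

    def add_read(self, sample: int, seq: str, quals: np.ndarray) -> None:
        self.depth[sample] += 1
        self.qualsum[:, sample] += quals
        if seq != self.ref_seq:
            for i, (x, y) in enumerate(zip(seq, self.ref_seq)):
                if x != y:
                    entry = self.alt.get((i, x))
                    if entry is None:
                        entry = [
                            np.zeros(self.n_samples, dtype=np.int64),
                            np.zeros(self.n_samples, dtype=np.float64),
                        ]
                        self.alt[(i, x)] = entry
                    entry[0][sample] += 1
                    entry[1][sample] += quals[i]

    # -- queries ----------------------------------------------------------

    def base_counts(self, offset: int) -> dict[str, np.ndarray]:
        """Per-sample read counts of every base observed at ``offset``."""
        ref_base = self.ref_seq[offset]
        counts = {ref_base: self.depth.copy()}
        for (off, base), (c, _q) in self.alt.items():
            if off == offset:
                counts[ref_base] = counts[ref_base] - c
                counts[base] = c.copy()
        return counts

    def base_qualsums(self, offset: int) -> dict[str, np.ndarray]:
        ref_base = self.ref_seq[offset]
        sums = {ref_base: self.qualsum[offset].copy()}
        for (off, base), (_c, q) in self.alt.items():
            if off == offset:
                sums[ref_base] = sums[ref_base] - q
                sums[base] = q.copy()
        return sums

    def variable_offsets(self) -> list[int]:
        return sorted({off for (off, _b), (c, _q) in self.alt.items() if c.sum() > 0})


class AlleleDepths:
    """Pileup container: tag_id -> :class:`TagPileup`, with sample bookkeeping."""

    def __init__(self, samples: Sequence[str]):
        self.samples = list(samples)
        self.sample_index = {s: i for i, s in enumerate(self.samples)}
        self.tags: dict[str, TagPileup] = {}

    def pileup_for(self, tag_id: str, ref_seq: str) -> TagPileup:
        p = self.tags.get(tag_id)
        if p is None:
            p = TagPileup(tag_id, ref_seq, len(self.samples))
            self.tags[tag_id] = p
        return p

    def tag_depths(self) -> dict[str, np.ndarray]:
        return {tid: p.depth for tid, p in self.tags.items()}

    def total_reads(self) -> int:
        return int(sum(p.depth.sum() for p in self.tags.values()))


@dataclass
class MappingStats:
    mapped: int = 0
    ambiguous: int = 0
    unmapped: int = 0
    mismatched: int = 0  # mapped with 1 mismatch

    @property
    def total(self) -> int:
        return self.mapped + self.ambiguous + self.unmapped


def accumulate_pileup(
    reads: Iterable,
    index: TagIndex,
    samples: Sequence[str],
) -> tuple[AlleleDepths, MappingStats]:
    """Map demultiplexed reads and accumulate per-sample pileups.

    ``reads`` yields objects with ``sample_id``, ``sequence`` and
    ``qualities`` (anything :mod:`gbsmap.demultiplex` emits).  Returns the
    pileups plus conservation-checked mapping statistics.
    """
    depths = AlleleDepths(samples)
    stats = MappingStats()
    seqs = {tid: seq for tid, seq in zip(index.tag_ids, index.sequences)}
    sample_index = depths.sample_index
    for read in reads:
        status, aln = map_read(read.sequence, index)
        if status == MAPPED:
            stats.mapped += 1
            if aln.mismatch_count:
                stats.mismatched += 1
            pile = depths.pileup_for(aln.tag_id, seqs[aln.tag_id])
            pile.add_read(sample_index[read.sample_id], read.sequence, read.qualities)
        elif status == AMBIGUOUS:
            stats.ambiguous += 1
        else:
            stats.unmapped += 1
    return depths, stats


def write_sam(depths_or_alignments, index: TagIndex, path) -> None:
    """Export alignments as SAM with tags as reference sequences (optional)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"LN": index.tag_len, "SN": tid} for tid in index.tag_ids
        ],
    }
    ref_ids = {tid: i for i, tid in enumerate(index.tag_ids)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read_id, sample_id, aln, seq, qual in depths_or_alignments:
            a = pysam.AlignedSegment()
            a.query_name = f"{sample_id}|{read_id}"
            a.query_sequence = seq
            a.reference_id = ref_ids[aln.tag_id]
            a.reference_start = 0
            a.cigarstring = f"{len(seq)}M"
            a.mapping_quality = 255
            if qual is not None:
                a.query_qualities = pysam.qualitystring_to_array(qual)
            a.set_tag("NM", aln.mismatch_count)
            out.write(a)
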