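"""Reference-tag construction from genome assemblies.

A GBS read always starts at a PstI cut site, so the mapping reference is not
the genome itself but the set of fixed-length (64 bp) sequences flanking every
PstI recognition site (CTGCAG), taken in both directions.  Each flank keeps
the 5-base TGCAG overhang at its 5' end, which is also the first thing a
demultiplexed read contains — tags and reads are therefore directly
comparable, end to end.

The tag set is built from one primary assembly, augmented with sufficiently
divergent tags from additional assemblies, and screened against the
chloroplast genome (plastid DNA is a common contaminant of whole-genome
shotgun assemblies).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO

from .dna import UNAMBIGUOUS, hamming, is_dna, revcomp
from .errors import ConfigurationError

PSTI_MOTIF = "CTGCAG"

# exclusion reason codes
REASON_EDGE = "edge"
REASON_AMBIGUOUS = "ambiguous-base"


@dataclass(frozen=True)
class Contig:
    """A contiguous assembled sequence from one assembly."""

    id: str
    sequence: str
    source: str = ""

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValueError(f"contig {self.id} has empty sequence")


@dataclass(frozen=True)
class RestrictionSite:
    """Occurrence of a recognition motif; position is the 0-based offset of
    the motif's first base on the forward strand."""

    contig_id: str
    position: int
    motif: str = PSTI_MOTIF


@dataclass(frozen=True)
class ReferenceTag:
    """A strand-resolved restriction-site flank used as a mapping reference.

    ``tag_id`` encodes contig, site position and direction (``contig:pos:F``
    or ``:R``) so provenance is always recoverable.
    """

    tag_id: str
    sequence: str
    source: str = ""
    direction: str = "F"


@dataclass(frozen=True)
class ExclusionRecord:
    """A flank that could not be emitted, with a reason code."""

    contig_id: str
    position: int
    direction: str
    reason: str


def find_restriction_sites(
    contigs: Iterable[Contig], motif: str = PSTI_MOTIF
) -> list[RestrictionSite]:
    """Locate every forward-strand occurrence of ``motif``.

    PstI's CTGCAG is its own reverse complement, so scanning one strand
    finds every cut site; a warning is raised for non-palindromic motifs,
    for which a single-strand scan is incomplete.
    """
    if not motif:
        raise ConfigurationError("restriction motif must be non-empty")
    if not is_dna(motif, allow_n=False):
        raise ConfigurationError(
            f"restriction motif {motif!r} contains non-ACGT characters"
        )
    if motif != revcomp(motif):
        warnings.warn(
            f"motif {motif} is not palindromic; only forward-strand sites are reported",
            stacklevel=2,
        )
    sites: list[RestrictionSite] = []
    for contig in contigs:
        seq = contig.sequence
        start = seq.find(motif)
        while start != -1:
            sites.append(RestrictionSite(contig.id, start, motif))
            start = seq.find(motif, start + 1)
    return sites


def extract_flank_tags(
    contig: Contig,
    site: RestrictionSite,
    flank_len: int = 64,
    source: str | None = None,
) -> tuple[list[ReferenceTag], list[ExclusionRecord]]:
    """Extract the forward and reverse flanking tags of one site.

    With the motif at position ``p`` (first base of CTGCAG), the forward tag
    is ``contig[p+1 : p+1+flank_len]`` and the reverse tag is the reverse
    complement of ``contig[p+5-flank_len : p+5]``; both start with the TGCAG
    overhang.  A flank is emitted only if it lies fully within the contig and
    contains no ambiguous base; otherwise an exclusion record is produced, so
    tags + exclusions always equals two per site.
    """
    if flank_len < 6:
        raise ConfigurationError("flank_len must be at least 6 (overhang + 1)")
    p = site.position
    m = len(site.motif)
    if p < 0 or p + m > len(contig.sequence):
        raise ValueError(f"site at {p} does not lie on contig {contig.id}")
    src = source if source is not None else contig.source
    tags: list[ReferenceTag] = []
    exclusions: list[ExclusionRecord] = []

    # forward flank: overhang + downstream sequence
    fwd_end = p + 1 + flank_len
    if fwd_end <= len(contig.sequence):
        seq = contig.sequence[p + 1 : fwd_end]
        if set(seq) <= UNAMBIGUOUS:
            tags.append(ReferenceTag(f"{contig.id}:{p}:F", seq, src, "F"))
        else:
            exclusions.append(ExclusionRecord(contig.id, p, "F", REASON_AMBIGUOUS))
    else:
        exclusions.append(ExclusionRecord(contig.id, p, "F", REASON_EDGE))

    # reverse flank: upstream sequence, reverse-complemented so that it too
    # begins with the overhang
    rev_start = p + 5 - flank_len
    if rev_start >= 0:
        seq = contig.sequence[rev_start : p + 5]
        if set(seq) <= UNAMBIGUOUS:
            tags.append(ReferenceTag(f"{contig.id}:{p}:R", revcomp(seq), src, "R"))
        else:
            exclusions.append(ExclusionRecord(contig.id, p, "R", REASON_AMBIGUOUS))
    else:
        exclusions.append(ExclusionRecord(contig.id, p, "R", REASON_EDGE))

    return tags, exclusions


def extract_all_tags(
    contigs: Sequence[Contig], motif: str = PSTI_MOTIF, flank_len: int = 64
) -> tuple[list[ReferenceTag], list[ExclusionRecord], list[RestrictionSite]]:
    """Site discovery plus flank extraction over a whole assembly."""
    by_id = {}
    for c in contigs:
        if c.id in by_id:
            raise ConfigurationError(f"duplicate contig id {c.id!r} within assembly")
        by_id[c.id] = c
    sites = find_restriction_sites(contigs, motif)
    tags: list[ReferenceTag] = []
    exclusions: list[ExclusionRecord] = []
    for site in sites:
        t, e = extract_flank_tags(by_id[site.contig_id], site, flank_len)
        tags.extend(t)
        exclusions.extend(e)
    return tags, exclusions, sites


def merge_assemblies(
    primary_tags: Sequence[ReferenceTag],
    other_tags: Sequence[ReferenceTag],
    min_mismatches: int = 2,
    include_no_hit: bool = True,
    no_hit_mismatches: int = 6,
) -> list[ReferenceTag]:
    """Merge secondary-assembly tags into the primary tag set.

    A secondary tag is added when its best full-length ungapped match against
    the primary set carries at least ``min_mismatches`` substitutions — i.e.
    it represents sequence the primary assembly does not already cover at
    read-mapping resolution (the mapper tolerates one mismatch, so a
    2+-mismatch tag cannot cross-map).  Tags with no primary match at all
    (best distance beyond ``no_hit_mismatches``) are included by default and
    dropped with ``include_no_hit=False``.  Identical sequences within the
    added set collapse to one.
    """
    from .tag_mapper import TagIndex  # local import to avoid a cycle

    if min_mismatches < 1:
        raise ConfigurationError("min_mismatches must be >= 1")
    merged = list(primary_tags)
    if not other_tags:
        return merged
    index = TagIndex([(t.tag_id, t.sequence) for t in primary_tags])
    seen: set[str] = set()
    for tag in other_tags:
        if tag.sequence in seen:
            continue
        if index.has_within(tag.sequence, min_mismatches - 1):
            continue  # too close to an existing primary tag
        if not include_no_hit and not index.has_within(
            tag.sequence, no_hit_mismatches
        ):
            continue  # no primary hit at all and no-hit tags are disabled
        merged.append(tag)
        seen.add(tag.sequence)
    return merged


def _chunk_bounds(length: int, parts: int) -> list[tuple[int, int]]:
    base, extra = divmod(length, parts)
    bounds = []
    start = 0
    for i in range(parts):
        size = base + (1 if i < extra else 0)
        bounds.append((start, start + size))
        start += size
    return bounds


def screen_chloroplast(
    tags: Sequence[ReferenceTag],
    cp_genome: Contig | Sequence[Contig],
    min_identity: float = 0.90,
    min_align_len: int = 64,
) -> tuple[list[ReferenceTag], list[ReferenceTag]]:
    """Remove tags that match the chloroplast genome.

    A tag is removed iff some window on either strand of the chloroplast
    genome aligns to it ungapped over its full length with identity >=
    ``min_identity``; for 64 bp tags at 90% this is at most 6 mismatches.
    Candidate windows come from a pigeonhole chunk prefilter: any window
    within ``max_mm`` mismatches must share at least one of ``max_mm + 1``
    exact chunks with the tag, so the prefilter is lossless.
    """
    cps = [cp_genome] if isinstance(cp_genome, Contig) else list(cp_genome)
    if not cps or all(not c.sequence for c in cps):
        raise ConfigurationError("chloroplast genome must be non-empty")
    if not tags:
        return [], []
    tag_len = len(tags[0].sequence)
    if min_align_len > tag_len:
        # no full-length tag alignment can reach the required length
        return list(tags), []
    max_mm = int(tag_len * (1.0 - min_identity))
    parts = max_mm + 1
    bounds = _chunk_bounds(tag_len, parts)

    # index every window start of both strands by its exact chunks
    chunk_index: dict[tuple[int, str], list[tuple[int, int]]] = {}
    strands: list[str] = []
    for c in cps:
        strands.append(c.sequence)
        strands.append(revcomp(c.sequence))
    for s_idx, seq in enumerate(strands):
        for w in range(len(seq) - tag_len + 1):
            for j, (a, b) in enumerate(bounds):
                chunk_index.setdefault((j, seq[w + a : w + b]), []).append((s_idx, w))

    kept: list[ReferenceTag] = []
    removed: list[ReferenceTag] = []
    for tag in tags:
        t = tag.sequence
        candidates: set[tuple[int, int]] = set()
        for j, (a, b) in enumerate(bounds):
            candidates.update(chunk_index.get((j, t[a:b]), ()))
        hit = False
        for s_idx, w in candidates:
            if hamming(t, strands[s_idx][w : w + tag_len], limit=max_mm) <= max_mm:
                hit = True
                break
        (removed if hit else kept).append(tag)
    return kept, removed


# ---------------------------------------------------------------------------
# file I/O


def read_assembly(path, source: str | None = None) -> list[Contig]:
    """Load a multi-FASTA assembly as a list of contigs."""
    name = source if source is not None else str(path)
    return [
        Contig(rec.id, str(rec.seq).upper(), name)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_tags_fasta(tags: Iterable[ReferenceTag], path) -> None:
    with open(path, "w") as fh:
        for tag in tags:
            fh.write(f">{tag.tag_id}\n{tag.sequence}\n")


def read_tags_fasta(path, source: str = "") -> list[ReferenceTag]:
    tags = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tid = rec.id
        direction = tid.rsplit(":", 1)[-1] if ":" in tid else "F"
        tags.append(ReferenceTag(tid, str(rec.seq).upper(), source, direction))
    return tags


def write_exclusion_ledger(exclusions: Iterable[ExclusionRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tposition\tdirection\treason\n")
        for e in exclusions:
            fh.write(f"{e.contig_id}\t{e.position}\t{e.direction}\t{e.reason}\n")
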