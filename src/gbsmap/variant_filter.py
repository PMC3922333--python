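"""Candidate SNP discovery and the population-level filter cascade.

Candidate sites are tag offsets where at least ``min_alt_reads`` (default 4,
i.e. "more than 3") reads across the population carry the same non-reference
base.  Candidates then pass through an ordered cascade of pure per-record
predicates; the per-stage survivor ledger mirrors the count chain a real run
reports, while the final surviving set is order-independent because each
predicate depends only on the record itself.

Stage definitions (defaults in parentheses):

1. ``alt-fraction``      population alt-read fraction >= 0.1
2. ``baseq-diff``        |mean ref baseq - mean alt baseq| / max(...) * 100 <= 5
3. ``site-quality``      site quality score >= 20
4. ``coverage``          total ref+alt reads >= 5 per sample on average
5. ``het-percent``       heterozygous samples (provisional calls) <= 2%
6. ``alt-ref-ratio``     population alt:ref read ratio >= 0.5
7. ``dominant``          tag has mapped reads in both parents (null-allele
                         tags are indistinguishable from missing data)
8. ``parent-missing``    both parents have a called genotype

The site quality score is a Phred-scaled binomial tail: the probability that
all alt-supporting reads arise from per-base sequencing error at the rate
implied by their mean base quality.  It approximates (and stands in for) a
full genotype-likelihood caller's site score; the threshold is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError
from .genotype_caller import HET, MISSING, call_genotypes_vector
from .tag_mapper import AlleleDepths

QUALITY_CAP = 3000.0

STAGE_ALT_FRACTION = "alt-fraction"
STAGE_BASEQ_DIFF = "baseq-diff"
STAGE_QUALITY = "site-quality"
STAGE_COVERAGE = "coverage"
STAGE_HET = "het-percent"
STAGE_ALT_REF_RATIO = "alt-ref-ratio"
STAGE_DOMINANT = "dominant"
STAGE_PARENT_MISSING = "parent-missing"

STAGE_ORDER = (
    STAGE_ALT_FRACTION,
    STAGE_BASEQ_DIFF,
    STAGE_QUALITY,
    STAGE_COVERAGE,
    STAGE_HET,
    STAGE_ALT_REF_RATIO,
    STAGE_DOMINANT,
    STAGE_PARENT_MISSING,
)

DEFAULT_THRESHOLDS = {
    "min_alt_fraction": 0.1,
    "max_baseq_pct_diff": 5.0,
    "min_quality": 20.0,
    "min_mean_depth": 5.0,
    "max_het_pct": 2.0,
    "min_alt_ref_ratio": 0.5,
    "alt_ref_ratio_mode": "reads",  # or "samples"
}


@dataclass
class SnpRecord:
    """A biallelic candidate site on a tag with per-sample evidence."""

    tag_id: str
    offset: int  # 0-based within the tag
    ref_allele: str
    alt_allele: str
    quality: float
    ref_depths: np.ndarray
    alt_depths: np.ndarray
    mean_ref_baseq: np.ndarray  # per sample, nan where no ref reads
    mean_alt_baseq: np.ndarray
    multiallelic: bool = False
    filter_flags: list[str] = field(default_factory=list)

    @property
    def marker_id(self) -> str:
        return f"{self.tag_id}:{self.offset}"

    @property
    def total_ref(self) -> int:
        return int(self.ref_depths.sum())

    @property
    def total_alt(self) -> int:
        return int(self.alt_depths.sum())

    def pop_mean_ref_baseq(self) -> float:
        w = self.ref_depths.astype(float)
        q = np.where(np.isnan(self.mean_ref_baseq), 0.0, self.mean_ref_baseq)
        return float((q * w).sum() / w.sum()) if w.sum() else float("nan")

    def pop_mean_alt_baseq(self) -> float:
        w = self.alt_depths.astype(float)
        q = np.where(np.isnan(self.mean_alt_baseq), 0.0, self.mean_alt_baseq)
        return float((q * w).sum() / w.sum()) if w.sum() else float("nan")


def site_quality(total_depth: int, alt_count: int, mean_alt_baseq: float) -> float:
    """Phred-scaled probability that the alt reads are all sequencing error."""
    if alt_count <= 0 or total_depth <= 0:
        return 0.0
    err = 10.0 ** (-mean_alt_baseq / 10.0)
    p = stats.binom.sf(alt_count - 1, total_depth, min(err, 0.75))
    if p <= 0.0:
        return QUALITY_CAP
    return float(min(-10.0 * np.log10(p), QUALITY_CAP))


def call_candidate_snps(
    pileups: AlleleDepths, min_alt_reads: int = 4
) -> list[SnpRecord]:
    """Scan pileups for biallelic candidates.

    The reference allele is the tag base; the alternative allele is the most
    frequent non-reference base population-wide.  Sites with more than two
    observed alleles keep the top alternative and are flagged multiallelic.
    """
    records: list[SnpRecord] = []
    for tag_id in sorted(pileups.tags):
        pile = pileups.tags[tag_id]
        for offset in pile.variable_offsets():
            counts = pile.base_counts(offset)
            qsums = pile.base_qualsums(offset)
            ref_base = pile.ref_seq[offset]
            alts = {
                b: c for b, c in counts.items() if b != ref_base and c.sum() > 0
            }
            if not alts:
                continue
            alt_base = max(alts, key=lambda b: alts[b].sum())
            if int(alts[alt_base].sum()) < min_alt_reads:
                continue
            ref_c = counts[ref_base].astype(np.int64)
            alt_c = alts[alt_base].astype(np.int64)
            with np.errstate(invalid="ignore", divide="ignore"):
                mean_ref_q = np.where(
                    ref_c > 0, qsums[ref_base] / np.maximum(ref_c, 1), np.nan
                )
                mean_alt_q = np.where(
                    alt_c > 0, qsums[alt_base] / np.maximum(alt_c, 1), np.nan
                )
            pop_alt_q = (
                float(qsums[alt_base].sum() / alt_c.sum()) if alt_c.sum() else 0.0
            )
            qual = site_quality(
                int(ref_c.sum() + alt_c.sum()), int(alt_c.sum()), pop_alt_q
            )
            records.append(
                SnpRecord(
                    tag_id=tag_id,
                    offset=offset,
                    ref_allele=ref_base,
                    alt_allele=alt_base,
                    quality=qual,
                    ref_depths=ref_c,
                    alt_depths=alt_c,
                    mean_ref_baseq=mean_ref_q,
                    mean_alt_baseq=mean_alt_q,
                    multiallelic=len(alts) > 1,
                )
            )
    return records


@dataclass
class FilterLedger:
    stages: list[tuple[str, int]]

    def survivors(self) -> int:
        return self.stages[-1][1] if self.stages else 0

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("stage\tsurvivors\n")
            for name, n in self.stages:
                fh.write(f"{name}\t{n}\n")


def _stage_predicates(
    n_samples: int,
    samples: Sequence[str],
    parent_a_id: str,
    parent_b_id: str,
    tag_depths: dict[str, np.ndarray] | None,
    th: dict,
):
    """Build the pure predicate for every cascade stage."""
    pa = samples.index(parent_a_id) if parent_a_id in samples else None
    pb = samples.index(parent_b_id) if parent_b_id in samples else None

    def provisional_states(rec: SnpRecord) -> np.ndarray:
        return call_genotypes_vector(rec.ref_depths, rec.alt_depths)

    def alt_fraction(rec):
        total = rec.total_ref + rec.total_alt
        return total > 0 and rec.total_alt / total >= th["min_alt_fraction"]

    def baseq_diff(rec):
        rq, aq = rec.pop_mean_ref_baseq(), rec.pop_mean_alt_baseq()
        if np.isnan(rq) or np.isnan(aq):
            return False
        denom = max(rq, aq)
        return denom > 0 and abs(rq - aq) / denom * 100.0 <= th["max_baseq_pct_diff"]

    def quality(rec):
        return rec.quality >= th["min_quality"]

    def coverage(rec):
        return rec.total_ref + rec.total_alt >= th["min_mean_depth"] * n_samples

    def het_percent(rec):
        states = provisional_states(rec)
        n_het = int((states == HET).sum())
        return n_het / n_samples * 100.0 <= th["max_het_pct"]

    def alt_ref_ratio(rec):
        if th["alt_ref_ratio_mode"] == "samples":
            states = provisional_states(rec)
            n_ref = int((states == "hom_ref").sum())
            n_alt = int((states == "hom_alt").sum())
            return n_ref > 0 and n_alt / n_ref >= th["min_alt_ref_ratio"]
        return (
            rec.total_ref > 0
            and rec.total_alt / rec.total_ref >= th["min_alt_ref_ratio"]
        )

    def dominant(rec):
        if tag_depths is None or pa is None or pb is None:
            return True
        d = tag_depths.get(rec.tag_id)
        if d is None:
            return False
        return d[pa] > 0 and d[pb] > 0

    def parent_missing(rec):
        if pa is None or pb is None:
            return True
        states = provisional_states(rec)
        return states[pa] != MISSING and states[pb] != MISSING

    return {
        STAGE_ALT_FRACTION: alt_fraction,
        STAGE_BASEQ_DIFF: baseq_diff,
        STAGE_QUALITY: quality,
        STAGE_COVERAGE: coverage,
        STAGE_HET: het_percent,
        STAGE_ALT_REF_RATIO: alt_ref_ratio,
        STAGE_DOMINANT: dominant,
        STAGE_PARENT_MISSING: parent_missing,
    }


def apply_filter_cascade(
    records: Sequence[SnpRecord],
    n_samples: int,
    samples: Sequence[str],
    parent_a_id: str,
    parent_b_id: str,
    tag_depths: dict[str, np.ndarray] | None = None,
    thresholds: dict | None = None,
) -> tuple[list[SnpRecord], FilterLedger]:
    """Apply the eight-stage cascade in order, recording survivors per stage.

    Records failing a stage get that stage appended to ``filter_flags`` and do
    not proceed; the returned survivors carry empty flags.
    """
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        unknown = set(thresholds) - set(DEFAULT_THRESHOLDS)
        if unknown:
            raise ConfigurationError(f"unknown filter threshold(s): {sorted(unknown)}")
        th.update(thresholds)
    samples = list(samples)
    predicates = _stage_predicates(
        n_samples, samples, parent_a_id, parent_b_id, tag_depths, th
    )
    ledger = FilterLedger([("candidates", len(records))])
    surviving = list(records)
    for stage in STAGE_ORDER:
        pred = predicates[stage]
        next_surviving = []
        for rec in surviving:
            if pred(rec):
                next_surviving.append(rec)
            else:
                rec.filter_flags.append(stage)
        surviving = next_surviving
        ledger.stages.append((stage, len(surviving)))
    return surviving, ledger


# ---------------------------------------------------------------------------
# VCF export (tag-relative coordinates: CHROM = tag_id, POS = offset + 1)


def export_vcf(
    records: Sequence[SnpRecord],
    samples: Sequence[str],
    path,
    tag_length: int = 64,
) -> None:
    """Write records as VCF via pysam, one contig per tag."""
    import pysam

    header = pysam.VariantHeader()
    header.add_meta("source", "gbsmap")
    contigs = sorted({r.tag_id for r in records})
    for tid in contigs:
        header.contigs.add(tid, length=tag_length)
    for stage in STAGE_ORDER:
        header.filters.add(stage, None, None, f"failed cascade stage {stage}")
    header.info.add("MULTI", 0, "Flag", "more than two alleles observed")
    header.formats.add("GT", 1, "String", "provisional proportion-rule genotype")
    header.formats.add("AD", "R", "Integer", "ref,alt allele depths")
    header.formats.add("DP", 1, "Integer", "total depth")
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in sorted(records, key=lambda r: (r.tag_id, r.offset)):
            row = out.new_record(
                contig=rec.tag_id,
                start=rec.offset,
                stop=rec.offset + 1,
                alleles=(rec.ref_allele, rec.alt_allele),
                qual=rec.quality,
            )
            if rec.filter_flags:
                for fl in rec.filter_flags:
                    row.filter.add(fl)
            else:
                row.filter.add("PASS")
            if rec.multiallelic:
                row.info["MULTI"] = True
            states = call_genotypes_vector(rec.ref_depths, rec.alt_depths)
            gt_map = {"hom_ref": (0, 0), "hom_alt": (1, 1), "het": (0, 1)}
            for i, s in enumerate(samples):
                row.samples[s]["AD"] = (
                    int(rec.ref_depths[i]),
                    int(rec.alt_depths[i]),
                )
                row.samples[s]["DP"] = int(rec.ref_depths[i] + rec.alt_depths[i])
                row.samples[s]["GT"] = gt_map.get(states[i], (None, None))
            out.write(row)


def import_vcf(path) -> tuple[list[SnpRecord], list[str]]:
    """Read a gbsmap VCF back into records (depth-exact round trip)."""
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for row in vcf:
            ad = np.array(
                [row.samples[s]["AD"] for s in samples], dtype=np.int64
            )
            ref_c, alt_c = ad[:, 0], ad[:, 1]
            flags = [f for f in row.filter.keys() if f != "PASS"]
            records.append(
                SnpRecord(
                    tag_id=row.chrom,
                    offset=row.start,
                    ref_allele=row.alleles[0],
                    alt_allele=row.alleles[1],
                    quality=float(row.qual) if row.qual is not None else 0.0,
                    ref_depths=ref_c,
                    alt_depths=alt_c,
                    mean_ref_baseq=np.full(len(samples), np.nan),
                    mean_alt_baseq=np.full(len(samples), np.nan),
                    multiallelic="MULTI" in row.info,
                    filter_flags=flags,
                )
            )
    return records, samples
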