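"""Candidate SNP discovery and the filter cascade: boundary behaviour,
ledger bookkeeping, order-independence of the final set, VCF round trip."""

import numpy as np
import pytest

from gbsmap.errors import ConfigurationError
from gbsmap.tag_mapper import AlleleDepths
from gbsmap.variant_filter import (
    DEFAULT_THRESHOLDS,
    STAGE_ORDER,
    SnpRecord,
    _stage_predicates,
    apply_filter_cascade,
    call_candidate_snps,
    export_vcf,
    import_vcf,
)

REF_TAG = ("tag1", "TGCAG" + "ACT" * 19 + "AC")  # 64 bp


def _pileups(pop_counts, n_samples=4, offset=17, alt_base=None):
    """Build pileups with given total (ref, alt) read counts at one offset,
    spread evenly over samples."""
    tag_id, ref_seq = REF_TAG
    depths = AlleleDepths([f"s{i}" for i in range(n_samples)])
    pile = depths.pileup_for(tag_id, ref_seq)
    ref_n, alt_n = pop_counts
    alt_base = alt_base or ("G" if ref_seq[offset] != "G" else "A")
    alt_seq = ref_seq[:offset] + alt_base + ref_seq[offset + 1 :]
    q = np.full(64, 35.0)
    for i in range(ref_n):
        pile.add_read(i % n_samples, ref_seq, q)
    for i in range(alt_n):
        pile.add_read(i % n_samples, alt_seq, q)
    return depths


class TestCandidateCalling:
    def test_three_alt_reads_not_emitted(self):
        assert call_candidate_snps(_pileups((100, 3))) == []

    def test_four_alt_reads_emitted(self):
        recs = call_candidate_snps(_pileups((100, 4)))
        assert len(recs) == 1
        rec = recs[0]
        assert (rec.tag_id, rec.offset) == ("tag1", 17)
        assert rec.total_alt == 4 and rec.total_ref == 100
        assert rec.ref_allele == REF_TAG[1][17]

    def test_monomorphic_tag_yields_nothing(self):
        assert call_candidate_snps(_pileups((50, 0))) == []

    def test_multiallelic_keeps_top_alt_with_flag(self):
        depths = _pileups((40, 10), alt_base="G")
        pile = depths.tags["tag1"]
        third = REF_TAG[1][:17] + "T" + REF_TAG[1][18:]
        assert REF_TAG[1][17] == "A"
        for i in range(4):
            pile.add_read(0, third, np.full(64, 35.0))
        recs = call_candidate_snps(depths)
        assert len(recs) == 1
        assert recs[0].alt_allele == "G" and recs[0].multiallelic

    def test_quality_reflects_error_improbability(self):
        shallow = call_candidate_snps(_pileups((100, 4)))[0]
        deep = call_candidate_snps(_pileups((60, 60)))[0]
        assert 0 < shallow.quality <= 3000.0
        assert shallow.quality < deep.quality <= 3000.0


def _record(
    ref=700, alt=700, n_samples=140, quality=500.0, ref_q=38.0, alt_q=38.0,
    het_samples=0, tag="tagA",
):
    """Constructed SnpRecord with exact population totals: a proportional
    block of samples carries all alt reads, the rest carry the ref reads."""

    def spread(total, idx):
        d = np.zeros(n_samples, dtype=np.int64)
        if len(idx) and total:
            d[idx] = total // len(idx)
            d[idx[: total % len(idx)]] += 1
        return d

    k_alt = int(round(n_samples * alt / max(ref + alt, 1))) if alt else 0
    k_alt = min(max(k_alt, 1 if alt else 0), n_samples - 1)
    alt_idx = np.arange(n_samples - k_alt, n_samples - 2)  # keep parents ref/alt
    alt_idx = np.append(alt_idx, n_samples - 1)  # parent B carries alt
    ref_idx = np.array([i for i in range(n_samples) if i not in set(alt_idx)])
    ref_d = spread(ref, ref_idx)
    alt_d = spread(alt, alt_idx)
    for i in range(het_samples):  # plant heterozygous-looking samples
        tot = max(ref_d[i] + alt_d[i], 8)
        ref_d[i] = tot // 2
        alt_d[i] = tot - tot // 2
    return SnpRecord(
        tag_id=tag, offset=5, ref_allele="A", alt_allele="G", quality=quality,
        ref_depths=ref_d, alt_depths=alt_d,
        mean_ref_baseq=np.where(ref_d > 0, ref_q, np.nan),
        mean_alt_baseq=np.where(alt_d > 0, alt_q, np.nan),
    )


def _run(records, n_samples=140, tag_depths=None, thresholds=None):
    samples = [f"s{i}" for i in range(n_samples - 2)] + ["GP", "Mx"]
    if tag_depths is None:
        tag_depths = {}
        for r in records:
            tag_depths.setdefault(r.tag_id, np.ones(n_samples, dtype=np.int64))
    return apply_filter_cascade(
        records, n_samples, samples, "GP", "Mx", tag_depths, thresholds
    )


class TestCascade:
    def test_baseq_difference_boundary(self):
        # 2.1 / 40 * 100 = 5.25% fails; 2.0 / 40 -> 5.0% passes
        fail = _record(ref_q=40.0, alt_q=37.9)
        ok = _record(ref_q=40.0, alt_q=38.0)
        surviving, _ = _run([fail, ok])
        assert surviving == [ok]
        assert fail.filter_flags == ["baseq-diff"]

    def test_heterozygous_percent_boundary(self):
        # 3 het of 138 samples = 2.17% > 2 -> removed; 2 of 138 passes
        fail = _record(n_samples=138, het_samples=3)
        ok = _record(n_samples=138, het_samples=2)
        surviving, _ = _run([fail, ok], n_samples=138)
        assert surviving == [ok]
        assert fail.filter_flags == ["het-percent"]

    def test_coverage_boundary(self):
        fail = _record(ref=350, alt=340)  # 690 < 700 at 140 samples
        ok = _record(ref=350, alt=350)
        surviving, _ = _run([fail, ok])
        assert surviving == [ok]
        assert fail.filter_flags == ["coverage"]

    def test_alt_fraction_and_ratio(self):
        frac_fail = _record(ref=1300, alt=130)  # 130/1430 < 0.1
        ratio_fail = _record(ref=1000, alt=420)  # frac 0.29 ok; 0.42 < 0.5 ratio
        ok = _record(ref=700, alt=700)
        surviving, _ = _run([frac_fail, ratio_fail, ok])
        assert surviving == [ok]
        assert frac_fail.filter_flags == ["alt-fraction"]
        assert ratio_fail.filter_flags == ["alt-ref-ratio"]

    def test_parent_null_tag_dropped_as_dominant(self):
        rec = _record(tag="tagNull")
        depths = {"tagNull": np.ones(140, dtype=np.int64)}
        depths["tagNull"][-2] = 0  # GP has no reads anywhere on the tag
        surviving, _ = _run([rec], tag_depths=depths)
        assert surviving == [] and rec.filter_flags == ["dominant"]

    def test_parent_missing_genotype_dropped(self):
        rec = _record()
        rec.ref_depths[-2] = 2  # GP: depth 2 -> provisional call missing
        rec.alt_depths[-2] = 0
        surviving, _ = _run([rec])
        assert surviving == [] and rec.filter_flags == ["parent-missing"]

    def test_unknown_threshold_rejected(self):
        with pytest.raises(ConfigurationError, match="no_such"):
            _run([_record()], thresholds={"no_such": 1})

    def test_constructed_ledger_counts(self):
        """10 records: 3 fail alt-fraction, then 2 of the rest fail coverage."""
        records = (
            [_record(ref=1300, alt=100) for _ in range(3)]
            + [_record(ref=340, alt=340) for _ in range(2)]
            + [_record() for _ in range(5)]
        )
        _, ledger = _run(records)
        counts = dict(ledger.stages)
        assert counts["candidates"] == 10
        assert counts["alt-fraction"] == 7
        assert counts["coverage"] == 5
        assert counts["parent-missing"] == 5  # final survivors

    def test_ledger_monotone(self):
        rng = np.random.default_rng(0)
        records = [
            _record(ref=int(rng.integers(100, 1500)), alt=int(rng.integers(100, 1500)),
                    het_samples=int(rng.integers(0, 5)))
            for _ in range(30)
        ]
        _, ledger = _run(records)
        survivors = [n for _, n in ledger.stages]
        assert all(a >= b for a, b in zip(survivors, survivors[1:]))

    def test_final_set_is_order_independent(self):
        """Each stage is a pure per-record predicate, so the surviving set
        equals the records passing every predicate, in any order."""
        rng = np.random.default_rng(1)
        records = [
            _record(ref=int(rng.integers(100, 1500)), alt=int(rng.integers(100, 1500)),
                    quality=float(rng.integers(5, 50)),
                    het_samples=int(rng.integers(0, 5)))
            for _ in range(40)
        ]
        samples = [f"s{i}" for i in range(138)] + ["GP", "Mx"]
        tag_depths = {r.tag_id: np.ones(140, dtype=np.int64) for r in records}
        surviving, _ = _run(
            [SnpRecord(**{**r.__dict__, "filter_flags": []}) for r in records]
        )
        preds = _stage_predicates(140, samples, "GP", "Mx", tag_depths,
                                  DEFAULT_THRESHOLDS)
        expected = [
            r for r in records if all(preds[s](r) for s in STAGE_ORDER)
        ]
        assert [r.ref_depths.tolist() for r in surviving] == [
            r.ref_depths.tolist() for r in expected
        ]


class TestVcf:
    def test_round_trip_preserves_depths(self, tmp_path):
        records = [_record(tag="tagA"), _record(ref=800, alt=650, tag="tagB")]
        records[1].filter_flags.append("coverage")
        path = tmp_path / "out.vcf"
        samples = [f"s{i}" for i in range(138)] + ["GP", "Mx"]
        export_vcf(records, samples, path)
        back, back_samples = import_vcf(path)
        assert back_samples == samples
        assert len(back) == 2
        for orig, rec in zip(records, back):
            assert rec.tag_id == orig.tag_id and rec.offset == orig.offset
            assert rec.ref_depths.tolist() == orig.ref_depths.tolist()
            assert rec.alt_depths.tolist() == orig.alt_depths.tolist()
            assert rec.filter_flags == orig.filter_flags

    def test_empty_record_set_gives_header_only(self, tmp_path):
        path = tmp_path / "empty.vcf"
        export_vcf([], ["s0", "s1"], path)
        lines = path.read_text().splitlines()
        assert all(l.startswith("#") for l in lines)
        back, _ = import_vcf(path)
        assert back == []

    def test_vcf_positions_are_one_based(self, tmp_path):
        rec = _record()
        path = tmp_path / "pos.vcf"
        export_vcf([rec], [f"s{i}" for i in range(140)], path)
        row = next(l for l in path.read_text().splitlines() if not l.startswith("#"))
        chrom, pos = row.split("\t")[:2]
        assert chrom == "tagA" and int(pos) == rec.offset + 1
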