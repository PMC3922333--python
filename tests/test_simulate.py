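"""The synthetic-data generator: construction audits, meiosis statistics
against the Haldane-Waddington closed form, phenotype calibration, read
truth, and byte-level determinism."""

import numpy as np
import pandas as pd
import pytest

from gbsmap.dna import hamming
from gbsmap.errors import GenerationError
from gbsmap.ref_tags import extract_all_tags, read_assembly
from gbsmap.simulate import (
    SimConfig,
    make_barcodes,
    make_marker_map,
    make_parental_genomes,
    qtl_indices,
    simulate_population,
    simulate_ril_population,
    simulate_run,
)

SMALL = dict(n_lines=12, n_markers=40, n_extra_tags=10, depth_scale=0.02)


def small_config(**over):
    return SimConfig(**{**SMALL, **over})


class TestGenomes:
    def test_marker_tag_pairs_differ_at_one_base(self):
        cfg = small_config(n_markers=10, n_extra_tags=0, n_cp_contigs=0)
        rng = np.random.default_rng(0)
        mm = make_marker_map(cfg, rng)
        genome = make_parental_genomes(cfg, mm, rng)
        snp = genome.loci[genome.loci["kind"] == "snp"]
        assert len(snp) == 12  # 10 + the two row-type co-segregating markers
        a = dict(genome.contigs_a)
        b = dict(genome.contigs_b)
        for _, row in snp.iterrows():
            assert hamming(a[row.contig_id], b[row.contig_id]) == 1
            pos = a[row.contig_id].index("CTGCAG") + 1 + row.snp_offset
            assert a[row.contig_id][pos] != b[row.contig_id][pos]

    def test_dominant_fraction_audit(self):
        cfg = small_config(n_extra_tags=100, dominant_fraction=0.1, n_cp_contigs=0)
        rng = np.random.default_rng(1)
        mm = make_marker_map(cfg, rng)
        genome = make_parental_genomes(cfg, mm, rng)
        dom = genome.loci[genome.loci["kind"] == "dominant"]
        assert len(dom) == 10
        a = dict(genome.contigs_a)
        b = dict(genome.contigs_b)
        for _, row in dom.iterrows():
            null_seq = a[row.contig_id] if row.null_parent == "A" else b[row.contig_id]
            kept_seq = b[row.contig_id] if row.null_parent == "A" else a[row.contig_id]
            assert "CTGCAG" not in null_seq and "CTGCAG" in kept_seq

    def test_all_flanks_extract_cleanly(self, tmp_path):
        cfg = small_config(n_cp_contigs=0)
        run = simulate_run(cfg, seed=3, outdir=tmp_path)
        for key in ("assembly_a", "assembly_b"):
            contigs = read_assembly(run.paths[key])
            tags, exclusions, sites = extract_all_tags(contigs)
            assert not exclusions
            assert len(tags) == 2 * len(sites)

    def test_impossible_marker_demand_raises(self):
        cfg = small_config(n_markers=2, n_chromosomes=7)
        with pytest.raises(GenerationError):
            make_marker_map(cfg, np.random.default_rng(0))


class TestMeiosis:
    def _two_marker_codes(self, d_cm, n_lines, seed):
        cfg = SimConfig(n_lines=n_lines)
        mm = pd.DataFrame(
            {"locus_id": ["x", "y"], "chrom": [1, 1], "cm": [0.0, d_cm],
             "kind": ["snp", "snp"]}
        )
        return simulate_ril_population(mm, cfg, np.random.default_rng(seed))

    def test_zero_distance_never_recombines(self):
        codes = self._two_marker_codes(0.0, 400, seed=5)
        assert (codes[0] == codes[1]).all()

    def test_ril_recombination_matches_haldane_waddington(self):
        """At 20 cM: r = 0.5(1 - e^-0.4) = 0.1648; RIL-scale R = 2r/(1+2r)
        = 0.248.  Observed fraction must sit within 3 binomial SEs."""
        codes = self._two_marker_codes(20.0, 1000, seed=7)
        hom = (codes[0] != 1) & (codes[1] != 1)
        rec = (codes[0][hom] != codes[1][hom]).mean()
        r = 0.5 * (1 - np.exp(-2 * 20.0 / 100))
        R = 2 * r / (1 + 2 * r)
        se = np.sqrt(R * (1 - R) / hom.sum())
        assert abs(rec - R) < 3 * se

    def test_allele_frequency_near_half(self, gpmx_run):
        freq = (gpmx_run.codes / 2.0).mean()
        assert abs(freq - 0.5) < 0.02

    def test_residual_heterozygosity_expectation(self):
        """Unlinked loci x many lines: het rate = (1/2)^10 within 3 SE.
        (Unlinked so the binomial SE is exact; linked loci share coalescent
        history and would need a far wider band.)"""
        cfg = SimConfig(n_lines=500, n_chromosomes=200,
                        chrom_lengths_cm=tuple([1.0] * 200),
                        n_markers=200, qtls=())
        mm = pd.DataFrame({
            "locus_id": [f"m{i}" for i in range(200)],
            "chrom": np.arange(1, 201), "cm": 0.0, "kind": "snp",
        })
        codes = simulate_ril_population(mm, cfg, np.random.default_rng(13))
        het = (codes == 1).mean()
        expected = 0.5**10
        se = np.sqrt(expected * (1 - expected) / codes.size)
        assert abs(het - expected) < 3 * se


class TestPhenotypes:
    def test_zero_residual_gives_exact_genetic_values(self):
        cfg = SimConfig(line_sd=0.0, year_sd=0.0, n_lines=50)
        run = simulate_population(cfg, seed=2)
        qi = qtl_indices(run.marker_map, cfg)
        dosage = run.codes[qi] / 2.0
        expected = cfg.baseline_height + sum(
            q.effects[0] * dosage[k] for k, q in enumerate(cfg.qtls)
        )
        assert np.allclose(run.phenotypes["height_2009"], expected)
        corr = np.corrcoef(
            run.phenotypes["height_2009"], run.phenotypes["height_2010"]
        )[0, 1]
        # the per-year effect sizes differ slightly, so the noise-free
        # correlation is near (not exactly) one
        assert corr > 0.99

    def test_year_correlation_calibrated(self):
        corrs = [
            np.corrcoef(
                simulate_population(SimConfig(), seed=200 + i).phenotypes[
                    ["height_2009", "height_2010"]
                ].to_numpy().T
            )[0, 1]
            for i in range(6)
        ]
        assert abs(np.mean(corrs) - 0.887) < 0.05

    def test_major_qtl_variance_in_band(self):
        """Marker regression at the major QTL explains 55-62% (+-8) of the
        height variance under the default architecture."""
        varexps = []
        for i in range(6):
            run = simulate_population(SimConfig(), seed=300 + i)
            qi = qtl_indices(run.marker_map, run.config)
            d = run.codes[qi[0]] / 2.0
            for col in ("height_2009", "height_2010"):
                r = np.corrcoef(d, run.phenotypes[col])[0, 1]
                varexps.append(100 * r * r)
        assert 47.0 <= np.median(varexps) <= 70.0

    def test_row_type_follows_its_locus(self):
        run = simulate_population(SimConfig(n_lines=60), seed=4)
        cfg = run.config
        qi = qtl_indices(run.marker_map, cfg)
        row_locus = next(k for k, q in enumerate(cfg.qtls) if q.row_type_locus)
        codes = run.codes[qi[row_locus]]
        expected = np.where(codes == 2, "six", "two")  # two-row allele dominant
        assert (run.phenotypes["row_type"].to_numpy() == expected).all()

    def test_height_range_plausible(self, gpmx_run):
        h = gpmx_run.phenotypes[["height_2009", "height_2010"]].to_numpy()
        assert 40 < h.min() and h.max() < 160


class TestBarcodes:
    def test_set_is_prefix_free_with_overhang(self):
        rng = np.random.default_rng(0)
        codes = make_barcodes(48, rng)
        assert len(set(codes)) == 48
        keyed = sorted(c + "TGCAG" for c in codes)
        for a, b in zip(keyed, keyed[1:]):
            assert not b.startswith(a)
        assert {len(c) for c in codes} == {4, 5, 6, 7, 8}


class TestReads:
    def test_error_free_reads_equal_parental_tags(self, tmp_path):
        cfg = small_config(
            error_rate=0.0, n_rate=0.0, frac_bad_barcode=0.0,
            frac_bad_overhang=0.0, n_cp_contigs=0, depth_scale=0.01,
        )
        run = simulate_run(cfg, seed=9, outdir=tmp_path)
        tag64 = set()
        for tmpl in list(run.genome.templates_a.values()) + list(
            run.genome.templates_b.values()
        ):
            tag64.add(tmpl[:64])
        from gbsmap.demultiplex import iter_fastq

        n = 0
        for fq in run.paths["fastq"]:
            for rid, seq, qual in iter_fastq(fq):
                bc_len = next(
                    len(b)
                    for b in run.library_barcodes[0].values()
                    if seq.startswith(b + "TGCAG")
                )
                assert seq[bc_len : bc_len + 64] in tag64
                n += 1
        assert n == len(run.read_truth.sample)

    def test_planted_error_rate_recovered(self, tmp_path):
        cfg = small_config(
            error_rate=0.005, n_rate=0.0, frac_bad_barcode=0.0,
            frac_bad_overhang=0.0, depth_scale=0.05,
        )
        run = simulate_run(cfg, seed=10, outdir=tmp_path)
        L = cfg.read_len
        n_reads = len(run.read_truth.n_errors)
        frac_with_err = (run.read_truth.n_errors > 0).mean()
        expected = 1 - (1 - 0.005) ** L
        se = np.sqrt(expected * (1 - expected) / n_reads)
        assert abs(frac_with_err - expected) < 3 * se

    def test_per_sample_depth_scales_with_sources(self, tmp_path):
        cfg = small_config(depth_scale=0.05, reads_log_sd=0.05)
        run = simulate_run(cfg, seed=11, outdir=tmp_path)
        truth = run.read_truth
        counts = np.bincount(truth.sample, minlength=len(truth.samples))
        assert (counts > 0).all()
        parents = [truth.samples.index("GP"), truth.samples.index("Mx")]
        progeny = [i for i in range(len(truth.samples)) if i not in parents]
        # parents are sequenced at a 2x depth multiplier
        assert counts[parents].mean() > 1.5 * counts[progeny].mean()


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = small_config(depth_scale=0.02)
        run1 = simulate_run(cfg, seed=42, outdir=tmp_path / "a")
        run2 = simulate_run(cfg, seed=42, outdir=tmp_path / "b")
        for key in ("assembly_a", "assembly_b", "phenotypes", "truth_genotypes",
                    "truth_markers"):
            assert (
                open(run1.paths[key], "rb").read() == open(run2.paths[key], "rb").read()
            )
        for f1, f2 in zip(run1.paths["fastq"], run2.paths["fastq"]):
            assert open(f1, "rb").read() == open(f2, "rb").read()

    def test_different_seed_differs(self, tmp_path):
        cfg = small_config(depth_scale=0.02)
        run1 = simulate_run(cfg, seed=42, outdir=tmp_path / "a")
        run2 = simulate_run(cfg, seed=43, outdir=tmp_path / "b")
        assert (
            open(run1.paths["fastq"][0], "rb").read()
            != open(run2.paths["fastq"][0], "rb").read()
        )
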