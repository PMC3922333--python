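"""Seeded generator of everything the pipeline consumes.

The generator emulates the design of a barley GBS experiment on a
Golden Promise x Morex style F11 recombinant-inbred population:

* two parental haplotypes as FASTA assemblies, each tag locus a contig with
  a planted PstI site (CTGCAG) whose PstI-MseI fragment falls in (or out of)
  the 200-500 bp size-selection window, the parents differing by one
  substitution inside the 64 bp forward flank at every SNP marker locus;
* an F11 single-seed-descent RIL population (default 138 lines) produced by
  ten selfing meioses with Haldane (no-interference) crossover placement on
  the true cM map, leaving the expected (1/2)^10 residual heterozygosity;
* plant heights over two correlated year replicates controlled by three
  QTLs — a major one on chromosome 5 and two minor ones on chromosomes 3
  and 2, the last co-segregating with the two-row/six-row spike-type locus;
* barcoded 100 bp single-end reads with Phred qualities, substitution
  errors, and planted demultiplexing failures, written as one FASTQ per
  48-plex library with both parents replicated in every library.

Background sequence is drawn from the {A,C,T} alphabet so that the only
CTGCAG motifs are the planted ones; every stochastic step derives from one
seed, making runs byte-identical.  Default read depths are desk-scale:
roughly 5k-65k reads per sample, about 100x below a production sequencing
run, with ``depth_scale`` available to change that.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import GenerationError

_ACT = np.frombuffer(b"ACT", dtype=np.uint8)

MOTIF = "CTGCAG"
OVERHANG = "TGCAG"


def _random_act(rng: np.random.Generator, n: int) -> str:
    return _ACT[rng.integers(0, 3, size=n)].tobytes().decode("ascii")


@dataclass(frozen=True)
class QtlSpec:
    """One simulated QTL: map location, per-year additive effects (bb - aa,
    cm of plant height), and whether it doubles as the row-type locus."""

    chrom: int  # 1-based
    cm: float
    effects: tuple[float, ...]
    row_type_locus: bool = False


# Defaults are calibrated to the study conditions being emulated: a major
# height QTL explaining ~55-62% of variance, two minor QTLs, between-year
# height correlation ~0.887, heights spanning roughly 60-130 cm.
DEFAULT_QTLS = (
    QtlSpec(chrom=5, cm=29.7, effects=(27.5, 24.8)),
    QtlSpec(chrom=3, cm=51.6, effects=(9.7, 8.9)),
    QtlSpec(chrom=2, cm=80.5, effects=(-10.1, -6.8), row_type_locus=True),
)


@dataclass
class SimConfig:
    n_chromosomes: int = 7
    chrom_lengths_cm: tuple[float, ...] = (140.0, 190.0, 180.0, 130.0, 190.0, 160.0, 210.0)
    n_markers: int = 1300
    n_extra_tags: int = 200
    dominant_fraction: float = 0.03
    n_cp_contigs: int = 5
    n_lines: int = 138
    selfing_generations: int = 10
    qtls: tuple[QtlSpec, ...] = DEFAULT_QTLS
    years: tuple[int, ...] = (2009, 2010)
    baseline_height: float = 81.5
    line_sd: float = 6.97
    year_sd: float = 5.73
    # a marker-free window adjacent to the major QTL (shared parental
    # haplotype): markers exist up to the QTL on one side, none for
    # gap_width_cm beyond it, mirroring a map whose peak marker sits at the
    # locus with a marker-poor flanking interval
    gap_enabled: bool = True
    gap_width_cm: float = 6.0
    gap_offset_cm: float = 0.5
    # sequencing
    read_len: int = 100
    barcodes_per_library: int = 48
    reads_log_mean: float = float(np.log(18000.0))
    reads_log_sd: float = 0.65
    depth_scale: float = 1.0
    parent_depth_multiplier: float = 2.0
    error_rate: float = 0.002
    n_rate: float = 0.0005
    frac_bad_barcode: float = 0.04
    frac_bad_overhang: float = 0.03
    frag_window: tuple[int, int] = (200, 500)
    flank_pad: int = 70
    parent_a_id: str = "GP"
    parent_b_id: str = "Mx"

    def validate(self) -> None:
        if len(self.chrom_lengths_cm) != self.n_chromosomes:
            raise GenerationError("chrom_lengths_cm must match n_chromosomes")
        if self.n_markers < self.n_chromosomes:
            raise GenerationError("need at least one marker per chromosome")
        for p, name in ((self.dominant_fraction, "dominant_fraction"),
                        (self.error_rate, "error_rate"), (self.n_rate, "n_rate"),
                        (self.frac_bad_barcode, "frac_bad_barcode"),
                        (self.frac_bad_overhang, "frac_bad_overhang")):
            if not 0.0 <= p <= 1.0:
                raise GenerationError(f"{name} must be in [0, 1]")
        if self.n_lines < 2 or self.read_len < 70:
            raise GenerationError("n_lines >= 2 and read_len >= 70 required")

    def total_map_length(self) -> float:
        return float(sum(self.chrom_lengths_cm))


# ---------------------------------------------------------------------------
# marker map and parental genomes


def make_marker_map(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """True map of tag loci: SNP markers, monomorphic and dominant tags, and
    QTL pseudo-loci, sorted by (chrom, cM)."""
    config.validate()
    lengths = np.asarray(config.chrom_lengths_cm, dtype=float)
    per_chrom = np.maximum(
        np.round(config.n_markers * lengths / lengths.sum()).astype(int), 1
    )
    # adjust rounding drift
    while per_chrom.sum() > config.n_markers:
        per_chrom[np.argmax(per_chrom)] -= 1
    while per_chrom.sum() < config.n_markers:
        per_chrom[np.argmin(per_chrom)] += 1

    major = next((q for q in config.qtls if abs(q.effects[0]) ==
                  max(abs(x.effects[0]) for x in config.qtls)), None)
    rows = []
    for c in range(config.n_chromosomes):
        chrom = c + 1
        n = per_chrom[c]
        pos = rng.uniform(0.0, lengths[c], size=n * 3)
        if config.gap_enabled and major is not None and chrom == major.chrom:
            lo_gap = major.cm + config.gap_offset_cm
            keep = (pos <= lo_gap) | (pos > lo_gap + config.gap_width_cm)
            pos = pos[keep]
        if len(pos) < n:
            raise GenerationError("not enough flank space for requested markers")
        pos = np.sort(pos[:n])
        for p in pos:
            rows.append({"chrom": chrom, "cm": float(p), "kind": "snp"})
    n_dom = int(round(config.n_extra_tags * config.dominant_fraction))
    n_mono = config.n_extra_tags - n_dom
    for kind, count in (("dominant", n_dom), ("mono", n_mono)):
        chroms = rng.integers(1, config.n_chromosomes + 1, size=count)
        for chrom in chroms:
            rows.append({
                "chrom": int(chrom),
                "cm": float(rng.uniform(0.0, lengths[chrom - 1])),
                "kind": kind,
            })
    for q in config.qtls:
        rows.append({"chrom": q.chrom, "cm": q.cm, "kind": "qtl"})
        if q.row_type_locus:
            # two markers in complete coupling with the row-type locus
            # (zero recombination by construction)
            rows.append({"chrom": q.chrom, "cm": q.cm, "kind": "snp"})
            rows.append({"chrom": q.chrom, "cm": q.cm, "kind": "snp"})
    df = pd.DataFrame(rows).sort_values(["chrom", "cm"], kind="stable")
    df = df.reset_index(drop=True)
    df["locus_id"] = [
        f"L{c}_{i:05d}_{k}" for i, (c, k) in enumerate(zip(df["chrom"], df["kind"]))
    ]
    return df[["locus_id", "chrom", "cm", "kind"]]


@dataclass
class SimGenome:
    """Parental assemblies plus per-locus layout needed for read simulation."""

    contigs_a: list  # (id, sequence)
    contigs_b: list
    cp_genome: str
    loci: pd.DataFrame  # locus_id, chrom, cm, kind, contig_id, frag_len,
    #                     in_window, snp_offset, null_parent
    templates_a: dict[str, str]  # locus_id -> read template (post-barcode part)
    templates_b: dict[str, str]


def make_parental_genomes(
    config: SimConfig, marker_map: pd.DataFrame, rng: np.random.Generator
) -> SimGenome:
    """Build the two parental assemblies contig-by-contig.

    Each tag locus becomes one contig: left pad, planted CTGCAG, then the
    downstream fragment ending at a planted MseI site (TTAA).  SNP loci get
    one substitution in the forward 64 bp flank; dominant loci lose the
    restriction site in one parent; monomorphic loci are identical.
    """
    lo, hi = config.frag_window
    contigs_a, contigs_b = [], []
    templates_a, templates_b = {}, {}
    rows = []
    pad = config.flank_pad
    tmpl_len = config.read_len + 10
    tag_loci = marker_map[marker_map["kind"] != "qtl"]
    for locus_id, chrom, cm, kind in tag_loci[
        ["locus_id", "chrom", "cm", "kind"]
    ].itertuples(index=False):
        if kind == "snp":
            frag_len = int(rng.integers(lo + 10, hi - 10))
        else:
            frag_len = int(rng.integers(150, 600))
        frag_len = max(frag_len, tmpl_len + 10)
        in_window = lo <= frag_len <= hi
        left = _random_act(rng, pad)
        downstream = _random_act(rng, frag_len)
        downstream = downstream[: frag_len - 10] + "TTAA" + downstream[frag_len - 6 :]
        body = left + MOTIF + downstream
        seq_a = seq_b = body
        snp_offset = -1
        null_parent = ""
        if kind == "snp":
            snp_offset = int(rng.integers(6, 64))  # inside the tag, past the overhang
            pos = pad + 1 + snp_offset  # contig coordinate of the flank base
            ref = body[pos]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            seq_b = body[:pos] + alt + body[pos + 1 :]
        elif kind == "dominant":
            null_parent = str(rng.choice(["A", "B"]))
            ablated = body[:pad] + "A" + body[pad + 1 :]  # CTGCAG -> ATGCAG
            if null_parent == "A":
                seq_a = ablated
            else:
                seq_b = ablated
        contig_id = f"ctg_{locus_id}"
        contigs_a.append((contig_id, seq_a))
        contigs_b.append((contig_id, seq_b))
        # read template: genomic sequence from the overhang onwards
        templates_a[locus_id] = seq_a[pad + 1 : pad + 1 + tmpl_len]
        templates_b[locus_id] = seq_b[pad + 1 : pad + 1 + tmpl_len]
        rows.append({
            "locus_id": locus_id, "chrom": chrom, "cm": cm, "kind": kind,
            "contig_id": contig_id, "frag_len": frag_len,
            "in_window": in_window, "snp_offset": snp_offset,
            "null_parent": null_parent,
        })

    # chloroplast genome + contaminant contigs in the primary assembly
    cp_core = _random_act(rng, 4000)
    cp_genome = cp_core[:1200] + MOTIF + cp_core[1200:2600] + MOTIF + cp_core[2600:]
    for i in range(config.n_cp_contigs):
        start = int(rng.integers(0, len(cp_genome) - 400))
        piece = cp_genome[start : start + 400]
        contigs_b.append((f"cp_contam_{i}", piece))

    loci = pd.DataFrame(rows)
    return SimGenome(contigs_a, contigs_b, cp_genome, loci, templates_a, templates_b)


# ---------------------------------------------------------------------------
# RIL population


def _gamete(
    h0: np.ndarray, h1: np.ndarray, r_adj: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One meiotic product over a chromosome's locus grid (Haldane, i.e. the
    crossover indicator per interval is an independent Bernoulli(r))."""
    n = len(h0)
    switch = rng.random(n - 1) < r_adj if n > 1 else np.empty(0, dtype=bool)
    state = np.empty(n, dtype=np.int8)
    state[0] = rng.integers(0, 2)
    if n > 1:
        state[1:] = state[0] ^ np.cumsum(switch.astype(np.int8)) % 2
    return np.where(state == 0, h0, h1)


def simulate_ril_population(
    marker_map: pd.DataFrame, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Genotype codes (0 = aa, 1 = het, 2 = bb) for every locus x line.

    The F1 is selfed for ``selfing_generations`` rounds, one seed per
    generation; crossovers follow Haldane per-meiosis recombination on the
    true cM positions.
    """
    codes = np.empty((len(marker_map), config.n_lines), dtype=np.int8)
    chrom_slices = []
    r_by_chrom = []
    for chrom, sub in marker_map.groupby("chrom", sort=True):
        idx = sub.index.to_numpy()
        pos = sub["cm"].to_numpy(dtype=float)
        d = np.diff(pos)
        r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
        chrom_slices.append(idx)
        r_by_chrom.append(r)
    for line in range(config.n_lines):
        for idx, r in zip(chrom_slices, r_by_chrom):
            n = len(idx)
            h0 = np.zeros(n, dtype=np.int8)  # parent A haplotype
            h1 = np.ones(n, dtype=np.int8)  # parent B haplotype
            for _ in range(config.selfing_generations):
                g0 = _gamete(h0, h1, r, rng)
                g1 = _gamete(h0, h1, r, rng)
                h0, h1 = g0, g1
            codes[idx, line] = h0 + h1
    return codes


# ---------------------------------------------------------------------------
# phenotypes


def simulate_phenotypes(
    qtl_codes: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
    line_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Two-year plant heights plus row type from the QTL genotypes.

    height = baseline + sum(effect * dosage) + shared line deviation +
    year-specific noise; the variance components are calibrated so the major
    QTL explains ~55-62% of the height variance and the two years correlate
    at ~0.887.  Row type follows the designated locus with the two-row
    allele dominant (heterozygotes are two-rowed).
    """
    n_lines = qtl_codes.shape[1]
    if line_ids is None:
        line_ids = [f"RIL{i+1:03d}" for i in range(n_lines)]
    dosage = qtl_codes.astype(float) / 2.0  # 0, 0.5, 1
    line_dev = rng.normal(0.0, config.line_sd, size=n_lines)
    out = {"line": line_ids}
    for yi, year in enumerate(config.years):
        genetic = config.baseline_height + sum(
            q.effects[min(yi, len(q.effects) - 1)] * dosage[k]
            for k, q in enumerate(config.qtls)
        )
        noise = rng.normal(0.0, config.year_sd, size=n_lines)
        out[f"height_{year}"] = genetic + line_dev + noise
    row_locus = next(
        (k for k, q in enumerate(config.qtls) if q.row_type_locus), None
    )
    if row_locus is not None:
        out["row_type"] = np.where(qtl_codes[row_locus] == 2, "six", "two")
    return pd.DataFrame(out).set_index("line")


# ---------------------------------------------------------------------------
# barcodes and reads


def make_barcodes(n: int, rng: np.random.Generator) -> list[str]:
    """A set of n unique 4-8 nt barcodes whose barcode+TGCAG strings are
    prefix-free (unambiguous longest-match assignment)."""
    barcodes: list[str] = []
    keyed: list[str] = []
    lengths = [4, 5, 6, 7, 8]
    attempts = 0
    while len(barcodes) < n:
        attempts += 1
        if attempts > 100000:
            raise GenerationError("could not build a prefix-free barcode set")
        L = lengths[len(barcodes) % len(lengths)]
        cand = "".join("ACGT"[i] for i in rng.integers(0, 4, size=L))
        key = cand + OVERHANG
        if any(key.startswith(k) or k.startswith(key) for k in keyed):
            continue
        barcodes.append(cand)
        keyed.append(key)
    return barcodes


@dataclass
class ReadTruth:
    """Compact per-read ground truth, one entry per emitted read."""

    sample: np.ndarray  # index into samples list
    locus: np.ndarray  # index into loci table, -1 for junk
    allele: np.ndarray  # 0 = parent A template, 1 = parent B
    n_errors: np.ndarray
    category: np.ndarray  # 0 ok, 1 bad-barcode, 2 bad-overhang, 3 contains-N
    samples: list[str]
    locus_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": [self.samples[i] for i in self.sample],
                "locus": [
                    self.locus_ids[i] if i >= 0 else "" for i in self.locus
                ],
                "allele": self.allele,
                "n_errors": self.n_errors,
                "category": self.category,
            }
        )


def _quality_pool(
    rng: np.random.Generator, read_len: int, size: int = 256
) -> list[str]:
    """Pool of plausible Illumina-like quality strings: high quality sloping
    down 3'-wards, a fraction with a low-quality tail that trimming removes."""
    pool = []
    base = 38.0 - 8.0 * np.arange(read_len) / read_len
    for i in range(size):
        q = np.clip(np.round(base + rng.normal(0, 2.0, size=read_len)), 2, 40)
        if i % 8 == 0:  # low-quality 3' tail
            tail = int(rng.integers(5, min(30, read_len // 2)))
            q[-tail:] = rng.integers(3, 15, size=tail)
        pool.append("".join(chr(int(v) + 33) for v in q))
    return pool


def simulate_gbs_reads(
    genome: SimGenome,
    tag_codes: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
    library_samples: list[list[str]],
    library_barcodes: list[dict[str, str]],
    line_ids: list[str],
    fastq_paths: list[Path],
) -> ReadTruth:
    """Write one FASTQ per library and return the per-read truth table.

    ``tag_codes`` are genotype codes over ``genome.loci`` rows x lines;
    parents are handled as all-a / all-b pseudo-lines.  Per-sample read
    totals are log-normal (desk scale by default); reads are distributed
    over in-window fragment sources in proportion to per-locus efficiency
    weights, with heterozygous lines splitting a locus between both
    parental templates.
    """
    loci = genome.loci
    in_win = loci["in_window"].to_numpy()
    locus_ids = list(loci["locus_id"])
    n_loci = len(loci)
    eff = np.exp(rng.normal(0.0, 0.3, size=n_loci))
    null_parent = loci["null_parent"].to_numpy()
    line_index = {l: i for i, l in enumerate(line_ids)}
    qpool = _quality_pool(rng, config.read_len)

    t_sample, t_locus, t_allele, t_err, t_cat = [], [], [], [], []
    all_samples: list[str] = []
    sample_slot: dict[str, int] = {}
    read_counter = 0

    for lib_idx, (samples, bc_map, path) in enumerate(
        zip(library_samples, library_barcodes, fastq_paths)
    ):
        with open(path, "w") as fh:
            for sample in samples:
                if sample not in sample_slot:
                    sample_slot[sample] = len(all_samples)
                    all_samples.append(sample)
                s_idx = sample_slot[sample]
                barcode = bc_map[sample]
                if sample == config.parent_a_id:
                    codes = np.zeros(n_loci, dtype=np.int8)
                elif sample == config.parent_b_id:
                    codes = np.full(n_loci, 2, dtype=np.int8)
                else:
                    codes = tag_codes[:, line_index[sample]]
                # per-source weights: (locus, allele)
                w_a = np.where((codes == 0) | (codes == 1), eff, 0.0)
                w_b = np.where((codes == 2) | (codes == 1), eff, 0.0)
                het = codes == 1
                w_a[het] *= 0.5
                w_b[het] *= 0.5
                # null alleles: a parent lacking the site contributes no reads
                w_a = np.where((null_parent == "A"), 0.0, w_a)
                w_b = np.where((null_parent == "B"), 0.0, w_b)
                w = np.concatenate([w_a * in_win, w_b * in_win])
                if w.sum() <= 0:
                    continue
                n_reads = int(
                    np.exp(rng.normal(config.reads_log_mean, config.reads_log_sd))
                    * config.depth_scale
                )
                if sample in (config.parent_a_id, config.parent_b_id):
                    n_reads = int(n_reads * config.parent_depth_multiplier)
                n_reads = max(n_reads, 1)
                counts = rng.multinomial(n_reads, w / w.sum())
                for src in np.nonzero(counts)[0]:
                    c = int(counts[src])
                    locus_i = src % n_loci
                    allele = src // n_loci
                    tmpl = (
                        genome.templates_a[locus_ids[locus_i]]
                        if allele == 0
                        else genome.templates_b[locus_ids[locus_i]]
                    )
                    genomic = tmpl[: config.read_len - len(barcode)]
                    base_read = barcode + genomic
                    L = len(base_read)
                    n_err = rng.binomial(L, config.error_rate, size=c)
                    n_ns = rng.binomial(L, config.n_rate, size=c)
                    u_bc = rng.random(c)
                    q_idx = rng.integers(0, len(qpool), size=c)
                    for j in range(c):
                        seq = base_read
                        cat = 0
                        if u_bc[j] < config.frac_bad_barcode:
                            p = int(rng.integers(0, len(barcode)))
                            seq = _mutate(seq, p, rng)
                            cat = 1
                        elif u_bc[j] < config.frac_bad_barcode + config.frac_bad_overhang:
                            p = len(barcode) + int(rng.integers(0, 5))
                            seq = _mutate(seq, p, rng)
                            cat = 2
                        if n_err[j]:
                            for p in rng.integers(0, L, size=n_err[j]):
                                seq = _mutate(seq, int(p), rng)
                        if n_ns[j]:
                            for p in rng.integers(0, L, size=n_ns[j]):
                                seq = seq[:p] + "N" + seq[p + 1 :]
                            if cat == 0:
                                cat = 3
                        qual = qpool[q_idx[j]][:L]
                        fh.write(f"@r{read_counter}\n{seq}\n+\n{qual}\n")
                        read_counter += 1
                        t_sample.append(s_idx)
                        t_locus.append(locus_i)
                        t_allele.append(allele)
                        t_err.append(int(n_err[j]))
                        t_cat.append(cat)
    return ReadTruth(
        sample=np.array(t_sample, dtype=np.int32),
        locus=np.array(t_locus, dtype=np.int32),
        allele=np.array(t_allele, dtype=np.int8),
        n_errors=np.array(t_err, dtype=np.int16),
        category=np.array(t_cat, dtype=np.int8),
        samples=all_samples,
        locus_ids=locus_ids,
    )


def _mutate(seq: str, pos: int, rng: np.random.Generator) -> str:
    old = seq[pos]
    new = str(rng.choice([b for b in "ACGT" if b != old]))
    return seq[:pos] + new + seq[pos + 1 :]


# ---------------------------------------------------------------------------
# orchestrated run


@dataclass
class SimRun:
    """All artefacts of one seeded simulation."""

    config: SimConfig
    marker_map: pd.DataFrame  # every locus incl. QTL pseudo-loci
    genome: SimGenome
    codes: np.ndarray  # loci x lines genotype codes, rows follow marker_map
    phenotypes: pd.DataFrame
    line_ids: list[str]
    library_samples: list[list[str]] = field(default_factory=list)
    library_barcodes: list[dict[str, str]] = field(default_factory=list)
    read_truth: ReadTruth | None = None
    paths: dict[str, object] = field(default_factory=dict)

    def qtl_rows(self) -> pd.DataFrame:
        return self.marker_map[self.marker_map["kind"] == "qtl"]

    def snp_rows(self) -> pd.DataFrame:
        return self.marker_map[self.marker_map["kind"] == "snp"]

    def true_genotype_frame(self) -> pd.DataFrame:
        """Loci x lines frame of a/h/b symbols for the tag loci."""
        sym = np.array(["a", "h", "b"], dtype=object)
        return pd.DataFrame(
            sym[self.codes],
            index=self.marker_map["locus_id"],
            columns=self.line_ids,
        )


def qtl_indices(marker_map: pd.DataFrame, config: SimConfig) -> np.ndarray:
    """Row indices of the QTL pseudo-loci, ordered to match ``config.qtls``."""
    qtl_rows = marker_map[marker_map["kind"] == "qtl"]
    idx = []
    for q in config.qtls:
        match = qtl_rows[
            (qtl_rows["chrom"] == q.chrom) & (np.isclose(qtl_rows["cm"], q.cm))
        ]
        if len(match) != 1:
            raise GenerationError(f"QTL at chrom {q.chrom} / {q.cm} cM not unique")
        idx.append(int(match.index[0]))
    return np.array(idx)


def simulate_population(config: SimConfig, seed: int) -> SimRun:
    """Map + genotypes + phenotypes only (no sequencing); fast path used for
    map- and QTL-scale analyses."""
    root = np.random.default_rng(seed)
    r_map, r_pop, r_phen = root.spawn(3)
    marker_map = make_marker_map(config, r_map)
    codes = simulate_ril_population(marker_map, config, r_pop)
    line_ids = [f"RIL{i+1:03d}" for i in range(config.n_lines)]
    qtl_idx = qtl_indices(marker_map, config)
    phen = simulate_phenotypes(codes[qtl_idx], config, r_phen, line_ids)
    return SimRun(config, marker_map, None, codes, phen, line_ids)


def simulate_run(config: SimConfig, seed: int, outdir) -> SimRun:
    """Full seeded run: genomes, population, phenotypes, reads and truth
    tables, everything written under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(seed)
    r_map, r_pop, r_phen, r_gen, r_bc, r_reads = root.spawn(6)

    marker_map = make_marker_map(config, r_map)
    genome = make_parental_genomes(config, marker_map, r_gen)
    codes = simulate_ril_population(marker_map, config, r_pop)
    line_ids = [f"RIL{i+1:03d}" for i in range(config.n_lines)]
    qtl_idx = qtl_indices(marker_map, config)
    phen = simulate_phenotypes(codes[qtl_idx], config, r_phen, line_ids)

    # libraries: both parents in every library plus a chunk of progeny
    per_lib = config.barcodes_per_library - 2
    chunks = [line_ids[i : i + per_lib] for i in range(0, len(line_ids), per_lib)]
    barcodes = make_barcodes(config.barcodes_per_library, r_bc)
    library_samples, library_barcodes = [], []
    for chunk in chunks:
        samples = [config.parent_a_id, config.parent_b_id] + chunk
        library_samples.append(samples)
        library_barcodes.append({s: b for s, b in zip(samples, barcodes)})

    run = SimRun(
        config, marker_map, genome, codes, phen, line_ids,
        library_samples, library_barcodes,
    )

    # genotype codes over tag loci only, aligned with genome.loci rows
    tag_mask = (marker_map["kind"] != "qtl").to_numpy()
    tag_codes = codes[tag_mask]

    paths: dict[str, object] = {}
    paths["assembly_a"] = outdir / "parent_a_assembly.fa"
    paths["assembly_b"] = outdir / "parent_b_assembly.fa"
    paths["chloroplast"] = outdir / "chloroplast.fa"
    for key, contigs in (("assembly_a", genome.contigs_a), ("assembly_b", genome.contigs_b)):
        with open(paths[key], "w") as fh:
            for cid, seq in contigs:
                fh.write(f">{cid}\n{seq}\n")
    with open(paths["chloroplast"], "w") as fh:
        fh.write(f">chloroplast\n{genome.cp_genome}\n")

    paths["fastq"] = [
        outdir / f"library_{i+1}.fastq" for i in range(len(library_samples))
    ]
    paths["barcodes"] = [
        outdir / f"barcodes_library_{i+1}.tsv" for i in range(len(library_samples))
    ]
    for p, mapping in zip(paths["barcodes"], library_barcodes):
        with open(p, "w") as fh:
            fh.write("sample_id\tbarcode\n")
            for s, b in mapping.items():
                fh.write(f"{s}\t{b}\n")

    run.read_truth = simulate_gbs_reads(
        genome, tag_codes, config, r_reads,
        library_samples, library_barcodes, line_ids, paths["fastq"],
    )

    paths["phenotypes"] = outdir / "phenotypes.tsv"
    phen.to_csv(paths["phenotypes"], sep="\t")
    paths["truth_markers"] = outdir / "truth_marker_map.tsv"
    marker_map.to_csv(paths["truth_markers"], sep="\t", index=False)
    paths["truth_genotypes"] = outdir / "truth_genotypes.tsv"
    run.true_genotype_frame().to_csv(paths["truth_genotypes"], sep="\t")
    paths["config"] = outdir / "sim_config.yaml"
    with open(paths["config"], "w") as fh:
        cfg = dataclasses.asdict(config)
        cfg["qtls"] = [dataclasses.asdict(q) for q in config.qtls]
        cfg["seed"] = seed
        yaml.safe_dump(cfg, fh)
    run.paths = paths
    return run
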