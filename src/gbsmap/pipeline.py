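"""End-to-end orchestration: simulate -> ref-tags -> demux -> map -> call ->
genotypes -> mapbuild -> qtl, with a conserved survivor ledger.

Every stage consumes files the previous stage wrote and persists its own
outputs under the run directory, so a run can resume from any completed
stage.  The ledger records, for every stage, how many items went in, how
many came out, and a histogram of rejection reasons; inputs always equal
outputs plus rejections.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import demultiplex as dx
from . import linkage, qtl as qtl_mod, ref_tags as rt, simulate as sim
from . import variant_filter as vf
from .errors import ConfigurationError, PipelineError
from .genotype_caller import GenotypeMatrix, build_genotype_matrix
from .tag_mapper import TagIndex, accumulate_pileup

DEFAULT_CONFIG: dict = {
    "simulate": {
        "seed": None,  # mandatory
        "n_lines": 138,
        "n_markers": 1300,
        "n_extra_tags": 200,
        "depth_scale": 1.0,
        "error_rate": 0.002,
    },
    "ref_tags": {
        "motif": rt.PSTI_MOTIF,
        "flank_len": 64,
        "min_mismatches": 2,
        "include_no_hit": True,
        "cp_min_identity": 0.90,
        "cp_min_align_len": 64,
    },
    "demux": {"min_q": 20, "out_len": 64},
    "call": {
        "min_alt_reads": 4,
        "min_alt_fraction": 0.1,
        "max_baseq_pct_diff": 5.0,
        "min_quality": 20.0,
        "min_mean_depth": 5.0,
        "max_het_pct": 2.0,
        "min_alt_ref_ratio": 0.5,
    },
    "genotypes": {"hi": 0.8, "lo": 0.2, "min_hom_depth": 3, "min_het_depth": 6},
    "mapbuild": {
        "lod_threshold": 6.0,
        "max_missing": 0.2,
        "max_dxo": 3,
        "seed": 17,
        "n_starts": 10,
    },
    "qtl": {
        "seed": None,  # mandatory
        "step_cm": 1.0,
        "n_perm": 1000,
        "alpha": 0.05,
        "window_cm": 10.0,
        "cofactors": "auto",
    },
}

_MANDATORY_SEEDS = (("simulate", "seed"), ("qtl", "seed"))


def validate_config(config: dict | None) -> dict:
    """Fill defaults, reject unknown keys, require seeds for stochastic stages."""
    config = config or {}
    if not isinstance(config, dict):
        raise ConfigurationError("config must be a mapping of sections")
    out = copy.deepcopy(DEFAULT_CONFIG)
    for section, values in config.items():
        if section not in out:
            raise ConfigurationError(f"unknown config section {section!r}")
        if not isinstance(values, dict):
            raise ConfigurationError(f"section {section!r} must be a mapping")
        for key, val in values.items():
            if key not in out[section]:
                raise ConfigurationError(
                    f"unknown key {key!r} in section {section!r}"
                )
            out[section][key] = val
    for section, key in _MANDATORY_SEEDS:
        if out[section][key] is None:
            raise ConfigurationError(
                f"config value {section}.{key} is mandatory (stochastic stage)"
            )
    return out


def config_hash(config: dict) -> str:
    """Stable short hash of a normalized config (key order independent)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class StageRecord:
    stage: str
    n_in: int
    n_out: int
    reasons: dict = field(default_factory=dict)

    def conserved(self) -> bool:
        return self.n_in == self.n_out + sum(self.reasons.values())


@dataclass
class RunLedger:
    records: list[StageRecord] = field(default_factory=list)
    seed_info: dict = field(default_factory=dict)
    config_digest: str = ""

    def add(self, stage: str, n_in: int, n_out: int, reasons: dict | None = None):
        rec = StageRecord(stage, n_in, n_out, dict(reasons or {}))
        self.records.append(rec)
        return rec

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("stage\tn_in\tn_out\treasons\n")
            for r in self.records:
                reasons = ";".join(f"{k}={v}" for k, v in sorted(r.reasons.items()))
                fh.write(f"{r.stage}\t{r.n_in}\t{r.n_out}\t{reasons}\n")

    def report(self) -> str:
        lines = [f"config {self.config_digest}  seeds {self.seed_info}"]
        for r in self.records:
            lines.append(
                f"{r.stage:<22} in={r.n_in:>9} out={r.n_out:>9} "
                + " ".join(f"{k}={v}" for k, v in sorted(r.reasons.items()))
            )
        return "\n".join(lines)


@dataclass
class RunResult:
    outdir: Path
    config: dict
    ledger: RunLedger
    paths: dict = field(default_factory=dict)


def _done(path: Path) -> bool:
    return path.exists()


def run_pipeline(config: dict | None, outdir, resume: bool = False) -> RunResult:
    """Execute the full pipeline on a simulated dataset.

    With ``resume=True``, stages whose outputs already exist are skipped.
    Raises :class:`PipelineError` on stage failure; completed outputs stay
    on disk.
    """
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ledger = RunLedger(
        seed_info={"simulate": cfg["simulate"]["seed"], "qtl": cfg["qtl"]["seed"]},
        config_digest=config_hash(cfg),
    )
    result = RunResult(outdir, cfg, ledger)
    try:
        _stage_simulate(cfg, outdir, ledger, result, resume)
        _stage_ref_tags(cfg, outdir, ledger, result, resume)
        _stage_demux(cfg, outdir, ledger, result, resume)
        _stage_map_call(cfg, outdir, ledger, result, resume)
        _stage_genotypes(cfg, outdir, ledger, result, resume)
        _stage_mapbuild(cfg, outdir, ledger, result, resume)
        _stage_qtl(cfg, outdir, ledger, result, resume)
    except PipelineError:
        raise
    except Exception as exc:  # keep partial outputs, surface the cause
        ledger.to_tsv(outdir / "run_ledger.partial.tsv")
        raise PipelineError(f"pipeline stage failed: {exc}") from exc
    ledger.to_tsv(outdir / "run_ledger.tsv")
    (outdir / "run_report.txt").write_text(ledger.report() + "\n")
    return result


# ---------------------------------------------------------------------------
# stages


def _sim_config(cfg: dict) -> sim.SimConfig:
    s = cfg["simulate"]
    return sim.SimConfig(
        n_lines=s["n_lines"],
        n_markers=s["n_markers"],
        n_extra_tags=s["n_extra_tags"],
        depth_scale=s["depth_scale"],
        error_rate=s["error_rate"],
    )


def _stage_simulate(cfg, outdir, ledger, result, resume):
    simdir = outdir / "sim"
    marker_path = simdir / "truth_marker_map.tsv"
    if resume and _done(marker_path):
        result.paths["sim"] = simdir
        return
    run = sim.simulate_run(_sim_config(cfg), cfg["simulate"]["seed"], simdir)
    result.paths["sim"] = simdir
    n_reads = len(run.read_truth.sample) if run.read_truth else 0
    ledger.add("simulate", n_reads, n_reads, {})


def _stage_ref_tags(cfg, outdir, ledger, result, resume):
    tags_path = outdir / "tags.fa"
    result.paths["tags"] = tags_path
    if resume and _done(tags_path):
        return
    simdir = result.paths["sim"]
    rc = cfg["ref_tags"]
    primary = rt.read_assembly(simdir / "parent_b_assembly.fa", source="primary")
    extra = rt.read_assembly(simdir / "parent_a_assembly.fa", source="extra")
    cp = rt.read_assembly(simdir / "chloroplast.fa", source="cp")
    p_tags, p_excl, p_sites = rt.extract_all_tags(primary, rc["motif"], rc["flank_len"])
    e_tags, e_excl, _ = rt.extract_all_tags(extra, rc["motif"], rc["flank_len"])
    merged = rt.merge_assemblies(
        p_tags, e_tags, rc["min_mismatches"], rc["include_no_hit"]
    )
    kept, removed = rt.screen_chloroplast(
        merged, cp, rc["cp_min_identity"], rc["cp_min_align_len"]
    )
    rt.write_tags_fasta(kept, tags_path)
    rt.write_exclusion_ledger(p_excl + e_excl, outdir / "tag_exclusions.tsv")
    ledger.add(
        "ref-tags:extract", 2 * len(p_sites), len(p_tags),
        {"excluded-flank": len(p_excl)},
    )
    ledger.add(
        "ref-tags:merge", len(p_tags) + len(e_tags), len(merged),
        {"too-similar-or-duplicate": len(p_tags) + len(e_tags) - len(merged)},
    )
    ledger.add("ref-tags:chloroplast", len(merged), len(kept),
               {"chloroplast": len(removed)})


def _stage_demux(cfg, outdir, ledger, result, resume):
    demux_path = outdir / "demuxed.fastq"
    stats_path = outdir / "demux_stats.tsv"
    result.paths["demux"] = demux_path
    if resume and _done(demux_path) and _done(stats_path):
        return
    simdir = Path(result.paths["sim"])
    dc = cfg["demux"]
    lib_fastqs = sorted(simdir.glob("library_*.fastq"))
    lib_barcodes = sorted(simdir.glob("barcodes_library_*.tsv"))
    if not lib_fastqs:
        raise PipelineError("no library FASTQ files found in simulation output")
    per_sample: dict[str, int] = {}
    rejections = {r: 0 for r in dx.REJECT_REASONS}
    total = 0
    with open(demux_path, "w") as out:
        for fq, bc in zip(lib_fastqs, lib_barcodes):
            barcodes = dx.BarcodeSet.from_tsv(bc)
            for item in dx.demultiplex_fastq(
                fq, barcodes, min_q=dc["min_q"], out_len=dc["out_len"]
            ):
                total += 1
                if isinstance(item, dx.DemuxedRead):
                    per_sample[item.sample_id] = per_sample.get(item.sample_id, 0) + 1
                    out.write(
                        f"@{item.sample_id}|{item.read_id}\n{item.sequence}\n+\n"
                        f"{item.quality_string}\n"
                    )
                else:
                    rejections[item.reason] += 1
    stats = dx.DemuxStats(per_sample, rejections, total)
    stats.to_tsv(stats_path)
    ledger.add("demux", total, stats.assigned, rejections)


def _demuxed_reads(path):
    for read_id, seq, qual in dx.iter_fastq(path):
        sample, _, orig = read_id.partition("|")
        yield dx.DemuxedRead(sample, orig, seq, qual)


def _stage_map_call(cfg, outdir, ledger, result, resume):
    cand_path = outdir / "candidates.npz"
    result.paths["candidates"] = cand_path
    if resume and _done(cand_path):
        return
    simdir = Path(result.paths["sim"])
    samples = _collect_samples(simdir, cfg)
    tags = rt.read_tags_fasta(result.paths["tags"])
    index = TagIndex(tags)
    depths, stats = accumulate_pileup(
        _demuxed_reads(result.paths["demux"]), index, samples
    )
    records = vf.call_candidate_snps(depths, cfg["call"]["min_alt_reads"])
    _save_candidates(cand_path, records, samples, depths.tag_depths())
    ledger.add(
        "map", stats.total, stats.mapped,
        {"ambiguous": stats.ambiguous, "unmapped": stats.unmapped},
    )
    # discovery changes units (reads -> candidate sites); recorded as its own
    # trivially-conserving entry
    ledger.add("candidate-snps", len(records), len(records), {})


def _collect_samples(simdir: Path, cfg) -> list[str]:
    samples: list[str] = []
    for bc in sorted(simdir.glob("barcodes_library_*.tsv")):
        for line in open(bc):
            if line.startswith("sample_id"):
                continue
            s = line.split("\t")[0].strip()
            if s and s not in samples:
                samples.append(s)
    return samples


def _save_candidates(path, records, samples, tag_depths):
    n = len(records)
    S = len(samples)
    arr = {
        "samples": np.array(samples),
        "tag_id": np.array([r.tag_id for r in records]),
        "offset": np.array([r.offset for r in records], dtype=np.int32),
        "ref_allele": np.array([r.ref_allele for r in records]),
        "alt_allele": np.array([r.alt_allele for r in records]),
        "quality": np.array([r.quality for r in records]),
        "multiallelic": np.array([r.multiallelic for r in records], dtype=bool),
        "ref_depths": np.vstack([r.ref_depths for r in records]) if n else np.zeros((0, S), dtype=np.int64),
        "alt_depths": np.vstack([r.alt_depths for r in records]) if n else np.zeros((0, S), dtype=np.int64),
        "mean_ref_baseq": np.vstack([r.mean_ref_baseq for r in records]) if n else np.zeros((0, S)),
        "mean_alt_baseq": np.vstack([r.mean_alt_baseq for r in records]) if n else np.zeros((0, S)),
        "depth_tags": np.array(sorted(tag_depths)),
        "depth_values": np.vstack([tag_depths[t] for t in sorted(tag_depths)])
        if tag_depths else np.zeros((0, S), dtype=np.int64),
    }
    np.savez_compressed(path, **arr)


def _load_candidates(path):
    data = np.load(path, allow_pickle=False)
    samples = [str(s) for s in data["samples"]]
    records = []
    for i in range(len(data["tag_id"])):
        records.append(
            vf.SnpRecord(
                tag_id=str(data["tag_id"][i]),
                offset=int(data["offset"][i]),
                ref_allele=str(data["ref_allele"][i]),
                alt_allele=str(data["alt_allele"][i]),
                quality=float(data["quality"][i]),
                ref_depths=data["ref_depths"][i],
                alt_depths=data["alt_depths"][i],
                mean_ref_baseq=data["mean_ref_baseq"][i],
                mean_alt_baseq=data["mean_alt_baseq"][i],
                multiallelic=bool(data["multiallelic"][i]),
            )
        )
    tag_depths = {
        str(t): data["depth_values"][i] for i, t in enumerate(data["depth_tags"])
    }
    return records, samples, tag_depths


def _stage_genotypes(cfg, outdir, ledger, result, resume):
    # runs together with the filter cascade: records -> VCF -> genotype matrix
    geno_path = outdir / "genotypes.tsv"
    vcf_path = outdir / "snps.vcf"
    result.paths["genotypes"] = geno_path
    result.paths["vcf"] = vcf_path
    if resume and _done(geno_path):
        return
    records, samples, tag_depths = _load_candidates(result.paths["candidates"])
    cc = cfg["call"]
    thresholds = {k: v for k, v in cc.items() if k != "min_alt_reads"}
    sim_cfg = _sim_config(cfg)
    surviving, fledger = vf.apply_filter_cascade(
        records, len(samples), samples,
        sim_cfg.parent_a_id, sim_cfg.parent_b_id,
        tag_depths, thresholds,
    )
    fledger.to_tsv(outdir / "filter_ledger.tsv")
    vf.export_vcf(records, samples, vcf_path)
    ledger.add("filter-cascade", len(records), len(surviving),
               {"filtered": len(records) - len(surviving)})
    gc = cfg["genotypes"]
    matrix, dropped = build_genotype_matrix(
        surviving, samples, sim_cfg.parent_a_id, sim_cfg.parent_b_id,
        hi=gc["hi"], lo=gc["lo"],
        min_hom_depth=gc["min_hom_depth"], min_het_depth=gc["min_het_depth"],
    )
    matrix.to_tsv(geno_path)
    reasons: dict[str, int] = {}
    for r in dropped.values():
        reasons[r] = reasons.get(r, 0) + 1
    ledger.add("genotype-recode", len(surviving), len(matrix.markers), reasons)


def _stage_mapbuild(cfg, outdir, ledger, result, resume):
    map_path = outdir / "map.tsv"
    result.paths["map"] = map_path
    if resume and _done(map_path):
        return
    sim_cfg = _sim_config(cfg)
    matrix = GenotypeMatrix.from_tsv(
        result.paths["genotypes"], sim_cfg.parent_a_id, sim_cfg.parent_b_id
    )
    mc = cfg["mapbuild"]
    gmap = linkage.build_map(
        matrix,
        lod_threshold=mc["lod_threshold"],
        max_missing=mc["max_missing"],
        max_dxo=mc["max_dxo"],
        seed=mc["seed"],
        n_starts=mc["n_starts"],
    )
    gmap.to_tsv(map_path)
    gmap.ledger().to_csv(outdir / "map_group_ledger.tsv", sep="\t", index=False)
    n_in = len(matrix.markers)
    n_coseg = sum(len(v) for v in gmap.redundancy.values())
    ledger.add(
        "mapbuild", n_in, len(gmap.table),
        {
            "cosegregating": n_coseg,
            "missing-filtered": len(gmap.dropped_missing),
            "isolated": len(gmap.isolated),
            "poor-fit": len(gmap.dropped_poor_fit),
        },
    )
    result.genetic_map = gmap


def _stage_qtl(cfg, outdir, ledger, result, resume):
    qdir = outdir / "qtl"
    qdir.mkdir(exist_ok=True)
    result.paths["qtl"] = qdir
    thresholds_path = qdir / "thresholds.json"
    if resume and _done(thresholds_path):
        return
    sim_cfg = _sim_config(cfg)
    matrix = GenotypeMatrix.from_tsv(
        result.paths["genotypes"], sim_cfg.parent_a_id, sim_cfg.parent_b_id
    )
    gmap = linkage.GeneticMap.from_tsv(result.paths["map"])
    if gmap.table.empty:
        raise PipelineError(
            "genetic map has no linkage groups (population too small or LOD "
            "threshold too high); cannot scan for QTLs"
        )
    phen = pd.read_csv(
        Path(result.paths["sim"]) / "phenotypes.tsv", sep="\t", index_col="line"
    )
    qc = cfg["qtl"]
    grid = qtl_mod.genotype_probabilities(gmap, matrix, qc["step_cm"])
    thresholds = {}
    scans = {}
    height_cols = [c for c in phen.columns if c.startswith("height_")]
    for col in height_cols:
        trait = phen[col]
        scan = qtl_mod.interval_scan(trait, grid)
        th = qtl_mod.permutation_threshold(
            trait, grid, qc["n_perm"], qc["alpha"], qc["seed"]
        )
        scan.threshold = th
        thresholds[col] = th
        scan.to_tsv(qdir / f"scan_{col}.tsv")
        scans[col] = scan
        # support intervals per significant group
        rows = []
        for g in scan.significant_groups():
            si1 = qtl_mod.support_interval(scan, 1.0, group=g)
            si2 = qtl_mod.support_interval(scan, 2.0, group=g)
            rows.append({"group": g, "one_lod": si1, "two_lod": si2})
        pd.DataFrame(rows).to_csv(
            qdir / f"support_{col}.tsv", sep="\t", index=False
        )
        # rMQM with the most significant marker(s) as cofactors
        cofs = qc["cofactors"]
        if cofs == "auto":
            cofs = _auto_cofactors(scan, grid)
        if cofs:
            rscan = qtl_mod.rmqm_scan(trait, grid, cofs, qc["window_cm"])
            rscan.threshold = th
            rscan.to_tsv(qdir / f"rmqm_{col}.tsv")
    with open(thresholds_path, "w") as fh:
        json.dump(thresholds, fh, indent=1)
    if "row_type" in phen.columns:
        assoc = qtl_mod.binary_association(matrix, phen["row_type"])
        assoc.to_csv(qdir / "row_type_association.tsv", sep="\t")
        joint = _joint_model(scans, grid, phen, height_cols)
        with open(qdir / "joint_model.json", "w") as fh:
            json.dump(joint, fh, indent=1, default=str)
    ledger.add("qtl", len(height_cols), len(thresholds), {})


def _auto_cofactors(scan, grid, max_cofactors: int = 3) -> list[str]:
    """Peak marker of each significant linkage group, strongest first."""
    if scan.threshold is None:
        return []
    cofs = []
    peaks = scan.group_peaks().sort_values("lod", ascending=False)
    for _, row in peaks.iterrows():
        if row["lod"] < scan.threshold or len(cofs) >= max_cofactors:
            break
        sub = scan.frame[
            (scan.frame["group"] == row["group"]) & (scan.frame["marker"] != "")
        ]
        if len(sub):
            cofs.append(sub.loc[sub["lod"].idxmax(), "marker"])
    return cofs


def _joint_model(scans, grid, phen, height_cols):
    out = {}
    for col in height_cols:
        scan = scans[col]
        loci_markers = _auto_cofactors(scan, grid)
        if not loci_markers:
            continue
        loci = pd.DataFrame(
            {m: grid.marker_dosage(m) for m in loci_markers}, index=grid.lines
        )
        if "row_type" in phen.columns:
            loci["row_type"] = (
                phen["row_type"].reindex(grid.lines) == "six"
            ).astype(float)
        res = qtl_mod.joint_model(phen[col], loci)
        out[col] = {
            "n": res.n,
            "varexp": res.varexp,
            "interaction_f": res.interaction_f,
            "interaction_p": res.interaction_p,
            "effects": res.effects.to_dict(),
        }
    return out
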