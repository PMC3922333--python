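import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from gbsmap.genotype_caller import GenotypeMatrix
from gbsmap import linkage
from gbsmap.qtl import genotype_probabilities
from gbsmap.simulate import SimConfig, simulate_population

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def matrix_from_truth(run, qualities_seed: int = 0) -> GenotypeMatrix:
    """Genotype matrix over the simulator's true SNP-marker genotypes, with
    the parents included as perfectly typed columns."""
    snp = run.marker_map[run.marker_map["kind"] == "snp"]
    sym = np.array(["a", "h", "b"], dtype=object)
    calls = pd.DataFrame(
        sym[run.codes[snp.index.to_numpy()]],
        index=snp["locus_id"],
        columns=run.line_ids,
    )
    calls.insert(0, "GP", "a")
    calls.insert(1, "Mx", "b")
    qual = pd.Series(
        np.random.default_rng(qualities_seed).uniform(20, 60, len(calls)),
        index=calls.index,
    )
    return GenotypeMatrix(calls, "GP", "Mx", qual)


@pytest.fixture(scope="session")
def gpmx_run():
    """One GPMx-scale population: 7 chromosomes, ~1,300 markers, 138 lines."""
    return simulate_population(SimConfig(), seed=101)


@pytest.fixture(scope="session")
def gpmx_matrix(gpmx_run):
    return matrix_from_truth(gpmx_run)


@pytest.fixture(scope="session")
def gpmx_map(gpmx_matrix):
    return linkage.build_map(gpmx_matrix, seed=17)


@pytest.fixture(scope="session")
def gpmx_grid(gpmx_map, gpmx_matrix):
    return genotype_probabilities(gpmx_map, gpmx_matrix)


@pytest.fixture(scope="session")
def e2e_run(tmp_path_factory):
    """One full read-level pipeline run on a mid-size population.

    Sized so chromosomes stay intact at the default LOD-6 grouping while the
    whole run (about one million reads) finishes in around a minute.
    """
    from gbsmap.pipeline import run_pipeline

    outdir = tmp_path_factory.mktemp("e2e")
    cfg = {
        "simulate": {
            "seed": 5,
            "n_lines": 96,
            "n_markers": 520,
            "n_extra_tags": 40,
            "depth_scale": 0.45,
        },
        "qtl": {"seed": 7, "n_perm": 300},
    }
    result = run_pipeline(cfg, outdir)
    return result


def true_chrom_of_marker(marker_id: str) -> int:
    """Recover the simulator's chromosome from a pipeline marker id
    (``ctg_L<chrom>_<i>_snp:<pos>:<dir>:<offset>``)."""
    locus = marker_id.split(":")[0]
    if locus.startswith("ctg_"):
        locus = locus[4:]
    return int(locus[1])
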