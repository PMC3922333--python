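"""QTL scanning: conditional dosages, Haley-Knott scans, permutation
thresholds, rMQM cofactor scans, support intervals, the joint model and
binary-trait association."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from gbsmap.genotype_caller import GenotypeMatrix
from gbsmap.linkage import GeneticMap
from gbsmap.qtl import (
    QtlScan,
    binary_association,
    genotype_probabilities,
    interval_scan,
    joint_model,
    permutation_threshold,
    rmqm_scan,
    support_interval,
)
from gbsmap.simulate import SimConfig, qtl_indices, simulate_population

from .conftest import matrix_from_truth, true_chrom_of_marker


def _tiny_map(markers_cm: dict[str, float]) -> GeneticMap:
    table = pd.DataFrame(
        {"group": 1, "marker": list(markers_cm), "cM": list(markers_cm.values())}
    )
    return GeneticMap(table)


def _tiny_matrix(calls: dict[str, list[str]]):
    frame = pd.DataFrame.from_dict(calls, orient="index")
    frame.columns = [f"p{i}" for i in range(frame.shape[1])]
    return GenotypeMatrix(frame, "GP", "Mx", pd.Series(30.0, index=frame.index))


class TestGenotypeProbabilities:
    def test_called_marker_positions_are_deterministic(self):
        grid = genotype_probabilities(
            _tiny_map({"m1": 0.0, "m2": 20.0}),
            _tiny_matrix({"m1": ["a", "b"], "m2": ["a", "b"]}),
        )
        row = grid.marker_rows["m1"]
        assert grid.dosage[row].tolist() == [0.0, 1.0]

    def test_midpoint_between_concordant_flanks(self):
        grid = genotype_probabilities(
            _tiny_map({"m1": 0.0, "m2": 20.0}),
            _tiny_matrix({"m1": ["a", "b"], "m2": ["a", "b"]}),
        )
        mid = grid.positions.index[grid.positions["cM"] == 10.0][0]
        p_b = grid.dosage[mid]
        assert p_b[0] < 0.05 and p_b[1] > 0.95

    def test_discordant_flanks_at_equal_distance_give_half(self):
        grid = genotype_probabilities(
            _tiny_map({"m1": 0.0, "m2": 20.0}),
            _tiny_matrix({"m1": ["a"], "m2": ["b"]}),
        )
        mid = grid.positions.index[grid.positions["cM"] == 10.0][0]
        assert grid.dosage[mid, 0] == pytest.approx(0.5)

    def test_no_informative_marker_gives_half(self):
        grid = genotype_probabilities(
            _tiny_map({"m1": 0.0, "m2": 20.0}),
            _tiny_matrix({"m1": ["-", "a"], "m2": ["h", "a"]}),
        )
        assert np.allclose(grid.dosage[:, 0], 0.5)

    def test_single_flank_extrapolation(self):
        grid = genotype_probabilities(
            _tiny_map({"m1": 0.0, "m2": 30.0}),
            _tiny_matrix({"m1": ["b"], "m2": ["-"]}),
        )
        end = grid.positions.index[grid.positions["cM"] == 30.0][0]
        assert 0.5 < grid.dosage[end, 0] < 1.0


class TestIntervalScan:
    def _orthogonal_case(self):
        calls = {"m1": ["a", "a", "b", "b"] * 6}
        trait = pd.Series(
            [1.0, -1.0] * 12, index=[f"p{i}" for i in range(24)]
        )
        grid = genotype_probabilities(_tiny_map({"m1": 0.0}), _tiny_matrix(calls))
        return trait, grid

    def test_trait_independent_of_genotype_gives_zero_lod(self):
        trait, grid = self._orthogonal_case()
        scan = interval_scan(trait, grid)
        assert np.allclose(scan.frame["lod"], 0.0, atol=1e-10)

    def test_trait_equal_to_dosage_flags_degenerate(self):
        calls = {"m1": ["a", "b"] * 12}
        grid = genotype_probabilities(_tiny_map({"m1": 0.0}), _tiny_matrix(calls))
        trait = pd.Series(grid.dosage[0], index=grid.lines)
        scan = interval_scan(trait, grid)
        assert bool(scan.frame["degenerate"].iloc[0])

    def test_too_few_lines_rejected(self):
        calls = {"m1": ["a", "b"] * 5}
        grid = genotype_probabilities(_tiny_map({"m1": 0.0}), _tiny_matrix(calls))
        with pytest.raises(ValueError, match="20"):
            interval_scan(pd.Series(1.0, index=grid.lines), grid)

    def test_marker_positions_equal_single_marker_regression(self, gpmx_grid, gpmx_run):
        """Haley-Knott at a fully informative marker is exactly OLS of the
        trait on that marker's 0/1 genotype."""
        trait = gpmx_run.phenotypes["height_2009"]
        scan = interval_scan(trait, gpmx_grid)
        y = trait.reindex(gpmx_grid.lines).to_numpy()
        checked = 0
        for marker, row in list(gpmx_grid.marker_rows.items())[::37]:
            x = gpmx_grid.dosage[row]
            if not np.isin(x, [0.0, 1.0]).all():
                continue  # only the no-missing case reduces exactly
            X = np.column_stack([np.ones_like(x), x])
            beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss1 = float(res[0])
            rss0 = float(((y - y.mean()) ** 2).sum())
            lod = len(y) / 2 * np.log10(rss0 / rss1)
            got = scan.frame.iloc[row]
            assert got["lod"] == pytest.approx(lod, rel=1e-9)
            assert got["effect"] == pytest.approx(beta[1], rel=1e-9)
            checked += 1
        assert checked >= 5

    def test_lod_invariant_under_affine_trait_transform(self, gpmx_grid, gpmx_run):
        trait = gpmx_run.phenotypes["height_2010"]
        s1 = interval_scan(trait, gpmx_grid)
        s2 = interval_scan(3.7 * trait - 120.0, gpmx_grid)
        assert np.allclose(s1.frame["lod"], s2.frame["lod"], atol=1e-8)
        assert np.allclose(s1.frame["varexp"], s2.frame["varexp"], atol=1e-8)


class TestPermutationThreshold:
    def test_alpha_one_gives_minimum(self, gpmx_grid, gpmx_run):
        trait = gpmx_run.phenotypes["height_2009"]
        th = permutation_threshold(trait, gpmx_grid, n_perm=120, alpha=1.0, seed=3)
        # alpha=1 -> 0th quantile -> the smallest max-LOD; must be small but > 0
        assert 0 < th < permutation_threshold(trait, gpmx_grid, 120, 0.05, 3)

    def test_same_seed_is_deterministic(self, gpmx_grid, gpmx_run):
        trait = gpmx_run.phenotypes["height_2009"]
        a = permutation_threshold(trait, gpmx_grid, 150, 0.05, seed=11)
        b = permutation_threshold(trait, gpmx_grid, 150, 0.05, seed=11)
        assert a == b

    def test_low_n_perm_warns(self, gpmx_grid, gpmx_run):
        with pytest.warns(UserWarning, match="noisy"):
            permutation_threshold(
                gpmx_run.phenotypes["height_2009"], gpmx_grid, 50, 0.05, 1
            )


class TestRmqm:
    def test_no_cofactors_reduces_to_plain_scan(self, gpmx_grid, gpmx_run):
        trait = gpmx_run.phenotypes["height_2009"]
        plain = interval_scan(trait, gpmx_grid)
        r = rmqm_scan(trait, gpmx_grid, [])
        assert np.allclose(plain.frame["lod"], r.frame["lod"])

    def test_masking_major_qtl_raises_minor_peak(self, gpmx_grid, gpmx_run):
        trait = gpmx_run.phenotypes["height_2009"]
        plain = interval_scan(trait, gpmx_grid)
        peak = plain.peak()
        sub = plain.frame[
            (plain.frame["group"] == peak["group"]) & (plain.frame["marker"] != "")
        ]
        cof = sub.loc[sub["lod"].idxmax(), "marker"]
        r = rmqm_scan(trait, gpmx_grid, [cof])
        # the chromosome-3 minor QTL gains LOD once the major one is a cofactor
        chrom3_groups = {
            g
            for g in plain.frame["group"].unique()
            if true_chrom_of_marker(
                plain.frame[(plain.frame.group == g) & (plain.frame.marker != "")]
                .marker.iloc[0]
            ) == 3
        }
        mask = plain.frame["group"].isin(chrom3_groups)
        assert r.frame.loc[mask, "lod"].max() > plain.frame.loc[mask, "lod"].max()

    def test_unknown_cofactor_rejected(self, gpmx_grid, gpmx_run):
        with pytest.raises(ValueError, match="not on the map"):
            rmqm_scan(gpmx_run.phenotypes["height_2009"], gpmx_grid, ["nope"])


class TestSupportInterval:
    def _triangle(self):
        cm = np.arange(0.0, 61.0)
        lod = 10.0 - np.abs(cm - 30.0)  # slope 1 LOD / cM
        frame = pd.DataFrame(
            {"group": 1, "cM": cm, "marker": "", "lod": np.clip(lod, 0, None)}
        )
        return QtlScan(frame, n=100)

    def test_one_lod_drop_on_triangular_profile(self):
        assert support_interval(self._triangle(), drop=1.0) == (29.0, 31.0)

    def test_zero_drop_returns_peak_alone(self):
        assert support_interval(self._triangle(), drop=0.0) == (30.0, 30.0)

    def test_plateau_returned_in_full(self):
        frame = pd.DataFrame(
            {"group": 1, "cM": np.arange(10.0), "marker": "",
             "lod": [0, 1, 5, 5, 5, 5, 5, 1, 0, 0]}
        )
        assert support_interval(QtlScan(frame, 50), drop=1.0) == (2.0, 6.0)

    def test_no_significant_peak_returns_none(self):
        scan = self._triangle()
        scan.threshold = 99.0
        assert support_interval(scan, drop=1.0) is None


class TestJointModel:
    def test_single_locus_equals_marker_regression(self, gpmx_grid, gpmx_run):
        trait = gpmx_run.phenotypes["height_2009"]
        scan = interval_scan(trait, gpmx_grid)
        sub = scan.frame[scan.frame["marker"] != ""]
        marker = sub.loc[sub["lod"].idxmax(), "marker"]
        x = gpmx_grid.marker_dosage(marker)
        res = joint_model(trait, pd.DataFrame({marker: x}, index=gpmx_grid.lines))
        row = scan.frame.iloc[gpmx_grid.marker_rows[marker]]
        assert res.varexp == pytest.approx(row["varexp"], abs=1e-6)
        assert res.effects.loc[marker, "effect"] == pytest.approx(row["effect"], abs=1e-9)

    def test_additive_three_qtl_architecture(self):
        """Across replicates the additive model holds: interactions are
        non-significant nearly always and the joint variance explained sits
        near its simulated value."""
        cfg = SimConfig()
        non_sig = 0
        varexps = []
        n_rep = 20
        for seed in range(n_rep):
            run = simulate_population(cfg, seed=900 + seed)
            qi = qtl_indices(run.marker_map, cfg)
            loci = pd.DataFrame(
                {f"q{k}": run.codes[qi[k]] / 2.0 for k in range(3)},
                index=run.line_ids,
            )
            res = joint_model(run.phenotypes["height_2009"], loci)
            non_sig += res.interaction_p >= 0.05
            varexps.append(res.varexp)
        assert non_sig >= int(0.9 * n_rep)
        assert abs(np.median(varexps) - 72.0) <= 8.0  # simulated truth ~72%

    def test_planted_interaction_detected(self):
        cfg = SimConfig()
        detected = 0
        for seed in range(10):
            run = simulate_population(cfg, seed=700 + seed)
            qi = qtl_indices(run.marker_map, cfg)
            loci = pd.DataFrame(
                {f"q{k}": run.codes[qi[k]] / 2.0 for k in range(3)},
                index=run.line_ids,
            )
            trait = run.phenotypes["height_2009"] + 14.0 * loci["q0"] * loci["q1"]
            res = joint_model(trait, loci)
            detected += res.interaction_p < 0.05
        assert detected >= 8

    def test_collinear_loci_reduced_with_warning(self, gpmx_grid, gpmx_run):
        trait = gpmx_run.phenotypes["height_2009"]
        x = gpmx_grid.marker_dosage(next(iter(gpmx_grid.marker_rows)))
        loci = pd.DataFrame({"l1": x, "l2": x}, index=gpmx_grid.lines)
        with pytest.warns(UserWarning, match="collinear"):
            res = joint_model(trait, loci)
        assert res.dropped_collinear == ["l2"]


class TestBinaryAssociation:
    def _matrix_with(self, calls):
        frame = pd.DataFrame.from_dict(calls, orient="index")
        frame.columns = [f"p{i}" for i in range(frame.shape[1])]
        return GenotypeMatrix(frame, "GP", "Mx", pd.Series(dtype=float))

    def test_perfect_cosegregation_flagged(self):
        calls = {"m1": ["a"] * 56 + ["b"] * 80}
        trait = pd.Series(
            ["two"] * 56 + ["six"] * 80, index=[f"p{i}" for i in range(136)]
        )
        out = binary_association(self._matrix_with(calls), trait)
        assert bool(out.loc["m1", "perfect"])
        expected = chi2_contingency(
            [[56, 0], [0, 80]], correction=False
        ).statistic
        assert out.loc["m1", "chi2"] == pytest.approx(expected)

    def test_balanced_table_gives_zero(self):
        calls = {"m1": (["a"] * 30 + ["b"] * 30) * 2}
        trait = pd.Series(
            ["two"] * 60 + ["six"] * 60, index=[f"p{i}" for i in range(120)]
        )
        out = binary_association(self._matrix_with(calls), trait)
        assert out.loc["m1", "chi2"] == 0.0 and not out.loc["m1", "perfect"]

    def test_zero_margin_flagged_zero(self):
        calls = {"m1": ["a"] * 40}
        trait = pd.Series(
            ["two"] * 20 + ["six"] * 20, index=[f"p{i}" for i in range(40)]
        )
        out = binary_association(self._matrix_with(calls), trait)
        assert out.loc["m1", "chi2"] == 0.0 and bool(out.loc["m1", "zero_margin"])

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(8)
        trait = pd.Series(
            rng.choice(["two", "six"], size=136), index=[f"p{i}" for i in range(136)]
        )
        calls = {
            f"m{j}": rng.choice(["a", "b", "-"], size=136, p=[0.46, 0.46, 0.08])
            for j in range(25)
        }
        out = binary_association(self._matrix_with(calls), trait)
        for j in range(25):
            sub = pd.crosstab(
                pd.Series(calls[f"m{j}"]), trait.reset_index(drop=True)
            ).reindex(index=["a", "b"], columns=["six", "two"], fill_value=0)
            if (sub.sum(0) == 0).any() or (sub.sum(1) == 0).any():
                continue
            expected = chi2_contingency(sub.to_numpy(), correction=False)
            assert out.loc[f"m{j}", "chi2"] == pytest.approx(expected.statistic)
            assert out.loc[f"m{j}", "p"] == pytest.approx(expected.pvalue)

    def test_null_chi2_mean_near_one(self):
        rng = np.random.default_rng(21)
        trait = pd.Series(
            (["two"] * 68 + ["six"] * 68), index=[f"p{i}" for i in range(136)]
        )
        calls = {
            f"m{j}": rng.choice(["a", "b"], size=136) for j in range(200)
        }
        out = binary_association(self._matrix_with(calls), trait)
        assert 0.75 < out["chi2"].mean() < 1.3
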