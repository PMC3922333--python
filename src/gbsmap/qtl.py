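"""QTL scanning on the genetic map: interval mapping, permutation thresholds,
cofactor-adjusted (rMQM-style) scans, support intervals, joint multi-locus
regression and marker/binary-trait association.

Interval mapping uses Haley-Knott regression: at each position on a cM grid
the trait is regressed on the expected 'b'-allele dosage given the flanking
marker genotypes, and LOD = (n/2) * log10(RSS0 / RSS1).  For a RIL population
at GBS marker density the difference from full mixture-model interval mapping
is negligible.  Between markers, conditional genotype probabilities follow
Haldane recombination over the RIL-corrected distances; lines are two-class
(a/b) with residual heterozygotes treated as missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_caller import GenotypeMatrix
from .linkage import GeneticMap, encode_ab

LOD_CAP = 300.0


def _ril_recomb(d_cm: np.ndarray | float) -> np.ndarray | float:
    """RIL-scale recombinant fraction across a map distance in cM.

    Haldane per-meiosis r = (1 - exp(-2d/100)) / 2 followed by the
    Haldane-Waddington accumulation R = 2r / (1 + 2r) for selfed RILs.
    """
    r = 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))
    return 2.0 * r / (1.0 + 2.0 * r)


@dataclass
class QtlGrid:
    """Per-line P(b) dosages on a cM grid spanning every linkage group."""

    positions: pd.DataFrame  # columns: group, cM, marker ('' off-marker)
    dosage: np.ndarray  # n_positions x n_lines, P(genotype = b)
    lines: list[str]
    marker_rows: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.positions)

    def marker_dosage(self, marker: str) -> np.ndarray:
        return self.dosage[self.marker_rows[marker]]


def genotype_probabilities(
    gmap: GeneticMap,
    matrix: GenotypeMatrix,
    step_cm: float = 1.0,
) -> QtlGrid:
    """Expected 'b' dosage for every line on a grid over the map.

    The grid is the union of a regular ``step_cm`` lattice and the marker
    positions themselves, so marker-position scans reduce exactly to
    single-marker regression.  At a called marker the probability is 0/1;
    between informative markers it is the two-point conditional probability
    from the flanks; beyond the outermost informative marker a single flank
    is used; lines with no informative marker in a group get 0.5.
    """
    frame = matrix.progeny_frame()
    lines = list(frame.columns)
    rows = []
    dosage_blocks = []
    marker_rows: dict[str, int] = {}
    row_counter = 0
    for g in gmap.groups:
        sub = gmap.group_table(g)
        if len(sub) == 0:
            warnings.warn(f"linkage group {g} is empty; skipped")
            continue
        mpos = sub["cM"].to_numpy(dtype=float)
        mnames = list(sub["marker"])
        present = [m for m in mnames if m in frame.index]
        calls = encode_ab(frame.loc[present])  # markers x lines
        pos_present = np.array(
            [mpos[mnames.index(m)] for m in present], dtype=float
        )
        grid = np.union1d(
            np.arange(0.0, mpos.max() + 1e-9, step_cm), np.round(mpos, 6)
        )
        block = np.full((len(grid), len(lines)), 0.5)
        for li in range(len(lines)):
            obs = ~np.isnan(calls[:, li])
            if not obs.any():
                continue
            opos = pos_present[obs]
            ostate = calls[obs, li]
            left_idx = np.searchsorted(opos, grid, side="right") - 1
            right_idx = np.searchsorted(opos, grid, side="left")
            for gi, gpos in enumerate(grid):
                L = left_idx[gi]
                Rr = right_idx[gi]
                has_left = L >= 0
                has_right = Rr < len(opos)
                if has_left and has_right:
                    rl = _ril_recomb(gpos - opos[L])
                    rr = _ril_recomb(opos[Rr] - gpos)
                    pb = ((rl if ostate[L] == 0 else 1 - rl)
                          * (rr if ostate[Rr] == 0 else 1 - rr))
                    pa = (((1 - rl) if ostate[L] == 0 else rl)
                          * ((1 - rr) if ostate[Rr] == 0 else rr))
                    block[gi, li] = pb / (pa + pb)
                elif has_left:
                    rl = _ril_recomb(gpos - opos[L])
                    block[gi, li] = rl if ostate[L] == 0 else 1 - rl
                elif has_right:
                    rr = _ril_recomb(opos[Rr] - gpos)
                    block[gi, li] = rr if ostate[Rr] == 0 else 1 - rr
        name_at = {round(p, 6): m for m, p in zip(present, pos_present)}
        for gpos in grid:
            marker = name_at.get(round(gpos, 6), "")
            rows.append({"group": g, "cM": float(gpos), "marker": marker})
            if marker:
                marker_rows[marker] = row_counter
            row_counter += 1
        dosage_blocks.append(block)
    positions = pd.DataFrame(rows, columns=["group", "cM", "marker"])
    dosage = np.vstack(dosage_blocks)
    return QtlGrid(positions, dosage, lines, marker_rows)


# ---------------------------------------------------------------------------
# scans


@dataclass
class QtlScan:
    """LOD profile with per-position effect estimates."""

    frame: pd.DataFrame  # group, cM, marker, lod, varexp, effect, se, degenerate
    n: int
    threshold: float | None = None

    def peak(self) -> pd.Series:
        return self.frame.loc[self.frame["lod"].idxmax()]

    def group_peaks(self) -> pd.DataFrame:
        idx = self.frame.groupby("group")["lod"].idxmax()
        return self.frame.loc[idx].reset_index(drop=True)

    def significant_groups(self, threshold: float | None = None) -> list[int]:
        th = threshold if threshold is not None else self.threshold
        if th is None:
            raise ValueError("no LOD threshold available")
        peaks = self.group_peaks()
        return list(peaks.loc[peaks["lod"] >= th, "group"])

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def _prepare_trait(trait: pd.Series, grid: QtlGrid) -> tuple[np.ndarray, np.ndarray]:
    y = trait.reindex(grid.lines).to_numpy(dtype=float)
    mask = ~np.isnan(y)
    return y[mask], mask


def interval_scan(trait: pd.Series, grid: QtlGrid) -> QtlScan:
    """Haley-Knott regression of the trait on expected dosage at each grid
    position.  ``effect`` is the fitted bb - aa class-mean difference."""
    y, mask = _prepare_trait(trait, grid)
    n = len(y)
    if n < 20:
        raise ValueError(f"only {n} lines with trait and genotypes (need >= 20)")
    X = grid.dosage[:, mask]
    yc = y - y.mean()
    syy = float(yc @ yc)
    Xc = X - X.mean(axis=1, keepdims=True)
    sxx = (Xc * Xc).sum(axis=1)
    sxy = Xc @ yc
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(sxx > 0, sxy / np.maximum(sxx, 1e-300), 0.0)
        rss1 = syy - np.where(sxx > 0, sxy**2 / np.maximum(sxx, 1e-300), 0.0)
    rss1 = np.maximum(rss1, 0.0)
    degenerate = rss1 <= 1e-12 * max(syy, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        lod = (n / 2.0) * np.log10(np.maximum(syy, 1e-300) / np.maximum(rss1, 1e-300))
        varexp = 100.0 * (1.0 - rss1 / syy) if syy > 0 else np.zeros_like(rss1)
        se = np.sqrt(
            np.maximum(rss1, 0.0) / max(n - 2, 1) / np.maximum(sxx, 1e-300)
        )
    lod = np.where(degenerate, LOD_CAP, np.minimum(lod, LOD_CAP))
    lod = np.where(sxx > 0, lod, 0.0)
    frame = grid.positions.copy()
    frame["lod"] = lod
    frame["varexp"] = np.clip(varexp, 0.0, 100.0)
    frame["effect"] = beta
    frame["se"] = np.where(sxx > 0, se, np.nan)
    frame["degenerate"] = degenerate
    return QtlScan(frame, n)


def permutation_threshold(
    trait: pd.Series,
    grid: QtlGrid,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Genome-wide LOD threshold from trait permutations.

    Trait values are permuted across lines (whole-line genotype vectors stay
    intact, preserving the marker correlation structure); the (1 - alpha)
    quantile of the per-permutation maximum LOD is returned.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; thresholds will be noisy")
    y, mask = _prepare_trait(trait, grid)
    n = len(y)
    X = grid.dosage[:, mask]
    Xc = X - X.mean(axis=1, keepdims=True)
    xnorm = np.sqrt((Xc * Xc).sum(axis=1))
    ok = xnorm > 1e-12
    Xn = np.zeros_like(Xc)
    Xn[ok] = Xc[ok] / xnorm[ok, None]
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    Y = y[perms]  # n_perm x n
    Yc = Y - Y.mean(axis=1, keepdims=True)
    ynorm = np.sqrt((Yc * Yc).sum(axis=1, keepdims=True))
    Yn = Yc / ynorm
    corr = Yn @ Xn.T  # n_perm x n_positions
    r2max = np.clip((corr**2).max(axis=1), 0.0, 1.0 - 1e-12)
    max_lods = -(n / 2.0) * np.log10(1.0 - r2max)
    return float(np.quantile(max_lods, 1.0 - alpha))


def rmqm_scan(
    trait: pd.Series,
    grid: QtlGrid,
    cofactor_markers: Sequence[str],
    window_cm: float = 10.0,
) -> QtlScan:
    """Cofactor-adjusted scan (restricted multiple-QTL mapping style).

    Cofactor marker genotypes enter the regression as covariates, except
    within ``window_cm`` of the test position on the same group, so each
    cofactor's own region remains scannable.  The LOD compares against the
    cofactor-only null at each position.
    """
    cofactor_markers = list(cofactor_markers)
    if not cofactor_markers:
        return interval_scan(trait, grid)
    missing = [m for m in cofactor_markers if m not in grid.marker_rows]
    if missing:
        raise ValueError(f"cofactors not on the map grid: {missing}")
    y, mask = _prepare_trait(trait, grid)
    n = len(y)
    X = grid.dosage[:, mask]
    C = np.stack([grid.marker_dosage(m)[mask] for m in cofactor_markers])
    cof_pos = grid.positions.iloc[[grid.marker_rows[m] for m in cofactor_markers]]
    cof_group = cof_pos["group"].to_numpy()
    cof_cm = cof_pos["cM"].to_numpy(dtype=float)

    pos_group = grid.positions["group"].to_numpy()
    pos_cm = grid.positions["cM"].to_numpy(dtype=float)
    active_sets: dict[tuple, list[int]] = {}
    for i in range(len(grid)):
        act = tuple(
            j
            for j in range(len(cofactor_markers))
            if not (
                cof_group[j] == pos_group[i]
                and abs(cof_cm[j] - pos_cm[i]) <= window_cm
            )
        )
        active_sets.setdefault(act, []).append(i)
    if all(len(a) == 0 for a in active_sets):
        warnings.warn("every cofactor excluded everywhere; plain scan returned")

    lod = np.zeros(len(grid))
    varexp = np.zeros(len(grid))
    effect = np.zeros(len(grid))
    se = np.full(len(grid), np.nan)
    degenerate = np.zeros(len(grid), dtype=bool)
    for act, rows in active_sets.items():
        if act:
            design = np.column_stack([np.ones(n)] + [C[j] for j in act])
        else:
            design = np.ones((n, 1))
        Q, _ = np.linalg.qr(design)
        resid_y = y - Q @ (Q.T @ y)
        rss0 = float(resid_y @ resid_y)
        Xr = X[rows]
        Xres = Xr - (Xr @ Q) @ Q.T
        sxx = (Xres * Xres).sum(axis=1)
        sxy = Xres @ resid_y
        with np.errstate(invalid="ignore", divide="ignore"):
            beta = np.where(sxx > 1e-12, sxy / np.maximum(sxx, 1e-300), 0.0)
            rss1 = rss0 - np.where(sxx > 1e-12, sxy**2 / np.maximum(sxx, 1e-300), 0.0)
        rss1 = np.maximum(rss1, 0.0)
        dgn = rss1 <= 1e-12 * max(rss0, 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            l = (n / 2.0) * np.log10(
                np.maximum(rss0, 1e-300) / np.maximum(rss1, 1e-300)
            )
            v = 100.0 * (1.0 - rss1 / rss0) if rss0 > 0 else np.zeros_like(rss1)
            s = np.sqrt(rss1 / max(n - 2 - len(act), 1) / np.maximum(sxx, 1e-300))
        idx = np.array(rows)
        lod[idx] = np.where(dgn, LOD_CAP, np.minimum(l, LOD_CAP))
        lod[idx] = np.where(sxx > 1e-12, lod[idx], 0.0)
        varexp[idx] = np.clip(v, 0.0, 100.0)
        effect[idx] = beta
        se[idx] = np.where(sxx > 1e-12, s, np.nan)
        degenerate[idx] = dgn
    frame = grid.positions.copy()
    frame["lod"] = lod
    frame["varexp"] = varexp
    frame["effect"] = effect
    frame["se"] = se
    frame["degenerate"] = degenerate
    return QtlScan(frame, n)


def support_interval(
    scan: QtlScan,
    drop: float = 1.0,
    group: int | None = None,
    threshold: float | None = None,
) -> tuple[float, float] | None:
    """Widest contiguous interval around the peak with LOD >= peak - drop.

    Returns None when no peak reaches the threshold (if one is known).
    """
    frame = scan.frame
    if group is not None:
        frame = frame[frame["group"] == group]
    if frame.empty:
        return None
    peak_idx = frame["lod"].idxmax()
    peak_lod = float(frame.loc[peak_idx, "lod"])
    th = threshold if threshold is not None else scan.threshold
    if th is not None and peak_lod < th:
        return None
    g = frame.loc[peak_idx, "group"]
    sub = frame[frame["group"] == g].reset_index()
    i_peak = int(sub["index"].eq(peak_idx).idxmax())
    ok = sub["lod"].to_numpy() >= peak_lod - drop
    left = i_peak
    while left > 0 and ok[left - 1]:
        left -= 1
    right = i_peak
    while right < len(sub) - 1 and ok[right + 1]:
        right += 1
    return float(sub.loc[left, "cM"]), float(sub.loc[right, "cM"])


# ---------------------------------------------------------------------------
# joint multi-locus model


@dataclass
class JointModelResult:
    n: int
    varexp: float  # joint additive variance explained, percent
    effects: pd.DataFrame  # per locus: effect, se
    interaction_f: float
    interaction_p: float
    dropped_collinear: list[str] = field(default_factory=list)


def joint_model(trait: pd.Series, loci: pd.DataFrame) -> JointModelResult:
    """Additive regression of the trait on several locus dosages.

    ``loci``: lines x loci, numeric dosage (0 = aa, 1 = bb; NaN drops the
    line).  Reports the joint variance explained, per-locus effects with SEs,
    and an F-test of all pairwise interactions against the additive model.
    Collinear loci are reduced with a warning.
    """
    import statsmodels.api as sm

    df = loci.copy()
    df["__y"] = trait.reindex(df.index)
    df = df.dropna()
    y = df.pop("__y").to_numpy(dtype=float)
    Xl = df.to_numpy(dtype=float)
    names = list(df.columns)
    n = len(y)

    dropped: list[str] = []
    keep = []
    seen_cols: list[np.ndarray] = []
    for j, name in enumerate(names):
        trial = seen_cols + [Xl[:, j]]
        mat = np.column_stack([np.ones(n)] + trial)
        if np.linalg.matrix_rank(mat) == mat.shape[1]:
            keep.append(j)
            seen_cols.append(Xl[:, j])
        else:
            dropped.append(name)
    if dropped:
        warnings.warn(f"collinear loci reduced from the joint model: {dropped}")
    names = [names[j] for j in keep]
    Xl = Xl[:, keep]

    X_add = sm.add_constant(Xl)
    fit_add = sm.OLS(y, X_add).fit()
    inter_cols = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            inter_cols.append(Xl[:, i] * Xl[:, j])
    if inter_cols:
        X_full = np.column_stack([X_add] + inter_cols)
        if np.linalg.matrix_rank(X_full) > np.linalg.matrix_rank(X_add):
            fit_full = sm.OLS(y, X_full).fit()
            f_res = fit_full.compare_f_test(fit_add)
            f_stat, f_p = float(f_res[0]), float(f_res[1])
        else:
            f_stat, f_p = 0.0, 1.0
    else:
        f_stat, f_p = 0.0, 1.0
    effects = pd.DataFrame(
        {"effect": fit_add.params[1:], "se": fit_add.bse[1:]}, index=names
    )
    return JointModelResult(
        n=n,
        varexp=float(fit_add.rsquared * 100.0),
        effects=effects,
        interaction_f=f_stat,
        interaction_p=f_p,
        dropped_collinear=dropped,
    )


# ---------------------------------------------------------------------------
# marker / binary-trait association


def binary_association(
    matrix: GenotypeMatrix, binary_trait: pd.Series
) -> pd.DataFrame:
    """Per-marker 2x2 chi-square of independence against a binary trait.

    No continuity correction (the use-case is ranking markers); tables with a
    zero margin get statistic 0 and a flag.  Perfect co-segregation (no
    recombinant in either direction with both classes present) is flagged.
    """
    frame = matrix.progeny_frame()
    levels = sorted(binary_trait.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"binary trait must have 2 levels, got {levels}")
    t = binary_trait.reindex(frame.columns)
    is_l1 = (t == levels[1]).to_numpy()
    known = t.notna().to_numpy()
    X = encode_ab(frame)  # markers x lines; 0=a, 1=b, nan otherwise
    valid = ~np.isnan(X) & known
    b = np.where(valid, X, 0.0)
    a = valid.astype(float) - b
    n11 = (a * (known & ~is_l1)).sum(axis=1)  # a-call, first level
    n12 = (a * is_l1).sum(axis=1)
    n21 = (b * (known & ~is_l1)).sum(axis=1)
    n22 = (b * is_l1).sum(axis=1)
    n = n11 + n12 + n21 + n22
    row1, row2 = n11 + n12, n21 + n22
    col1, col2 = n11 + n21, n12 + n22
    denom = row1 * row2 * col1 * col2
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(
            denom > 0, n * (n11 * n22 - n12 * n21) ** 2 / np.maximum(denom, 1), 0.0
        )
    pvals = stats.chi2.sf(chi2, df=1)
    pvals = np.where(denom > 0, pvals, 1.0)
    perfect = (
        (denom > 0)
        & (((n12 == 0) & (n21 == 0)) | ((n11 == 0) & (n22 == 0)))
    )
    out = pd.DataFrame(
        {
            "chi2": chi2,
            "p": pvals,
            "zero_margin": denom == 0,
            "perfect": perfect,
            "n": n.astype(int),
        },
        index=frame.index,
    )
    return out.sort_values("chi2", ascending=False)


def plot_lod_profiles(
    scans: dict[str, QtlScan], path, threshold: float | None = None
) -> None:
    """LOD profiles per linkage group, one panel per group (optional output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = sorted(next(iter(scans.values())).frame["group"].unique())
    fig, axes = plt.subplots(
        1, len(groups), figsize=(3 * len(groups), 3), sharey=True
    )
    axes = np.atleast_1d(axes)
    for ax, g in zip(axes, groups):
        for label, scan in scans.items():
            sub = scan.frame[scan.frame["group"] == g]
            ax.plot(sub["cM"], sub["lod"], label=label)
        if threshold is not None:
            ax.axhline(threshold, ls=":", color="k")
        ax.set_title(f"group {g}")
        ax.set_xlabel("cM")
    axes[0].set_ylabel("LOD")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
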