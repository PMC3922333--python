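"""Genetic-map construction from an a/b/h genotype matrix.

The stages mirror standard biparental-map building: collapse co-segregating
markers (keeping the highest-quality representative), drop markers with too
much missing data, cluster by the pairwise independence LOD, order each
linkage group with a seeded heuristic that minimises the sum of adjacent
recombination fractions, convert the observed RIL recombinant fractions to
per-meiosis values (Haldane-Waddington, r = R / 2(1-R)) and to centimorgans
with the Haldane map function, and finally prune markers that fit their
neighbours poorly (excess apparent double crossovers).

Heterozygous calls are treated as missing throughout the pair statistics:
an F11 population carries ~0.1% residual heterozygosity, so the information
loss is negligible and the two-class RIL likelihood stays exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .genotype_caller import GenotypeMatrix

DEFAULT_LOD_THRESHOLD = 6.0
DEFAULT_MAX_MISSING = 0.2
DEFAULT_MAX_DXO = 3
DEFAULT_MAX_GAP_CM = 50.0


def encode_ab(frame: pd.DataFrame) -> np.ndarray:
    """Encode an a/b/h/- frame as float {0, 1, nan}; h counts as missing."""
    arr = frame.to_numpy(dtype=object)
    out = np.full(arr.shape, np.nan)
    out[arr == "a"] = 0.0
    out[arr == "b"] = 1.0
    return out


# ---------------------------------------------------------------------------
# redundancy collapse and missing filter


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def collapse_identical(
    matrix: GenotypeMatrix,
    min_overlap: float = 0.5,
    exact_only: bool = False,
) -> tuple[GenotypeMatrix, dict[str, list[str]]]:
    """Collapse markers with identical segregation patterns.

    Two markers join a redundancy group when their non-missing progeny calls
    agree everywhere they are both called and the shared-call count reaches
    ``min_overlap`` of the progeny (``exact_only`` additionally requires
    identical missingness patterns).  Each group is represented by its
    highest-quality member.
    """
    frame = matrix.progeny_frame()
    markers = list(frame.index)
    arr = frame.to_numpy(dtype=object)
    called = arr != "-"
    n_prog = arr.shape[1]
    M = len(markers)
    uf = _UnionFind(M)
    # integer encoding for fast comparison: a=0 b=1 h=2, missing=3
    enc = np.full(arr.shape, 3, dtype=np.int8)
    for code, sym in enumerate(("a", "b", "h")):
        enc[arr == sym] = code
    for i in range(M):
        ei, ci = enc[i], called[i]
        for j in range(i + 1, M):
            cj = called[j]
            shared = ci & cj
            n_shared = int(shared.sum())
            if n_shared < min_overlap * n_prog:
                continue
            if exact_only and not np.array_equal(ci, cj):
                continue
            if not (ei[shared] == enc[j][shared]).all():
                continue
            uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(M):
        groups.setdefault(uf.find(i), []).append(i)
    qual = matrix.qualities
    redundancy: dict[str, list[str]] = {}
    keep: list[str] = []
    for members in groups.values():
        names = [markers[i] for i in members]
        if len(names) == 1:
            keep.append(names[0])
            continue
        rep = max(names, key=lambda m: (qual.get(m, 0.0), m))
        keep.append(rep)
        redundancy[rep] = [m for m in names if m != rep]
    keep_sorted = [m for m in markers if m in set(keep)]
    return matrix.subset(keep_sorted), redundancy


def filter_missing(
    matrix: GenotypeMatrix, max_missing: float = DEFAULT_MAX_MISSING
) -> tuple[GenotypeMatrix, list[str]]:
    """Keep markers whose progeny missing fraction is <= ``max_missing``."""
    frame = matrix.progeny_frame()
    frac = (frame == "-").mean(axis=1)
    kept = list(frame.index[frac <= max_missing])
    dropped = list(frame.index[frac > max_missing])
    return matrix.subset(kept), dropped


# ---------------------------------------------------------------------------
# pairwise linkage statistics


@dataclass(frozen=True)
class MarkerPair:
    marker_1: str
    marker_2: str
    informative_n: int
    r_obs: float
    lod_independence: float


def _lod_from_counts(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Independence LOD from informative counts n and recombinant counts k.

    LOD = k*log10(R/0.5) + (n-k)*log10((1-R)/0.5) with R = k/n, clamped to 0
    for R >= 0.5 (repulsion-side deviations carry no linkage evidence in a/b
    coding).
    """
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.where(n > 0, k / np.maximum(n, 1), np.nan)
        term1 = np.where(k > 0, k * np.log10(np.maximum(2 * R, 1e-300)), 0.0)
        term2 = np.where(
            n - k > 0, (n - k) * np.log10(np.maximum(2 * (1 - R), 1e-300)), 0.0
        )
        lod = term1 + term2
    lod = np.where(np.isnan(R) | (R >= 0.5), 0.0, lod)
    return np.maximum(lod, 0.0)


def pairwise_linkage(calls_1: Sequence[str], calls_2: Sequence[str],
                     marker_1: str = "m1", marker_2: str = "m2") -> MarkerPair:
    """Recombinant fraction and independence LOD for one marker pair."""
    x1 = encode_ab(pd.DataFrame([list(calls_1)]))[0]
    x2 = encode_ab(pd.DataFrame([list(calls_2)]))[0]
    valid = ~np.isnan(x1) & ~np.isnan(x2)
    n = int(valid.sum())
    if n == 0:
        return MarkerPair(marker_1, marker_2, 0, float("nan"), float("nan"))
    k = int((x1[valid] != x2[valid]).sum())
    lod = float(_lod_from_counts(np.array([n]), np.array([k]))[0])
    return MarkerPair(marker_1, marker_2, n, k / n, lod)


def pairwise_matrices(
    X: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs informative counts N, recombinant fraction R and LOD.

    ``X`` is markers x progeny over {0, 1, nan}.
    """
    valid = ~np.isnan(X)
    V = valid.astype(float)
    A = np.where(valid, X, 0.0)  # 1 where call is 'b'
    B = V - A  # 1 where call is 'a'
    N = V @ V.T
    K = A @ B.T + B @ A.T  # recombinant counts
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.where(N > 0, K / np.maximum(N, 1), np.nan)
    LOD = _lod_from_counts(N, K)
    np.fill_diagonal(LOD, 0.0)
    return N.astype(np.int64), R, LOD


# ---------------------------------------------------------------------------
# grouping and ordering


def group_markers(
    lod: np.ndarray, markers: Sequence[str], lod_threshold: float = DEFAULT_LOD_THRESHOLD
) -> tuple[list[list[str]], list[str]]:
    """Single-linkage clustering at the given independence-LOD threshold.

    Returns (groups sorted largest first, isolated markers).
    """
    adj = csr_matrix(lod >= lod_threshold)
    n_comp, labels = connected_components(adj, directed=False)
    comps: dict[int, list[str]] = {}
    for m, lab in zip(markers, labels):
        comps.setdefault(int(lab), []).append(m)
    groups = [g for g in comps.values() if len(g) > 1]
    groups.sort(key=len, reverse=True)
    isolated = [g[0] for g in comps.values() if len(g) == 1]
    return groups, isolated


def _path_cost(order: np.ndarray, D: np.ndarray) -> float:
    return float(D[order[:-1], order[1:]].sum())


def _two_opt(order: np.ndarray, D: np.ndarray, max_sweeps: int = 60) -> np.ndarray:
    """Path 2-opt: segment reversals until no improving move remains."""
    n = len(order)
    order = order.copy()
    for _ in range(max_sweeps):
        improved = False
        for i in range(n - 1):
            js = np.arange(i + 1, n)
            left = D[order[i - 1], order[js]] if i > 0 else np.zeros(len(js))
            old_left = D[order[i - 1], order[i]] if i > 0 else 0.0
            right_idx = js + 1
            inner = right_idx < n
            right = np.zeros(len(js))
            right[inner] = D[order[i], order[right_idx[inner]]]
            old_right = np.zeros(len(js))
            old_right[inner] = D[order[js[inner]], order[right_idx[inner]]]
            delta = (left - old_left) + (right - old_right)
            best = int(np.argmin(delta))
            if delta[best] < -1e-12:
                j = int(js[best])
                order[i : j + 1] = order[i : j + 1][::-1]
                improved = True
        if not improved:
            break
    return order


def order_group(
    R: np.ndarray,
    markers: Sequence[str],
    seed: int = 0,
    n_starts: int = 10,
) -> tuple[list[str], float]:
    """Order markers within a group by minimising adjacent recombination.

    Greedy nearest-neighbour construction from multiple seeded starts,
    polished by 2-opt segment reversal; deterministic given the seed.
    Returns the best order and its objective value.
    """
    m = len(markers)
    if m <= 2:
        return list(markers), 0.0 if m < 2 else float(np.nan_to_num(R[0, 1], nan=0.5))
    D = np.where(np.isnan(R), 0.5, R)
    np.fill_diagonal(D, np.inf)
    rng = np.random.default_rng(seed)
    best_order = None
    best_cost = np.inf
    starts = rng.choice(m, size=min(n_starts, m), replace=False)
    for start in starts:
        order = [int(start)]
        used = np.zeros(m, dtype=bool)
        used[start] = True
        while len(order) < m:
            d = D[order[-1]].copy()
            d[used] = np.inf
            nxt = int(np.argmin(d))
            order.append(nxt)
            used[nxt] = True
        order = _two_opt(np.array(order), D)
        cost = _path_cost(order, D)
        if cost < best_cost - 1e-12:
            best_cost = cost
            best_order = order
    return [markers[i] for i in best_order], best_cost


# ---------------------------------------------------------------------------
# map distances


def ril_to_meiotic_r(R: float) -> float:
    """Invert the Haldane-Waddington relation R = 2r/(1+2r) for selfed RILs."""
    R = min(max(R, 0.0), 0.499999)
    return R / (2.0 * (1.0 - R))


def haldane_cm(r: float) -> float:
    """Haldane map function d = -50 ln(1 - 2r), in centimorgans."""
    r = min(max(r, 0.0), 0.499999)
    return -50.0 * np.log(1.0 - 2.0 * r)


def kosambi_cm(r: float) -> float:
    r = min(max(r, 0.0), 0.499999)
    return 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))


def assign_cm(
    adjacent_R: Sequence[float],
    max_gap_cm: float = DEFAULT_MAX_GAP_CM,
    map_function: str = "haldane",
) -> list[float]:
    """Cumulative cM positions from adjacent observed RIL fractions."""
    import warnings

    fn = haldane_cm if map_function == "haldane" else kosambi_cm
    positions = [0.0]
    for R in adjacent_R:
        if np.isnan(R):
            R = 0.4999
        if R >= 0.5:
            warnings.warn("adjacent recombinant fraction >= 0.5; distance capped")
        d = min(fn(ril_to_meiotic_r(R)), max_gap_cm)
        positions.append(positions[-1] + d)
    return positions


# ---------------------------------------------------------------------------
# poor-fit pruning


def double_crossover_counts(
    frame: pd.DataFrame, ordered_markers: Sequence[str]
) -> dict[str, int]:
    """Apparent double-crossover count per interior marker.

    A progeny contributes when both immediate neighbours carry the same
    homozygous call and the focal marker carries the opposite one.
    """
    X = encode_ab(frame.loc[list(ordered_markers)])
    counts: dict[str, int] = {}
    for idx in range(1, len(ordered_markers) - 1):
        left, mid, right = X[idx - 1], X[idx], X[idx + 1]
        ok = ~np.isnan(left) & ~np.isnan(mid) & ~np.isnan(right)
        dxo = ok & (left == right) & (mid != left)
        counts[ordered_markers[idx]] = int(dxo.sum())
    return counts


# ---------------------------------------------------------------------------
# the assembled map


@dataclass
class GeneticMap:
    """Ordered linkage groups with cM positions plus build bookkeeping."""

    table: pd.DataFrame  # columns: group, marker, cM
    isolated: list[str] = field(default_factory=list)
    redundancy: dict[str, list[str]] = field(default_factory=dict)
    dropped_missing: list[str] = field(default_factory=list)
    dropped_poor_fit: list[str] = field(default_factory=list)
    n_input_markers: int = 0

    @property
    def groups(self) -> list[int]:
        return sorted(self.table["group"].unique())

    def group_table(self, group: int) -> pd.DataFrame:
        return self.table[self.table["group"] == group].reset_index(drop=True)

    def positions(self, markers: Sequence[str]) -> pd.DataFrame:
        return self.table.set_index("marker").loc[list(markers)]

    def total_length(self) -> float:
        return float(
            sum(self.group_table(g)["cM"].max() for g in self.groups)
        )

    def ledger(self) -> pd.DataFrame:
        """Per-group clustered/mapped/co-segregating counts."""
        rows = []
        mapped_markers = set(self.table["marker"])
        for g in self.groups:
            sub = self.group_table(g)
            mapped = len(sub)
            coseg = sum(len(self.redundancy.get(m, [])) for m in sub["marker"])
            rows.append(
                {
                    "group": g,
                    "clustered": mapped + self._poor_fit_in_group(g),
                    "mapped": mapped,
                    "cosegregating": coseg,
                }
            )
        return pd.DataFrame(rows)

    def _poor_fit_in_group(self, group: int) -> int:
        return sum(
            1 for m, g in self._poor_fit_groups.items() if g == group
        ) if hasattr(self, "_poor_fit_groups") else 0

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["cosegregating"] = [
            len(self.redundancy.get(m, [])) for m in out["marker"]
        ]
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GeneticMap":
        df = pd.read_csv(path, sep="\t")
        return cls(df[["group", "marker", "cM"]].copy())


def build_map(
    matrix: GenotypeMatrix,
    lod_threshold: float = DEFAULT_LOD_THRESHOLD,
    max_missing: float = DEFAULT_MAX_MISSING,
    max_dxo: int = DEFAULT_MAX_DXO,
    min_overlap: float = 0.5,
    seed: int = 0,
    n_starts: int = 10,
    max_gap_cm: float = DEFAULT_MAX_GAP_CM,
    map_function: str = "haldane",
) -> GeneticMap:
    """Run the full map-construction cascade on a genotype matrix."""
    n_input = len(matrix.markers)
    reduced, redundancy = collapse_identical(matrix, min_overlap=min_overlap)
    reduced, dropped_missing = filter_missing(reduced, max_missing)
    frame = reduced.progeny_frame()
    markers = list(frame.index)
    X = encode_ab(frame)
    _N, R, LOD = pairwise_matrices(X)
    groups, isolated = group_markers(LOD, markers, lod_threshold)

    marker_pos = {m: i for i, m in enumerate(markers)}
    poor_fit: list[str] = []
    poor_fit_groups: dict[str, int] = {}
    rows = []
    for g_idx, group in enumerate(groups, start=1):
        idx = [marker_pos[m] for m in group]
        subR = R[np.ix_(idx, idx)]
        ordered, _cost = order_group(subR, group, seed=seed + g_idx, n_starts=n_starts)
        # prune poor-fitting markers (excess apparent double crossovers), once
        dxo = double_crossover_counts(frame, ordered)
        bad = [m for m, c in dxo.items() if c > max_dxo]
        if bad:
            poor_fit.extend(bad)
            for m in bad:
                poor_fit_groups[m] = g_idx
            kept = [m for m in ordered if m not in set(bad)]
            idx = [marker_pos[m] for m in kept]
            subR = R[np.ix_(idx, idx)]
            ordered, _cost = order_group(
                subR, kept, seed=seed + g_idx, n_starts=n_starts
            )
        pos_of = {m: marker_pos[m] for m in ordered}
        adj = [
            R[pos_of[a], pos_of[b]] for a, b in zip(ordered, ordered[1:])
        ]
        cms = assign_cm(adj, max_gap_cm=max_gap_cm, map_function=map_function)
        for m, cm in zip(ordered, cms):
            rows.append({"group": g_idx, "marker": m, "cM": round(cm, 4)})

    table = pd.DataFrame(rows, columns=["group", "marker", "cM"])
    gmap = GeneticMap(
        table=table,
        isolated=isolated,
        redundancy=redundancy,
        dropped_missing=dropped_missing,
        dropped_poor_fit=poor_fit,
        n_input_markers=n_input,
    )
    gmap._poor_fit_groups = poor_fit_groups
    return gmap
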