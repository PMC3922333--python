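"""Proportion-rule genotype calling and parental a/b/h recoding.

A sample's genotype at a biallelic site is decided by the fraction of
reference-allele reads: above 0.8 homozygous reference, below 0.2 homozygous
alternative, in between (boundaries included) heterozygous.  Calls backed by
too few reads are recoded as missing: fewer than three for a homozygote,
fewer than six for a heterozygote.  Markers are then recoded against the two
parents — 'a' for the parent-A allele, 'b' for parent B, 'h' heterozygous —
and dropped when either parent is missing, heterozygous, or the parents are
identical at the site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

HOM_REF = "hom_ref"
HOM_ALT = "hom_alt"
HET = "het"
MISSING = "missing"

DROP_PARENT_MISSING = "parent-missing"
DROP_PARENT_HET = "parent-het"
DROP_PARENTS_IDENTICAL = "parents-identical"

MISSING_SYMBOL = "-"


@dataclass(frozen=True)
class GenotypeCall:
    state: str
    depth: int
    p_ref: float  # nan when depth == 0


def call_genotype(
    ref_depth: int,
    alt_depth: int,
    hi: float = 0.8,
    lo: float = 0.2,
    min_hom_depth: int = 3,
    min_het_depth: int = 6,
) -> GenotypeCall:
    """Call one sample at one site from its allele depths."""
    depth = ref_depth + alt_depth
    if depth == 0:
        return GenotypeCall(MISSING, 0, float("nan"))
    p_ref = ref_depth / depth
    if p_ref > hi:
        state = HOM_REF
    elif p_ref < lo:
        state = HOM_ALT
    else:
        state = HET
    if state in (HOM_REF, HOM_ALT) and depth < min_hom_depth:
        state = MISSING
    elif state == HET and depth < min_het_depth:
        state = MISSING
    return GenotypeCall(state, depth, p_ref)


def call_genotypes_vector(
    ref_depths: np.ndarray,
    alt_depths: np.ndarray,
    hi: float = 0.8,
    lo: float = 0.2,
    min_hom_depth: int = 3,
    min_het_depth: int = 6,
) -> np.ndarray:
    """Vectorised :func:`call_genotype` over samples; returns a state array."""
    ref = np.asarray(ref_depths, dtype=float)
    alt = np.asarray(alt_depths, dtype=float)
    depth = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(depth > 0, ref / np.maximum(depth, 1), np.nan)
    out = np.full(ref.shape, MISSING, dtype=object)
    hom_ref = (depth > 0) & (p > hi) & (depth >= min_hom_depth)
    hom_alt = (depth > 0) & (p < lo) & (depth >= min_hom_depth)
    het = (depth > 0) & (p >= lo) & (p <= hi) & (depth >= min_het_depth)
    out[hom_ref] = HOM_REF
    out[hom_alt] = HOM_ALT
    out[het] = HET
    return out


@dataclass
class GenotypeMatrix:
    """Markers x samples grid over {a, b, h, -} with parental metadata."""

    calls: pd.DataFrame  # index: marker ids; columns: sample ids
    parent_a_id: str
    parent_b_id: str
    qualities: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    @property
    def markers(self) -> list[str]:
        return list(self.calls.index)

    @property
    def samples(self) -> list[str]:
        return list(self.calls.columns)

    def progeny_ids(self) -> list[str]:
        return [
            s for s in self.calls.columns if s not in (self.parent_a_id, self.parent_b_id)
        ]

    def progeny_frame(self) -> pd.DataFrame:
        return self.calls[self.progeny_ids()]

    def subset(self, markers: Sequence[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.calls.loc[list(markers)],
            self.parent_a_id,
            self.parent_b_id,
            self.qualities.reindex(list(markers)).dropna()
            if len(self.qualities)
            else self.qualities,
        )

    def to_tsv(self, path) -> None:
        out = self.calls.copy()
        out.insert(0, "quality", self.qualities.reindex(out.index))
        out.to_csv(path, sep="\t", index_label="marker")

    @classmethod
    def from_tsv(cls, path, parent_a_id: str, parent_b_id: str) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="marker", dtype=str)
        qual = pd.to_numeric(df.pop("quality"), errors="coerce") if "quality" in df else pd.Series(dtype=float)
        return cls(df, parent_a_id, parent_b_id, qual)


def recode_parental(
    states: np.ndarray,
    samples: Sequence[str],
    parent_a_id: str,
    parent_b_id: str,
) -> tuple[np.ndarray, None] | tuple[None, str]:
    """Recode one marker's hom_ref/hom_alt/het states to parental a/b/h coding.

    Returns ``(symbols, None)`` on success (symbols over all samples,
    parents included) or ``(None, reason)`` when the marker must be dropped.
    """
    sample_index = {s: i for i, s in enumerate(samples)}
    try:
        pa = states[sample_index[parent_a_id]]
        pb = states[sample_index[parent_b_id]]
    except KeyError as exc:
        raise ValueError(f"parent {exc} not among samples") from exc
    if pa == MISSING or pb == MISSING:
        return None, DROP_PARENT_MISSING
    if pa == HET or pb == HET:
        return None, DROP_PARENT_HET
    if pa == pb:
        return None, DROP_PARENTS_IDENTICAL
    # map the allele carried by parent A to 'a'
    if pa == HOM_REF:
        mapping = {HOM_REF: "a", HOM_ALT: "b", HET: "h", MISSING: MISSING_SYMBOL}
    else:
        mapping = {HOM_REF: "b", HOM_ALT: "a", HET: "h", MISSING: MISSING_SYMBOL}
    return np.array([mapping[s] for s in states], dtype=object), None


def build_genotype_matrix(
    records,
    samples: Sequence[str],
    parent_a_id: str,
    parent_b_id: str,
    merge_parent_replicates: bool = True,
    **call_kwargs,
) -> tuple[GenotypeMatrix, dict[str, str]]:
    """Call genotypes for a set of SNP records and recode to a/b/h.

    ``records`` are :class:`gbsmap.variant_filter.SnpRecord`; parent
    replicate columns named ``<parent>.repN`` are merged by summing depths
    before calling when ``merge_parent_replicates`` is set.  Returns the
    genotype matrix plus a dict of dropped marker -> reason.
    """
    samples = list(samples)
    rep_groups: dict[str, list[int]] = {}
    if merge_parent_replicates:
        for i, s in enumerate(samples):
            base = s.split(".rep")[0]
            if base in (parent_a_id, parent_b_id) and base != s:
                rep_groups.setdefault(base, []).append(i)
    keep_mask = np.ones(len(samples), dtype=bool)
    for base, idx in rep_groups.items():
        keep_mask[idx] = False
    out_samples = [s for s, k in zip(samples, keep_mask) if k]

    rows = {}
    dropped: dict[str, str] = {}
    qualities = {}
    for rec in records:
        ref = np.asarray(rec.ref_depths, dtype=np.int64)
        alt = np.asarray(rec.alt_depths, dtype=np.int64)
        for base, idx in rep_groups.items():
            j = samples.index(base)
            ref = ref.copy()
            alt = alt.copy()
            ref[j] += ref[idx].sum()
            alt[j] += alt[idx].sum()
        states = call_genotypes_vector(ref[keep_mask], alt[keep_mask], **call_kwargs)
        symbols, reason = recode_parental(states, out_samples, parent_a_id, parent_b_id)
        if reason is not None:
            dropped[rec.marker_id] = reason
            continue
        rows[rec.marker_id] = symbols
        qualities[rec.marker_id] = rec.quality
    calls = pd.DataFrame.from_dict(rows, orient="index", columns=out_samples)
    matrix = GenotypeMatrix(
        calls, parent_a_id, parent_b_id, pd.Series(qualities, dtype=float)
    )
    return matrix, dropped
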