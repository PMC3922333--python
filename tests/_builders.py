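"""Constructed-input builders for the bookkeeping-identity tests.

These build, in memory, synthetic assemblies and tag sets whose exact counts
mirror a real reference-construction run: a primary assembly with a known
number of restriction sites of which a known number of flanks are
edge-blocked, secondary tag sets divergent enough that every tag is added,
and a chloroplast genome containing verbatim copies of a chosen subset of
tags.  Background sequence uses the {A,C,T} alphabet so the only CTGCAG
motifs are the planted ones.
"""

from __future__ import annotations

import numpy as np

from gbsmap.ref_tags import Contig, ReferenceTag

_ACT = np.frombuffer(b"ACT", dtype=np.uint8)
MOTIF = b"CTGCAG"


def _act_matrix(rng, rows, cols):
    return _ACT[rng.integers(0, 3, size=(rows, cols))]


def build_site_accounting_assembly(
    n_sites: int, n_edge_flanks: int, seed: int = 0, sites_per_contig: int = 100
):
    """Assembly with exactly ``n_sites`` PstI sites of which exactly
    ``n_edge_flanks`` flanks are blocked by a contig edge.

    Edge contigs are 70 bp with the site at position 5: the forward flank
    fits, the reverse flank needs position >= 59 and is blocked.  Internal
    contigs carry ``sites_per_contig`` sites spaced 70 bp apart, every flank
    fully inside the contig.
    """
    rng = np.random.default_rng(seed)
    contigs = []

    # edge contigs: one site each, reverse flank blocked
    edge = _act_matrix(rng, n_edge_flanks, 70)
    edge[:, 5:11] = np.frombuffer(MOTIF, dtype=np.uint8)
    for i in range(n_edge_flanks):
        contigs.append(Contig(f"edge{i}", edge[i].tobytes().decode(), "primary"))

    # internal contigs: sites at 60, 130, ... every flank fits
    n_internal = n_sites - n_edge_flanks
    n_full, rest = divmod(n_internal, sites_per_contig)
    length = 60 + 70 * (sites_per_contig - 1) + 6 + 64
    blocks = _act_matrix(rng, n_full, length)
    for k in range(sites_per_contig):
        blocks[:, 60 + 70 * k : 66 + 70 * k] = np.frombuffer(MOTIF, dtype=np.uint8)
    for i in range(n_full):
        contigs.append(Contig(f"int{i}", blocks[i].tobytes().decode(), "primary"))
    if rest:
        tail_len = 60 + 70 * (rest - 1) + 6 + 64
        tail = _act_matrix(rng, 1, tail_len)
        for k in range(rest):
            tail[0, 60 + 70 * k : 66 + 70 * k] = np.frombuffer(MOTIF, dtype=np.uint8)
        contigs.append(Contig("int_tail", tail[0].tobytes().decode(), "primary"))
    return contigs


def build_divergent_tags(n: int, source: str, seed: int):
    """``n`` distinct random tags (TGCAG + 59 random bases): at typical
    Hamming distance ~39 from any independently drawn tag, far beyond any
    merge or duplicate threshold."""
    rng = np.random.default_rng(seed)
    body = _act_matrix(rng, n, 59)
    seen = set()
    tags = []
    i = 0
    while len(tags) < n:
        if i >= len(body):  # top up in the (vanishingly rare) duplicate case
            body = _act_matrix(rng, n, 59)
            i = 0
        seq = "TGCAG" + body[i].tobytes().decode()
        i += 1
        if seq in seen:
            continue
        seen.add(seq)
        tags.append(ReferenceTag(f"{source}:{len(tags)}:F", seq, source, "F"))
    return tags


def build_cp_genome_from_tags(tags, n_copy: int, seed: int, stride: int | None = None):
    """Chloroplast genome containing verbatim copies of ``n_copy`` of the
    given tags (evenly strided), so exactly those tags match at 100%.

    Use tags from single-site contigs here: a tag whose source contig holds
    further restriction sites shares up to 54 genomic bases with the
    neighbouring site's flank, and that neighbour would then also match the
    chloroplast copy within the 6-mismatch screen allowance.
    """
    rng = np.random.default_rng(seed)
    if stride is None:
        stride = max(len(tags) // n_copy, 1)
    chosen = [tags[(i * stride) % len(tags)] for i in range(n_copy)]
    assert len({t.sequence for t in chosen}) == n_copy
    pad = _ACT[rng.integers(0, 3, size=500)].tobytes().decode()
    seq = pad + "".join(t.sequence for t in chosen) + pad
    return Contig("chloroplast", seq, "cp"), [t.tag_id for t in chosen]
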