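"""Nei–Gojobori (1986) counting estimator for synonymous/nonsynonymous divergence.

Implements the classic pathway-counting estimator on a codon alignment:

* per codon, the synonymous site fraction at each position is the fraction
  of the three single-base neighbours that preserve the amino acid, with
  mutations creating a stop codon counted as nonsynonymous opportunities
  (the convention of the original counting method and of the field's
  reference implementations); the three positions sum to ``s`` synonymous
  sites, with ``n = 3 - s``;
* for a pair of codons differing at ``k`` positions, synonymous and
  nonsynonymous differences are averaged over the ``k!`` orderings of
  single-step mutational pathways, excluding pathways that pass through a
  stop codon;
* proportions ``pS = Sd/S`` and ``pN = Nd/N`` are corrected for multiple
  hits with the Jukes–Cantor formula ``K = -(3/4) ln(1 - (4/3) p)``.

All per-codon and per-codon-pair quantities are precomputed into lookup
tables at import, so estimation over thousands of long alignments is a
vectorised table sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

_TABLE = unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
_AA = dict(_TABLE.forward_table)

_BASES = "ACGT"


def _syn_site_count(codon: str) -> float:
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            # a mutation to a stop codon is a nonsynonymous opportunity
            if mut not in STOP_CODONS and _AA[mut] == _AA[codon]:
                syn += 1
        s += syn / 3.0
    return s


def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) differences over mutational pathways."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order, allow_stops):
        cur, sd, nd = c1, 0, 0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                if not allow_stops:
                    return None
                nd += 1  # stop intermediate counted as a nonsynonymous step
            elif _AA.get(nxt) == _AA.get(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    paths = [p for p in (walk(o, False) for o in permutations(diff)) if p is not None]
    if not paths:  # every ordering blocked by a stop intermediate (rare)
        paths = [walk(o, True) for o in permutations(diff)]
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def _build_tables():
    n = len(SENSE_CODONS)
    syn_sites = np.array([_syn_site_count(c) for c in SENSE_CODONS])
    sd = np.zeros((n, n))
    nd = np.zeros((n, n))
    for i, c1 in enumerate(SENSE_CODONS):
        for j, c2 in enumerate(SENSE_CODONS):
            if i <= j:
                sd[i, j], nd[i, j] = _pathway_diffs(c1, c2)
                sd[j, i], nd[j, i] = sd[i, j], nd[i, j]
    return syn_sites, sd, nd


SYN_SITES, SD_TABLE, ND_TABLE = _build_tables()


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction; returns nan when p >= 3/4 (saturated)."""
    if p >= 0.75:
        return math.nan
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


@dataclass(frozen=True)
class PairStats:
    """NG86 statistics for one aligned coding-sequence pair.

    ``S``/``N`` are fractional synonymous/nonsynonymous site counts averaged
    over the two sequences; ``Sd``/``Nd`` pathway-averaged difference counts;
    ``Ks``/``Ka`` the Jukes–Cantor-corrected distances (nan when the
    proportion is saturated, i.e. >= 3/4).
    """

    n_codons: int
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float
    Ka: float

    @property
    def ks_defined(self) -> bool:
        return not math.isnan(self.Ks)


def codon_indices(seq: str) -> np.ndarray:
    """Map an ungapped, in-frame nucleotide sequence to sense-codon indices.

    Codons containing gaps, Ns or stops map to -1 and are excluded from
    counting by :func:`ng86_from_indices`.
    """
    idx = np.empty(len(seq) // 3, dtype=np.int64)
    for k in range(len(idx)):
        idx[k] = CODON_INDEX.get(seq[3 * k : 3 * k + 3], -1)
    return idx


def ng86_from_indices(idx_a: np.ndarray, idx_b: np.ndarray) -> PairStats:
    """NG86 statistics from two equal-length sense-codon index arrays."""
    if idx_a.shape != idx_b.shape:
        raise ValueError("codon index arrays differ in length")
    keep = (idx_a >= 0) & (idx_b >= 0)
    a, b = idx_a[keep], idx_b[keep]
    n_codons = int(a.size)
    if n_codons == 0:
        raise ValueError("no ungapped, unambiguous codon columns to compare")
    S = 0.5 * (SYN_SITES[a].sum() + SYN_SITES[b].sum())
    N = 3.0 * n_codons - S
    Sd = float(SD_TABLE[a, b].sum())
    Nd = float(ND_TABLE[a, b].sum())
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    return PairStats(
        n_codons=n_codons,
        S=float(S),
        N=float(N),
        Sd=Sd,
        Nd=Nd,
        pS=pS,
        pN=pN,
        Ks=jukes_cantor(pS),
        Ka=jukes_cantor(pN),
    )


def ng86_stats(aln_a: str, aln_b: str) -> PairStats:
    """NG86 statistics for a codon alignment given as two gapped sequences.

    Columns containing gaps, ambiguous bases or stop codons are excluded
    from site and difference counting.
    """
    if len(aln_a) != len(aln_b):
        raise ValueError("aligned sequences differ in length")
    if len(aln_a) % 3 != 0:
        raise ValueError("alignment length is not a multiple of 3")
    return ng86_from_indices(codon_indices(aln_a), codon_indices(aln_b))
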