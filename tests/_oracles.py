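"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities from first principles (translation
tables, regular expressions, exhaustive enumeration) rather than sharing
code with the implementation under test.
"""

from __future__ import annotations

import itertools
import math
import re

from Bio.Seq import Seq

STOPS = {"TAA", "TAG", "TGA"}


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


# -- Nei-Gojobori counting ---------------------------------------------------

def ng_sites_codon(codon: str) -> float:
    """Synonymous sites of one codon: per position, the fraction of the three
    mutations that are synonymous; mutations to stops are nonsynonymous."""
    s = 0.0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if mut not in STOPS and _aa(mut) == _aa(codon):
                s += 1.0 / 3.0
    return s


def ng_diffs_codon_pair(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (Sd, Nd) for one codon pair: enumerate all orderings
    of the differing positions, drop pathways with stop intermediates (fall
    back to all pathways, stop steps nonsynonymous, if none survive)."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0

    def path_codons(order):
        cur = c1
        chain = [cur]
        for p in order:
            cur = cur[:p] + c2[p] + cur[p + 1:]
            chain.append(cur)
        return chain

    chains = [path_codons(o) for o in itertools.permutations(positions)]
    valid = [ch for ch in chains if not any(c in STOPS for c in ch[1:-1])]
    use, stop_is_nonsyn = (valid, False) if valid else (chains, True)
    sds, nds = [], []
    for ch in use:
        sd = nd = 0
        for x, y in zip(ch, ch[1:]):
            if x in STOPS or y in STOPS:
                nd += 1
            elif _aa(x) == _aa(y):
                sd += 1
            else:
                nd += 1
        sds.append(sd)
        nds.append(nd)
    return sum(sds) / len(sds), sum(nds) / len(nds)


def ng_counts(codons_a: list[str], codons_b: list[str]):
    """(S, N, Sd, Nd) for an alignment given as parallel codon lists."""
    S = 0.5 * (sum(map(ng_sites_codon, codons_a))
               + sum(map(ng_sites_codon, codons_b)))
    N = 3.0 * len(codons_a) - S
    Sd = Nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        sd, nd = ng_diffs_codon_pair(ca, cb)
        Sd += sd
        Nd += nd
    return S, N, Sd, Nd


# -- microsatellites ---------------------------------------------------------

def _primitive(motif: str) -> bool:
    return all(motif != motif[:d] * (len(motif) // d)
               for d in range(1, len(motif)) if len(motif) % d == 0)


def regex_microsatellites(seq: str, thresholds: dict[int, int],
                          min_flank: int):
    """Regex-based tandem-repeat finder; returns tuples
    (start, end, unit, repeats, motif, passes_flank) after the same
    leftmost-longest cross-unit resolution rule."""
    candidates = []
    for unit, thr in thresholds.items():
        pat = re.compile(r"(.{%d})\1{%d,}" % (unit, thr - 1))
        for m in pat.finditer(seq):
            motif = m.group(1)
            if any(c not in "ACGT" for c in motif) or not _primitive(motif):
                continue
            reps = len(m.group(0)) // unit
            candidates.append((m.start(), m.start() + unit * reps, unit,
                               reps, motif))
    candidates.sort(key=lambda c: (c[0], -(c[1] - c[0]), c[2]))
    out, last_end = [], -1
    for start, end, unit, reps, motif in candidates:
        if start < last_end:
            continue
        last_end = end
        out.append((start, end, unit, reps, motif,
                    start > min_flank and len(seq) - end > min_flank))
    return out


# -- hypergeometric upper tail ----------------------------------------------

def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by direct summation of the hypergeometric pmf."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
        if n - j <= N - K
    ) / total


# -- local alignment (Gotoh, affine gaps, first gap base costs `open`) -------

def local_align_score(a: str, b: str, match=1.0, mismatch=-2.0,
                      gap_open=-5.0, gap_extend=-2.0) -> float:
    NEG = -1e9
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend)
            sub = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(0.0,
                          max(M[i - 1][j - 1], X[i - 1][j - 1],
                              Y[i - 1][j - 1]) + sub)
            best = max(best, M[i][j], X[i][j], Y[i][j])
    return best
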