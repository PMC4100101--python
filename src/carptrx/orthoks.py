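"""Ortholog identification, Ks estimation and molecular-clock dating.

Orthologs between the two transcript sets are defined operationally as
reciprocal best hits under BLASTN-like local alignment scoring (match +1,
mismatch -2, gap open -5, extend -2), kept only when aligned over 300 bp.
Each ortholog pair's coding regions are aligned globally at the protein
level (BLOSUM62, affine gaps) and back-threaded to codons; synonymous
divergence Ks is then estimated with the Nei–Gojobori counting method
(:mod:`carptrx.ng86`). The Ks values are binned at 0.002 and the modal bin
— the divergence peak — is converted to an absolute age with a synonymous
molecular clock, T = Ks_peak / (2r per-lineage rate expressed pairwise),
here simply T = peak Ks / rate with the rate already on the pairwise scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .config import AlignmentScoring
from .io import TranscriptRecord
from .ng86 import PairStats, ng86_stats


@dataclass(frozen=True)
class BestHit:
    query: str
    target: str
    score: float
    aln_length: int  # alignment columns, gaps included


@dataclass(frozen=True)
class OrthologPair:
    """A reciprocal-best-hit ortholog pair with its codon alignment and
    NG86 statistics."""

    id_a: str
    id_b: str
    aln_a: str
    aln_b: str
    stats: PairStats


@dataclass(frozen=True)
class KsDistribution:
    """Binned Ks histogram (half-open bins labelled by left edge)."""

    bin_width: float
    counts: dict[float, int]
    n_pairs: int
    n_undefined: int

    @property
    def peak_ks(self) -> float | None:
        """Left edge of the modal bin; ties resolved to the lower edge."""
        if not self.counts:
            return None
        best = max(self.counts.items(), key=lambda kv: (kv[1], -kv[0]))
        return best[0]


@dataclass(frozen=True)
class DatingResult:
    peak_ks: float
    rate: float
    t_years: float
    t_my: float  # millions of years, truncated to one decimal
    t_low_years: float | None = None
    t_high_years: float | None = None
    t_low_my: float | None = None
    t_high_my: float | None = None


def _nucleotide_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def all_pairs_best_hits(
    set_a: list[TranscriptRecord],
    set_b: list[TranscriptRecord],
    scoring: AlignmentScoring | None = None,
) -> dict[str, BestHit]:
    """Best local-alignment hit in ``set_b`` for every query in ``set_a``.

    Ties on score are broken by longer alignment, then lexicographic
    target id. Exhaustive all-vs-all scoring — intended for the desk-scale
    catalogs this toolkit targets, not genome-scale BLAST replacement.
    """
    if not set_a or not set_b:
        raise ValueError("both transcript sets must be nonempty")
    scoring = scoring or AlignmentScoring()
    aligner = _nucleotide_aligner(scoring)
    hits: dict[str, BestHit] = {}
    for q in set_a:
        best: BestHit | None = None
        for t in set_b:
            alns = aligner.align(q.seq, t.seq)
            score = alns.score
            length = alns[0].length
            cand = BestHit(q.id, t.id, score, length)
            if (best is None
                    or (cand.score, cand.aln_length, ) > (best.score, best.aln_length)
                    or ((cand.score, cand.aln_length) == (best.score, best.aln_length)
                        and cand.target < best.target)):
                best = cand
        hits[q.id] = best
    return hits


def reciprocal_best_hits(
    hits_ab: dict[str, BestHit],
    hits_ba: dict[str, BestHit],
    min_aln: int = 300,
) -> list[tuple[str, str]]:
    """Pairs (a, b) that are mutual best hits aligned over ``min_aln`` bp."""
    pairs = []
    for a, hit in sorted(hits_ab.items()):
        b = hit.target
        back = hits_ba.get(b)
        if back is not None and back.target == a and hit.aln_length >= min_aln:
            pairs.append((a, b))
    return pairs


def build_codon_alignment(
    cds_a: str,
    cds_b: str,
    scoring: AlignmentScoring | None = None,
    id_a: str = "a",
    id_b: str = "b",
) -> tuple[str, str]:
    """Codon alignment via global protein alignment back-threading.

    The coding sequences (in frame, no stop codons) are translated, aligned
    globally with BLOSUM62 and affine gaps, and every protein gap becomes a
    codon gap. Raises ``ValueError`` on internal stops or frame problems.
    """
    scoring = scoring or AlignmentScoring()
    prots = []
    for name, cds in ((id_a, cds_a), (id_b, cds_b)):
        if len(cds) % 3 != 0:
            raise ValueError(f"length of {name} is not a multiple of 3")
        prot = str(Seq(cds).translate())
        if "*" in prot:
            raise ValueError(f"internal stop codon in {name}")
        prots.append(prot)

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = scoring.protein_gap_open
    aligner.extend_gap_score = scoring.protein_gap_extend
    aln = aligner.align(prots[0], prots[1])[0]
    pa, pb = str(aln[0]), str(aln[1])

    out = []
    for cds, gapped in ((cds_a, pa), (cds_b, pb)):
        pos = 0
        codons = []
        for aa in gapped:
            if aa == "-":
                codons.append("---")
            else:
                codons.append(cds[pos : pos + 3])
                pos += 3
        if pos != len(cds):
            raise ValueError("back-threading did not consume the full CDS")
        out.append("".join(codons))
    return out[0], out[1]


def analyze_ortholog_pair(
    rec_a: TranscriptRecord,
    rec_b: TranscriptRecord,
    cds_a: str,
    cds_b: str,
    scoring: AlignmentScoring | None = None,
) -> OrthologPair:
    aln_a, aln_b = build_codon_alignment(cds_a, cds_b, scoring,
                                         rec_a.id, rec_b.id)
    return OrthologPair(rec_a.id, rec_b.id, aln_a, aln_b,
                        ng86_stats(aln_a, aln_b))


def ks_histogram(ks_values, bin_width: float = 0.002) -> KsDistribution:
    """Bin Ks estimates into half-open bins [k*w, (k+1)*w).

    Undefined estimates (nan/None, from saturated pS >= 3/4) are excluded
    from the bins and counted in ``n_undefined``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    counts: dict[float, int] = {}
    n_pairs = 0
    n_undefined = 0
    for v in ks_values:
        n_pairs += 1
        if v is None or (isinstance(v, float) and math.isnan(v)):
            n_undefined += 1
            continue
        # small epsilon so values sitting exactly on a bin edge (up to float
        # representation) land in the bin they label
        idx = int(math.floor(v / bin_width + 1e-9))
        edge = round(idx * bin_width, 10)
        counts[edge] = counts.get(edge, 0) + 1
    return KsDistribution(bin_width, counts, n_pairs, n_undefined)


def _truncate_my(years: float) -> float:
    return math.floor(years / 1e6 * 10) / 10


def date_divergence(
    peak_ks: float,
    rate: float = 3.51e-9,
    mode_interval: tuple[float, float] | None = None,
) -> DatingResult:
    """Convert a Ks peak to an age under a constant synonymous clock.

    T = peak_ks / rate, with the rate in substitutions per synonymous site
    per year on the pairwise scale. ``t_my`` is reported in millions of
    years truncated (not rounded) to one decimal. An optional mode interval
    of Ks values propagates to an age range the same way.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if peak_ks < 0:
        raise ValueError("peak_ks must be >= 0")
    t = peak_ks / rate
    res = {"peak_ks": peak_ks, "rate": rate, "t_years": t,
           "t_my": _truncate_my(t)}
    if mode_interval is not None:
        lo, hi = sorted(mode_interval)
        res.update(
            t_low_years=lo / rate, t_high_years=hi / rate,
            t_low_my=_truncate_my(lo / rate), t_high_my=_truncate_my(hi / rate),
        )
    return DatingResult(**res)


def ortholog_ks_pipeline(
    set_a: list[TranscriptRecord],
    set_b: list[TranscriptRecord],
    min_orf_aa: int = 50,
    min_aln: int = 300,
    bin_width: float = 0.002,
    scoring: AlignmentScoring | None = None,
) -> tuple[list[OrthologPair], KsDistribution]:
    """Full ortholog/Ks stage: RBH pairs → ORF regions → codon alignments →
    NG86 → binned Ks distribution. Pairs whose members lack an intact ORF
    of the required length are dropped."""
    from .catalog import find_best_orf, orf_region

    hits_ab = all_pairs_best_hits(set_a, set_b, scoring)
    hits_ba = all_pairs_best_hits(set_b, set_a, scoring)
    rbh = reciprocal_best_hits(hits_ab, hits_ba, min_aln)
    by_a = {r.id: r for r in set_a}
    by_b = {r.id: r for r in set_b}
    pairs = []
    for a, b in rbh:
        ra, rb = by_a[a], by_b[b]
        ca, cb = find_best_orf(ra, min_orf_aa), find_best_orf(rb, min_orf_aa)
        if not (ca.is_coding and cb.is_coding):
            continue
        pairs.append(analyze_ortholog_pair(
            ra, rb, orf_region(ra, ca), orf_region(rb, cb), scoring))
    hist = ks_histogram((p.stats.Ks for p in pairs), bin_width)
    return pairs, hist
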