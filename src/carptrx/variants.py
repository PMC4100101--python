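"""Polymorphic-site calling, allele multiplicity, and microsatellites.

Sites are called from pooled read pileups at a minimum coverage of 5; a
base counts as an allele when it is supported by at least 2 reads and at
least 10% of the site's coverage (both configurable) — tri-allelic sites,
possible only at ploidy >= 3, are the diagnostic of retained hybrid
heterozygosity in the triploid. Microsatellites are maximal perfect tandem
repeats of 2-6-bp motifs above unit-specific repeat thresholds
(di: 8, tri-hexa: 5) with more than 50 bp of flanking sequence on both
sides, genotyped per individual by the number of distinct allele lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import BASES, PileupSite, TranscriptRecord

MULTIPLICITY_CLASSES = ("monomorphic", "di-allelic", "tri-allelic", "higher")


def _multiplicity_class(n_alleles: int) -> str:
    if n_alleles <= 1:
        return "monomorphic"
    if n_alleles == 2:
        return "di-allelic"
    if n_alleles == 3:
        return "tri-allelic"
    return "higher"


@dataclass(frozen=True)
class SiteCall:
    transcript: str
    pos: int  # 0-based
    coverage: int
    alleles: tuple[str, ...]
    multiplicity: str

    @property
    def is_polymorphic(self) -> bool:
        return len(self.alleles) >= 2


def call_sites(
    sites: list[PileupSite],
    min_coverage: int = 5,
    allele_min_reads: int = 2,
    allele_min_fraction: float = 0.1,
) -> list[SiteCall]:
    """Classify allele multiplicity at sites with sufficient coverage.

    Sites below ``min_coverage`` pooled reads are excluded entirely. A base
    is an allele iff its pooled count is >= ``allele_min_reads`` AND >=
    ``allele_min_fraction`` of the coverage; the allele-set size gives the
    multiplicity class.
    """
    if min_coverage <= 0 or allele_min_reads <= 0 or allele_min_fraction <= 0:
        raise ValueError("thresholds must be strictly positive")
    calls = []
    for s in sites:
        cov = s.coverage
        if cov < min_coverage:
            continue
        alleles = tuple(
            b for b in BASES
            if s.pooled[b] >= allele_min_reads
            and s.pooled[b] >= allele_min_fraction * cov
        )
        calls.append(SiteCall(s.transcript, s.pos, cov, alleles,
                              _multiplicity_class(len(alleles))))
    return calls


@dataclass(frozen=True)
class DiversitySummary:
    total_polymorphic: int
    n_transcripts: int  # transcripts containing >= 1 polymorphic site
    average: float      # sites per transcript, one decimal
    no_polymorphism: bool
    per_transcript: dict[str, int]
    multiplicity_counts: dict[str, int]


def sites_per_transcript(total_sites: int, n_transcripts: int) -> float:
    """Average polymorphic sites per polymorphic transcript, one decimal."""
    if n_transcripts == 0:
        return 0.0
    return round(total_sites / n_transcripts, 1)


def diversity_summary(calls: list[SiteCall]) -> DiversitySummary:
    """Per-transcript polymorphic-site counts and the population average.

    The average divides total polymorphic sites by the number of
    transcripts that contain at least one polymorphic site, reported to one
    decimal; with no polymorphism at all the average is 0 and flagged.
    """
    per: dict[str, int] = {}
    mult: dict[str, int] = {c: 0 for c in MULTIPLICITY_CLASSES}
    for c in calls:
        mult[c.multiplicity] += 1
        if c.is_polymorphic:
            per[c.transcript] = per.get(c.transcript, 0) + 1
    total = sum(per.values())
    return DiversitySummary(
        total_polymorphic=total,
        n_transcripts=len(per),
        average=sites_per_transcript(total, len(per)),
        no_polymorphism=total == 0,
        per_transcript=per,
        multiplicity_counts=mult,
    )


def ploidy_ratio(content_a: float, content_b: float) -> float:
    """Ratio of mean DNA contents from flow cytometry — 1.5 for a triploid
    measured against a diploid reference."""
    if content_a <= 0 or content_b <= 0:
        raise ValueError("DNA contents must be positive")
    return content_a / content_b


# --------------------------------------------------------------------------
# microsatellites
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MicrosatelliteLocus:
    transcript: str
    motif: str            # as found at the array start
    canonical_motif: str  # lexicographic minimum over rotations
    unit: int
    repeats: int
    start: int  # 0-based half-open
    end: int
    left_flank: int
    right_flank: int
    passes_flank: bool


def _is_primitive(motif: str) -> bool:
    u = len(motif)
    for d in range(1, u):
        if u % d == 0 and motif == motif[:d] * (u // d):
            return False
    return True


def _canonical(motif: str) -> str:
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def find_microsatellites(
    transcripts: list[TranscriptRecord],
    thresholds: dict[int, int] | None = None,
    min_flank: int = 50,
) -> list[MicrosatelliteLocus]:
    """Maximal perfect tandem arrays of primitive 2-6-bp motifs.

    Forward strand only (transcripts are oriented). Arrays whose motif is a
    repetition of a shorter motif are reported once, at the shortest unit
    (so (ACAC)x4 is (AC)x8). Overlapping candidates of different units are
    resolved leftmost-longest. ``passes_flank`` is true iff both flanks are
    strictly longer than ``min_flank``.
    """
    if thresholds is None:
        thresholds = {2: 8, 3: 5, 4: 5, 5: 5, 6: 5}
    if set(thresholds) != {2, 3, 4, 5, 6}:
        raise ValueError("thresholds must cover unit lengths 2-6")

    loci = []
    for rec in transcripts:
        seq = rec.seq
        n = len(seq)
        candidates = []
        for unit, min_reps in sorted(thresholds.items()):
            for i in range(n - unit + 1):
                motif = seq[i : i + unit]
                if any(c not in "ACGT" for c in motif):
                    continue
                # left-maximality: a run continuing from i-unit was already seen
                if i >= 1 and i + unit - 1 < n and seq[i - 1] == seq[i + unit - 1]:
                    continue
                if not _is_primitive(motif):
                    continue
                j = i + unit
                while j < n and seq[j] == seq[j - unit]:
                    j += 1
                reps = (j - i) // unit
                if reps >= min_reps:
                    candidates.append((i, i + unit * reps, unit, reps, motif))
        # leftmost-longest resolution across unit lengths
        candidates.sort(key=lambda c: (c[0], -(c[1] - c[0]), c[2]))
        last_end = -1
        for start, end, unit, reps, motif in candidates:
            if start < last_end:
                continue
            last_end = end
            left, right = start, n - end
            loci.append(MicrosatelliteLocus(
                transcript=rec.id, motif=motif,
                canonical_motif=_canonical(motif), unit=unit, repeats=reps,
                start=start, end=end, left_flank=left, right_flank=right,
                passes_flank=left > min_flank and right > min_flank,
            ))
    return loci


# --------------------------------------------------------------------------
# microsatellite genotyping
# --------------------------------------------------------------------------

GENOTYPE_CLASSES = {1: "homozygous", 2: "di-allelic heterozygous",
                    3: "tri-allelic heterozygous"}


@dataclass(frozen=True)
class GenotypeCall:
    locus: str
    individual: str
    n_alleles: int
    alleles: tuple[int, ...]  # distinct observed fragment lengths
    genotype_class: str


def genotype_msat(
    locus: str,
    observations: dict[str, list[int]],
    ploidy: int,
) -> tuple[list[GenotypeCall], str]:
    """Classify each individual by its distinct allele lengths at one locus.

    One distinct length → homozygous, two → di-allelic heterozygous, three
    → tri-allelic heterozygous (an ABC genotype, requiring triploidy). The
    locus-level class is the highest multiplicity seen in any individual.
    More distinct lengths than the ploidy is a genotyping artifact and an
    error.
    """
    if not observations:
        raise ValueError("no observations")
    if ploidy not in (2, 3):
        raise ValueError("ploidy must be 2 or 3")
    calls = []
    for ind in sorted(observations):
        lengths = tuple(sorted(set(observations[ind])))
        if not lengths:
            raise ValueError(f"no allele lengths for individual {ind}")
        if len(lengths) > ploidy:
            raise ValueError(
                f"individual {ind} shows {len(lengths)} alleles at {locus} "
                f"(ploidy {ploidy}): probable genotyping artifact"
            )
        calls.append(GenotypeCall(locus, ind, len(lengths), lengths,
                                  GENOTYPE_CLASSES[len(lengths)]))
    locus_class = GENOTYPE_CLASSES[max(c.n_alleles for c in calls)]
    return calls, locus_class


def summarize_locus_classes(locus_classes: list[str]) -> dict[str, float]:
    """Fraction of loci in each genotype class across a panel."""
    if not locus_classes:
        raise ValueError("no loci")
    n = len(locus_classes)
    return {cls: locus_classes.count(cls) / n
            for cls in GENOTYPE_CLASSES.values()}
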