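"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be produced here with its truth
recorded: orthologous coding-sequence pairs diverged to a target expected
synonymous divergence, diploid/triploid read pileups from planted
genotypes, transcripts with planted perfect microsatellites, and
two-condition count tables with planted fold changes. All generators are
seeded and reproducible byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ng86
from .io import BASES, PileupSite, TranscriptRecord

# --------------------------------------------------------------------------
# ortholog pair evolution
# --------------------------------------------------------------------------

# per sense codon: lists of single-base neighbour codons, split by effect
_SYN_NEIGHBOURS: list[list[int]] = []
_NONSYN_NEIGHBOURS: list[list[int]] = []
for _codon in ng86.SENSE_CODONS:
    _syn, _non = [], []
    _aa = ng86._AA[_codon]
    for _pos in range(3):
        for _b in "ACGT":
            if _b == _codon[_pos]:
                continue
            _mut = _codon[:_pos] + _b + _codon[_pos + 1 :]
            if _mut in ng86.STOP_CODONS:
                continue
            (_syn if ng86._AA[_mut] == _aa else _non).append(ng86.CODON_INDEX[_mut])
    _SYN_NEIGHBOURS.append(_syn)
    _NONSYN_NEIGHBOURS.append(_non)
_N_SYN = np.array([len(x) for x in _SYN_NEIGHBOURS], dtype=float)
_N_NONSYN = np.array([len(x) for x in _NONSYN_NEIGHBOURS], dtype=float)


@dataclass(frozen=True)
class EvolverParams:
    """Parameters for one simulated ortholog pair.

    ``target_ks`` is the expected number of synonymous substitutions per
    synonymous site accumulated across the pair (split evenly between the
    two lineages, as under a molecular clock); ``omega`` scales the
    nonsynonymous rate relative to the synonymous one.
    """

    n_codons: int
    target_ks: float
    omega: float = 0.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_codons < 10:
            raise ValueError("n_codons must be >= 10")
        if self.target_ks < 0:
            raise ValueError("target_ks must be >= 0")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")


@dataclass(frozen=True)
class PlantedGenotype:
    """A known genotype at one transcript position, e.g. {A,A,B} in a triploid."""

    transcript: str
    position: int  # 0-based
    alleles: tuple[str, ...]  # multiset of size == ploidy
    ploidy: int

    def __post_init__(self) -> None:
        if self.ploidy not in (2, 3):
            raise ValueError("ploidy must be 2 or 3")
        if len(self.alleles) != self.ploidy:
            raise ValueError("allele multiset size must equal ploidy")
        if any(a not in BASES for a in self.alleles):
            raise ValueError("alleles must be drawn from A,C,G,T")


def _indices_to_seq(idx: np.ndarray) -> str:
    return "".join(ng86.SENSE_CODONS[i] for i in idx)


def _apply_events(seq: np.ndarray, n_events: int, weights_per_codon: np.ndarray,
                  neighbours: list[list[int]], rng: np.random.Generator) -> int:
    """Place substitution events, one at a time, uniformly over all eligible
    single-base changes of the requested class; returns events applied."""
    applied = 0
    for _ in range(n_events):
        w = weights_per_codon[seq]
        total = w.sum()
        if total == 0:
            break
        j = rng.choice(seq.size, p=w / total)
        options = neighbours[seq[j]]
        seq[j] = options[rng.integers(len(options))]
        applied += 1
    return applied


def evolve_ortholog_pair(params: EvolverParams):
    """Evolve an ancestral CDS down two lineages to a target Ks.

    Returns ``(ancestor, (seq_a, seq_b), truth)`` where the sequences are
    ungapped in-frame coding sequences of ``n_codons`` sense codons and
    ``truth`` records the planted event counts and ancestral site counts:
    ``syn_events``, ``nonsyn_events``, ``S_anc``, ``N_anc``, ``true_ks``
    (= syn_events / S_anc) and ``true_ka``.

    Synonymous events per lineage are Poisson with mean
    ``target_ks/2 * S_anc``; nonsynonymous events Poisson with mean
    ``target_ks/2 * omega * N_anc``; each event is a uniformly chosen
    eligible single-base change (stop codons are never created), so the
    expected synonymous substitutions per synonymous site across the pair
    equal ``target_ks``.
    """
    rng = np.random.default_rng(params.seed)
    anc = rng.integers(len(ng86.SENSE_CODONS), size=params.n_codons)
    s_anc = float(ng86.SYN_SITES[anc].sum())
    n_anc = 3.0 * params.n_codons - s_anc

    truth = {"syn_events": 0, "nonsyn_events": 0,
             "S_anc": s_anc, "N_anc": n_anc}
    derived = []
    for _branch in range(2):
        seq = anc.copy()
        n_syn = rng.poisson(params.target_ks / 2.0 * s_anc)
        n_non = rng.poisson(params.target_ks / 2.0 * params.omega * n_anc)
        truth["syn_events"] += _apply_events(seq, n_syn, _N_SYN,
                                             _SYN_NEIGHBOURS, rng)
        truth["nonsyn_events"] += _apply_events(seq, n_non, _N_NONSYN,
                                                _NONSYN_NEIGHBOURS, rng)
        derived.append(seq)

    truth["true_ks"] = truth["syn_events"] / s_anc
    truth["true_ka"] = truth["nonsyn_events"] / n_anc if n_anc else 0.0
    return (
        _indices_to_seq(anc),
        (_indices_to_seq(derived[0]), _indices_to_seq(derived[1])),
        truth,
    )


def evolve_ortholog_pairs(n_pairs: int, params: EvolverParams):
    """Simulate ``n_pairs`` independent pairs; per-pair seeds are derived
    from ``params.seed``. Returns (records_a, records_b, truth DataFrame)."""
    seeds = np.random.SeedSequence(params.seed).generate_state(n_pairs) % (2**31)
    recs_a, recs_b, rows = [], [], []
    for i, seed in enumerate(seeds):
        p = EvolverParams(params.n_codons, params.target_ks, params.omega,
                          int(seed))
        _, (sa, sb), truth = evolve_ortholog_pair(p)
        name = f"pair{i:05d}"
        recs_a.append(TranscriptRecord(f"{name}_a", sa))
        recs_b.append(TranscriptRecord(f"{name}_b", sb))
        rows.append({"pair": name, **truth})
    return recs_a, recs_b, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# pileup simulation
# --------------------------------------------------------------------------

def simulate_pileup(
    genotypes: list[PlantedGenotype],
    coverage: float,
    error_rate: float,
    seed: int,
    n_individuals: int = 1,
    min_coverage_flag: int = 5,
):
    """Simulate per-site read pileups from planted genotypes.

    Per individual, the read count at a site is Poisson(``coverage``); each
    read samples one chromosome copy uniformly (so each copy contributes in
    expected proportion 1/ploidy) and is mis-read with probability
    ``error_rate`` into a uniformly chosen other base.

    Returns ``(sites, truth)``: aggregated :class:`PileupSite` objects and a
    truth DataFrame with the planted distinct-allele count per site and a
    flag for sites whose pooled coverage fell below ``min_coverage_flag``.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if not 0 <= error_rate < 0.25:
        raise ValueError("error_rate must be in [0, 0.25)")
    rng = np.random.default_rng(seed)
    base_idx = {b: i for i, b in enumerate(BASES)}

    sites, rows = [], []
    for g in genotypes:
        site = PileupSite(g.transcript, g.position)
        copy_bases = np.array([base_idx[a] for a in g.alleles])
        for ind in range(n_individuals):
            n_reads = rng.poisson(coverage)
            counts = np.zeros(4, dtype=int)
            if n_reads:
                reads = copy_bases[rng.integers(g.ploidy, size=n_reads)]
                errs = rng.random(n_reads) < error_rate
                if errs.any():
                    # substitute a uniformly chosen *other* base
                    shift = rng.integers(1, 4, size=int(errs.sum()))
                    reads[errs] = (reads[errs] + shift) % 4
                counts = np.bincount(reads, minlength=4)
            site.add(f"ind{ind + 1}", dict(zip(BASES, counts)))
        sites.append(site)
        rows.append({
            "transcript": g.transcript,
            "position": g.position,
            "ploidy": g.ploidy,
            "planted_alleles": "".join(sorted(set(g.alleles))),
            "n_alleles": len(set(g.alleles)),
            "pooled_coverage": site.coverage,
            "below_min_coverage": site.coverage < min_coverage_flag,
        })
    return sites, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# microsatellite planting
# --------------------------------------------------------------------------

def _random_nonrepetitive_flank(length: int, rng: np.random.Generator,
                                forbidden_unit_max: int = 6) -> str:
    """Random flank rejected-and-resampled until it contains no tandem array
    of units 1-6 with 4+ repeats (so planted arrays stay the only signal)."""
    import re

    pat = re.compile(r"(.{1,%d}?)\1{3,}" % forbidden_unit_max)
    while True:
        s = "".join(np.array(list("ACGT"))[rng.integers(4, size=length)])
        if not pat.search(s):
            return s


def plant_microsatellites(
    n_transcripts: int,
    spec: list[tuple[str, int, int, int]],
    seed: int,
    thresholds: dict[int, int] | None = None,
    min_flank: int = 50,
):
    """Embed exact tandem repeats in random non-repetitive flanks.

    ``spec`` is a list of ``(motif, repeat_count, left_flank, right_flank)``;
    entries are assigned round-robin to ``n_transcripts`` transcripts (one
    array per transcript). Returns ``(records, truth)`` where truth lists
    the planted coordinates and whether each array passes the detection
    thresholds (repeat count for its unit length, both flanks > min_flank).
    """
    if thresholds is None:
        thresholds = {2: 8, 3: 5, 4: 5, 5: 5, 6: 5}
    rng = np.random.default_rng(seed)
    records, rows = [], []
    for i in range(n_transcripts):
        motif, reps, left, right = spec[i % len(spec)]
        if not 2 <= len(motif) <= 6:
            raise ValueError("motif length must be 2-6")
        if left < 0 or right < 0:
            raise ValueError("flank lengths must be >= 0")
        lf = _random_nonrepetitive_flank(left, rng)
        rf = _random_nonrepetitive_flank(right, rng)
        seq = lf + motif * reps + rf
        name = f"ssr{i:04d}"
        records.append(TranscriptRecord(name, seq))
        unit = len(motif)
        rows.append({
            "transcript": name,
            "motif": motif,
            "unit": unit,
            "repeats": reps,
            "start": left,
            "end": left + unit * reps,
            "left_flank": left,
            "right_flank": right,
            "meets_repeat_threshold": reps >= thresholds[unit],
            "passes_flank": left > min_flank and right > min_flank,
            "detectable": reps >= thresholds[unit]
            and left > min_flank and right > min_flank,
        })
    return records, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# count-table simulation
# --------------------------------------------------------------------------

def simulate_counts(
    n_genes: int,
    lib_sizes: tuple[int, int],
    planted: list[tuple[str, float]] | None,
    dispersion: float,
    seed: int,
    base_mean: float = 500.0,
):
    """Two-condition count table with planted fold changes.

    Condition-B means equal condition-A means times the planted fold times
    the library-size ratio. Counts are negative-binomial (gamma-Poisson)
    with variance ``mu + dispersion * mu^2``; ``dispersion=0`` gives the
    Poisson limit. Gene ids are ``g00000``…; ``planted`` maps gene ids to
    fold changes (unlisted genes have fold 1).

    Returns ``(counts DataFrame indexed by gene, truth DataFrame)``.
    """
    if lib_sizes[0] <= 0 or lib_sizes[1] <= 0:
        raise ValueError("lib_sizes must be positive")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    folds = dict(planted or [])
    if any(f <= 0 for f in folds.values()):
        raise ValueError("fold changes must be > 0")
    rng = np.random.default_rng(seed)
    lib_ratio = lib_sizes[1] / lib_sizes[0]

    genes = [f"g{i:05d}" for i in range(n_genes)]
    fold = np.array([folds.get(g, 1.0) for g in genes])
    mu_a = np.full(n_genes, float(base_mean))
    mu_b = mu_a * fold * lib_ratio

    def draw(mu):
        if dispersion == 0:
            return rng.poisson(mu)
        shape = 1.0 / dispersion
        return rng.poisson(rng.gamma(shape, mu / shape))

    counts = pd.DataFrame(
        {"count_a": draw(mu_a), "count_b": draw(mu_b)}, index=pd.Index(genes, name="gene")
    )
    truth = pd.DataFrame(
        {"gene": genes, "planted_fold": fold, "is_de": fold != 1.0}
    )
    return counts, truth
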