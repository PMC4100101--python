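"""Transcript catalog: protein-coding classification and splice-variant collapse.

A transcript is called protein-coding when its longest intact ORF
(ATG … stop, scanned in all six frames) encodes at least 50 amino acids —
the 150-nt rule commonly used to separate mRNAs from noncoding RNAs in
assembled transcriptomes. Putative splice variants are collapsed by exact
sequence sharing: any two transcripts with an identical substring of at
least 100 bp are clustered, and the longest member represents the cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .io import TranscriptRecord
from .ng86 import STOP_CODONS


@dataclass(frozen=True)
class OrfCall:
    """Best ORF of one transcript; coordinates are 0-based half-open on the
    scanned strand (the reverse complement for negative frames) and include
    the stop codon; ``length_aa`` is the encoded protein length (Met
    counted, stop excluded)."""

    transcript: str
    frame: int  # +1..+3 forward, -1..-3 on the reverse complement; 0 = none
    start: int
    end: int
    length_aa: int
    is_coding: bool


def _scan_frame(seq: str, offset: int) -> list[tuple[int, int]]:
    """Intact ORFs (start of ATG to end of stop) in one forward frame.

    Codons containing characters outside ACGT abort the ORF in progress:
    an ambiguous codon can be neither a confident start, stop nor sense
    codon, so no ORF may span it.
    """
    orfs = []
    start = None
    for i in range(offset, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if any(c not in "ACGT" for c in codon):
            start = None
            continue
        if start is None:
            if codon == "ATG":
                start = i
        elif codon in STOP_CODONS:
            orfs.append((start, i + 3))
            start = None
    return orfs


def find_best_orf(record: TranscriptRecord | str, min_aa: int = 50) -> OrfCall:
    """Longest intact ORF over all six frames.

    Ties are broken in favour of the forward strand, then the lowest start
    coordinate, then the lowest frame. With no intact ORF anywhere, a
    non-coding call with ``length_aa=0`` and ``frame=0`` is returned.
    """
    if isinstance(record, str):
        record = TranscriptRecord("", record)
    if len(record.seq) < 3:
        raise ValueError("sequence shorter than one codon")

    best: tuple | None = None  # (-(length), strand_rank, start, frame_rank, call)
    for strand, seq in (("+", record.seq),
                        ("-", str(Seq(record.seq).reverse_complement()))):
        for offset in range(3):
            frame = (offset + 1) if strand == "+" else -(offset + 1)
            for start, end in _scan_frame(seq, offset):
                length_aa = (end - start) // 3 - 1
                key = (-length_aa, 0 if strand == "+" else 1, start, offset)
                if best is None or key < best[0]:
                    best = (key, OrfCall(record.id, frame, start, end,
                                         length_aa, length_aa >= min_aa))
    if best is None:
        return OrfCall(record.id, 0, 0, 0, 0, False)
    return best[1]


def orf_region(record: TranscriptRecord, call: OrfCall,
               include_stop: bool = False) -> str:
    """Extract the CDS of an ORF call (on the called strand), stop excluded
    by default so the region translates without ``*``."""
    seq = record.seq if call.frame >= 0 else \
        str(Seq(record.seq).reverse_complement())
    end = call.end if include_stop else call.end - 3
    return seq[call.start : end]


class _UnionFind:
    def __init__(self):
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        p = self.parent.setdefault(x, x)
        if p != x:
            p = self.parent[x] = self.find(p)
        return p

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def dedup_splice_variants(
    transcripts: list[TranscriptRecord], min_overlap: int = 100
) -> tuple[list[TranscriptRecord], dict[str, str]]:
    """Collapse transcripts sharing an exact substring of >= ``min_overlap`` bp.

    Sharing is detected through a k-mer index with k = ``min_overlap`` (two
    sequences share a >=k identical block iff they share a k-mer); k-mers
    containing N never match. Connected components collapse to their
    longest member, ties to the lexicographically smallest id. Returns the
    representatives (input order preserved) and the member→representative map.
    """
    if not transcripts:
        raise ValueError("empty transcript collection")
    uf = _UnionFind()
    by_id = {}
    for rec in transcripts:
        if rec.id in by_id:
            raise ValueError(f"duplicate id {rec.id}")
        by_id[rec.id] = rec
        uf.find(rec.id)

    kmer_owner: dict[str, str] = {}
    k = min_overlap
    for rec in transcripts:
        seq = rec.seq
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            owner = kmer_owner.setdefault(kmer, rec.id)
            if owner != rec.id:
                uf.union(rec.id, owner)

    clusters: dict[str, list[str]] = {}
    for rec in transcripts:
        clusters.setdefault(uf.find(rec.id), []).append(rec.id)
    cluster_map: dict[str, str] = {}
    for members in clusters.values():
        rep = min(members, key=lambda m: (-len(by_id[m].seq), m))
        for m in members:
            cluster_map[m] = rep
    reps = [rec for rec in transcripts if cluster_map[rec.id] == rec.id]
    return reps, cluster_map
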