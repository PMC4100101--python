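"""Readers and writers for the on-disk formats the pipeline consumes.

FASTA for transcripts (via Biopython), tab-separated text for everything
else: pileups (transcript, 1-based position, individual, base counts),
gene→category maps, two-condition count tables and qPCR Cq tables.
Coordinates are 1-based closed on disk and 0-based half-open in memory.
Every table written by the pipeline starts with a commented header naming
the tool version and the parameters used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class TranscriptRecord:
    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class PileupSite:
    """Per-site read support: per-individual and pooled base counts."""

    transcript: str
    pos: int  # 0-based
    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    pooled: dict[str, int] = field(
        default_factory=lambda: {b: 0 for b in BASES}
    )

    @property
    def coverage(self) -> int:
        return sum(self.pooled.values())

    def add(self, individual: str, counts: dict[str, int]) -> None:
        ind = self.counts.setdefault(individual, {b: 0 for b in BASES})
        for b in BASES:
            c = int(counts.get(b, 0))
            ind[b] += c
            self.pooled[b] += c


def read_fasta(path: str | Path) -> list[TranscriptRecord]:
    """Read transcripts; sequences are uppercased and U is normalised to T.

    Raises ``ValueError`` on duplicate identifiers or empty sequences.
    """
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise ValueError(f"empty sequence for id {rec.id}")
        records.append(TranscriptRecord(rec.id, seq))
    return records


def write_fasta(records: list[TranscriptRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.seq), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


PILEUP_COLUMNS = ["transcript", "position", "individual",
                  "countA", "countC", "countG", "countT"]


def _read_tsv(path: str | Path, names: list[str],
              numeric: list[str]) -> pd.DataFrame:
    """Read a TSV with known columns; '#' comments and an optional header
    row naming the columns are both tolerated."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=names,
                     dtype=str)
    if len(df) and list(df.iloc[0]) == names:
        df = df.iloc[1:].reset_index(drop=True)
    for col in numeric:
        df[col] = pd.to_numeric(df[col])
    return df


def read_pileup(
    path: str | Path,
    transcript_lengths: dict[str, int] | None = None,
) -> list[PileupSite]:
    """Read a pileup TSV (1-based positions) into aggregated sites.

    Rows for the same (transcript, position) are pooled across individuals;
    the result is sorted by (transcript, position) so ingestion is
    independent of row order. Positions are converted to 0-based.
    """
    count_cols = ["countA", "countC", "countG", "countT"]
    df = _read_tsv(path, PILEUP_COLUMNS, ["position", *count_cols])
    if (df[count_cols] < 0).to_numpy().any():
        raise ValueError("negative base count in pileup")
    if (df["position"] < 1).any():
        raise ValueError("pileup positions must be 1-based (>= 1)")
    sites: dict[tuple[str, int], PileupSite] = {}
    for row in df.itertuples(index=False):
        pos0 = int(row.position) - 1
        if transcript_lengths is not None:
            length = transcript_lengths.get(row.transcript)
            if length is not None and pos0 >= length:
                raise ValueError(
                    f"position {row.position} exceeds length of {row.transcript}"
                )
        key = (row.transcript, pos0)
        site = sites.get(key)
        if site is None:
            site = sites[key] = PileupSite(row.transcript, pos0)
        site.add(str(row.individual),
                 {"A": row.countA, "C": row.countC,
                  "G": row.countG, "T": row.countT})
    return [sites[k] for k in sorted(sites)]


def write_pileup(sites: list[PileupSite], path: str | Path,
                 header: str | None = None) -> None:
    rows = []
    for s in sorted(sites, key=lambda s: (s.transcript, s.pos)):
        for ind in sorted(s.counts):
            c = s.counts[ind]
            rows.append((s.transcript, s.pos + 1, ind,
                         c["A"], c["C"], c["G"], c["T"]))
    df = pd.DataFrame(rows, columns=PILEUP_COLUMNS)
    write_table(df, path, header=header)


def read_category_map(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV ``gene<TAB>term`` → gene → set of terms."""
    df = _read_tsv(path, ["gene", "term"], [])
    out: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.gene), set()).add(str(row.term))
    return out


def read_counts(path: str | Path) -> pd.DataFrame:
    """Count table ``gene<TAB>countA<TAB>countB`` → DataFrame indexed by gene."""
    df = _read_tsv(path, ["gene", "count_a", "count_b"],
                   ["count_a", "count_b"])
    return df.set_index("gene")


def read_cq_table(path: str | Path) -> pd.DataFrame:
    """Cq table ``gene<TAB>group<TAB>Cq_target<TAB>Cq_reference`` (replicate rows)."""
    return _read_tsv(path, ["gene", "group", "cq_target", "cq_reference"],
                     ["cq_target", "cq_reference"])


def table_header(stage: str, **params) -> str:
    from . import __version__

    parts = " ".join(f"{k}={v}" for k, v in params.items())
    return f"# carptrx {__version__} | {stage} | {parts}".rstrip(" |")


def write_table(df: pd.DataFrame, path: str | Path,
                header: str | None = None, index: bool = False) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header.rstrip("\n") + "\n")
        df.to_csv(fh, sep="\t", index=index)
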