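"""Pipeline configuration: the analysis constants, with file round-trip.

Defaults are the constants the analysis is built around: a 50-aa minimum
ORF for calling a transcript protein-coding, splice-variant collapse at
100% identity over 100 bp, a 300-bp reciprocal-best-hit alignment floor,
0.002-wide Ks bins, a synonymous-site clock of 3.51e-9 substitutions per
site per year, minimum read coverage 5 for SNP calling, microsatellite
repeat thresholds {2:8, 3:5, 4:5, 5:5, 6:5} with >50-bp flanks, and DEG
cutoffs of FDR 0.001 with a minimum 4-fold change.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path


@dataclass
class AlignmentScoring:
    """Scoring constants for the nucleotide local alignments used in best-hit
    searches (BLASTN-like defaults) and the protein global alignments used
    for codon-alignment back-threading."""

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    protein_gap_open: float = -10.0
    protein_gap_extend: float = -1.0


@dataclass
class PipelineConfig:
    min_orf_aa: int = 50                 # amino acids, protein-coding cutoff
    dedup_identity: float = 1.0          # fraction; only exact identity supported
    dedup_min_overlap: int = 100         # bp of shared identical sequence
    rbh_min_aln: int = 300               # bp, ortholog alignment-length floor
    ks_bin_width: float = 0.002          # Ks units
    clock_rate: float = 3.51e-9          # subs / synonymous site / year
    min_coverage: int = 5                # reads, SNP-calling floor
    allele_min_reads: int = 2            # reads supporting an allele
    allele_min_fraction: float = 0.1     # fraction of site coverage
    ssr_thresholds: dict[int, int] = field(
        default_factory=lambda: {2: 8, 3: 5, 4: 5, 5: 5, 6: 5}
    )
    ssr_min_flank: int = 50              # bp, both sides, strict
    deg_fdr: float = 0.001               # BH-adjusted p cutoff
    deg_min_fold: float = 4.0            # minimum fold change
    rng_seed: int = 1
    scoring: AlignmentScoring = field(default_factory=AlignmentScoring)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        numeric = (
            "min_orf_aa", "dedup_identity", "dedup_min_overlap", "rbh_min_aln",
            "ks_bin_width", "clock_rate", "min_coverage", "allele_min_reads",
            "allele_min_fraction", "ssr_min_flank", "deg_fdr", "deg_min_fold",
            "rng_seed",
        )
        for name in numeric:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if set(self.ssr_thresholds) != {2, 3, 4, 5, 6}:
            raise ValueError("ssr_thresholds must have exactly keys 2,3,4,5,6")
        if any(v <= 0 for v in self.ssr_thresholds.values()):
            raise ValueError("ssr_thresholds values must be strictly positive")
        if self.deg_min_fold < 1:
            raise ValueError("deg_min_fold must be >= 1")
        if self.dedup_identity != 1.0:
            raise ValueError("only dedup_identity == 1.0 (exact) is supported")

    # -- flat key/value file round-trip -------------------------------------

    def to_file(self, path: str | Path) -> None:
        lines = ["# carptrx pipeline configuration"]
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "ssr_thresholds":
                v = ",".join(f"{k}:{n}" for k, n in sorted(v.items()))
            elif f.name == "scoring":
                for sf in fields(AlignmentScoring):
                    lines.append(f"scoring.{sf.name} = {getattr(v, sf.name)}")
                continue
            lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Read a flat ``key = value`` file; keyword overrides win over file values."""
        raw: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            raw[key.strip()] = val.strip()
        kwargs: dict = {}
        scoring_kwargs: dict = {}
        int_fields = {"min_orf_aa", "dedup_min_overlap", "rbh_min_aln",
                      "min_coverage", "allele_min_reads", "ssr_min_flank",
                      "rng_seed"}
        for key, val in raw.items():
            if key.startswith("scoring."):
                scoring_kwargs[key.split(".", 1)[1]] = float(val)
            elif key == "ssr_thresholds":
                kwargs[key] = {
                    int(k): int(n)
                    for k, n in (item.split(":") for item in val.split(","))
                }
            elif key in int_fields:
                kwargs[key] = int(val)
            else:
                kwargs[key] = float(val)
        if scoring_kwargs:
            kwargs["scoring"] = AlignmentScoring(**scoring_kwargs)
        kwargs.update(overrides)
        return cls(**kwargs)

    def with_overrides(self, **overrides) -> "PipelineConfig":
        return replace(self, **{k: v for k, v in overrides.items() if v is not None})
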