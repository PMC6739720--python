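"""Core domain types shared by every pipeline stage.

Coordinates are 0-based half-open throughout; GTF/GFF readers and writers
convert at the file boundary.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, fields
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

TISSUES = ("leaf", "phloem", "xylem", "root")
SALT_LEVELS = (0, 150, 300)
STRANDS = ("+", "-")


class ValidationError(ValueError):
    """Raised when an input object violates a documented invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded interval on a chromosome, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}, got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int:
        """Gap length between two non-overlapping intervals (0 when overlapping)."""
        if self.overlaps(other):
            return 0
        if self.chrom != other.chrom:
            raise ValueError("gap undefined across chromosomes")
        if other.start >= self.end:
            return other.start - self.end
        return self.start - other.end

    def shift(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset, self.strand)


@dataclass
class TranscriptModel:
    """A stranded, exon-structured transcript, optionally carrying its sequence."""

    id: str
    exons: Sequence[GenomicInterval]
    gene_id: str | None = None
    sequence: str | None = None
    biotype: str = "unknown"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"transcript {self.id}: no exons")
        if self.biotype not in ("coding", "unknown"):
            raise ValidationError(f"transcript {self.id}: bad biotype {self.biotype!r}")
        ex = sorted(self.exons, key=lambda e: e.start)
        chroms = {e.chrom for e in ex}
        strands = {e.strand for e in ex}
        if len(chroms) > 1:
            raise ValidationError(f"transcript {self.id}: exons on multiple chromosomes")
        if len(strands) > 1:
            raise ValidationError(f"transcript {self.id}: exons on mixed strands")
        for a, b in zip(ex, ex[1:]):
            if a.end > b.start:
                raise ValidationError(f"transcript {self.id}: overlapping exons")
        self.exons = tuple(ex)
        if self.sequence is not None:
            self.sequence = self.sequence.upper().replace("U", "T")
            if len(self.sequence) != self.spliced_length:
                raise ValidationError(
                    f"transcript {self.id}: sequence length {len(self.sequence)} "
                    f"!= spliced length {self.spliced_length}"
                )

    @property
    def interval(self) -> GenomicInterval:
        """Genomic span from first exon start to last exon end."""
        return GenomicInterval(
            self.exons[0].chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(a.chrom, a.end, b.start, a.strand))
        return tuple(out)


@dataclass(frozen=True)
class SampleMeta:
    """Per-library design metadata: tissue x salt dose x replicate."""

    tissue: str
    salt_mM: int
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValidationError(f"replicate must be >= 1, got {self.replicate}")


class ExpressionMatrix:
    """FPKM table (transcripts x samples) plus per-sample design metadata."""

    def __init__(self, values: pd.DataFrame, samples: Mapping[str, SampleMeta]):
        values = values.astype(float)
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()][0]
            raise ValidationError(f"duplicate transcript id {dup!r}")
        if values.isna().any().any():
            r, c = next(zip(*np.where(values.isna().to_numpy())))
            raise ValidationError(
                f"missing FPKM at transcript {values.index[r]!r}, sample {values.columns[c]!r}"
            )
        if (values.to_numpy() < 0).any():
            raise ValidationError("negative FPKM values present")
        missing = [s for s in values.columns if s not in samples]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing}")
        self.values = values
        self.samples = dict(samples)

    # -- design introspection ------------------------------------------------

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.samples.values():
            seen.setdefault(m.tissue, None)
        return list(seen)

    @property
    def salt_levels(self) -> list[int]:
        return sorted({m.salt_mM for m in self.samples.values()})

    def columns_for(self, tissue: str | None = None, salt_mM: int | None = None) -> list[str]:
        out = []
        for sid in self.values.columns:
            m = self.samples[sid]
            if tissue is not None and m.tissue != tissue:
                continue
            if salt_mM is not None and m.salt_mM != salt_mM:
                continue
            out.append(sid)
        return out

    def tissue_means(self, salt_mM: int | None = 0) -> pd.DataFrame:
        """Mean FPKM per tissue (columns) over replicates, at one salt level or all."""
        cols = {}
        for t in self.tissues:
            sids = self.columns_for(tissue=t, salt_mM=salt_mM)
            if not sids:
                raise ValidationError(f"no samples for tissue {t!r} at salt {salt_mM!r}")
            cols[t] = self.values[sids].mean(axis=1)
        return pd.DataFrame(cols)

    def condition_means(self) -> pd.DataFrame:
        """Mean FPKM per (tissue, salt) condition, one column per condition."""
        cols = {}
        for t in self.tissues:
            for s in self.salt_levels:
                sids = self.columns_for(tissue=t, salt_mM=s)
                if sids:
                    cols[f"{t}:{s}"] = self.values[sids].mean(axis=1)
        return pd.DataFrame(cols)

    def subset(self, ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(ids)
        missing = [i for i in ids if i not in self.values.index]
        if missing:
            raise ValidationError(f"transcripts without expression rows: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[ids], self.samples)

    def __contains__(self, tid: str) -> bool:
        return tid in self.values.index


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, each with its conventional default."""

    min_fpkm: float = 1.0
    min_length_nt: int = 200
    log2fc_cut: float = 1.0
    p_cut: float = 0.05
    tau_specific: float = 0.9
    tau_housekeeping: float = 0.1
    cis_window_bp: int = 10_000
    trans_min_identity: float = 0.95
    trans_max_evalue: float = 1e-5
    duplex_energy_cut: float = -60.0
    concordance_rho: float = 0.9
    homolog_expression_fc: float = 4.0
    go_p_cut: float = 0.05
    seed: int = 0
    # stand-in coding-potential scorer parameters
    orf_coding_nt: int = 300
    w_orf: float = 1.0
    w_fickett: float = 1.0
    pseudocount: float = 0.01
    # which samples feed the tissue-specificity index: "control" or "all"
    tau_samples: str = "control"

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not math.isfinite(v):
                raise ValidationError(f"config field {f.name} is not finite")
        if not self.tau_housekeeping < self.tau_specific:
            raise ValidationError("tau_housekeeping must be < tau_specific")
        if self.tau_samples not in ("control", "all"):
            raise ValidationError("tau_samples must be 'control' or 'all'")
        if self.pseudocount < 0:
            raise ValidationError("pseudocount must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def validate_design(samples: Mapping[str, SampleMeta], require_control: bool = True) -> None:
    """Check the sample sheet forms a usable tissue x salt x replicate design."""
    if not samples:
        raise ValidationError("empty sample sheet")
    salts = {m.salt_mM for m in samples.values()}
    if require_control and 0 not in salts:
        raise ValidationError("design has no 0 mM control level; contrasts undefined")
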