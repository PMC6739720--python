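"""Readers and writers for the formats the pipeline touches.

GTF (attribute style ``key "value";``) and GFF3 (``key=value``) exon records
are accepted; only ``exon`` features are used to build transcript models.
File coordinates are 1-based inclusive and converted to internal 0-based
half-open on read, and back on write.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    ExpressionMatrix,
    GenomicInterval,
    SampleMeta,
    TranscriptModel,
    ValidationError,
)

log = logging.getLogger(__name__)

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')
_GFF3_ATTR = re.compile(r"(\w+)=([^;]+)")


class ParseError(ValueError):
    pass


def _parse_attributes(field: str) -> dict[str, str]:
    if "=" in field and '"' not in field:
        return {k: v.strip() for k, v in _GFF3_ATTR.findall(field)}
    return dict(_GTF_ATTR.findall(field))


def read_annotation(path: str | Path) -> list[TranscriptModel]:
    """Read a GTF/GFF file into transcript models (exon features only)."""
    path = Path(path)
    exons: dict[str, list[GenomicInterval]] = {}
    info: dict[str, dict[str, str]] = {}
    order: list[str] = []
    n_records = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated fields, got {len(parts)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = parts
            if feature.lower() != "exon":
                continue
            try:
                start_1b, end_1b = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            attrs = _parse_attributes(attr_s)
            tid = attrs.get("transcript_id") or attrs.get("Parent")
            if not tid:
                raise ParseError(f"{path}:{lineno}: no transcript_id/Parent attribute")
            try:
                iv = GenomicInterval(chrom, start_1b - 1, end_1b, strand)
            except ValidationError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if tid not in exons:
                exons[tid] = []
                info[tid] = {
                    "gene_id": attrs.get("gene_id", tid),
                    "biotype": attrs.get("biotype", attrs.get("gene_biotype", "unknown")),
                }
                order.append(tid)
            exons[tid].append(iv)
            n_records += 1
    if n_records == 0:
        log.warning("no exon records found in %s", path)
        return []
    out = []
    for tid in order:
        bt = info[tid]["biotype"]
        try:
            out.append(
                TranscriptModel(
                    id=tid,
                    exons=exons[tid],
                    gene_id=info[tid]["gene_id"],
                    biotype=bt if bt in ("coding", "unknown") else "unknown",
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: {exc}") from exc
    return out


def write_annotation(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcripts as GTF (transcript + exon rows, 1-based inclusive)."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.gene_id or t.id}"; transcript_id "{t.id}"; biotype "{t.biotype}";'
            iv = t.interval
            fh.write(
                f"{iv.chrom}\tlncsalt\ttranscript\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
            )
            for e in t.exons:
                fh.write(
                    f"{e.chrom}\tlncsalt\texon\t{e.start + 1}\t{e.end}\t.\t{e.strand}\t.\t{attrs}\n"
                )


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def attach_sequences(transcripts: Iterable[TranscriptModel], sequences: Mapping[str, str]) -> None:
    """Attach spliced sequences to transcript models in place."""
    for t in transcripts:
        seq = sequences.get(t.id)
        if seq is not None:
            if len(seq) != t.spliced_length:
                raise ValidationError(
                    f"transcript {t.id}: FASTA length {len(seq)} != spliced length {t.spliced_length}"
                )
            t.sequence = seq.upper().replace("U", "T")


def read_sample_sheet(path: str | Path) -> dict[str, SampleMeta]:
    """TSV with columns sample_id, tissue, salt_mM, replicate."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"sample_id", "tissue", "salt_mM", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"sample sheet missing columns: {sorted(missing)}")
    out = {}
    for _, row in df.iterrows():
        sid = row["sample_id"]
        if sid in out:
            raise ValidationError(f"duplicate sample id {sid!r}")
        out[sid] = SampleMeta(
            tissue=row["tissue"], salt_mM=int(row["salt_mM"]), replicate=int(row["replicate"])
        )
    return out


def read_expression(path: str | Path, meta: Mapping[str, SampleMeta] | str | Path) -> ExpressionMatrix:
    """Read an FPKM TSV (first column transcript ids) plus a sample sheet."""
    if not isinstance(meta, Mapping):
        meta = read_sample_sheet(meta)
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    for sid in df.columns:
        if sid not in meta:
            raise ValidationError(f"sample {sid!r} in expression header absent from sample sheet")
    raw = df.apply(pd.to_numeric, errors="coerce")
    if raw.isna().any().any():
        bad = raw.isna().stack()
        tid, sid = bad[bad].index[0]
        raise ValidationError(f"non-numeric/missing FPKM at transcript {tid!r}, sample {sid!r}")
    return ExpressionMatrix(raw, {s: meta[s] for s in df.columns})


def write_expression(matrix: ExpressionMatrix, values_path: str | Path, meta_path: str | Path) -> None:
    df = matrix.values.copy()
    df.index.name = "transcript_id"
    df.to_csv(values_path, sep="\t", float_format="%.6g")
    rows = [
        {"sample_id": sid, "tissue": m.tissue, "salt_mM": m.salt_mM, "replicate": m.replicate}
        for sid, m in matrix.samples.items()
    ]
    pd.DataFrame(rows).to_csv(meta_path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path: str | Path, config_hash: str | None = None) -> None:
    """Write a result TSV with an optional config-hash header comment."""
    with open(path, "w") as fh:
        if config_hash is not None:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g", lineterminator="\n")
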