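"""Strand-aware positional classification of lncRNAs against coding genes.

Decision cascade (first rule that fires wins):
  1. exon-exon overlap with a same-strand gene   -> sense_overlap
  2. exon-exon overlap with an opposite-strand gene -> antisense
  3. span wholly inside one intron of any gene (either strand) -> intronic
  4. otherwise lincRNA, with the distance to the nearest gene span recorded
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_left
from dataclasses import dataclass
from typing import Sequence

from .core import TranscriptModel, ValidationError

log = logging.getLogger(__name__)

CLASSES = ("lincRNA", "intronic", "antisense", "sense_overlap")


@dataclass
class ClassificationResult:
    transcript_id: str
    positional_class: str
    host_or_nearest_gene: str | None
    distance_bp: float  # 0 when overlapping/contained; inf when no gene on chrom


class GeneIndex:
    """Sorted per-chromosome lookups for exon overlap, intron containment
    and nearest-span queries."""

    def __init__(self, genes: Sequence[TranscriptModel]):
        for g in genes:
            if g.biotype != "coding":
                raise ValidationError(f"gene {g.id} is not biotype=coding")
        self._exons: dict[str, list[tuple[int, int, str, str]]] = {}
        self._introns: dict[str, list[tuple[int, int, str]]] = {}
        self._spans: dict[str, list[tuple[int, int, str]]] = {}
        for g in genes:
            chrom = g.chrom
            for e in g.exons:
                self._exons.setdefault(chrom, []).append((e.start, e.end, g.strand, g.id))
            for i in g.introns:
                self._introns.setdefault(chrom, []).append((i.start, i.end, g.id))
            iv = g.interval
            self._spans.setdefault(chrom, []).append((iv.start, iv.end, g.id))
        for d in (self._exons, self._introns, self._spans):
            for chrom in d:
                d[chrom].sort()
        self._span_starts = {c: [s for s, _, _ in v] for c, v in self._spans.items()}
        # prefix (max end, gene id at max) enables O(log n) nearest-left lookup
        self._span_maxend: dict[str, list[tuple[int, str]]] = {}
        for c, v in self._spans.items():
            acc: list[tuple[int, str]] = []
            best_e, best_g = -1, ""
            for _, e, gid in v:
                if e > best_e:
                    best_e, best_g = e, gid
                acc.append((best_e, best_g))
            self._span_maxend[c] = acc

    def _overlapping(self, table: dict, chrom: str, start: int, end: int):
        rows = table.get(chrom, [])
        # rows sorted by start; any overlapping row has row.start < end
        hi = bisect_left(rows, (end,))
        for row in rows[:hi]:
            if row[1] > start:
                yield row

    def exon_overlaps(self, t: TranscriptModel) -> list[tuple[str, str]]:
        """(gene_id, gene_strand) for every gene exon overlapping a t exon."""
        hits = []
        for e in t.exons:
            for s, en, strand, gid in self._overlapping(self._exons, e.chrom, e.start, e.end):
                hits.append((gid, strand))
        return hits

    def containing_intron(self, t: TranscriptModel) -> str | None:
        iv = t.interval
        for s, en, gid in self._introns.get(iv.chrom, []):
            if s <= iv.start and iv.end <= en:
                return gid
        return None

    def nearest_span(self, t: TranscriptModel) -> tuple[str | None, float]:
        iv = t.interval
        spans = self._spans.get(iv.chrom)
        if not spans:
            return None, math.inf
        for _s, _e, gid in self._overlapping(self._spans, iv.chrom, iv.start, iv.end):
            return gid, 0.0
        best_gid: str | None = None
        best_d = math.inf
        starts = self._span_starts[iv.chrom]
        i = bisect_left(starts, iv.end)
        if i < len(spans):  # nearest gene starting to the right
            s, _e, gid = spans[i]
            best_gid, best_d = gid, float(s - iv.end)
        if i > 0:  # with no overlaps, every span left of i ends at or before iv.start
            max_e, gid = self._span_maxend[iv.chrom][i - 1]
            d = float(iv.start - max_e)
            if d < best_d:
                best_gid, best_d = gid, d
        return best_gid, best_d


def classify_transcript(t: TranscriptModel, index: GeneIndex) -> ClassificationResult:
    hits = index.exon_overlaps(t)
    same = [gid for gid, strand in hits if strand == t.strand]
    if same:
        return ClassificationResult(t.id, "sense_overlap", same[0], 0.0)
    anti = [gid for gid, strand in hits if strand != t.strand]
    if anti:
        return ClassificationResult(t.id, "antisense", anti[0], 0.0)
    host = index.containing_intron(t)
    if host is not None:
        return ClassificationResult(t.id, "intronic", host, 0.0)
    gid, dist = index.nearest_span(t)
    if gid is None:
        log.warning("transcript %s on chromosome with no annotated gene", t.id)
    return ClassificationResult(t.id, "lincRNA", gid, dist)


def classify_all(
    lncrnas: Sequence[TranscriptModel], genes: Sequence[TranscriptModel]
) -> tuple[dict[str, int], list[ClassificationResult]]:
    """Classify every lncRNA; counts always partition the input."""
    index = GeneIndex([g for g in genes if g.biotype == "coding"])
    results = [classify_transcript(t, index) for t in lncrnas]
    counts = {c: 0 for c in CLASSES}
    for r in results:
        counts[r.positional_class] += 1
    assert sum(counts.values()) == len(lncrnas)
    return counts, results
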