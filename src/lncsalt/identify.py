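"""lncRNA identification: the expression / length / coding-potential cascade.

The coding-potential scorer is a self-contained stand-in for external
classifiers (longest-ORF rule plus Fickett TESTCODE statistic) and keeps the
conventional sign convention: score > 0 means coding, and coding transcripts
are discarded. Precomputed external scores can be supplied instead and are
honored verbatim.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import _fickett
from .core import ExpressionMatrix, PipelineConfig, TranscriptModel, ValidationError

log = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass
class CodingAssessment:
    longest_orf_nt: int
    orf_fraction: float
    fickett: float
    score: float

    @property
    def is_coding(self) -> bool:
        return self.score > 0


@dataclass
class LncRNARecord:
    """A transcript that survived all identification filters."""

    transcript: TranscriptModel
    assessment: CodingAssessment | None = None
    positional_class: str | None = None
    host_or_nearest_gene: str | None = None
    distance_bp: float | None = None
    tau: float | None = None
    max_tissue: str | None = None
    de_flags: dict = field(default_factory=dict)
    housekeeping: bool = False

    @property
    def id(self) -> str:
        return self.transcript.id


def _clean(sequence: str) -> str:
    return sequence.upper().replace("U", "T")


def longest_orf(sequence: str) -> tuple[int, int, int]:
    """Longest sense-strand ORF (ATG..stop, stop included) over the 3 frames.

    Returns (length_nt, frame, start); (0, -1, -1) when no complete ORF
    exists. Ties are broken in favor of the 5'-most start.
    """
    seq = _clean(sequence)
    n = len(seq)
    best = (0, -1, -1)
    for frame in range(3):
        open_start = -1
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if open_start < 0:
                if codon == "ATG":
                    open_start = pos
            elif codon in STOP_CODONS:
                length = pos + 3 - open_start
                if length > best[0]:
                    best = (length, frame, open_start)
                open_start = -1
    return best


def fickett_score(sequence: str) -> float:
    """Fickett TESTCODE statistic via the packaged lookup tables.

    Ns are ignored in all counts; a warning is logged when they exceed 10%
    of the sequence.
    """
    seq = _clean(sequence)
    n_frac = seq.count("N") / max(len(seq), 1)
    if n_frac > 0.1:
        log.warning("sequence has %.0f%% Ns; they are ignored in Fickett counts", 100 * n_frac)
    counts = {b: [0, 0, 0] for b in "ACGT"}
    totals = dict.fromkeys("ACGT", 0)
    effective = 0
    for i, base in enumerate(seq):
        if base not in counts:
            continue
        counts[base][i % 3] += 1
        totals[base] += 1
        effective += 1
    score = 0.0
    for base in "ACGT":
        c = counts[base]
        param = max(c) / (min(c) + 1)
        score += _fickett.POSITION_WEIGHT[base] * _fickett.POSITION_PROB[base][
            _fickett.position_bin(param)
        ]
        frac = totals[base] / effective if effective else 0.0
        score += _fickett.CONTENT_WEIGHT[base] * _fickett.CONTENT_PROB[base][
            _fickett.content_bin(frac)
        ]
    return score


def coding_potential(
    sequence: str,
    orf_coding_nt: int = 300,
    w_orf: float = 1.0,
    w_fickett: float = 1.0,
) -> CodingAssessment:
    """Score coding potential; score > 0 flags the transcript as coding.

    Any ORF of at least ``orf_coding_nt`` forces score 1; otherwise the score
    is a weighted sum of the ORF-coverage and Fickett deviations from their
    conventional noncoding anchors (0.5 and 0.95).
    """
    seq = _clean(sequence)
    orf_nt, _frame, _start = longest_orf(seq)
    frac = orf_nt / len(seq) if seq else 0.0
    fick = fickett_score(seq) if seq else 0.0
    if orf_nt >= orf_coding_nt:
        score = 1.0
    else:
        score = w_orf * (frac - 0.5) + w_fickett * (fick - 0.95)
    return CodingAssessment(longest_orf_nt=orf_nt, orf_fraction=frac, fickett=fick, score=score)


def filter_expression(
    transcripts: Sequence[TranscriptModel],
    matrix: ExpressionMatrix,
    min_fpkm: float,
) -> list[TranscriptModel]:
    """Keep transcripts whose FPKM reaches min_fpkm in at least one sample."""
    missing = [t.id for t in transcripts if t.id not in matrix]
    if missing:
        raise ValidationError(f"transcripts without expression rows: {missing[:5]}")
    if not transcripts:
        return []
    maxima = matrix.values.max(axis=1)
    return [t for t in transcripts if maxima[t.id] >= min_fpkm]


def filter_length(
    transcripts: Sequence[TranscriptModel], min_length_nt: int
) -> list[TranscriptModel]:
    """Keep transcripts whose summed exon length is at least min_length_nt."""
    return [t for t in transcripts if t.spliced_length >= min_length_nt]


def filter_noncoding(
    transcripts: Sequence[TranscriptModel],
    config: PipelineConfig,
    external_scores: Mapping[str, tuple[float, float]] | None = None,
) -> tuple[list[TranscriptModel], dict[str, CodingAssessment]]:
    """Drop reference-coding transcripts and those scored coding.

    ``external_scores`` maps transcript id -> (cpc, cnci); when present for a
    transcript it overrides the built-in scorer: discard iff either is > 0.
    """
    kept: list[TranscriptModel] = []
    assessments: dict[str, CodingAssessment] = {}
    for t in transcripts:
        if t.biotype == "coding":
            continue
        if external_scores is not None and t.id in external_scores:
            cpc, cnci = external_scores[t.id]
            if cpc > 0 or cnci > 0:
                continue
            kept.append(t)
            continue
        if t.sequence is None:
            raise ValidationError(f"transcript {t.id} has no sequence for coding assessment")
        a = coding_potential(
            t.sequence,
            orf_coding_nt=config.orf_coding_nt,
            w_orf=config.w_orf,
            w_fickett=config.w_fickett,
        )
        assessments[t.id] = a
        if not a.is_coding:
            kept.append(t)
    return kept, assessments


def identify_lncrnas(
    transcripts: Sequence[TranscriptModel],
    matrix: ExpressionMatrix,
    config: PipelineConfig,
    external_scores: Mapping[str, tuple[float, float]] | None = None,
) -> tuple[list[LncRNARecord], dict[str, int]]:
    """Run the three filters in cascade order and report survivor counts."""
    funnel = {"input": len(transcripts)}
    stage1 = filter_expression(transcripts, matrix, config.min_fpkm)
    funnel["after_expression"] = len(stage1)
    stage2 = filter_length(stage1, config.min_length_nt)
    funnel["after_length"] = len(stage2)
    stage3, assessments = filter_noncoding(stage2, config, external_scores)
    funnel["after_coding_potential"] = len(stage3)
    for name, count in funnel.items():
        log.info("identify funnel %s: %d", name, count)
    records = [
        LncRNARecord(transcript=t, assessment=assessments.get(t.id)) for t in stage3
    ]
    return records, funnel
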