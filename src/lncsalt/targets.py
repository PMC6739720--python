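"""cis and trans lncRNA target prediction.

cis: genes whose span lies within a fixed window of the lncRNA span (or
overlaps it); intronic lncRNAs always pair with their host gene.

trans: two conjunctive gates in order — a local-alignment gate on the
lncRNA vs the reverse complement of each mRNA (identity and Karlin-Altschul
E-value), then a duplex free-energy gate on the matched region.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from scipy import optimize, stats

from .classify import ClassificationResult
from .core import ExpressionMatrix, PipelineConfig, TranscriptModel, ValidationError
from .duplex import duplex_energy

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_MATCH = 1
DEFAULT_MISMATCH = -2
DEFAULT_GAP_OPEN = -5
DEFAULT_GAP_EXTEND = -2


def reverse_complement(seq: str) -> str:
    return seq.upper().replace("U", "T").translate(_COMPLEMENT)[::-1]


@dataclass
class AlignmentHit:
    score: float
    identity: float
    aligned_length: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    evalue: float


@dataclass
class TargetPair:
    lncrna_id: str
    gene_id: str
    mode: str  # cis | trans
    relation: str | None = None  # upstream | downstream | overlapping | intron_host
    distance_bp: float | None = None
    identity: float | None = None
    evalue: float | None = None
    energy_kcal_mol: float | None = None
    rho: float | None = None
    trend: str = "none"


@lru_cache(maxsize=None)
def karlin_lambda(match: int, mismatch: int) -> float:
    """Ungapped Karlin-Altschul lambda under uniform base frequencies:
    the positive root of (4/16) e^(lambda*match) + (12/16) e^(lambda*mismatch) = 1.
    """
    if match <= 0 or mismatch >= 0:
        raise ValidationError("need match > 0 and mismatch < 0")

    def f(lam: float) -> float:
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0

    return float(optimize.brentq(f, 1e-9, 50.0))


# K for the ungapped pair is approximated by the customary nucleotide value;
# the E-value is used only as a monotone gate, so the constant prefactor is
# not load-bearing (lambda is computed exactly).
KARLIN_K = 0.3


def karlin_evalue(score: float, m: int, n: int, match: int = DEFAULT_MATCH,
                  mismatch: int = DEFAULT_MISMATCH, k: float = KARLIN_K) -> float:
    lam = karlin_lambda(match, mismatch)
    return float(k * m * n * math.exp(-lam * score))


def _aligner(match: int, mismatch: int, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    return al


def local_align(
    query: str,
    subject: str,
    match: int = DEFAULT_MATCH,
    mismatch: int = DEFAULT_MISMATCH,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> AlignmentHit:
    """Best Smith-Waterman local alignment with affine gaps.

    A gap of length g costs gap_open + (g - 1) * gap_extend.
    """
    q = query.upper().replace("U", "T")
    s = subject.upper().replace("U", "T")
    if not q or not s:
        raise ValidationError("empty sequence")
    for seq in (q, s):
        if set(seq) - set("ACGTN"):
            raise ValidationError("non-nucleotide characters in sequence")
    al = _aligner(match, mismatch, gap_open, gap_extend)
    alignments = al.align(q, s)
    if len(alignments) == 0 or alignments.score <= 0:
        return AlignmentHit(0.0, 0.0, 0, 0, 0, 0, 0, math.inf)
    best = alignments[0]
    counts = best.counts()
    aligned_length = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / aligned_length if aligned_length else 0.0
    (qs, qe) = (int(best.aligned[0][0][0]), int(best.aligned[0][-1][1]))
    (ss, se) = (int(best.aligned[1][0][0]), int(best.aligned[1][-1][1]))
    ev = karlin_evalue(best.score, len(q), len(s), match, mismatch)
    return AlignmentHit(float(best.score), identity, int(aligned_length), qs, qe, ss, se, ev)


# ---------------------------------------------------------------------------
# cis
# ---------------------------------------------------------------------------

def cis_targets(
    lncrnas: Sequence[TranscriptModel],
    genes: Sequence[TranscriptModel],
    window_bp: int,
    classifications: Mapping[str, ClassificationResult] | None = None,
) -> list[TargetPair]:
    """Pair every gene whose span is within window_bp of each lncRNA span."""
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for v in by_chrom.values():
        v.sort(key=lambda g: g.interval.start)
    pairs: list[TargetPair] = []
    for t in lncrnas:
        iv = t.interval
        seen: set[str] = set()
        for g in by_chrom.get(iv.chrom, []):
            gv = g.interval
            if gv.start > iv.end + window_bp:
                break
            if gv.end < iv.start - window_bp:
                continue
            gap = iv.gap_to(gv)
            if gap > window_bp:
                continue
            if gap == 0:
                relation = "overlapping"
            elif gv.start >= iv.end:
                relation = "downstream" if iv.strand == "+" else "upstream"
            else:
                relation = "upstream" if iv.strand == "+" else "downstream"
            pairs.append(TargetPair(t.id, g.id, "cis", relation, float(gap)))
            seen.add(g.id)
        if classifications is not None:
            cls = classifications.get(t.id)
            if cls is not None and cls.positional_class == "intronic":
                host = cls.host_or_nearest_gene
                pairs = [
                    p for p in pairs if not (p.lncrna_id == t.id and p.gene_id == host)
                ]
                pairs.append(TargetPair(t.id, host, "cis", "intron_host", 0.0))
    return pairs


# ---------------------------------------------------------------------------
# trans
# ---------------------------------------------------------------------------

def trans_targets(
    lnc_seqs: Mapping[str, str],
    mrna_seqs: Mapping[str, str],
    config: PipelineConfig,
    flank: int = 20,
) -> list[TargetPair]:
    """Two-stage screen: alignment gate, then duplex energy on the hit window."""
    out: list[TargetPair] = []
    for lid in sorted(lnc_seqs):
        lseq = lnc_seqs[lid]
        for gid in sorted(mrna_seqs):
            mseq = mrna_seqs[gid]
            hit = local_align(lseq, reverse_complement(mseq))
            if hit.aligned_length == 0:
                continue
            if hit.identity < config.trans_min_identity or hit.evalue >= config.trans_max_evalue:
                continue
            # energy computed on the matched region plus flanks, mapped back
            # to mRNA coordinates (the subject was reverse-complemented)
            qs = max(0, hit.query_start - flank)
            qe = min(len(lseq), hit.query_end + flank)
            ms = max(0, len(mseq) - hit.subject_end - flank)
            me = min(len(mseq), len(mseq) - hit.subject_start + flank)
            energy = duplex_energy(lseq[qs:qe], mseq[ms:me])
            if energy > config.duplex_energy_cut:
                continue
            out.append(
                TargetPair(
                    lid, gid, "trans",
                    identity=hit.identity, evalue=hit.evalue, energy_kcal_mol=energy,
                )
            )
    return out


# ---------------------------------------------------------------------------
# expression concordance
# ---------------------------------------------------------------------------

def pair_concordance(
    pairs: Iterable[TargetPair],
    matrix: ExpressionMatrix,
    concordance_rho: float = 0.9,
) -> list[TargetPair]:
    """Annotate pairs with the Spearman rho of per-(tissue, salt) mean profiles."""
    cond = matrix.condition_means()
    pairs = list(pairs)
    for p in pairs:
        if p.lncrna_id not in cond.index or p.gene_id not in cond.index:
            raise ValidationError(
                f"pair ({p.lncrna_id}, {p.gene_id}) lacks expression rows"
            )
        x = cond.loc[p.lncrna_id].to_numpy()
        y = cond.loc[p.gene_id].to_numpy()
        if np.all(x == x[0]) or np.all(y == y[0]):
            p.rho, p.trend = None, "none"
            continue
        rho = float(stats.spearmanr(x, y).statistic)
        p.rho = rho
        if rho > concordance_rho:
            p.trend = "same"
        elif rho < -concordance_rho:
            p.trend = "opposite"
        else:
            p.trend = "none"
    return pairs
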