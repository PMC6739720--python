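"""Cross-species lncRNA homology and expression comparison.

Homologs are reciprocal best hits of an all-vs-all sense-strand local
alignment, gated on E-value. An exact shared-k-mer prescreen keeps the
all-vs-all affordable; at the identity levels where homology is callable at
all, true pairs always share k-mers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionMatrix, PipelineConfig, ValidationError
from .targets import karlin_evalue, local_align

log = logging.getLogger(__name__)

PRESCREEN_K = 11


@dataclass
class HomologPair:
    id_a: str
    id_b: str
    identity: float
    evalue: float
    score: float
    rho: float | None = None
    similar_pattern: bool = False
    high_in_a_tissues: tuple[str, ...] = ()


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def find_homologs(
    set_a: Mapping[str, str],
    set_b: Mapping[str, str],
    config: PipelineConfig,
    prescreen_k: int = PRESCREEN_K,
) -> tuple[list[HomologPair], set[str], set[str]]:
    """Reciprocal-best-hit pairs plus the species-specific leftovers."""
    ids_a, ids_b = sorted(set_a), sorted(set_b)
    kmers_b = {j: _kmer_set(set_b[j].upper(), prescreen_k) for j in ids_b}
    scores: dict[tuple[str, str], float] = {}
    hits_of_a: dict[str, dict[str, float]] = {i: {} for i in ids_a}
    hits_of_b: dict[str, dict[str, float]] = {j: {} for j in ids_b}
    for i in ids_a:
        seq_a = set_a[i].upper()
        ka = _kmer_set(seq_a, prescreen_k)
        for j in ids_b:
            if not (ka & kmers_b[j]):
                continue
            hit = local_align(seq_a, set_b[j])
            ev = karlin_evalue(hit.score, len(seq_a), len(set_b[j]))
            if ev >= config.trans_max_evalue:
                continue
            scores[(i, j)] = hit.score
            hits_of_a[i][j] = hit.score
            hits_of_b[j][i] = hit.score
    pairs: list[HomologPair] = []
    used_a: set[str] = set()
    used_b: set[str] = set()
    for i in ids_a:
        if not hits_of_a[i]:
            continue
        j = max(sorted(hits_of_a[i]), key=lambda x: hits_of_a[i][x])
        back = max(sorted(hits_of_b[j]), key=lambda x: hits_of_b[j][x])
        if back != i:
            continue
        hit = local_align(set_a[i], set_b[j])
        ev = karlin_evalue(hit.score, len(set_a[i]), len(set_b[j]))
        pairs.append(HomologPair(i, j, hit.identity, ev, hit.score))
        used_a.add(i)
        used_b.add(j)
    specific_a = set(ids_a) - used_a
    specific_b = set(ids_b) - used_b
    return pairs, specific_a, specific_b


def homolog_concordance(
    pairs: Sequence[HomologPair],
    matrix_a: ExpressionMatrix,
    matrix_b: ExpressionMatrix,
    config: PipelineConfig,
) -> list[HomologPair]:
    """Spearman rho over control-condition tissue means; similar iff rho > cut."""
    tissues = matrix_a.tissues
    if set(tissues) != set(matrix_b.tissues):
        raise ValidationError("the two matrices do not share a tissue vocabulary")
    means_a = matrix_a.tissue_means(salt_mM=0)
    means_b = matrix_b.tissue_means(salt_mM=0)[tissues]
    for p in pairs:
        x = means_a.loc[p.id_a].to_numpy()
        y = means_b.loc[p.id_b].to_numpy()
        if np.all(x == x[0]) or np.all(y == y[0]):
            log.warning("constant profile for pair (%s, %s); not comparable", p.id_a, p.id_b)
            p.rho, p.similar_pattern = None, False
            continue
        p.rho = float(stats.spearmanr(x, y).statistic)
        p.similar_pattern = p.rho > config.concordance_rho
    return list(pairs)


def species_specific_de(
    set_a_ids: Iterable[str],
    pairs: Sequence[HomologPair],
    de_a: pd.DataFrame,
) -> tuple[set[str], dict[str, int]]:
    """A-side lncRNAs with no homolog that are salt-responsive; plus a
    per-tissue DE breakdown of that set."""
    paired = {p.id_a for p in pairs}
    de_rows = de_a.loc[de_a["is_de"]]
    responsive = set(de_rows["transcript_id"])
    result = (set(set_a_ids) - paired) & responsive
    per_tissue: dict[str, int] = {}
    sub = de_rows[de_rows["transcript_id"].isin(result)]
    for tissue, grp in sub.groupby("tissue"):
        per_tissue[str(tissue)] = int(grp["transcript_id"].nunique())
    return result, per_tissue


def high_expression_pairs(
    pairs: Sequence[HomologPair],
    matrix_a: ExpressionMatrix,
    matrix_b: ExpressionMatrix,
    fc: float,
) -> list[HomologPair]:
    """Flag tissues where the A member's control mean exceeds fc x the B mean."""
    if fc <= 1:
        raise ValidationError("fc must be > 1")
    tissues = matrix_a.tissues
    means_a = matrix_a.tissue_means(salt_mM=0)
    means_b = matrix_b.tissue_means(salt_mM=0)
    for p in pairs:
        flagged = []
        for t in tissues:
            a = float(means_a.loc[p.id_a, t])
            b = float(means_b.loc[p.id_b, t])
            if b == 0:
                if a > 0:
                    log.info("pair (%s, %s) tissue %s: zero B mean", p.id_a, p.id_b, t)
                    flagged.append(t)
                continue
            if a > fc * b:
                flagged.append(t)
        p.high_in_a_tissues = tuple(flagged)
    return list(pairs)


def tissue_specific_homolog_patterns(
    pairs: Sequence[HomologPair],
    tau_a: pd.DataFrame,
    tau_b: pd.DataFrame,
    config: PipelineConfig,
) -> tuple[int, int]:
    """Among pairs where both members are tissue-specific, count those whose
    max-expression tissue matches vs differs."""
    spec_a = tau_a.loc[tau_a["tau"] > config.tau_specific].set_index("transcript_id")["max_tissue"]
    spec_b = tau_b.loc[tau_b["tau"] > config.tau_specific].set_index("transcript_id")["max_tissue"]
    same = diff = 0
    for p in pairs:
        if p.id_a in spec_a.index and p.id_b in spec_b.index:
            if spec_a[p.id_a] == spec_b[p.id_b]:
                same += 1
            else:
                diff += 1
    return same, diff
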