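"""Hypergeometric over-representation of annotation terms in a gene set."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

from .core import PipelineConfig, ValidationError

log = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    term: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    p_adj_BH: float = 1.0
    enriched: bool = False


def _log_comb(n: int, k: int) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n), in log space."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValidationError(f"infeasible counts k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    hi = min(K, n)
    terms = [
        _log_comb(K, i) + _log_comb(N - K, n - i) - _log_comb(N, n)
        for i in range(k, hi + 1)
        if n - i <= N - K
    ]
    if not terms:
        return 0.0
    return float(min(1.0, np.exp(logsumexp(terms))))


def go_enrichment(
    target_genes: Iterable[str],
    annotation: Mapping[str, Iterable[str]] | pd.DataFrame,
    background: Iterable[str],
    config: PipelineConfig,
) -> list[EnrichmentResult]:
    """One test per term with at least one background hit.

    ``annotation`` maps gene -> terms (or a two-column DataFrame gene_id,
    term_id); genes absent from it count as term-free. The enriched flag uses
    the raw p-value cutoff; a BH-adjusted column is reported alongside.
    """
    background = set(background)
    targets = set(target_genes) & background
    if isinstance(annotation, pd.DataFrame):
        ann: dict[str, set[str]] = {}
        for gene, term in annotation.itertuples(index=False):
            ann.setdefault(str(gene), set()).add(str(term))
    else:
        ann = {g: set(ts) for g, ts in annotation.items()}
    if not set(target_genes) <= background:
        raise ValidationError("target set is not a subset of the background")
    if not targets:
        log.warning("empty target set: no enrichment computed")
        return []
    term_bg: dict[str, int] = {}
    term_hit: dict[str, int] = {}
    for gene in background:
        for term in ann.get(gene, ()):
            term_bg[term] = term_bg.get(term, 0) + 1
            if gene in targets:
                term_hit[term] = term_hit.get(term, 0) + 1
    N, n = len(background), len(targets)
    results = []
    for term in sorted(term_bg):
        K = term_bg[term]
        k = term_hit.get(term, 0)
        p = hypergeometric_tail(k, K, n, N)
        results.append(EnrichmentResult(term, k, K, n, N, p))
    if results:
        padj = stats.false_discovery_control([r.p_value for r in results], method="bh")
        for r, q in zip(results, padj):
            r.p_adj_BH = float(q)
            r.enriched = r.p_value < config.go_p_cut
    return sorted(results, key=lambda r: (r.p_value, r.term))
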