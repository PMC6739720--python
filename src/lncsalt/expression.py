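"""Salt-stress contrasts, tissue-specificity index and derived sets.

Differential expression between two salt doses within a tissue is a
two-sided pooled-variance t-test on log2(FPKM + pseudocount) over
replicates (with three replicates per group the Satterthwaite correction
is badly conservative, so the pooled test is used to keep the type-I error
at its nominal level); a
transcript is called DE when |log2FC| >= log2fc_cut and p < p_cut (raw p;
a Benjamini-Hochberg column is reported alongside).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionMatrix, PipelineConfig, ValidationError

log = logging.getLogger(__name__)

CONTRASTS = ((0, 150), (0, 300), (150, 300))
_P_FLOOR = 1e-300  # keep p in (0, 1] for degenerate zero-variance cases


@dataclass
class ContrastResult:
    transcript_id: str
    tissue: str
    contrast: tuple[int, int]
    log2fc: float
    p_value: float
    is_de: bool


@dataclass
class TauResult:
    transcript_id: str
    tau: float
    max_tissue: str


def log2_fold_change(mean_b: float, mean_a: float, pseudocount: float = 0.01) -> float:
    """log2((mean_b + pc) / (mean_a + pc)); b is the treated group."""
    if mean_a < 0 or mean_b < 0:
        raise ValidationError("negative group means")
    if pseudocount == 0 and (mean_a == 0 or mean_b == 0):
        raise ValidationError("zero mean with zero pseudocount: fold change undefined")
    return math.log2((mean_b + pseudocount) / (mean_a + pseudocount))


def contrast_test(group_a: Sequence[float], group_b: Sequence[float], pseudocount: float = 0.01) -> float:
    """Two-sided pooled-variance t-test on log2(FPKM + pseudocount)."""
    a = np.log2(np.asarray(group_a, dtype=float) + pseudocount)
    b = np.log2(np.asarray(group_b, dtype=float) + pseudocount)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("need >= 2 replicates per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else _P_FLOOR
    p = stats.ttest_ind(a, b, equal_var=True).pvalue
    return float(max(min(p, 1.0), _P_FLOOR))


def _ttest_vectorized(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise pooled-t p-values with the same degenerate-case handling."""
    p = stats.ttest_ind(A, B, axis=1, equal_var=True).pvalue
    var0 = (A.var(axis=1, ddof=1) == 0) & (B.var(axis=1, ddof=1) == 0)
    eq = np.isclose(A.mean(axis=1), B.mean(axis=1))
    p = np.where(var0, np.where(eq, 1.0, _P_FLOOR), p)
    return np.clip(np.nan_to_num(p, nan=1.0), _P_FLOOR, 1.0)


def call_de(matrix: ExpressionMatrix, config: PipelineConfig) -> pd.DataFrame:
    """One row per transcript x tissue x contrast.

    Columns: transcript_id, tissue, salt_a, salt_b, log2fc, p, p_adj_BH, is_de.
    """
    pc = config.pseudocount
    frames = []
    for tissue in matrix.tissues:
        for salt_a, salt_b in CONTRASTS:
            cols_a = matrix.columns_for(tissue=tissue, salt_mM=salt_a)
            cols_b = matrix.columns_for(tissue=tissue, salt_mM=salt_b)
            if len(cols_a) < 2 or len(cols_b) < 2:
                log.warning(
                    "skipping contrast %s %s vs %s: missing replicate group",
                    tissue, salt_a, salt_b,
                )
                continue
            A = np.log2(matrix.values[cols_a].to_numpy() + pc)
            B = np.log2(matrix.values[cols_b].to_numpy() + pc)
            mean_a = matrix.values[cols_a].mean(axis=1).to_numpy()
            mean_b = matrix.values[cols_b].mean(axis=1).to_numpy()
            lfc = np.log2((mean_b + pc) / (mean_a + pc))
            p = _ttest_vectorized(A, B)
            frames.append(
                pd.DataFrame(
                    {
                        "transcript_id": matrix.transcript_ids,
                        "tissue": tissue,
                        "salt_a": salt_a,
                        "salt_b": salt_b,
                        "log2fc": lfc,
                        "p": p,
                    }
                )
            )
    if not frames:
        raise ValidationError("no testable contrasts in the design")
    de = pd.concat(frames, ignore_index=True)
    de["p_adj_BH"] = stats.false_discovery_control(de["p"].to_numpy(), method="bh")
    de["is_de"] = (de["log2fc"].abs() >= config.log2fc_cut) & (de["p"] < config.p_cut)
    return de


def salt_responsive_ids(de: pd.DataFrame) -> set[str]:
    """Transcripts DE in at least one (tissue, contrast)."""
    if de.empty:
        return set()
    return set(de.loc[de["is_de"], "transcript_id"])


def tau_index(tissue_means: Sequence[float], tissue_names: Sequence[str] | None = None) -> TauResult | None:
    """Tissue-specificity index: sum_i (1 - x_i / x_max) / (n - 1).

    Returns None (with a warning) for an all-zero profile.
    """
    x = np.asarray(tissue_means, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValidationError("need >= 2 tissue means")
    if (x < 0).any():
        raise ValidationError("negative tissue means")
    if x.max() == 0:
        log.warning("all-zero expression profile: tau undefined")
        return None
    tau = float(np.sum(1.0 - x / x.max()) / (len(x) - 1))
    names = list(tissue_names) if tissue_names is not None else [str(i) for i in range(len(x))]
    return TauResult("", tau, names[int(np.argmax(x))])


def tau_table(matrix: ExpressionMatrix, config: PipelineConfig) -> pd.DataFrame:
    """Tau per transcript from tissue means (control samples by default)."""
    salt = 0 if config.tau_samples == "control" else None
    means = matrix.tissue_means(salt_mM=salt)
    rows = []
    for tid, profile in means.iterrows():
        r = tau_index(profile.to_numpy(), means.columns)
        if r is None:
            log.warning("transcript %s excluded from tau (all-zero profile)", tid)
            continue
        rows.append({"transcript_id": tid, "tau": r.tau, "max_tissue": r.max_tissue})
    return pd.DataFrame(rows, columns=["transcript_id", "tau", "max_tissue"])


def specificity_sets(
    tau_df: pd.DataFrame, de: pd.DataFrame, config: PipelineConfig
) -> tuple[set[str], set[str], set[str]]:
    """(tissue_specific, housekeeping, tissue_specific_de) per the thresholds.

    tissue_specific: tau > tau_specific (strict).
    housekeeping: tau < tau_housekeeping and never salt-responsive.
    tissue_specific_de: salt-responsive in exactly one tissue.
    """
    responsive = salt_responsive_ids(de)
    if tau_df.empty:
        tissue_specific: set[str] = set()
        low_tau: set[str] = set()
    else:
        tissue_specific = set(tau_df.loc[tau_df["tau"] > config.tau_specific, "transcript_id"])
        low_tau = set(tau_df.loc[tau_df["tau"] < config.tau_housekeeping, "transcript_id"])
    housekeeping = low_tau - responsive
    if de.empty:
        tissue_specific_de: set[str] = set()
    else:
        de_rows = de.loc[de["is_de"]]
        tissues_per_tx = de_rows.groupby("transcript_id")["tissue"].nunique()
        tissue_specific_de = set(tissues_per_tx.index[tissues_per_tx == 1])
    return tissue_specific, housekeeping, tissue_specific_de


def class_correlation_contrast(
    matrix: ExpressionMatrix,
    set_a: Iterable[str],
    set_b: Iterable[str],
    salt_mM: int | None = 0,
) -> tuple[float, float]:
    """Mean inter-tissue Spearman rho within each transcript set."""

    def mean_rho(ids: list[str]) -> float:
        if not ids:
            raise ValidationError("empty transcript set")
        means = matrix.subset(ids).tissue_means(salt_mM=salt_mM)
        rhos = []
        for t1, t2 in itertools.combinations(means.columns, 2):
            x, y = means[t1].to_numpy(), means[t2].to_numpy()
            if np.all(x == x[0]) or np.all(y == y[0]):
                log.warning("constant tissue vector; pair (%s, %s) excluded", t1, t2)
                continue
            rhos.append(stats.spearmanr(x, y).statistic)
        if not rhos:
            raise ValidationError("no tissue pair with non-constant vectors")
        return float(np.mean(rhos))

    return mean_rho(list(set_a)), mean_rho(list(set_b))
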