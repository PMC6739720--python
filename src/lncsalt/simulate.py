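"""Paired-species synthetic datasets with planted truth.

Generates a coding-gene annotation plus lncRNAs constructed to be
unambiguous members of the four positional classes, transcript sequences
honoring the coding/noncoding constraints the identification stage tests,
a tissue x salt x replicate FPKM matrix with planted differential and
tissue-specific effects, and a mutated sister species with a known homolog
map. Everything derives from numpy Generators seeded explicitly, so equal
seeds give byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    ExpressionMatrix,
    GenomicInterval,
    SampleMeta,
    TranscriptModel,
    ValidationError,
    SALT_LEVELS,
    TISSUES,
)
from .identify import longest_orf

log = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))
STOPS = ("TAA", "TAG", "TGA")

GENE_SPACING = 30_000
NEAR_LINC_GAP = 3_000
FAR_LINC_GAP = 14_000
LNC_MIN_LEN = 300
LNC_MAX_LEN = 1_200
TRANS_WINDOW = 150

LOW_LOG2 = math.log2(0.01)  # off-tissue baseline for tissue-specific transcripts


@dataclass
class SimTruth:
    """Planted ground truth, flat across both species (ids carry a prefix)."""

    lncrna_class: dict[str, str] = field(default_factory=dict)
    coding_ids: list[str] = field(default_factory=list)
    cis_pairs: list[tuple[str, str]] = field(default_factory=list)
    trans_pairs: list[tuple[str, str]] = field(default_factory=list)
    homolog_map: dict[str, str] = field(default_factory=dict)
    tissue_specific: dict[str, str] = field(default_factory=dict)
    de_effects: dict[str, dict[str, dict[int, float]]] = field(default_factory=dict)
    housekeeping_ids: list[str] = field(default_factory=list)
    high_pair_ids: list[str] = field(default_factory=list)
    baselines: dict[str, dict[str, float]] = field(default_factory=dict)

    def lnc_ids(self, prefix: str | None = None) -> list[str]:
        ids = sorted(self.lncrna_class)
        if prefix is None:
            return ids
        return [i for i in ids if i.startswith(prefix)]

    def lnc_by_class(self, prefix: str | None = None) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for tid in self.lnc_ids(prefix):
            out.setdefault(self.lncrna_class[tid], []).append(tid)
        return out

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["cis_pairs"] = [tuple(p) for p in d["cis_pairs"]]
        d["trans_pairs"] = [tuple(p) for p in d["trans_pairs"]]
        d["de_effects"] = {
            tid: {t: {int(s): e for s, e in per_salt.items()} for t, per_salt in per_t.items()}
            for tid, per_t in d["de_effects"].items()
        }
        return cls(**d)


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _enforce_noncoding(seq: str, rng: np.random.Generator, max_orf_nt: int = 180,
                       max_orf_fraction: float = 0.45,
                       protect: tuple[int, int] | None = None) -> str:
    """Break ATGs until no ORF exceeds the noncoding limits.

    ``protect`` is a half-open slice that must not be touched (used for
    planted complementarity windows); the start codon is then shifted by
    choosing a different offending ORF mutation point or gives up with an
    error after bounded retries.
    """
    limit = min(max_orf_nt, int(max_orf_fraction * len(seq)) // 3 * 3)
    s = list(seq)
    for _ in range(200):
        orf_nt, _frame, start = longest_orf("".join(s))
        if orf_nt <= limit:
            return "".join(s)
        if protect and protect[0] <= start < protect[1]:
            # drop an in-frame stop right after the protected window
            placed = False
            for pos in range(start, start + orf_nt - 2, 3):
                if pos >= protect[1] and pos + 3 <= len(s):
                    s[pos : pos + 3] = list("TAA")
                    placed = True
                    break
            if not placed:
                raise ValidationError("cannot break ORF without touching protected window")
        else:
            s[start] = "C"  # destroy the start codon
    raise ValidationError("failed to enforce noncoding constraint")


def _coding_sequence(rng: np.random.Generator, n_codons: int, utr5: int = 30, utr3: int = 60) -> str:
    """UTR + ATG + stop-free codons + stop + UTR; ORF length (n_codons+2)*3."""
    sense_codons = [
        a + b + c
        for a in "ACGT" for b in "ACGT" for c in "ACGT"
        if a + b + c not in STOPS and a + b + c != "ATG"
    ]
    body = "".join(rng.choice(sense_codons) for _ in range(n_codons))
    stop = STOPS[int(rng.integers(0, 3))]
    return _random_seq(rng, utr5) + "ATG" + body + stop + _random_seq(rng, utr3)


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    s = np.array(list(seq))
    hits = np.flatnonzero(rng.random(len(s)) < rate)
    for i in hits:
        choices = [b for b in "ACGT" if b != s[i]]
        s[i] = choices[int(rng.integers(0, 3))]
    return "".join(s)


def _split_lengths(total: int, parts: int) -> list[int]:
    """Split total into near-equal contiguous part lengths."""
    pts = [int(round(total * (i + 1) / parts)) for i in range(parts - 1)]
    lengths, prev = [], 0
    for p in pts + [total]:
        lengths.append(p - prev)
        prev = p
    return lengths


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

def simulate_genome(
    n_genes: int,
    n_lnc_per_class: int,
    seed: int,
    prefix: str = "A",
    chrom: str = "chr1",
) -> tuple[list[TranscriptModel], SimTruth]:
    """Coding genes plus unambiguous members of the four lncRNA classes."""
    if n_genes < 2:
        raise ValidationError("n_genes must be >= 2")
    rng = np.random.default_rng(seed)
    truth = SimTruth()
    transcripts: list[TranscriptModel] = []
    genes: list[TranscriptModel] = []

    cursor = 10_000
    for gi in range(n_genes):
        gid = f"{prefix}_G{gi:04d}"
        n_codons = int(rng.integers(120, 200))
        seq = _coding_sequence(rng, n_codons)
        strand = "+" if rng.random() < 0.5 else "-"
        exon_lengths = _split_lengths(len(seq), 3)
        intron1 = int(rng.integers(2_500, 4_000))
        intron2 = int(rng.integers(500, 1_500))
        starts = [
            cursor,
            cursor + exon_lengths[0] + intron1,
            cursor + exon_lengths[0] + intron1 + exon_lengths[1] + intron2,
        ]
        exons = [
            GenomicInterval(chrom, s, s + L, strand)
            for s, L in zip(starts, exon_lengths)
        ]
        g = TranscriptModel(id=gid, exons=exons, gene_id=gid, sequence=seq, biotype="coding")
        genes.append(g)
        transcripts.append(g)
        truth.coding_ids.append(gid)
        cursor = g.interval.end + GENE_SPACING

    lnc_counter = 0

    def new_lnc(
        cls: str,
        exons: list[GenomicInterval],
        seq: str,
    ) -> TranscriptModel:
        nonlocal lnc_counter
        tid = f"{prefix}_L{lnc_counter:04d}"
        lnc_counter += 1
        t = TranscriptModel(id=tid, exons=exons, gene_id=tid, sequence=seq, biotype="unknown")
        transcripts.append(t)
        truth.lncrna_class[tid] = cls
        return t

    def lnc_length() -> int:
        return int(rng.integers(LNC_MIN_LEN, LNC_MAX_LEN + 1))

    # intronic: wholly inside intron 1 of a host gene
    for i in range(n_lnc_per_class):
        host = genes[i % n_genes]
        intron = host.introns[0]
        length = min(lnc_length(), len(intron) - 200)
        if length < LNC_MIN_LEN:
            raise ValidationError("intronic class impossible: host introns too small")
        start = intron.start + 100
        strand = "+" if rng.random() < 0.5 else "-"
        seq = _enforce_noncoding(_random_seq(rng, length), rng)
        t = new_lnc("intronic", [GenomicInterval(chrom, start, start + length, strand)], seq)
        truth.cis_pairs.append((t.id, host.id))

    # antisense: exon-exon overlap with the host's first exon, opposite strand
    for i in range(n_lnc_per_class):
        host = genes[i % n_genes]
        ex = host.exons[0]
        length = lnc_length()
        start = ex.start + 20
        strand = "-" if host.strand == "+" else "+"
        seq = _enforce_noncoding(_random_seq(rng, length), rng)
        t = new_lnc("antisense", [GenomicInterval(chrom, start, start + length, strand)], seq)
        truth.cis_pairs.append((t.id, host.id))

    # sense_overlap: partial same-strand overlap with the host's last exon
    for i in range(n_lnc_per_class):
        host = genes[i % n_genes]
        ex = host.exons[-1]
        length = max(lnc_length(), 300)
        start = ex.end - 100  # 100 bp exon overlap, rest runs past the gene end
        seq = _enforce_noncoding(_random_seq(rng, length), rng)
        t = new_lnc(
            "sense_overlap", [GenomicInterval(chrom, start, start + length, host.strand)], seq
        )
        truth.cis_pairs.append((t.id, host.id))

    # lincRNA: alternating near (cis-paired) and far placements
    far_lincs: list[TranscriptModel] = []
    for i in range(n_lnc_per_class):
        host = genes[i % n_genes]
        length = lnc_length()
        near = i % 2 == 0
        gap = NEAR_LINC_GAP if near else FAR_LINC_GAP
        start = host.interval.end + gap + 60 * (i // n_genes)
        strand = "+" if rng.random() < 0.5 else "-"
        seq = _enforce_noncoding(_random_seq(rng, length), rng)
        t = new_lnc("lincRNA", [GenomicInterval(chrom, start, start + length, strand)], seq)
        if near:
            truth.cis_pairs.append((t.id, host.id))
        else:
            far_lincs.append(t)

    # plant trans pairs: far lincRNAs carry the reverse complement of a window
    # of a distal mRNA
    for k, t in enumerate(far_lincs[: max(2, len(far_lincs) // 2)]):
        target = genes[(k + n_genes // 2) % n_genes]
        if abs(target.interval.start - t.interval.start) < 12_000:
            continue
        embedded = _embed_complement(t.sequence, target.sequence, rng)
        if embedded is None:
            log.warning("could not plant trans pair for %s", t.id)
            continue
        t.sequence = embedded
        truth.trans_pairs.append((t.id, target.id))

    return transcripts, truth


def _embed_complement(
    lnc_seq: str, mrna_seq: str, rng: np.random.Generator, window: int = TRANS_WINDOW
) -> str | None:
    """Replace a slice of lnc_seq with the reverse complement of an mRNA window,
    keeping the result noncoding."""
    comp = str.maketrans("ACGT", "TGCA")
    if len(mrna_seq) < window or len(lnc_seq) < window + 40:
        return None
    insert_at = (len(lnc_seq) - window) // 2
    for _ in range(25):
        w0 = int(rng.integers(0, len(mrna_seq) - window + 1))
        rc = mrna_seq[w0 : w0 + window].translate(comp)[::-1]
        candidate = lnc_seq[:insert_at] + rc + lnc_seq[insert_at + window:]
        try:
            fixed = _enforce_noncoding(
                candidate, rng, protect=(insert_at, insert_at + window)
            )
            return fixed
        except ValidationError:
            continue
    return None


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------

def plan_expression(
    truth: SimTruth,
    prefix: str,
    seed: int,
    tissues: Sequence[str] = TISSUES,
    de_fraction: float = 0.4,
    ts_fraction: float = 0.2,
    hk_fraction: float = 0.1,
    lnc_tissue_jitter_sd: float = 2.0,
    mrna_tissue_jitter_sd: float = 0.3,
    de_effect_150: float = 1.0,
    de_effect_300: float = 2.0,
) -> None:
    """Assign expression roles and per-tissue log2-FPKM baselines (in truth).

    Roles partition the species' lncRNAs into DE, tissue-specific,
    housekeeping and null; coding genes get near-uniform tissue baselines.
    """
    rng = np.random.default_rng(seed)
    # skip transcripts that already carry a plan (e.g. shared homologs copied
    # over from the sister species)
    lnc_ids = [i for i in truth.lnc_ids(prefix) if i not in truth.baselines]
    coding = [
        g for g in truth.coding_ids if g.startswith(prefix) and g not in truth.baselines
    ]
    rng.shuffle(lnc_ids)
    # lncRNAs carrying planted trans windows must be salt-responsive, or the
    # trans screen (which only sees DE lncRNAs) could never recover them
    forced_de = [l for l, _ in truth.trans_pairs if l in lnc_ids]
    lnc_ids = forced_de + [i for i in lnc_ids if i not in forced_de]
    n = len(lnc_ids)
    n_de = max(int(round(de_fraction * n)), len(forced_de))
    n_ts = int(round(ts_fraction * n))
    n_hk = int(round(hk_fraction * n))
    de_ids = lnc_ids[:n_de]
    ts_ids = lnc_ids[n_de : n_de + n_ts]
    hk_ids = lnc_ids[n_de + n_ts : n_de + n_ts + n_hk]
    null_ids = lnc_ids[n_de + n_ts + n_hk :]

    for gid in coding:
        base = rng.uniform(2.0, 5.0)
        truth.baselines[gid] = {
            t: float(base + rng.normal(0, mrna_tissue_jitter_sd)) for t in tissues
        }
    for tid in de_ids:
        base = rng.uniform(1.0, 5.0)
        truth.baselines[tid] = {
            t: float(base + rng.normal(0, lnc_tissue_jitter_sd)) for t in tissues
        }
        sign = 1.0 if rng.random() < 0.5 else -1.0
        k_tissues = 1 + int(rng.random() < 0.4)
        chosen = list(rng.choice(list(tissues), size=k_tissues, replace=False))
        truth.de_effects[tid] = {
            t: {150: float(sign * de_effect_150), 300: float(sign * de_effect_300)}
            for t in chosen
        }
    for tid in ts_ids:
        target = str(rng.choice(list(tissues)))
        base = rng.uniform(3.0, 6.0)
        truth.baselines[tid] = {
            t: float(base) if t == target else LOW_LOG2 for t in tissues
        }
        truth.tissue_specific[tid] = target
    for tid in hk_ids:
        base = rng.uniform(2.0, 5.0)
        truth.baselines[tid] = {t: float(base) for t in tissues}
        truth.housekeeping_ids.append(tid)
    for tid in null_ids:
        base = rng.uniform(1.0, 5.0)
        truth.baselines[tid] = {
            t: float(base + rng.normal(0, lnc_tissue_jitter_sd)) for t in tissues
        }
    truth.housekeeping_ids.sort()


def copy_expression_plan(
    truth: SimTruth,
    n_high_pairs: int,
    seed: int,
    high_factor_log2: float = math.log2(5.0),
) -> None:
    """Give shared species-B lncRNAs the expression plan of their A homolog.

    A deterministic subset of shared pairs is planted with a B baseline
    shifted down by ``high_factor_log2`` in every tissue (high-in-A pairs).
    """
    rng = np.random.default_rng(seed)
    shared_a = sorted(truth.homolog_map)
    high = set(shared_a[: min(n_high_pairs, len(shared_a))])
    for aid in shared_a:
        bid = truth.homolog_map[aid]
        shift = high_factor_log2 if aid in high else 0.0
        truth.baselines[bid] = {
            t: v - shift for t, v in truth.baselines[aid].items()
        }
        if aid in truth.de_effects:
            truth.de_effects[bid] = {
                t: dict(per_salt) for t, per_salt in truth.de_effects[aid].items()
            }
        if aid in truth.tissue_specific:
            truth.tissue_specific[bid] = truth.tissue_specific[aid]
        if aid in truth.housekeeping_ids:
            truth.housekeeping_ids.append(bid)
    truth.high_pair_ids = sorted(high)


def simulate_expression(
    transcript_ids: Sequence[str],
    truth: SimTruth,
    noise_sd: float,
    seed: int,
    tissues: Sequence[str] = TISSUES,
    salts: Sequence[int] = SALT_LEVELS,
    replicates: int = 3,
) -> ExpressionMatrix:
    """FPKM matrix from planted baselines + DE effects + log2-normal noise."""
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    if 0 not in salts:
        raise ValidationError("design missing the 0 mM control level; contrasts undefined")
    missing = [t for t in transcript_ids if t not in truth.baselines]
    if missing:
        raise ValidationError(f"no expression plan for: {missing[:5]} (run plan_expression)")
    rng = np.random.default_rng(seed)
    samples: dict[str, SampleMeta] = {}
    cols: dict[str, np.ndarray] = {}
    ids = list(transcript_ids)
    for tissue in tissues:
        for salt in salts:
            for rep in range(1, replicates + 1):
                sid = f"{tissue}_{salt}_{rep}"
                samples[sid] = SampleMeta(tissue=tissue, salt_mM=int(salt), replicate=rep)
                x = np.array(
                    [
                        truth.baselines[tid][tissue]
                        + truth.de_effects.get(tid, {}).get(tissue, {}).get(int(salt), 0.0)
                        for tid in ids
                    ]
                )
                if noise_sd > 0:
                    x = x + rng.normal(0.0, noise_sd, size=len(ids))
                cols[sid] = np.power(2.0, x)
    values = pd.DataFrame(cols, index=ids)
    return ExpressionMatrix(values, samples)


# ---------------------------------------------------------------------------
# sister species
# ---------------------------------------------------------------------------

def simulate_sister_species(
    transcripts_a: Sequence[TranscriptModel],
    truth: SimTruth,
    divergence: float,
    fraction_shared_lnc: float,
    seed: int,
    prefix_a: str = "A",
    prefix_b: str = "B",
    min_identity_warn: float = 0.95,
) -> list[TranscriptModel]:
    """Species B: syntenic copy with mutated shared lncRNAs and fresh others.

    Updates ``truth`` in place (classes, cis/trans pairs, homolog_map).
    """
    if not (0 <= divergence <= 0.3):
        raise ValidationError("divergence must be in [0, 0.3]")
    if not (0 <= fraction_shared_lnc <= 1):
        raise ValidationError("fraction_shared_lnc must be in [0, 1]")
    if fraction_shared_lnc > 0 and 1 - divergence < min_identity_warn:
        log.warning(
            "divergence %.3f implies identity below %.2f: homology recall will drop",
            divergence, min_identity_warn,
        )
    rng = np.random.default_rng(seed)
    rename = {}
    lnc_a = [t for t in transcripts_a if t.id in truth.lncrna_class]
    n_shared = int(round(fraction_shared_lnc * len(lnc_a)))
    shared_ids = {t.id for t in lnc_a[:n_shared]}  # syntenic order
    out: list[TranscriptModel] = []
    for t in transcripts_a:
        bid = prefix_b + t.id[len(prefix_a):]
        rename[t.id] = bid
        if t.biotype == "coding":
            seq = t.sequence
        elif t.id in shared_ids:
            seq = _mutate(t.sequence, rng, divergence)
            seq = _enforce_noncoding(seq, rng)
            truth.homolog_map[t.id] = bid
        else:
            seq = _enforce_noncoding(_random_seq(rng, len(t.sequence)), rng)
        b = TranscriptModel(
            id=bid, exons=list(t.exons), gene_id=bid, sequence=seq, biotype=t.biotype
        )
        out.append(b)
        if t.id in truth.lncrna_class:
            truth.lncrna_class[bid] = truth.lncrna_class[t.id]
        else:
            truth.coding_ids.append(bid)
    for lid, gid in list(truth.cis_pairs):
        if lid.startswith(prefix_a + "_"):
            truth.cis_pairs.append((rename[lid], rename[gid]))
    for lid, gid in list(truth.trans_pairs):
        if lid.startswith(prefix_a + "_") and lid in shared_ids:
            truth.trans_pairs.append((rename[lid], rename[gid]))
    return out


# ---------------------------------------------------------------------------
# toy GO annotation
# ---------------------------------------------------------------------------

def simulate_go_annotation(
    gene_ids: Sequence[str], seed: int, n_terms: int = 20, mean_terms_per_gene: float = 1.5
) -> pd.DataFrame:
    """Random gene -> term table over a toy ontology of n_terms terms."""
    rng = np.random.default_rng(seed)
    terms = [f"GO:{i:07d}" for i in range(1, n_terms + 1)]
    rows = []
    for gid in sorted(gene_ids):
        k = min(rng.poisson(mean_terms_per_gene), n_terms)
        for term in sorted(rng.choice(terms, size=k, replace=False)):
            rows.append({"gene_id": gid, "term_id": term})
    return pd.DataFrame(rows, columns=["gene_id", "term_id"])
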