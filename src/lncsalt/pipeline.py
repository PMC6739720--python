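"""End-to-end orchestration: identify -> classify -> DE -> tau -> targets ->
cross-species -> enrichment, with TSV/JSON outputs and a per-stage summary."""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import pandas as pd

from . import classify as classify_mod
from . import enrichment as enrichment_mod
from . import expression as expression_mod
from . import homology as homology_mod
from . import identify as identify_mod
from . import io as io_mod
from . import simulate as simulate_mod
from . import targets as targets_mod
from .core import ExpressionMatrix, PipelineConfig, TranscriptModel

log = logging.getLogger(__name__)

SPECIES_FILES = {
    "annotation": "annotation_{s}.gtf",
    "fasta": "transcripts_{s}.fa",
    "expression": "expression_{s}.tsv",
    "samples": "samples_{s}.tsv",
    "go": "go_{s}.tsv",
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return wrapper
    return deco


def _fmt_dist(d: float | None) -> str:
    if d is None:
        return ""
    return "inf" if math.isinf(d) else str(int(d))


class SpeciesInputs:
    """Loaded per-species inputs."""

    def __init__(self, transcripts: list[TranscriptModel], matrix: ExpressionMatrix,
                 go: pd.DataFrame | None = None):
        self.transcripts = transcripts
        self.matrix = matrix
        self.go = go

    @classmethod
    def load(cls, data_dir: str | Path, species: str) -> "SpeciesInputs":
        data_dir = Path(data_dir)
        s = species.lower()
        transcripts = io_mod.read_annotation(data_dir / SPECIES_FILES["annotation"].format(s=s))
        seqs = io_mod.read_fasta(data_dir / SPECIES_FILES["fasta"].format(s=s))
        io_mod.attach_sequences(transcripts, seqs)
        matrix = io_mod.read_expression(
            data_dir / SPECIES_FILES["expression"].format(s=s),
            data_dir / SPECIES_FILES["samples"].format(s=s),
        )
        go_path = data_dir / SPECIES_FILES["go"].format(s=s)
        go = pd.read_csv(go_path, sep="\t", comment="#") if go_path.exists() else None
        return cls(transcripts, matrix, go)


def analyse_species(inputs: SpeciesInputs, config: PipelineConfig) -> dict:
    """Single-species stages; returns a dict of intermediate results."""
    r: dict = {}
    r["records"], r["funnel"] = _stage("identify")(identify_mod.identify_lncrnas)(
        inputs.transcripts, inputs.matrix, config
    )
    lnc_models = [rec.transcript for rec in r["records"]]
    genes = [t for t in inputs.transcripts if t.biotype == "coding"]
    r["class_counts"], class_results = _stage("classify")(classify_mod.classify_all)(
        lnc_models, genes
    )
    r["classifications"] = {c.transcript_id: c for c in class_results}
    lnc_ids = [t.id for t in lnc_models]
    lnc_matrix = inputs.matrix.subset(lnc_ids) if lnc_ids else inputs.matrix
    r["de"] = _stage("de")(expression_mod.call_de)(lnc_matrix, config)
    r["tau"] = _stage("tau")(expression_mod.tau_table)(lnc_matrix, config)
    r["tissue_specific"], r["housekeeping"], r["tissue_specific_de"] = _stage("tau")(
        expression_mod.specificity_sets
    )(r["tau"], r["de"], config)
    responsive = expression_mod.salt_responsive_ids(r["de"])
    r["salt_responsive"] = responsive
    de_lnc = [t for t in lnc_models if t.id in responsive]
    r["cis"] = _stage("targets")(targets_mod.cis_targets)(
        de_lnc, genes, config.cis_window_bp, r["classifications"]
    )
    lnc_seqs = {t.id: t.sequence for t in de_lnc if t.sequence}
    mrna_seqs = {g.id: g.sequence for g in genes if g.sequence}
    r["trans"] = _stage("targets")(targets_mod.trans_targets)(lnc_seqs, mrna_seqs, config)
    pairs = r["cis"] + r["trans"]
    known = set(inputs.matrix.transcript_ids)
    scorable = [p for p in pairs if p.lncrna_id in known and p.gene_id in known]
    r["targets"] = _stage("targets")(targets_mod.pair_concordance)(
        scorable, inputs.matrix, config.concordance_rho
    )
    r["genes"] = genes
    r["lnc_models"] = lnc_models
    return r


@_stage("compare")
def compare_species(res_a: dict, res_b: dict, matrix_a: ExpressionMatrix,
                    matrix_b: ExpressionMatrix, config: PipelineConfig) -> dict:
    seqs_a = {t.id: t.sequence for t in res_a["lnc_models"] if t.sequence}
    seqs_b = {t.id: t.sequence for t in res_b["lnc_models"] if t.sequence}
    pairs, specific_a, specific_b = homology_mod.find_homologs(seqs_a, seqs_b, config)
    pairs = homology_mod.homolog_concordance(
        pairs, matrix_a.subset(sorted(seqs_a)), matrix_b.subset(sorted(seqs_b)), config
    )
    pairs = homology_mod.high_expression_pairs(
        pairs, matrix_a.subset(sorted(seqs_a)), matrix_b.subset(sorted(seqs_b)),
        config.homolog_expression_fc,
    )
    ss_de, per_tissue = homology_mod.species_specific_de(
        sorted(seqs_a), pairs, res_a["de"]
    )
    same, diff = homology_mod.tissue_specific_homolog_patterns(
        pairs, res_a["tau"], res_b["tau"], config
    )
    return {
        "pairs": pairs,
        "specific_a": specific_a,
        "specific_b": specific_b,
        "species_specific_de": ss_de,
        "species_specific_de_per_tissue": per_tissue,
        "ts_homolog_same_tissue": same,
        "ts_homolog_diff_tissue": diff,
    }


def _lncrna_table(res: dict) -> pd.DataFrame:
    rows = []
    tau_map = res["tau"].set_index("transcript_id")["tau"] if len(res["tau"]) else {}
    max_t = res["tau"].set_index("transcript_id")["max_tissue"] if len(res["tau"]) else {}
    for rec in res["records"]:
        c = res["classifications"].get(rec.id)
        a = rec.assessment
        rows.append(
            {
                "transcript_id": rec.id,
                "class": c.positional_class if c else "",
                "host_or_nearest_gene": (c.host_or_nearest_gene or "") if c else "",
                "distance_bp": _fmt_dist(c.distance_bp) if c else "",
                "length_nt": rec.transcript.spliced_length,
                "longest_orf_nt": a.longest_orf_nt if a else "",
                "fickett": round(a.fickett, 4) if a else "",
                "coding_score": round(a.score, 4) if a else "",
                "tau": round(float(tau_map[rec.id]), 6) if rec.id in tau_map else "",
                "max_tissue": max_t[rec.id] if rec.id in max_t else "",
                "salt_responsive": rec.id in res["salt_responsive"],
                "tissue_specific": rec.id in res["tissue_specific"],
                "housekeeping": rec.id in res["housekeeping"],
            }
        )
    return pd.DataFrame(rows)


def _targets_table(pairs) -> pd.DataFrame:
    rows = []
    for p in pairs:
        rows.append(
            {
                "lncrna_id": p.lncrna_id,
                "gene_id": p.gene_id,
                "mode": p.mode,
                "relation": p.relation or "",
                "distance_bp": _fmt_dist(p.distance_bp),
                "identity": round(p.identity, 4) if p.identity is not None else "",
                "evalue": f"{p.evalue:.3g}" if p.evalue is not None else "",
                "energy_kcal_mol": round(p.energy_kcal_mol, 2)
                if p.energy_kcal_mol is not None else "",
                "rho": round(p.rho, 4) if p.rho is not None else "",
                "trend": p.trend,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(["lncrna_id", "gene_id", "mode"]).reset_index(drop=True) if len(df) else df


def run_pipeline(config: PipelineConfig, data_dir: str | Path, out_dir: str | Path) -> dict:
    """Run every stage available for the inputs under data_dir; write results."""
    data_dir, out_dir = Path(data_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    h = config.hash()
    summary: dict = {"config": config.to_dict(), "config_hash": h, "species": {}}

    inputs_a = _stage("load")(SpeciesInputs.load)(data_dir, "a")
    res_a = analyse_species(inputs_a, config)
    species_results = {"a": (inputs_a, res_a)}
    has_b = (data_dir / SPECIES_FILES["annotation"].format(s="b")).exists()
    if has_b:
        inputs_b = _stage("load")(SpeciesInputs.load)(data_dir, "b")
        res_b = analyse_species(inputs_b, config)
        species_results["b"] = (inputs_b, res_b)

    for s, (inputs, res) in species_results.items():
        io_mod.write_table(_lncrna_table(res), out_dir / f"lncrnas_{s}.tsv", h)
        de = res["de"].copy()
        io_mod.write_table(de, out_dir / f"de_{s}.tsv", h)
        io_mod.write_table(res["tau"], out_dir / f"tau_{s}.tsv", h)
        io_mod.write_table(_targets_table(res["targets"]), out_dir / f"targets_{s}.tsv", h)
        if inputs.go is not None:
            background = sorted(g.id for g in res["genes"])
            target_genes = sorted(
                {p.gene_id for p in res["targets"]} & set(background)
            )
            enr = _stage("enrich")(enrichment_mod.go_enrichment)(
                target_genes, inputs.go, background, config
            )
            enr_df = pd.DataFrame(
                [
                    {
                        "term": e.term, "k": e.k, "K": e.K, "n": e.n, "N": e.N,
                        "p": f"{e.p_value:.6g}", "p_adj_BH": f"{e.p_adj_BH:.6g}",
                        "enriched": e.enriched,
                    }
                    for e in enr
                ]
            )
            io_mod.write_table(enr_df, out_dir / f"enrichment_{s}.tsv", h)
            summary["species"].setdefault(s, {})["n_enriched_terms"] = int(
                sum(e.enriched for e in enr)
            )
        ssum = summary["species"].setdefault(s, {})
        ssum.update(
            {
                "funnel": res["funnel"],
                "class_counts": res["class_counts"],
                "n_lncrnas": len(res["records"]),
                "n_salt_responsive": len(res["salt_responsive"]),
                "n_tissue_specific": len(res["tissue_specific"]),
                "n_housekeeping": len(res["housekeeping"]),
                "n_tissue_specific_de": len(res["tissue_specific_de"]),
                "n_cis_pairs": len(res["cis"]),
                "n_trans_pairs": len(res["trans"]),
            }
        )

    if has_b:
        comp = compare_species(
            res_a, res_b, inputs_a.matrix, species_results["b"][0].matrix, config
        )
        hom_df = pd.DataFrame(
            [
                {
                    "id_a": p.id_a, "id_b": p.id_b,
                    "identity": round(p.identity, 4), "evalue": f"{p.evalue:.3g}",
                    "rho": round(p.rho, 4) if p.rho is not None else "",
                    "similar_pattern": p.similar_pattern,
                    "high_in_a_tissues": ",".join(p.high_in_a_tissues),
                }
                for p in sorted(comp["pairs"], key=lambda p: p.id_a)
            ]
        )
        io_mod.write_table(hom_df, out_dir / "homologs.tsv", h)
        ss_df = pd.DataFrame(
            [{"transcript_id": t, "species": "a"} for t in sorted(comp["specific_a"])]
            + [{"transcript_id": t, "species": "b"} for t in sorted(comp["specific_b"])]
        )
        io_mod.write_table(ss_df, out_dir / "species_specific.tsv", h)
        summary["comparison"] = {
            "n_homolog_pairs": len(comp["pairs"]),
            "n_similar_pattern": int(sum(p.similar_pattern for p in comp["pairs"])),
            "n_high_expression_pairs": int(
                sum(bool(p.high_in_a_tissues) for p in comp["pairs"])
            ),
            "n_species_specific_a": len(comp["specific_a"]),
            "n_species_specific_b": len(comp["specific_b"]),
            "n_species_specific_de_a": len(comp["species_specific_de"]),
            "species_specific_de_per_tissue": comp["species_specific_de_per_tissue"],
            "ts_homolog_same_tissue": comp["ts_homolog_same_tissue"],
            "ts_homolog_diff_tissue": comp["ts_homolog_diff_tissue"],
        }

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return summary


def simulate_dataset(
    out_dir: str | Path,
    n_genes: int = 10,
    n_lnc_per_class: int = 5,
    seed: int = 7,
    divergence: float = 0.02,
    fraction_shared_lnc: float = 0.5,
    noise_sd: float = 0.2,
    n_high_pairs: int = 3,
) -> simulate_mod.SimTruth:
    """Write a complete paired-species dataset (the layout run_pipeline reads)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tx_a, truth = simulate_mod.simulate_genome(n_genes, n_lnc_per_class, seed)
    tx_b = simulate_mod.simulate_sister_species(
        tx_a, truth, divergence, fraction_shared_lnc, seed + 1
    )
    simulate_mod.plan_expression(truth, "A", seed + 2)
    simulate_mod.copy_expression_plan(truth, n_high_pairs, seed + 3)
    simulate_mod.plan_expression(truth, "B", seed + 4)
    mat_a = simulate_mod.simulate_expression([t.id for t in tx_a], truth, noise_sd, seed + 5)
    mat_b = simulate_mod.simulate_expression([t.id for t in tx_b], truth, noise_sd, seed + 6)
    for s, tx, mat in (("a", tx_a, mat_a), ("b", tx_b, mat_b)):
        io_mod.write_annotation(tx, out_dir / SPECIES_FILES["annotation"].format(s=s))
        io_mod.write_fasta(
            {t.id: t.sequence for t in tx}, out_dir / SPECIES_FILES["fasta"].format(s=s)
        )
        io_mod.write_expression(
            mat,
            out_dir / SPECIES_FILES["expression"].format(s=s),
            out_dir / SPECIES_FILES["samples"].format(s=s),
        )
        go = simulate_mod.simulate_go_annotation(
            [t.id for t in tx if t.biotype == "coding"], seed + 8
        )
        go.to_csv(out_dir / SPECIES_FILES["go"].format(s=s), sep="\t", index=False)
    truth.to_json(out_dir / "truth.json")
    return truth
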