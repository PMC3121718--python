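"""End-to-end orchestration of the analysis from a single config.

Stages: simulate -> normalize -> diffexpr (per timepoint) -> union ->
anchor -> enrich -> tre -> adduct-stats.  Every output file is listed in a
manifest with a SHA-256 checksum; the summary report carries the
machine-readable analogue of the study's headline counts: differentially
expressed probesets per analysis (MAM vs vehicle within the knockout;
genotype difference in MAM response), anchored counts and percentages,
and the de-duplicated union size.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .adduct_stats import RankShiftTest
from .anchor import LesionAnchor
from .diffexpr import FactorialDE, combine_analyses
from .enrich import GeneSetEnrichment, read_gmt, write_gmt
from .normalize import ExpressionMatrix, rma
from .synthetic_data import (EffectSpec, LesionKinetics, StudyDesign,
                             generate_study, generate_gene_sets,
                             generate_promoters)
from .tre import HNF4_CONSENSUS, Motif, PromoterMotifAnalysis, read_motifs

logger = logging.getLogger("lesionlink")

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs", "anchored_percent"]


def anchored_percent(n_anchored: int, n_de: int) -> float:
    """Percentage of a DE gene list that is lesion-anchored, 100*|anchored|/|DE|."""
    if n_de < 0 or n_anchored < 0:
        raise ValueError("counts must be non-negative")
    if n_anchored > n_de:
        raise ValueError("anchored count cannot exceed the DE count")
    if n_de == 0:
        return float("nan")
    return 100.0 * n_anchored / n_de


@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the study's published thresholds."""

    out_dir: str = "lesionlink_out"
    seed: int = 0
    # stage parameters
    fdr: float = 0.05
    min_fc: float = 1.3
    alpha_lab: float = 0.15
    anchor_threshold: float = 0.70
    prevalence_min: float = 0.05
    alpha_tre: float = 0.05
    skip_background: bool = False
    # synthetic-data conditions (used when no input paths are given)
    design: StudyDesign = field(default_factory=StudyDesign)
    effects: EffectSpec = field(default_factory=EffectSpec)
    kinetics: LesionKinetics = field(default_factory=LesionKinetics)
    # optional pre-existing inputs
    expression_tsv: str | None = None
    sample_sheet_csv: str | None = None
    lesions_csv: str | None = None
    annotation_tsv: str | None = None
    gene_sets_gmt: str | None = None
    promoters_fasta: str | None = None
    motifs_file: str | None = None
    # stage toggles
    run_enrich: bool = True
    run_tre: bool = True
    run_adduct_stats: bool = True

    def to_yaml(self, path=None) -> str:
        d = asdict(self)
        text = yaml.safe_dump(d, sort_keys=True)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        if os.path.exists(str(source)):
            with open(source) as fh:
                d = yaml.safe_load(fh)
        else:
            d = yaml.safe_load(source)
        for key, typ in (("design", StudyDesign), ("effects", EffectSpec),
                         ("kinetics", LesionKinetics)):
            if key in d and isinstance(d[key], dict):
                sub = d[key]
                for f in dataclasses.fields(typ):
                    if f.name in sub and isinstance(sub[f.name], list):
                        sub[f.name] = tuple(sub[f.name])
                d[key] = typ(**sub)
        return cls(**d)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_fasta(promoters: dict, path: str) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=g, description="") for g, seq in promoters.items()]
    SeqIO.write(records, path, "fasta")


def _read_fasta(path: str) -> dict:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def validate_inputs(paths: dict) -> pd.DataFrame:
    """Schema checks for every provided input file.

    ``paths`` maps kind -> path for kinds expression / sample_sheet /
    lesions / annotation / gmt / fasta.  Returns a per-file report with
    pass/fail and the first offending line where applicable.
    """
    report = []

    def add(kind, path, ok, msg=""):
        report.append({"kind": kind, "path": str(path), "ok": ok, "detail": msg})

    for kind, path in paths.items():
        if path is None:
            continue
        if not os.path.exists(path):
            add(kind, path, False, "file not found")
            continue
        try:
            if kind == "expression":
                ExpressionMatrix.from_tsv(path, scale="raw")
                add(kind, path, True)
            elif kind == "sample_sheet":
                df = pd.read_csv(path)
                required = {"sample_id", "site", "genotype", "treatment",
                            "timepoint_h", "tissue", "animal_id"}
                missing = required - set(df.columns)
                if missing:
                    add(kind, path, False, f"missing columns: {sorted(missing)}")
                elif df["sample_id"].duplicated().any():
                    row = int(df.index[df["sample_id"].duplicated()][0]) + 2
                    add(kind, path, False, f"duplicate sample_id at line {row}")
                else:
                    add(kind, path, True)
            elif kind == "lesions":
                df = pd.read_csv(path)
                required = {"animal_id", "tissue", "timepoint_h",
                            "lesions_per_1e8", "censored"}
                missing = required - set(df.columns)
                if missing:
                    add(kind, path, False, f"missing columns: {sorted(missing)}")
                elif (df["lesions_per_1e8"] < 0).any():
                    row = int(df.index[df["lesions_per_1e8"] < 0][0]) + 2
                    add(kind, path, False, f"negative lesion burden at line {row}")
                else:
                    add(kind, path, True)
            elif kind == "annotation":
                df = pd.read_csv(path, sep="\t")
                missing = {"probe_id", "probeset_id", "gene_id"} - set(df.columns)
                add(kind, path, not missing,
                    f"missing columns: {sorted(missing)}" if missing else "")
            elif kind == "gmt":
                read_gmt(path)
                add(kind, path, True)
            elif kind == "fasta":
                seqs = _read_fasta(path)
                add(kind, path, bool(seqs), "" if seqs else "no sequences")
            else:
                add(kind, path, False, f"unknown input kind {kind!r}")
        except Exception as err:  # report, don't crash: this is a validator
            add(kind, path, False, str(err))
    return pd.DataFrame(report)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every enabled stage in dependency order.

    Returns ``{"manifest": {...}, "report": {...}}``; both are also written
    to ``out_dir`` as JSON.  Rerunning with the same config and seed
    reproduces the manifest checksums.
    """
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    outputs = {}

    # ---- stage: inputs / simulate -------------------------------------
    if config.expression_tsv is None:
        logger.info("simulating study: %d probesets, %d arrays, seed %d",
                    config.design.n_probesets, config.design.n_arrays, config.seed)
        effects = dataclasses.replace(config.effects, seed=config.seed)
        study = generate_study(config.design, effects, config.kinetics)
        paths = study.write(out)
        outputs.update(paths)
        expr, sheet, lesions = study.expression, study.sample_sheet, study.lesions
        annotation = study.annotation
    else:
        for name, p in (("expression", config.expression_tsv),
                        ("sample sheet", config.sample_sheet_csv),
                        ("lesions", config.lesions_csv),
                        ("annotation", config.annotation_tsv)):
            if p is None or not os.path.exists(str(p)):
                raise FileNotFoundError(f"missing upstream input: {name} ({p})")
        expr = ExpressionMatrix.from_tsv(config.expression_tsv, scale="raw")
        sheet = pd.read_csv(config.sample_sheet_csv)
        lesions = pd.read_csv(config.lesions_csv)
        annotation = pd.read_csv(config.annotation_tsv, sep="\t")

    probeset_of = annotation.set_index("probe_id")["probeset_id"]
    ps_to_gene = (annotation.drop_duplicates("probeset_id")
                  .set_index("probeset_id")["gene_id"].to_dict())

    # ---- stage: normalize ----------------------------------------------
    logger.info("RMA preprocessing: %d probes x %d arrays",
                *expr.values.shape)
    norm = rma(expr, probeset_of, skip_background=config.skip_background)
    norm_path = os.path.join(out, "normalized.tsv")
    norm.to_tsv(norm_path)
    outputs["normalized"] = norm_path

    # ---- stage: diffexpr -------------------------------------------------
    de_model = FactorialDE(fdr=config.fdr, min_fc=config.min_fc,
                           alpha_lab=config.alpha_lab)
    de_model.fit(norm, sheet)
    res_path = os.path.join(out, "diffexpr_results.tsv")
    de_model.results_.to_csv(res_path, sep="\t", index=False)
    outputs["diffexpr_results"] = res_path
    set_ko = de_model.de_set("treatment_in_ko", probeset_to_gene=ps_to_gene,
                             label="ko MAM-vs-vehicle")
    set_geno = de_model.de_set("interaction", probeset_to_gene=ps_to_gene,
                               label="genotype-difference")
    union_genes = combine_analyses(set_ko, set_geno)
    for de, fname in ((set_ko, "de_genes_ko_mam_vs_vehicle.txt"),
                      (set_geno, "de_genes_genotype_difference.txt")):
        p = os.path.join(out, fname)
        with open(p, "w") as fh:
            fh.write("\n".join(sorted(de.genes)) + ("\n" if de.genes else ""))
        outputs[fname.removesuffix(".txt")] = p
    union_path = os.path.join(out, "de_genes_union.txt")
    with open(union_path, "w") as fh:
        fh.write("\n".join(union_genes) + ("\n" if union_genes else ""))
    outputs["de_genes_union"] = union_path
    logger.info("DE counts: %s=%d, %s=%d, union=%d genes",
                set_ko.label, len(set_ko.genes), set_geno.label,
                len(set_geno.genes), len(union_genes))

    # ---- stage: anchor ---------------------------------------------------
    anchored = {}
    anchor_tables = {}
    for de in (set_ko, set_geno):
        cands = sorted(de.union)
        if cands:
            la = LesionAnchor(threshold=config.anchor_threshold).fit(
                norm, lesions, sheet, cands)
            anchor_tables[de.label] = la.results_
            anchored[de.label] = frozenset(ps_to_gene.get(p, p) for p in la.anchored_)
        else:
            anchored[de.label] = frozenset()
    if anchor_tables:
        anchor_path = os.path.join(out, "anchor_results.tsv")
        pd.concat(anchor_tables, names=["analysis"]).reset_index(level=0).to_csv(
            anchor_path, sep="\t", index=False)
        outputs["anchor_results"] = anchor_path

    # ---- stage: enrich -----------------------------------------------------
    universe = sorted(set(ps_to_gene.values()))
    if config.run_enrich:
        if config.gene_sets_gmt:
            gene_sets = read_gmt(config.gene_sets_gmt)
        else:
            gene_sets = generate_gene_sets(universe, rng, enriched_in=union_genes,
                                           n_enriched_terms=2 if union_genes else 0)
            gmt_path = os.path.join(out, "gene_sets.gmt")
            write_gmt(gene_sets, gmt_path)
            outputs["gene_sets"] = gmt_path
        if union_genes:
            enr = GeneSetEnrichment().fit(union_genes, gene_sets, universe)
            enrich_path = os.path.join(out, "enrichment.tsv")
            enr.results_.to_csv(enrich_path, sep="\t", index=False)
            outputs["enrichment"] = enrich_path

    # ---- stage: tre -------------------------------------------------------
    tre_sig = []
    if config.run_tre:
        candidates = sorted(anchored[set_geno.label] or anchored[set_ko.label])
        if config.promoters_fasta:
            promoters = _read_fasta(config.promoters_fasta)
        else:
            promoters = generate_promoters(universe, rng, length=2000,
                                           plant_motif=HNF4_CONSENSUS,
                                           plant_frac=0.0)
            # plant the HNF-4 site in 60% of the candidate promoters
            planted = generate_promoters(candidates, rng, length=2000,
                                         plant_motif=HNF4_CONSENSUS,
                                         plant_frac=0.6)
            promoters.update(planted)
            fasta_path = os.path.join(out, "promoters.fasta")
            _write_fasta(promoters, fasta_path)
            outputs["promoters"] = fasta_path
        motifs = (read_motifs(config.motifs_file) if config.motifs_file
                  else [Motif(name="HNF-4", consensus=HNF4_CONSENSUS),
                        Motif(name="GATA", consensus="WGATAR"),
                        Motif(name="EBOX", consensus="CANNTG")])
        if candidates:
            pma = PromoterMotifAnalysis(prevalence_min=config.prevalence_min,
                                        alpha=config.alpha_tre)
            pma.fit(promoters, motifs, candidates, reference_genes=universe)
            tre_matrix_path = os.path.join(out, "tre_interaction_matrix.tsv")
            with open(tre_matrix_path, "w") as fh:
                fh.write(f"# promoter_length_bp={pma.matrix_.promoter_length}\n")
                pma.matrix_.hits.to_csv(fh, sep="\t")
            tre_enrich_path = os.path.join(out, "tre_enrichment.tsv")
            pma.enrichment_.to_csv(tre_enrich_path, sep="\t", index=False)
            outputs["tre_interaction_matrix"] = tre_matrix_path
            outputs["tre_enrichment"] = tre_enrich_path
            tre_sig = pma.significant_

    # ---- stage: adduct stats ------------------------------------------------
    if config.run_adduct_stats:
        rst = RankShiftTest().fit(lesions, sheet)
        adduct_path = os.path.join(out, "adduct_stats.tsv")
        rst.results_.to_csv(adduct_path, sep="\t", index=False)
        outputs["adduct_stats"] = adduct_path

    # ---- manifest + report -------------------------------------------------
    report = {
        "seed": config.seed,
        "n_arrays": len(sheet),
        "n_probesets": int(len(norm.values)),
        "de_counts": {
            set_ko.label: len(set_ko.genes),
            set_geno.label: len(set_geno.genes),
        },
        "anchored_counts": {k: len(v) for k, v in anchored.items()},
        "anchored_percent": {
            k: anchored_percent(len(anchored[k]), n_de)
            for k, n_de in ((set_ko.label, len(set_ko.genes)),
                            (set_geno.label, len(set_geno.genes)))
            if n_de > 0
        },
        "union_size": len(union_genes),
        "significant_tres": tre_sig,
        "parameters": {"fdr": config.fdr, "min_fc": config.min_fc,
                       "alpha_lab": config.alpha_lab,
                       "anchor_threshold": config.anchor_threshold,
                       "prevalence_min": config.prevalence_min,
                       "alpha_tre": config.alpha_tre},
    }
    manifest = {name: {"path": path, "sha256": _sha256(path)}
                for name, path in outputs.items()}
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(os.path.join(out, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True,
                  default=lambda o: None if isinstance(o, float) and math.isnan(o) else o)
    return {"manifest": manifest, "report": report}
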