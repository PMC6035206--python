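"""End-to-end orchestration of the analysis stages.

Runs simulate (optional) -> harmonize -> differential expression ->
{enrichment, deconvolution, genomic clustering, subtype scoring, survival
meta-analysis} -> report, writing every stage's inputs and outputs to
disk along with a JSON manifest (seed, parameters, versions) sufficient
to reproduce the run bit-identically.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import asdict, dataclass, field
from importlib.resources import files
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import deconv as deconv_mod
from . import diffexpr, genomic, gsea, io, subtype, survmeta, synthdata
from .harmonize import (
    ExpressionMatrix,
    merge_cohorts,
    preservation_overlap_fraction,
    quantile_normalize,
    remove_preservation_genes,
)

log = logging.getLogger("ovimmune")


@dataclass
class PipelineConfig:
    outdir: str = "ovimmune_run"
    seed: int = 0
    lfc_threshold: float = diffexpr.DEFAULT_LFC_THRESHOLD
    p_threshold: float = diffexpr.DEFAULT_P_THRESHOLD
    deconv_p_max: float = deconv_mod.DEFAULT_P_MAX
    deconv_n_perm: int = 100
    fwer: float = 0.05
    n_perm: int = 1000
    run_gsea: bool = True
    run_deconv: bool = True
    run_genomic: bool = True
    run_subtype: bool = True
    run_survival: bool = True
    quantile_norm: bool = True
    simulation: synthdata.SimulationConfig = field(
        default_factory=synthdata.SimulationConfig
    )

    def validate(self) -> "PipelineConfig":
        for name in ("lfc_threshold", "p_threshold", "deconv_p_max", "fwer"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.simulation.validate()
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = synthdata.SimulationConfig(**raw.pop("simulation", {}))
        cfg = cls(**raw, simulation=sim)
        return cfg.validate()

    def to_yaml(self, path) -> None:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        Path(path).write_text(yaml.safe_dump(plain(asdict(self)), sort_keys=False))


def _setup_logging(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    for handler in (
        logging.StreamHandler(sys.stderr),
        logging.FileHandler(outdir / "pipeline.log"),
    ):
        handler.setFormatter(fmt)
        log.addHandler(handler)


def run_all(config: PipelineConfig) -> Path:
    """Execute every enabled stage on a synthetic study; returns the outdir.

    The synthetic study defined by ``config.simulation`` (root seed
    ``config.seed``) supplies all inputs; each stage writes its outputs as
    TSV/JSON under the output directory.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    report: dict = {"seed": config.seed, "version": __version__}

    sim_cfg = synthdata.SimulationConfig(
        **{**asdict(config.simulation), "seed": config.seed}
    )
    log.info("simulate: %d genes, %d control cohorts, %d cases",
             sim_cfg.n_genes, sim_cfg.n_control_cohorts, sim_cfg.n_case_samples)
    study = synthdata.simulate_all(sim_cfg)
    truth = study.truth
    io.write_bed(study.annotation, outdir / "genes.bed")
    io.write_survival(study.survival, outdir / "survival.csv")
    io.write_structure_map(truth.structure_map, outdir / "structures.tsv")

    log.info("harmonize: merging %d cohorts", len(study.cohorts))
    merged = merge_cohorts(study.cohorts)
    merged, n_removed = remove_preservation_genes(merged, truth.ffpe_genes)
    if config.quantile_norm:
        merged = quantile_normalize(merged)
    io.write_expression(merged, outdir / "expression.tsv", outdir / "samples.tsv")
    report["harmonize"] = {
        "n_genes": merged.n_genes,
        "n_samples": merged.n_samples,
        "n_ffpe_removed": n_removed,
    }

    log.info("diffexpr: fitting %d genes", merged.n_genes)
    de_table = diffexpr.fit_linear_de(merged)
    de_table.to_csv(outdir / "de_table.tsv", sep="\t")
    de_genes = diffexpr.select_de(
        de_table, config.lfc_threshold, config.p_threshold
    )
    planted_left = [g for g in truth.de_genes if g in merged.genes]
    report["diffexpr"] = {
        "n_selected": len(de_genes),
        "n_planted": len(planted_left),
        "recovered": len(set(de_genes) & set(planted_left)),
    }
    ranking = list(de_table.sort_values("p").index)
    report["ffpe_overlap_pct"] = preservation_overlap_fraction(
        ranking, truth.ffpe_genes, top_k=min(500, len(ranking))
    )

    if config.run_gsea:
        log.info("gsea: structure enrichment, %d structures", len(truth.structure_map))
        enriched = gsea.structure_enrichment(
            de_table,
            truth.structure_map,
            de_genes=de_genes,
            n_perm=config.n_perm,
            fwer=config.fwer,
            seed=config.seed,
            all_structures=True,
        )
        enriched.to_csv(outdir / "structure_enrichment.tsv", sep="\t", index=False)
        sig = enriched[enriched["significant"]]
        report["gsea"] = {
            "n_significant_structures": int(sig.shape[0]),
            "top_structure": sig["structure"].iloc[0] if len(sig) else None,
            "enriched_truth": truth.enriched_structure,
        }

    if config.run_deconv:
        log.info("deconv: %d mixture samples", study.mixtures.n_samples)
        results = deconv_mod.deconvolve_matrix(
            study.mixtures, study.signature,
            n_perm=config.deconv_n_perm, seed=config.seed,
        )
        results = deconv_mod.filter_by_p(results, config.deconv_p_max)
        fractions = deconv_mod.fractions_frame(results)
        fractions.to_csv(outdir / "cell_fractions.tsv", sep="\t")
        comparison = deconv_mod.compare_fraction_groups(
            results, study.mixtures.metadata["phenotype"]
        )
        comparison.to_csv(outdir / "fraction_comparison.tsv", sep="\t")
        report["deconv"] = {
            "n_samples_kept": len(results),
            "comparison": comparison.to_dict(orient="index"),
        }

    if config.run_genomic:
        log.info("genomic: clustering test, %d perms", config.n_perm)
        ct = genomic.clustering_test(
            de_genes, study.annotation, n_perm=config.n_perm, seed=config.seed
        )
        hotspot = genomic.detect_hotspot(de_genes, study.annotation)
        rain = genomic.rainfall(de_genes, study.annotation)
        rain.to_csv(outdir / "rainfall.tsv", sep="\t", index=False)
        report["genomic"] = {
            "observed_median_nn_bp": ct.observed,
            "p": ct.p,
            "clustered": bool(ct.clustered),
            "hotspot": None
            if hotspot is None
            else {
                "chrom": hotspot.chrom,
                "start": hotspot.start,
                "end": hotspot.end,
                "ratio": hotspot.ratio,
                "nearest_gene": hotspot.nearest_gene,
                "truth": truth.hotspot,
            },
        }

    if config.run_subtype:
        log.info("subtype: scoring + LOO classification")
        accuracy, ci = subtype.classify_phenotype_loo(merged)
        report["subtype"] = {"loo_accuracy_pct": accuracy, "ci_pct": list(ci)}

    if config.run_survival:
        log.info("survmeta: %d studies", sim_cfg.n_survival_studies)
        meta, fits, forest = survmeta.meta_analyse_gene(
            study.survival, covariates=("expression", "debulking", "stage")
        )
        forest.to_csv(outdir / "forest.tsv", sep="\t", index=False)
        report["survival"] = {
            "pooled_hr": meta.hr,
            "pooled_ci": list(meta.ci),
            "p": meta.p,
            "true_hr": float(np.exp(truth.true_log_hr)),
        }

    io.write_json(report, outdir / "manifest.json")
    log.info("done: %s", outdir)
    return outdir


# -- packaged clinical fixture ---------------------------------------------

def load_clinical_table() -> pd.DataFrame:
    """Clinical description of the 12-patient case cohort (packaged TSV)."""
    path = files("ovimmune").joinpath("data/table1.tsv")
    with path.open() as fh:
        return pd.read_csv(fh, sep="\t")


def clinical_summary(table: pd.DataFrame) -> dict:
    """Cohort-level summaries: histology counts, stage distribution, ages."""
    stage = table["figo_stage"].astype(str)
    stage_iii = stage.str.startswith("III") & ~stage.str.startswith("IIIV")
    return {
        "n_patients": int(len(table)),
        "hgsc_count": int((table["diagnosis"] == "HGSC").sum()),
        "stage_iii_count": int(stage_iii.sum()),
        "stage_iii_pct": 100.0 * float(stage_iii.mean()),
        "stage_iv_count": int((stage == "IV").sum()),
        "median_age": float(table["age_years"].median()),
    }
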