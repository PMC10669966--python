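"""End-to-end orchestration: simulate/ingest -> QC -> exclusion list -> DEGs
-> enrichment, with persisted TSV intermediates and a JSON run manifest."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import de, enrichment, qc, specificity
from .matrix import CountMatrix
from .simulate import CompendiumSpec, SimulationSpec, simulate_compendium, simulate_subtype_counts


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults are the analysis' stated values."""

    counts_path: str | None = None
    metadata_path: str | None = None
    compendium_path: str | None = None
    gmt_path: str | None = None
    simulate: bool = True
    seed: int = 0
    # sample / gene QC
    sample_qc_threshold: float = 0.10
    min_count: float = 10.0
    min_total_count: float = 15.0
    # exclusion list
    top_k: int = 500
    min_datapoints: int = 6
    max_healthy: int = 1
    max_cancer: int = 3
    # DEG calling
    logfc_min: float = 1.5
    p_max: float = 0.05
    prior_df: float = 10.0
    # simulation scale (used when simulate=True)
    n_genes: int = 600
    n_planted_per_subtype: int = 15
    planted_effect: float = 3.0
    dispersion: float = 0.1
    n_healthy_tissues: int = 8
    n_cancer_tissues: int = 8
    outdir: str = "lpsdeg_run"

    def validate(self) -> list[str]:
        """Every violated constraint, not just the first."""
        errors = []
        if self.sample_qc_threshold < 0:
            errors.append("sample_qc_threshold must be >= 0")
        if self.min_count < 0:
            errors.append("min_count must be >= 0")
        if self.min_total_count < 0:
            errors.append("min_total_count must be >= 0")
        if self.top_k <= 0:
            errors.append("top_k must be positive")
        if self.min_datapoints < 1:
            errors.append("min_datapoints must be >= 1")
        if self.max_healthy < 0:
            errors.append("max_healthy must be >= 0")
        if self.max_cancer < 0:
            errors.append("max_cancer must be >= 0")
        if self.logfc_min < 0:
            errors.append("logfc_min must be >= 0")
        if not 0 <= self.p_max <= 1:
            errors.append("p_max must be in [0, 1]")
        if self.prior_df <= 0:
            errors.append("prior_df must be positive")
        if self.dispersion <= 0:
            errors.append("dispersion must be positive")
        if self.n_genes <= 0:
            errors.append("n_genes must be positive")
        if not self.simulate and (self.counts_path is None or self.metadata_path is None):
            errors.append("counts_path and metadata_path required when simulate=False")
        return errors

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)


def validate_config(raw_text: str) -> PipelineConfig:
    """Parse YAML config text; raises with every violated constraint listed."""
    data = yaml.safe_load(raw_text) or {}
    unknown = set(data) - set(PipelineConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    config = PipelineConfig(**data)
    errors = config.validate()
    if errors:
        raise ValueError("; ".join(errors))
    return config


def _simulation_inputs(config: PipelineConfig):
    from .simulate import gene_names

    genes = gene_names(config.n_genes)
    groups = {"DDLPS": 20, "MLPS": 20, "PLPS": 10}
    planted, cursor = [], 0
    for subtype in groups:
        for _ in range(config.n_planted_per_subtype):
            planted.append((genes[cursor], subtype, config.planted_effect))
            cursor += 1
    sim_spec = SimulationSpec(
        n_genes=config.n_genes,
        group_sizes=groups,
        dispersion=config.dispersion,
        planted_degs=planted,
        seed=config.seed,
    )
    comp_spec = CompendiumSpec(
        n_genes=config.n_genes,
        n_healthy_tissues=config.n_healthy_tissues,
        n_cancer_tissues=config.n_cancer_tissues,
        samples_per_tissue=8,
        housekeeping_genes=genes[-20:],
        seed=config.seed + 1,
    )
    return sim_spec, comp_spec


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; returns (and persists) the run manifest."""
    errors = config.validate()
    if errors:
        raise ValueError("; ".join(errors))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": asdict(config), "stages": {}}

    # --- inputs
    if config.simulate:
        sim_spec, comp_spec = _simulation_inputs(config)
        matrix, truth = simulate_subtype_counts(sim_spec)
        compendium = simulate_compendium(comp_spec)
        matrix.to_tsv(outdir / "counts.tsv", outdir / "metadata.tsv")
        truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    else:
        matrix = CountMatrix.from_tsv(config.counts_path, config.metadata_path)
        truth = None
        compendium = (
            pd.read_csv(config.compendium_path, sep="\t")
            if config.compendium_path
            else None
        )
    manifest["stages"]["input"] = {
        "n_genes": int(matrix.counts.shape[0]),
        "n_samples": int(matrix.counts.shape[1]),
    }

    # --- sample QC
    matrix, reports = qc.filter_samples_by_median_logcount(
        matrix, threshold=config.sample_qc_threshold
    )
    qc.qc_report_frame(reports).to_csv(outdir / "sample_qc.tsv", sep="\t", index=False)
    manifest["stages"]["sample_qc"] = {
        "n_excluded": sum(r.excluded for r in reports),
        "n_kept": int(matrix.counts.shape[1]),
    }

    # --- gene filter
    kept_genes = qc.filter_genes_by_expression(
        matrix, qc.GeneFilterParams(config.min_count, config.min_total_count)
    )
    matrix = matrix.subset_genes(kept_genes)
    matrix.to_tsv(outdir / "filtered_counts.tsv", outdir / "filtered_metadata.tsv")
    manifest["stages"]["gene_filter"] = {"n_kept": len(kept_genes)}

    # --- exclusion list
    if compendium is not None:
        exclusion = specificity.exclusion_list_from_compendium(
            compendium,
            k=config.top_k,
            min_datapoints=config.min_datapoints,
            max_healthy=config.max_healthy,
            max_cancer=config.max_cancer,
        )
        exclusion.to_tsv(outdir / "exclusion_list.tsv")
    else:
        exclusion = specificity.ExclusionList.empty()
    manifest["stages"]["exclusion_list"] = {"n_genes": len(exclusion.genes)}

    # --- differential expression
    degs = de.call_subtype_degs(
        matrix,
        exclusion=exclusion,
        logfc_min=config.logfc_min,
        p_max=config.p_max,
        prior_df=config.prior_df,
    )
    deg_counts = {}
    called: dict[str, list[str]] = {}
    for subtype, records in degs.items():
        frame = de.deg_frame(records)
        frame.to_csv(outdir / f"degs_{subtype}.tsv", sep="\t", index=False)
        called[subtype] = [r.gene_id for r in records if r.is_deg]
        deg_counts[subtype] = len(called[subtype])
    manifest["stages"]["differential_expression"] = {"n_degs": deg_counts}

    # --- enrichment (optional, needs a GMT library)
    if config.gmt_path:
        library = enrichment.read_gmt(config.gmt_path)
        background = len(kept_genes)
        enr_counts = {}
        for subtype, genes in called.items():
            if not genes:
                enr_counts[subtype] = 0
                continue
            records = enrichment.enrich(genes, library, background_size=background)
            enrichment.enrichment_frame(records).to_csv(
                outdir / f"enrichment_{subtype}.tsv", sep="\t", index=False
            )
            enr_counts[subtype] = sum(r.adjusted_p < 0.05 for r in records)
        manifest["stages"]["enrichment"] = {"n_significant_sets": enr_counts}

    if truth is not None and not truth.empty:
        recovered = {
            subtype: sorted(
                set(truth[truth["subtype"] == subtype]["gene"]) & set(called.get(subtype, []))
            )
            for subtype in truth["subtype"].unique()
        }
        manifest["stages"]["ground_truth_recovery"] = {
            s: {"planted": int((truth["subtype"] == s).sum()), "recovered": len(g)}
            for s, g in recovered.items()
        }

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
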