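"""End-to-end pipeline: quantify → filter → model → PCA → GSEA → cluster.

Every stage is seeded from one master seed and contributes row counts to a
provenance log, so a rerun with the same configuration reproduces the
bundle exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as clustermod
from . import io as iomod
from . import model as modelmod
from . import pca as pcamod
from . import quant as quantmod
from . import synth
from .containers import ConfigurationError, Design, QuantMatrix
from .gsea import gsea as run_gsea
from .gsea import rank_proteins

log = logging.getLogger("synaptomics")

#: Default synthetic purity: each label leaks a little into its neighbours,
#: emulating the isotope impurities a real lot sheet would tabulate.
DEFAULT_NEIGHBOR_LEAK = {"minus2": 0.3, "minus1": 2.0, "plus1": 3.0, "plus2": 0.5}


@dataclass
class PipelineConfig:
    """Master configuration: simulation settings plus analysis knobs."""

    simulation: synth.SimulationConfig = field(default_factory=synth.SimulationConfig)
    seed: int = 0
    max_missing: int = 1
    alpha_interaction: float = 0.05
    n_components: int = pcamod.DEFAULT_N_COMPONENTS
    n_randomizations: int = 200
    gsea_permutations: int = 1000
    gsea_weight: float = 1.0
    # with 1000 gene-label permutations the attainable permutation p floor is
    # ~2/n_perm; 20 sets keeps BH q for a single strongly enriched set below 0.05
    n_gene_sets: int = 20
    gene_set_size_range: tuple = (10, 80)
    planted_set_name: str = "PLANTED_INTERACTION_SET"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = synth.SimulationConfig(**raw.pop("simulation", {}))
        known = {f for f in cls.__dataclass_fields__ if f != "simulation"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "gene_set_size_range" in raw:
            raw["gene_set_size_range"] = tuple(raw["gene_set_size_range"])
        return cls(simulation=sim, **raw)

    def digest(self) -> str:
        payload = {"simulation": self.simulation.to_dict(),
                   **{k: getattr(self, k) for k in self.__dataclass_fields__
                      if k != "simulation"}}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class ReportBundle:
    """Everything the pipeline computed, plus provenance."""

    config: PipelineConfig
    design: Design
    quant_matrix: QuantMatrix
    filtered_matrix: QuantMatrix
    anova: pd.DataFrame
    selected: pd.Index
    contrast_tw_ew: pd.DataFrame
    contrast_tf_tw: pd.DataFrame
    contrast_tf_ew: pd.DataFrame
    pc_model: pcamod.PCModel
    pc_fdr: pcamod.RandomizationResult
    enrichment: pd.DataFrame
    clusters: pd.Series
    plot_data: dict
    marker_report: pd.DataFrame
    concordance: dict
    truth: synth.GroundTruth
    provenance: dict


def _stage(provenance: dict, name: str, started: float, **counts) -> None:
    provenance["stages"].append(
        {"stage": name, "seconds": round(time.time() - started, 3), **counts}
    )
    log.info("stage %s done in %.2fs %s", name, time.time() - started, counts)


def default_purity(channels) -> quantmod.PurityMatrix:
    table = pd.DataFrame(
        {k: [v] * len(channels) for k, v in DEFAULT_NEIGHBOR_LEAK.items()},
        index=pd.Index(channels, name="channel"),
    )
    return quantmod.PurityMatrix.from_impurity_table(table)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run the full synthetic-data analysis chain deterministically."""
    rng = np.random.default_rng(config.seed)
    seeds = {k: int(rng.integers(2**31)) for k in
             ("simulate", "missing", "de", "pca", "gsea", "genesets")}
    provenance: dict = {"config_digest": config.digest(), "master_seed": config.seed,
                        "stages": []}

    t0 = time.time()
    sim_config = config.simulation
    spectra_true, _direct_matrix, truth, design = synth.simulate_experiment(sim_config)
    purity = default_purity(list(spectra_true.channels))
    observed = synth.mix_impurities(spectra_true, purity)
    _stage(provenance, "simulate", t0, n_proteins=sim_config.n_proteins,
           n_spectra=observed.n_spectra)

    t0 = time.time()
    corrected, clamped = quantmod.impurity_correct(observed, purity)
    normalized, n_iter = quantmod.iterative_normalize(corrected)
    processed, prep_counts = quantmod.preprocess_spectra(normalized)
    matrix, spectra_per_protein = quantmod.rollup_proteins(processed)
    if sim_config.missing_rate > 0:
        matrix = synth.inject_missingness(
            matrix, sim_config.missing_rate, seed=seeds["missing"], mnar=sim_config.mnar
        )
    _stage(provenance, "quantify", t0, n_clamped_cells=int(clamped.sum()),
           normalize_iterations=n_iter, **prep_counts,
           n_quantified_proteins=matrix.shape[0])

    t0 = time.time()
    filtered, filter_counts = modelmod.filter_missing(matrix, config.max_missing)
    _stage(provenance, "filter", t0, **filter_counts)

    t0 = time.time()
    anova = modelmod.fit_factorial_anova(filtered, design)
    selected = modelmod.select_interaction(anova, config.alpha_interaction)
    contrast_tw_ew = modelmod.group_contrast_from_data(filtered, design, "EW", "TW")
    contrast_tf_tw = modelmod.group_contrast_from_data(filtered, design, "TW", "TF")
    contrast_tf_ew = modelmod.group_contrast_from_data(filtered, design, "EW", "TF")
    _stage(provenance, "model", t0, n_fitted=len(anova), n_selected=len(selected))

    t0 = time.time()
    pc_fdr = pcamod.randomization_fdr(
        filtered, design, n_components=config.n_components,
        n_rand=config.n_randomizations, seed=seeds["pca"],
    )
    pc_model = pcamod.fit_pca(filtered, n_components=config.n_components)
    _stage(provenance, "pca", t0, n_components=pc_model.n_components,
           r2x=round(pc_model.r2x, 4),
           n_significant_pairs=pc_fdr.n_observed_pairs,
           fdr_pairs=pc_fdr.fdr_pairs)

    t0 = time.time()
    collection = synth.simulate_gene_sets(
        truth, n_sets=config.n_gene_sets, size_range=config.gene_set_size_range,
        enrichment_spec={config.planted_set_name: "interaction_true"},
        seed=seeds["genesets"],
    )
    # rank by the rescue contrast's pi score: interaction proteins sit in the
    # tails of TF vs TW, whereas TF vs EW is blind to a full rescue
    metric = contrast_tf_tw["pi"].rename("signed_logp")
    ranked, n_unranked = rank_proteins(metric, source="signed_logp")
    enrichment = run_gsea(
        ranked, collection, n_perm=config.gsea_permutations,
        weight_exponent=config.gsea_weight, seed=seeds["gsea"],
    )
    _stage(provenance, "gsea", t0, n_sets=len(collection),
           n_tested=int((~enrichment["skipped"]).sum()), n_unranked=n_unranked)

    t0 = time.time()
    if len(selected) >= 2:
        scaled = clustermod.standard_scale(filtered.subset(selected))
        tree = clustermod.correlation_ward_tree(scaled)
        clusters = clustermod.cut_first_branch(tree, scaled, design)
        plot_data = clustermod.export_plot_data(
            scaled, tree, clusters, pc_scores=pc_model.scores, design=design,
            raw_matrix=filtered.subset(selected),
        )
    else:
        clusters = pd.Series(dtype=object)
        plot_data = {}
    _stage(provenance, "cluster", t0, n_clustered=len(clusters))

    t0 = time.time()
    marker_report = iomod.marker_presence(filtered, design)
    concordance = iomod.direction_concordance(contrast_tw_ew, contrast_tf_tw)
    _stage(provenance, "report", t0, n_markers_present=int(marker_report["present"].sum()),
           concordance=concordance["concordance"])

    return ReportBundle(
        config=config, design=design, quant_matrix=matrix, filtered_matrix=filtered,
        anova=anova, selected=selected, contrast_tw_ew=contrast_tw_ew,
        contrast_tf_tw=contrast_tf_tw, contrast_tf_ew=contrast_tf_ew,
        pc_model=pc_model, pc_fdr=pc_fdr, enrichment=enrichment,
        clusters=clusters, plot_data=plot_data, marker_report=marker_report,
        concordance=concordance, truth=truth, provenance=provenance,
    )


def write_bundle(bundle: ReportBundle, outdir) -> None:
    """Serialize a bundle's tables and provenance under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    iomod.write_quant_tsv(bundle.quant_matrix, out / "quant_matrix.tsv")
    iomod.write_quant_tsv(bundle.filtered_matrix, out / "quant_matrix.filtered.tsv")
    iomod.write_sample_sheet(bundle.design, out / "sample_sheet.csv")
    bundle.anova.to_csv(out / "anova.tsv", sep="\t", index_label="protein")
    pd.Series(bundle.selected, name="protein").to_csv(
        out / "interaction_selected.tsv", sep="\t", index=False
    )
    for name in ("contrast_tw_ew", "contrast_tf_tw", "contrast_tf_ew"):
        getattr(bundle, name).to_csv(out / f"{name}.tsv", sep="\t", index_label="protein")
    bundle.pc_model.scores.to_csv(out / "pc_scores.tsv", sep="\t", index_label="sample")
    bundle.pc_model.loadings.to_csv(out / "pc_loadings.tsv", sep="\t", index_label="protein")
    bundle.pc_fdr.tests.to_csv(out / "pc_design_tests.tsv", sep="\t", index_label="component")
    bundle.enrichment.to_csv(out / "enrichment.tsv", sep="\t", index_label="set")
    if len(bundle.clusters):
        bundle.clusters.to_csv(out / "clusters.tsv", sep="\t", index_label="protein")
        bundle.plot_data["heatmap"].to_csv(out / "heatmap.tsv", sep="\t",
                                           index_label="protein")
    bundle.marker_report.to_csv(out / "marker_presence.tsv", sep="\t")
    bundle.concordance["detail"].to_csv(out / "concordance.tsv", sep="\t", index=False)
    iomod.write_ground_truth(bundle.truth, out / "ground_truth.json")
    meta = {
        "provenance": bundle.provenance,
        "pc_variance_fraction": list(bundle.pc_model.variance_fraction),
        "r2x": bundle.pc_model.r2x,
        "pc_fdr": {
            "fdr_pairs": bundle.pc_fdr.fdr_pairs,
            "fdr_components": bundle.pc_fdr.fdr_components,
            "n_observed_pairs": bundle.pc_fdr.n_observed_pairs,
            "no_discoveries": bundle.pc_fdr.no_discoveries,
        },
        "concordance": {k: v for k, v in bundle.concordance.items() if k != "detail"},
    }
    iomod.write_json(meta, out / "report.json")
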