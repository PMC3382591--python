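"""End-to-end workflow orchestration.

Runs the five analysis stages in order — TF activity scoring, CNV
normalization, correlation-profile TF selection, MCN extraction with
significance and negative control, and biomarker screening — against a
directory of flat-text inputs, writing each stage's outputs plus a
machine-readable manifest of every threshold used. Any stage can be
resumed from its on-disk outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .activity import differential_genes, tf_scores
from .biomarker import (annotation_filter, cancer_specific_genes,
                        central_tf_targets, normalize_patient_expression)
from .cnv import filter_significant_regions, gene_cnv_matrix, region_medians
from .errors import ConfigError, PreconditionError
from .mcn import (PpiNetwork, central_nodes, minimal_connected_network,
                  negative_control, subnetwork_significance)
from .select import correlation_profiles, fit_all, fits_table, select_tfs
from .survival import survival_screen

log = logging.getLogger(__name__)

#: every numeric threshold any stage uses; the manifest must list them all
THRESHOLDS = ("evalue_max", "q_max", "alpha", "alpha_bh", "alpha_survival",
              "min_evidence", "n_random", "n_control_lists", "top_k")


@dataclass
class PipelineConfig:
    """File paths, thresholds and the RNG seed for one pipeline run."""

    # inputs
    expression: str = ""
    samples: str = ""
    catalogue: str = ""
    regions: str = ""
    region_values: str = ""
    gene_locations: str = ""
    ppi: str = ""
    annotation_sets: str = ""
    patient_expression: str = ""
    phenotypes: str = ""
    cohorts: dict = field(default_factory=dict)  # label -> {expr, clinical}
    out_dir: str = "tfnet_run"
    # thresholds
    evalue_max: float = 10.0
    q_max: float = 0.25
    alpha: float = 0.05
    alpha_bh: float = 0.05
    alpha_survival: float = 0.05
    min_evidence: int = 2
    n_random: int = 1000
    n_control_lists: int = 100
    top_k: int = 10
    rng_seed: int = 0
    resume: bool = False

    def validate(self) -> None:
        for name in ("evalue_max", "q_max", "alpha", "alpha_bh", "alpha_survival"):
            v = getattr(self, name)
            if v < 0:
                raise ConfigError(f"{name} must be non-negative")
        for name in ("alpha", "alpha_bh", "alpha_survival", "q_max"):
            if getattr(self, name) > 1:
                raise ConfigError(f"{name} must be <= 1")
        for name in ("min_evidence", "n_random", "n_control_lists", "top_k"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")


_FLOAT_KEYS = {"evalue_max", "q_max", "alpha", "alpha_bh", "alpha_survival"}
_INT_KEYS = {"min_evidence", "n_random", "n_control_lists", "top_k", "rng_seed"}
_BOOL_KEYS = {"resume"}


def read_config(path) -> PipelineConfig:
    """Flat ``key = value`` config file; unknown keys are errors.

    Survival cohorts use dotted keys: ``cohort.<label>.expression`` and
    ``cohort.<label>.clinical``.
    """
    known = {f.name for f in fields(PipelineConfig)} - {"cohorts"}
    cfg = PipelineConfig()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected key = value, got {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key.startswith("cohort."):
            parts = key.split(".")
            if len(parts) != 3 or parts[2] not in ("expression", "clinical"):
                raise ConfigError(f"line {lineno}: bad cohort key {key!r}")
            cfg.cohorts.setdefault(parts[1], {})[parts[2]] = value
        elif key in known:
            if key in _FLOAT_KEYS:
                setattr(cfg, key, float(value))
            elif key in _INT_KEYS:
                setattr(cfg, key, int(value))
            elif key in _BOOL_KEYS:
                setattr(cfg, key, value.lower() in ("1", "true", "yes"))
            else:
                setattr(cfg, key, value)
        else:
            raise ConfigError(f"line {lineno}: unknown config key {key!r}")
    cfg.validate()
    return cfg


def write_config(cfg: PipelineConfig, path) -> None:
    """Serialize a :class:`PipelineConfig` as the flat key=value format
    accepted by :func:`read_config`."""
    lines = []
    for f in fields(PipelineConfig):
        if f.name == "cohorts":
            continue
        lines.append(f"{f.name} = {getattr(cfg, f.name)}")
    for label in sorted(cfg.cohorts):
        lines.append(f"cohort.{label}.expression = {cfg.cohorts[label]['expression']}")
        lines.append(f"cohort.{label}.clinical = {cfg.cohorts[label]['clinical']}")
    Path(path).write_text("\n".join(lines) + "\n")


def _stage_seed(rng_seed: int, stage: int) -> int:
    """Fixed per-stage child seed, independent of execution order."""
    ss = np.random.SeedSequence([int(rng_seed), stage])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def validate_inputs(cfg: PipelineConfig) -> dict:
    """Cross-check identifier namespaces before running; returns a report
    with ``warnings`` (run proceeds) and ``fatal`` (empty intersections).
    """
    report = {"warnings": [], "fatal": []}
    expr = tio.read_expression(cfg.expression, cfg.samples or None)
    catalogue = tio.read_catalogue(cfg.catalogue)
    genes = set(expr.genes)
    targets = catalogue.targets & genes
    if not targets:
        report["fatal"].append("no catalogue target is measured in the expression matrix")
    elif len(targets) < len(catalogue.targets):
        report["warnings"].append(
            f"{len(catalogue.targets) - len(targets)} catalogue targets unmeasured")
    ppi = tio.read_ppi_edges(cfg.ppi)
    nodes = set(ppi["a"]) | set(ppi["b"])
    mapped = catalogue.tfs & nodes
    if not mapped:
        report["fatal"].append("no catalogue TF maps onto the PPI graph")
    elif len(mapped) < len(catalogue.tfs):
        unmapped = sorted(catalogue.tfs - nodes)
        report["warnings"].append(
            f"{len(unmapped)} TFs absent from the interactome: {unmapped[:10]}")
    locations = tio.read_gene_locations(cfg.gene_locations)
    located = set(locations["gene"]) & genes
    if not located:
        report["fatal"].append("no measured gene has a chromosomal location")
    if cfg.patient_expression:
        pexpr = tio.read_expression(cfg.patient_expression)
        phen = tio.read_phenotypes(cfg.phenotypes)
        unlabelled = set(pexpr.values.columns) - set(phen.index)
        if unlabelled:
            report["warnings"].append(f"{len(unlabelled)} patient columns lack a phenotype")
        if not set(pexpr.values.columns) & set(phen.index):
            report["fatal"].append("phenotype table covers no patient column")
    for label, paths in cfg.cohorts.items():
        cexpr = tio.read_expression(paths["expression"])
        clin = tio.read_clinical(paths["clinical"])
        if not set(cexpr.values.columns) & set(clin.index):
            report["warnings"].append(f"cohort {label}: no overlapping patients; "
                                      "it will be skipped")
    return report


def write_synthetic_inputs(bundle, in_dir, out_dir=None, **threshold_overrides) -> PipelineConfig:
    """Write a :class:`~tfnet.synthetic.SyntheticBundle` as pipeline input
    files and return a ready-to-run :class:`PipelineConfig`."""
    from .synthetic import write_ground_truth
    d = Path(in_dir)
    d.mkdir(parents=True, exist_ok=True)
    tio.write_expression(bundle.expression, d / "expression.tsv", d / "samples.tsv")
    tio.write_catalogue(bundle.catalogue, d / "catalogue.tsv")
    tio.write_regions(bundle.regions, bundle.region_values,
                      d / "regions.tsv", d / "region_values.tsv")
    tio.write_gene_locations(bundle.locations, d / "genes.bed")
    bundle.ppi_edges.to_csv(d / "ppi.tsv", sep="\t", index=False, header=False)
    tio.write_gmt(bundle.annotation_sets, d / "annotations.gmt")
    tio.write_expression(bundle.patient_expr, d / "patients.tsv")
    tio.write_phenotypes(bundle.phenotypes, d / "phenotypes.tsv")
    cohorts = {}
    for label, cexpr, clin in bundle.survival_cohorts:
        tio.write_expression(cexpr, d / f"cohort_{label}_expr.tsv")
        tio.write_clinical(clin, d / f"cohort_{label}_clinical.tsv")
        cohorts[label] = {"expression": str(d / f"cohort_{label}_expr.tsv"),
                          "clinical": str(d / f"cohort_{label}_clinical.tsv")}
    write_ground_truth(bundle.truth, d / "ground_truth.tsv")
    cfg = PipelineConfig(
        expression=str(d / "expression.tsv"), samples=str(d / "samples.tsv"),
        catalogue=str(d / "catalogue.tsv"), regions=str(d / "regions.tsv"),
        region_values=str(d / "region_values.tsv"),
        gene_locations=str(d / "genes.bed"), ppi=str(d / "ppi.tsv"),
        annotation_sets=str(d / "annotations.gmt"),
        patient_expression=str(d / "patients.tsv"),
        phenotypes=str(d / "phenotypes.tsv"), cohorts=cohorts,
        out_dir=str(out_dir if out_dir is not None else d / "run"),
        rng_seed=bundle.config.rng_seed,
    )
    for key, value in threshold_overrides.items():
        if not hasattr(cfg, key):
            raise ConfigError(f"unknown pipeline option {key!r}")
        setattr(cfg, key, value)
    cfg.validate()
    return cfg


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns a result summary (also written to disk).

    Outputs land in ``cfg.out_dir``; with ``cfg.resume`` a stage whose
    output files already exist is loaded instead of recomputed.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = validate_inputs(cfg)
    if report["fatal"]:
        raise PreconditionError("input validation failed: " + "; ".join(report["fatal"]))
    for w in report["warnings"]:
        log.warning("validate_inputs: %s", w)

    expr = tio.read_expression(cfg.expression, cfg.samples or None)
    catalogue = tio.read_catalogue(cfg.catalogue)
    universe = frozenset(expr.genes)

    # stage 1: TF regulation scores
    scores_path = out / "tf_scores.tsv"
    if cfg.resume and scores_path.exists():
        scores = pd.read_csv(scores_path, sep="\t", index_col=0)
        never = frozenset(scores.index[(scores <= 0).all(axis=1)])
    else:
        regulated = {line: differential_genes(expr, line, cfg.evalue_max)
                     for line in expr.lines}
        sm = tf_scores(catalogue, regulated, universe)
        scores, never = sm.scores, sm.never_significant
        scores.rename_axis("tf").to_csv(scores_path, sep="\t", float_format="%.10g")

    # stage 2: CNV matrix
    cnv_path = out / "cnv_matrix.tsv"
    if cfg.resume and cnv_path.exists():
        cnv = pd.read_csv(cnv_path, sep="\t", index_col=0)
    else:
        regions, values = tio.read_regions(cfg.regions, cfg.region_values)
        sig = filter_significant_regions(regions, cfg.q_max)
        med = region_medians(sig, values)
        locations = tio.read_gene_locations(cfg.gene_locations)
        cnv = gene_cnv_matrix(sig, med, locations, list(scores.columns))
        cnv.rename_axis("gene").to_csv(cnv_path, sep="\t", float_format="%.10g")

    # stage 3: correlation-profile regression and TF selection
    fits_path, sel_path = out / "tf_fits.tsv", out / "selected_tfs.txt"
    if cfg.resume and fits_path.exists() and sel_path.exists():
        fits_df = pd.read_csv(fits_path, sep="\t")
        selected = sorted(sel_path.read_text().split())
    else:
        roster = sorted(frozenset(scores.index) - never)
        collapsed = expr.collapse_replicates()
        tf_expr = collapsed.loc[[t for t in roster if t in collapsed.index]]
        tf_cnv = cnv.loc[[t for t in roster if t in cnv.index]]
        roster = [t for t in roster if t in tf_expr.index and t in tf_cnv.index]
        profiles = correlation_profiles(scores, tf_expr, tf_cnv, roster)
        fit_list = fit_all(profiles)
        selected = sorted(select_tfs(fit_list, cfg.alpha))
        fits_df = fits_table(fit_list)
        fits_df.to_csv(fits_path, sep="\t", index=False, float_format="%.10g")
        sel_path.write_text("\n".join(selected) + "\n")

    # stage 4: MCN, significance, negative control, central nodes
    ppi = PpiNetwork.from_frame(tio.read_ppi_edges(cfg.ppi))
    graph = ppi.filtered(cfg.min_evidence)
    result = minimal_connected_network(selected, graph)
    sig_p = subnetwork_significance(result, graph, cfg.n_random,
                                    _stage_seed(cfg.rng_seed, 41))
    ctrl_p = negative_control(sorted(catalogue.tfs), graph, result,
                              list_size=min(len(selected), len(catalogue.tfs)),
                              n_lists=cfg.n_control_lists,
                              rng_seed=_stage_seed(cfg.rng_seed, 42))
    central = central_nodes(result.node_metrics, cfg.top_k)
    result.node_metrics.to_csv(out / "mcn_nodes.tsv", sep="\t", float_format="%.10g")
    tio.write_sif(sorted(tuple(sorted(e)) for e in result.mcn.edges), out / "mcn_edges.sif")
    mcn_summary = {
        "n_seeds": len(result.seeds), "n_mapped": len(result.mapped_seeds),
        "n_mcn_nodes": result.mcn.number_of_nodes(),
        "n_mcn_edges": result.mcn.number_of_edges(),
        "significance": sig_p, "negative_control_p": ctrl_p,
        "above_average": sorted(central.above_average),
        "top_central": central.top, "top_share": central.top_share,
    }
    tio.write_manifest(mcn_summary, out / "mcn_summary.json")

    # stage 5: biomarker screen
    central_tfs = [n for n in central.top if n in catalogue.tfs]
    targets = central_tf_targets(central_tfs, catalogue)
    sets = tio.read_gmt(cfg.annotation_sets)
    accessible, enrich = annotation_filter(targets, sets, catalogue.targets)
    pexpr = tio.read_expression(cfg.patient_expression)
    phen = tio.read_phenotypes(cfg.phenotypes)
    normed = normalize_patient_expression(pexpr)
    spec_res = cancer_specific_genes(normed, phen, sorted(accessible), cfg.alpha_bh)
    spec_res.table.to_csv(out / "cancer_specific.tsv", sep="\t", float_format="%.10g")
    cohorts = []
    for label in sorted(cfg.cohorts):
        cohorts.append((label,
                        tio.read_expression(cfg.cohorts[label]["expression"]),
                        tio.read_clinical(cfg.cohorts[label]["clinical"])))
    screen = survival_screen(sorted(spec_res.genes), cohorts, cfg.alpha_survival)
    screen.pvalues.to_csv(out / "survival_screen.tsv", sep="\t", float_format="%.10g")
    biomarkers = sorted(screen.passing)
    (out / "biomarkers.txt").write_text("\n".join(biomarkers) + "\n")

    manifest = {
        "thresholds": {k: getattr(cfg, k) for k in THRESHOLDS},
        "rng_seed": cfg.rng_seed,
        "stage_seeds": {"mcn_significance": _stage_seed(cfg.rng_seed, 41),
                        "negative_control": _stage_seed(cfg.rng_seed, 42)},
        "outputs": ["tf_scores.tsv", "cnv_matrix.tsv", "tf_fits.tsv",
                    "selected_tfs.txt", "mcn_nodes.tsv", "mcn_edges.sif",
                    "mcn_summary.json", "cancer_specific.tsv",
                    "survival_screen.tsv", "biomarkers.txt"],
        "warnings": report["warnings"],
        "annotation_enrichment": {k: {"overlap": v[0], "p": v[1]}
                                  for k, v in enrich.items()},
    }
    tio.write_manifest(manifest, out / "manifest.json")
    return {
        "selected_tfs": selected, "mcn": mcn_summary,
        "n_candidate_targets": len(targets), "n_accessible": len(accessible),
        "cancer_specific": sorted(spec_res.genes), "biomarkers": biomarkers,
        "manifest": manifest,
    }
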