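"""Synthetic pipeline inputs with planted ground truth.

Every downstream stage is testable without external downloads: the
generators emit a regulation catalogue, a replicate-structured cell-line
expression matrix, a GISTIC-style significant-CNV-region table, gene
locations on a toy chromosome, a PPI graph with a planted module,
secreted/transmembrane annotation sets, a mixed patient cohort and
survival cohorts — together with the ground truth needed to score
recovery.

The generative model mirrors the pipeline's assumptions:

* every TF has a latent per-line activity; for *driver* TFs it is
  ``b1*expr + b2*cnv + noise`` (so expression and copy number explain
  regulation), for null TFs it is independent noise;
* a TF active in a line (activity above its activation quantile) shifts
  all its catalogue targets upward in that line's replicate columns;
* TF expression and CNV each follow a one-factor model across lines, so
  TF-TF correlation profiles carry structure for the regression stage;
* a subset of drivers ("module" drivers) plus a few hub proteins form a
  densely wired PPI module; remaining proteins get sparse background
  edges, so the module dominates the minimal connected network and its
  nodes rank centrally;
* planted cancer-specific genes (targets of module drivers, preferring
  genes covered by several of them) are shifted in cancer patients only,
  decoy genes in cancer AND inflammation patients; a subset of the
  cancer-specific genes carries a per-cohort survival hazard.

Each generator draws from its own deterministic RNG stream derived from
``config.rng_seed``, so outputs are bit-identical under a fixed seed.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .catalogue import RegulationCatalogue
from .errors import ConfigError
from .matrices import ExpressionMatrix

log = logging.getLogger(__name__)

# stream offsets: one independent RNG stream per generator
_STREAMS = {"catalogue": 0, "cell_lines": 1, "ppi": 2, "patients": 3,
            "survival": 4, "annotation": 5, "roles": 6}


def _rng(config: "SyntheticConfig", stream: str) -> np.random.Generator:
    return np.random.default_rng([config.rng_seed, _STREAMS[stream]])


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic study, with defaults chosen so that
    every planted structure is recoverable by the stage that targets it.

    The defaults emulate a scaled-down cell-line panel: 80 lines assayed
    in triplicate, a catalogue of 60 TFs with ~25 targets each over 1,000
    genes, and a patient cohort with the 78/8/14 cancer/inflammation/
    healthy split.
    """

    # catalogue
    n_tfs: int = 150
    n_genes: int = 1000
    mean_targets_per_tf: float = 25.0
    module_program_size: int = 40          # shared target pool of the module drivers
    module_program_targets: int = 12       # targets each module driver draws from it

    # cell-line panel
    n_cell_lines: int = 100
    replicates_per_line: int = 3           # 2 or 3
    expr_base_mean: float = 7.0            # log2 intensity scale
    expr_base_sd: float = 1.0
    line_noise_sd: float = 0.15            # per-gene per-line deviation
    replicate_noise_sd: float = 0.2
    target_shift: float = 3.0              # log2 shift of an active TF's targets
    min_loading: float = 0.7               # |factor loading| range for TF expr / CNV

    # activity model
    n_driver_tfs: int = 40                 # TFs with activity = b1*E + b2*C + eps
    n_active_null_tfs: int = 15            # non-drivers regulated (independently) somewhere;
                                           # the remaining nulls are never active, like the
                                           # bulk of a real catalogue in any one panel
    b1: float = 1.0
    b2: float = 1.0
    activity_noise_sd: float = 0.2
    activation_quantile: float = 0.9       # active in the top decile of lines

    # CNV
    cnv_noise_sd: float = 0.3
    cnv_region_q: float = 0.01             # q-value of the planted significant regions
    n_decoy_regions: int = 5               # non-significant regions (q > 0.25)
    gene_spacing: int = 2000               # toy chromosome layout
    gene_length: int = 1000

    # PPI
    n_background_proteins: int = 250
    n_module_drivers: int = 7              # densely wired core of the planted module
    n_hubs: int = 3
    ppi_background_prob: float = 0.01      # p0
    ppi_module_prob: float = 0.5           # p1: wiring among module nodes (core + hubs)
    ppi_peripheral_hub_prob: float = 0.35  # each peripheral driver to each module node
    ppi_peripheral_prob: float = 0.03      # peripheral drivers to each other
    n_unmapped_tfs: int = 2                # driver TFs absent from the interactome

    # patient cohort
    n_patients: int = 500
    prop_cancer: float = 0.78
    prop_inflammation: float = 0.08
    prop_healthy: float = 0.14
    n_cancer_specific: int = 12
    n_decoy_genes: int = 6
    cancer_effect: float = 1.5             # shift in units of the patient noise SD
    patient_noise_sd: float = 1.0

    # survival cohorts
    n_cohorts: int = 3
    cohort_size: int = 300
    n_survival_genes: int = 8
    survival_log_hr: float = math.log(3.0)
    baseline_hazard: float = 1e-3          # events per day
    censoring_rate: float = 0.3

    rng_seed: int = 0

    def validate(self) -> None:
        if self.replicates_per_line not in (2, 3):
            raise ConfigError("replicates_per_line must be 2 or 3")
        props = self.prop_cancer + self.prop_inflammation + self.prop_healthy
        if abs(props - 1.0) > 1e-9:
            raise ConfigError("phenotype proportions (prop_*) must sum to 1")
        if not 0 <= self.censoring_rate < 1:
            raise ConfigError("censoring_rate must lie in [0, 1)")
        if self.n_driver_tfs < 1:
            raise ConfigError("n_driver_tfs must be >= 1")
        if self.n_driver_tfs > self.n_tfs:
            raise ConfigError("n_driver_tfs cannot exceed n_tfs")
        if self.n_driver_tfs + self.n_active_null_tfs > self.n_tfs:
            raise ConfigError("n_driver_tfs + n_active_null_tfs cannot exceed n_tfs")
        if self.ppi_peripheral_hub_prob <= self.ppi_background_prob:
            raise ConfigError("ppi_peripheral_hub_prob must exceed ppi_background_prob")
        if self.n_module_drivers > self.n_driver_tfs:
            raise ConfigError("n_module_drivers cannot exceed n_driver_tfs")
        if self.ppi_module_prob <= self.ppi_background_prob:
            raise ConfigError("ppi_module_prob must exceed ppi_background_prob "
                              "(module not denser than background)")
        for name in ("n_tfs", "n_genes", "n_cell_lines", "n_background_proteins",
                     "n_patients", "n_cohorts", "cohort_size"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if self.n_tfs >= 2 and self.mean_targets_per_tf < 1:
            raise ConfigError("mean_targets_per_tf must be >= 1")
        if not 0 < self.activation_quantile < 1:
            raise ConfigError("activation_quantile must lie in (0, 1)")


@dataclass
class GroundTruth:
    """What was planted, for scoring recovery downstream."""

    driver_tfs: frozenset[str]
    module_nodes: frozenset[str]              # module drivers + hubs
    cancer_specific_genes: frozenset[str]
    survival_genes: dict[str, dict[str, float]]  # gene -> cohort -> log HR
    # plumbing beyond the headline sets
    all_tfs: frozenset[str] = frozenset()
    active_null_tfs: frozenset[str] = frozenset()
    module_drivers: frozenset[str] = frozenset()
    hub_nodes: frozenset[str] = frozenset()
    decoy_genes: frozenset[str] = frozenset()
    unmapped_tfs: frozenset[str] = frozenset()
    activity: Optional[pd.DataFrame] = None   # TF x line latent activity
    active: Optional[pd.DataFrame] = None     # TF x line activation calls
    gene_baseline: Optional[pd.Series] = None


def _tf_ids(n: int) -> list[str]:
    return [f"TF{i + 1:03d}" for i in range(n)]


def _gene_ids(n: int) -> list[str]:
    return [f"G{i + 1:04d}" for i in range(n)]


def _tf_roles(config: SyntheticConfig) -> tuple[frozenset[str], frozenset[str], frozenset[str]]:
    """(drivers, active nulls, module drivers), reproducible from config.

    Drawn from a dedicated RNG stream so that the catalogue generator
    (which gives module drivers a shared target program) and the
    cell-line generator (which wires driver activity to expression and
    CNV) agree on the roles without passing state.
    """
    rng = _rng(config, "roles")
    tfs = _tf_ids(config.n_tfs)
    n_pick = min(config.n_driver_tfs + config.n_active_null_tfs, config.n_tfs)
    picked = [tfs[i] for i in sorted(rng.choice(config.n_tfs, size=n_pick, replace=False))]
    drivers = frozenset(picked[:config.n_driver_tfs])
    active_nulls = frozenset(picked[config.n_driver_tfs:])
    module_drivers = frozenset(sorted(drivers)[:config.n_module_drivers])
    return drivers, active_nulls, module_drivers


def _module_program(config: SyntheticConfig) -> list[str]:
    """Shared target pool of the module drivers (co-regulated program)."""
    rng = np.random.default_rng([config.rng_seed, _STREAMS["roles"], 1])
    genes = _gene_ids(config.n_genes)
    size = min(config.module_program_size, config.n_genes)
    return [genes[i] for i in sorted(rng.choice(config.n_genes, size=size, replace=False))]


def generate_catalogue(config: SyntheticConfig) -> RegulationCatalogue:
    """Random TF -> target catalogue.

    Per-TF target counts are Poisson around ``mean_targets_per_tf``
    (at least 1); targets are drawn without replacement per TF. Module
    drivers draw ``module_program_targets`` of their targets from a
    shared program pool — co-regulating TF modules share targets, which
    is the premise the downstream analysis exploits. When the mean
    reaches ``n_genes`` every TF targets every gene (saturation).
    """
    config.validate()
    rng = _rng(config, "catalogue")
    tfs, genes = _tf_ids(config.n_tfs), _gene_ids(config.n_genes)
    _, _, module_drivers = _tf_roles(config)
    program = _module_program(config)
    rows = []
    for tf in tfs:
        if config.mean_targets_per_tf >= config.n_genes:
            chosen = list(genes)
        else:
            k = int(min(config.n_genes, max(1, rng.poisson(config.mean_targets_per_tf))))
            if tf in module_drivers and len(program) > 0:
                n_prog = min(config.module_program_targets, k, len(program))
                prog_part = [program[i] for i in
                             sorted(rng.choice(len(program), size=n_prog, replace=False))]
                rest_pool = [g for g in genes if g not in set(prog_part)]
                n_rest = min(k - n_prog, len(rest_pool))
                rest = [rest_pool[i] for i in
                        sorted(rng.choice(len(rest_pool), size=n_rest, replace=False))]
                chosen = sorted(prog_part + rest)
            else:
                chosen = [genes[i] for i in sorted(rng.choice(config.n_genes, size=k,
                                                              replace=False))]
        rows.extend((tf, g, "") for g in chosen)
    return RegulationCatalogue(pd.DataFrame(rows, columns=["tf", "target", "sign"]))


def _pick_preferring_coverage(genes_by_cover: Mapping[str, int], k: int,
                              rng: np.random.Generator,
                              exclude: frozenset[str] = frozenset()) -> list[str]:
    """Sample k genes, preferring those targeted by more module drivers."""
    pool = [(cover, g) for g, cover in genes_by_cover.items() if g not in exclude]
    order = sorted(pool, key=lambda t: (-t[0], rng.random()))
    return [g for _, g in order[:k]]


def generate_cell_line_data(catalogue: RegulationCatalogue, config: SyntheticConfig
                            ) -> tuple[ExpressionMatrix, tuple[pd.DataFrame, pd.DataFrame],
                                       pd.DataFrame, GroundTruth]:
    """Cell-line expression, CNV regions, gene locations and ground truth.

    Returns ``(expression, (regions, region_values), locations, truth)``.
    Expression has ``replicates_per_line`` columns per line; CNV comes as
    a BED-like significant-region table plus per-sample peak values, with
    one region per TF locus and a few non-significant decoy regions.
    """
    config.validate()
    if config.n_driver_tfs < 1:
        raise ConfigError("no driver TFs requested")
    rng = _rng(config, "cell_lines")
    tfs = sorted(catalogue.tfs)
    genes = sorted(catalogue.targets | frozenset(_gene_ids(config.n_genes)))
    lines = [f"L{i + 1:03d}" for i in range(config.n_cell_lines)]
    n_l, n_t = len(lines), len(tfs)

    drivers, active_nulls, module_drivers = _tf_roles(config)
    drivers = frozenset(t for t in drivers if t in set(tfs))
    active_nulls = frozenset(t for t in active_nulls if t in set(tfs))
    module_drivers = frozenset(t for t in module_drivers if t in set(tfs))
    if not drivers:
        raise ConfigError("no driver TFs map onto the catalogue's TF ids")

    # one-factor structure across lines for TF expression and CNV
    f_expr = rng.normal(size=n_l)
    f_cnv = rng.normal(size=n_l)
    sign = rng.choice([-1.0, 1.0], size=(2, n_t))
    mag = rng.uniform(config.min_loading, 1.0, size=(2, n_t))
    u_expr, u_cnv = sign * mag

    tf_base = rng.normal(config.expr_base_mean, config.expr_base_sd, size=n_t)
    tf_expr = (tf_base[:, None] + u_expr[:, None] * f_expr[None, :]
               + rng.normal(0, config.line_noise_sd, size=(n_t, n_l)))
    tf_cnv = (u_cnv[:, None] * f_cnv[None, :]
              + rng.normal(0, config.cnv_noise_sd, size=(n_t, n_l)))

    activity = np.empty((n_t, n_l))
    for i, tf in enumerate(tfs):
        if tf in drivers:
            activity[i] = (config.b1 * tf_expr[i] + config.b2 * tf_cnv[i]
                           + rng.normal(0, config.activity_noise_sd, size=n_l))
        else:
            activity[i] = rng.normal(size=n_l)
    thresh = np.quantile(activity, config.activation_quantile, axis=1, keepdims=True)
    active = activity > thresh
    # quiet nulls: TFs not regulated anywhere in this panel
    regulated_tfs = drivers | active_nulls
    for i, tf in enumerate(tfs):
        if tf not in regulated_tfs:
            active[i, :] = False

    # target-gene expression: baseline + line deviation + shift when any
    # targeting TF is active in the line
    target_genes = [g for g in genes if not g.startswith("TF")]
    n_g = len(target_genes)
    g_index = {g: i for i, g in enumerate(target_genes)}
    base = rng.normal(config.expr_base_mean, config.expr_base_sd, size=n_g)
    line_vals = base[:, None] + rng.normal(0, config.line_noise_sd, size=(n_g, n_l))
    for i, tf in enumerate(tfs):
        rows = [g_index[g] for g in catalogue.targets_of(tf) if g in g_index]
        if rows:
            line_vals[np.ix_(rows, active[i])] += config.target_shift

    # replicate columns (TF genes first, then targets)
    all_ids = tfs + target_genes
    all_line_vals = np.vstack([tf_expr, line_vals])
    r = config.replicates_per_line
    cols, col_line = [], []
    for line in lines:
        for j in range(r):
            cols.append(f"{line}_r{j + 1}")
            col_line.append(line)
    values = (np.repeat(all_line_vals, r, axis=1)
              + rng.normal(0, config.replicate_noise_sd,
                           size=(len(all_ids), n_l * r)))
    expr = ExpressionMatrix(pd.DataFrame(values, index=all_ids, columns=cols),
                            pd.Series(col_line, index=cols))

    # toy chromosome: TF genes laid out first, one significant region per
    # TF locus; decoy regions (q > 0.25) over target genes
    loc_rows = []
    for i, g in enumerate(all_ids):
        start = i * config.gene_spacing
        loc_rows.append(("chr1", start, start + config.gene_length, g))
    locations = pd.DataFrame(loc_rows, columns=["chrom", "start", "end", "gene"])
    reg_rows, val_rows = [], []
    for i, tf in enumerate(tfs):
        start = i * config.gene_spacing
        rid = f"R{i + 1:03d}"
        reg_rows.append(("chr1", max(0, start - 100), start + config.gene_length + 100,
                         rid, "amp" if u_cnv[i] > 0 else "del", config.cnv_region_q))
        val_rows.append([rid, *tf_cnv[i]])
    for d in range(config.n_decoy_regions):
        i = n_t + d * 7  # land on target-gene loci
        start = i * config.gene_spacing
        rid = f"RD{d + 1:02d}"
        reg_rows.append(("chr1", start, start + config.gene_length, rid, "amp", 0.6))
        val_rows.append([rid, *rng.normal(0, 0.2, size=n_l)])
    regions = pd.DataFrame(reg_rows, columns=["chrom", "start", "end", "region_id",
                                              "type", "q"])
    region_values = pd.DataFrame(val_rows, columns=["region_id", *lines])

    # planted biomarker genes among module-driver targets, preferring
    # genes covered by several module drivers (robust to one TF slipping
    # out of the central set)
    cover: dict[str, int] = {}
    for tf in module_drivers:
        for g in catalogue.targets_of(tf):
            cover[g] = cover.get(g, 0) + 1
    cancer_specific = frozenset(_pick_preferring_coverage(
        cover, config.n_cancer_specific, rng))
    decoys = frozenset(_pick_preferring_coverage(
        cover, config.n_decoy_genes, rng, exclude=cancer_specific))
    cohorts = [f"C{i + 1}" for i in range(config.n_cohorts)]
    surv_pool = sorted(cancer_specific)
    surv_genes: dict[str, dict[str, float]] = {}
    chosen = [surv_pool[i] for i in
              sorted(rng.choice(len(surv_pool),
                                size=min(config.n_survival_genes, len(surv_pool)),
                                replace=False))]
    for g in chosen:
        k = int(rng.integers(1, min(2, len(cohorts)) + 1))
        cs = [cohorts[i] for i in sorted(rng.choice(len(cohorts), size=k, replace=False))]
        surv_genes[g] = {c: config.survival_log_hr for c in cs}

    hubs = frozenset(f"HUB{i + 1}" for i in range(config.n_hubs))
    truth = GroundTruth(
        driver_tfs=drivers,
        module_nodes=module_drivers | hubs,
        cancer_specific_genes=cancer_specific,
        survival_genes=surv_genes,
        all_tfs=frozenset(tfs),
        active_null_tfs=active_nulls,
        module_drivers=module_drivers,
        hub_nodes=hubs,
        decoy_genes=decoys,
        activity=pd.DataFrame(activity, index=tfs, columns=lines),
        active=pd.DataFrame(active, index=tfs, columns=lines),
        gene_baseline=pd.Series(np.concatenate([tf_base, base]), index=all_ids),
    )
    return expr, (regions, region_values), locations, truth


def generate_ppi(truth: GroundTruth, config: SyntheticConfig) -> pd.DataFrame:
    """PPI edge list (a, b, evidence) with the planted module.

    Erdos-Renyi background over all proteins at ``ppi_background_prob``;
    module nodes (core drivers + hub intermediates) are pairwise wired at
    ``ppi_module_prob`` and act as a bridge layer: every peripheral
    driver attaches to each module node at ``ppi_peripheral_hub_prob``
    (and to other peripheral drivers at ``ppi_peripheral_prob``), so
    shortest paths between peripheral drivers run through the module and
    betweenness within the extracted MCN concentrates on it.
    ``n_unmapped_tfs`` peripheral drivers are left out of the graph to
    emulate seeds lost in interactome mapping. All evidence counts
    are >= 2.
    """
    config.validate()
    if not truth.module_nodes:
        raise ConfigError("module_nodes is empty")
    rng = _rng(config, "ppi")
    background = [f"P{i + 1:04d}" for i in range(config.n_background_proteins)]
    peripheral = sorted(truth.driver_tfs - truth.module_drivers)
    unmapped = frozenset(peripheral[:config.n_unmapped_tfs])
    truth.unmapped_tfs = unmapped
    nodes = sorted((set(background) | truth.all_tfs | truth.hub_nodes) - unmapped)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)

    edges: dict[tuple[int, int], int] = {}

    def wire(a: str, b: str, prob: float, mean_extra: int) -> None:
        if a in idx and b in idx and rng.random() < prob:
            key = tuple(sorted((idx[a], idx[b])))
            edges[key] = int(2 + rng.poisson(mean_extra))

    p0 = config.ppi_background_prob
    if p0 > 0:
        ii, jj = np.triu_indices(n, k=1)
        hit = rng.random(len(ii)) < p0
        for i, j in zip(ii[hit], jj[hit]):
            edges[(int(i), int(j))] = int(2 + rng.poisson(1))
    module = sorted(truth.module_nodes)
    for a_i in range(len(module)):
        for b_i in range(a_i + 1, len(module)):
            wire(module[a_i], module[b_i], config.ppi_module_prob, 2)
    mapped_peripheral = [t for t in peripheral if t not in unmapped]
    for t in mapped_peripheral:
        for m in module:
            wire(t, m, config.ppi_peripheral_hub_prob, 2)
    for a_i, t in enumerate(mapped_peripheral):
        for other in mapped_peripheral[a_i + 1:]:
            wire(t, other, config.ppi_peripheral_prob, 1)
    rows = [(nodes[i], nodes[j], ev) for (i, j), ev in sorted(edges.items())]
    return pd.DataFrame(rows, columns=["a", "b", "evidence"])


def generate_annotation_sets(catalogue: RegulationCatalogue, truth: GroundTruth,
                             config: SyntheticConfig) -> dict[str, frozenset[str]]:
    """Secreted / transmembrane gene sets covering the planted biomarkers.

    The planted cancer-specific genes and decoys are split between the
    two sets (every planted gene is accessible); a random 15% of the
    remaining target genes pads each set.
    """
    rng = _rng(config, "annotation")
    planted = sorted(truth.cancer_specific_genes | truth.decoy_genes)
    half = len(planted) // 2
    secreted = set(planted[:half])
    transmembrane = set(planted[half:])
    others = sorted(catalogue.targets - set(planted))
    flips = rng.random(len(others))
    for g, x in zip(others, flips):
        if x < 0.15:
            secreted.add(g)
        elif x < 0.30:
            transmembrane.add(g)
    return {"secreted": frozenset(secreted), "transmembrane": frozenset(transmembrane)}


def phenotype_counts(n: int, config: SyntheticConfig) -> dict[str, int]:
    n_cancer = round(n * config.prop_cancer)
    n_inflam = round(n * config.prop_inflammation)
    return {"cancer": n_cancer, "inflammation": n_inflam,
            "healthy": n - n_cancer - n_inflam}


def generate_patient_cohort(genes: Sequence[str], truth: GroundTruth,
                            config: SyntheticConfig
                            ) -> tuple[ExpressionMatrix, pd.Series]:
    """Mixed cancer/inflammation/healthy patient expression matrix.

    Cancer-specific genes are shifted by ``cancer_effect`` (in units of
    the patient noise SD) in cancer samples only; decoy genes in cancer
    AND inflammation samples; everything else is null.
    """
    config.validate()
    if config.cancer_effect == 0:
        log.warning("generate_patient_cohort: cancer_effect is 0; "
                    "no planted gene will be recoverable")
    rng = _rng(config, "patients")
    genes = list(genes)
    counts = phenotype_counts(config.n_patients, config)
    phenos = (["cancer"] * counts["cancer"] + ["inflammation"] * counts["inflammation"]
              + ["healthy"] * counts["healthy"])
    patients = [f"PT{i + 1:04d}" for i in range(config.n_patients)]
    phenotypes = pd.Series(phenos, index=patients)
    base = rng.normal(config.expr_base_mean, config.expr_base_sd, size=len(genes))
    vals = base[:, None] + rng.normal(0, config.patient_noise_sd,
                                      size=(len(genes), len(patients)))
    shift = config.cancer_effect * config.patient_noise_sd
    is_cancer = (phenotypes == "cancer").to_numpy()
    is_inflam = (phenotypes == "inflammation").to_numpy()
    gidx = {g: i for i, g in enumerate(genes)}
    for g in truth.cancer_specific_genes:
        if g in gidx:
            vals[gidx[g], is_cancer] += shift
    for g in truth.decoy_genes:
        if g in gidx:
            vals[gidx[g], is_cancer | is_inflam] += shift
    expr = ExpressionMatrix.from_single_samples(
        pd.DataFrame(vals, index=genes, columns=patients))
    return expr, phenotypes


def generate_survival_cohort(genes: Sequence[str], truth: GroundTruth,
                             config: SyntheticConfig, cohort: str
                             ) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """One cohort's expression matrix and clinical (time, event) table.

    Event times are exponential with log-hazard linear in the planted
    per-cohort effect times the standardized expression; censoring times
    are independent exponentials calibrated to the configured rate.
    """
    config.validate()
    # str hash is process-randomized; crc32 keeps the stream reproducible
    rng = np.random.default_rng([config.rng_seed, _STREAMS["survival"],
                                 zlib.crc32(cohort.encode()) % (2 ** 31)])
    genes = list(genes)
    patients = [f"{cohort}_PT{i + 1:04d}" for i in range(config.cohort_size)]
    base = rng.normal(config.expr_base_mean, config.expr_base_sd, size=len(genes))
    vals = base[:, None] + rng.normal(0, config.patient_noise_sd,
                                      size=(len(genes), len(patients)))
    loghaz = np.full(len(patients), math.log(config.baseline_hazard))
    for g, effects in truth.survival_genes.items():
        beta = effects.get(cohort, 0.0)
        if beta and g in genes:
            x = vals[genes.index(g)]
            z = (x - x.mean()) / x.std()
            loghaz = loghaz + beta * z
    event_t = rng.exponential(1.0 / np.exp(loghaz))
    if config.censoring_rate > 0:
        # for a null patient, P(censor first) = rc / (rc + baseline)
        rc = config.baseline_hazard * config.censoring_rate / (1 - config.censoring_rate)
        censor_t = rng.exponential(1.0 / rc, size=len(patients))
    else:
        censor_t = np.full(len(patients), np.inf)
    time = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)
    time = np.maximum(time, 1e-6)  # times must be strictly positive
    clinical = pd.DataFrame({"time": time, "event": event}, index=patients)
    expr = ExpressionMatrix.from_single_samples(
        pd.DataFrame(vals, index=genes, columns=patients))
    return expr, clinical


def generate_profile_dataset(n_tfs: int = 40, beta: tuple[float, float, float] = (0.0, 0.3, 0.3),
                             noise_sd: float = 0.1, rng=None):
    """One planted correlation-profile regression dataset.

    Builds symmetric R/E/C profile matrices over an ``n_tfs`` roster in
    which the first TF's R-profile is exactly
    ``b0 + b1*E + b2*C + N(0, noise_sd)`` across the other TFs — the
    regression stage's model, planted at the profile level so that OLS
    theory (confidence-interval coverage, per-slope type-I error) applies
    exactly. Returns ``(profiles, target_tf)``.
    """
    from .select import TFCorrProfiles
    rng = np.random.default_rng(rng)
    tfs = [f"T{i:03d}" for i in range(n_tfs)]
    b0, b1, b2 = beta

    def sym(mat):
        m = (mat + mat.T) / 2
        np.fill_diagonal(m, 1.0)
        return np.clip(m, -1, 1)

    e = sym(rng.uniform(-0.9, 0.9, size=(n_tfs, n_tfs)))
    c = sym(rng.uniform(-0.9, 0.9, size=(n_tfs, n_tfs)))
    r = sym(rng.uniform(-0.9, 0.9, size=(n_tfs, n_tfs)))
    target = b0 + b1 * e[0] + b2 * c[0] + rng.normal(0, noise_sd, size=n_tfs)
    r[0, :] = target
    r[:, 0] = target
    r[0, 0] = 1.0
    idx = pd.Index(tfs)
    profiles = TFCorrProfiles(
        R=pd.DataFrame(r, index=idx, columns=idx),
        E=pd.DataFrame(e, index=idx, columns=idx),
        C=pd.DataFrame(c, index=idx, columns=idx),
        zero_variance={"R": frozenset(), "E": frozenset(), "C": frozenset()},
    )
    return profiles, tfs[0]


@dataclass
class SyntheticBundle:
    """Everything one pipeline run consumes, plus the ground truth."""

    config: SyntheticConfig
    catalogue: RegulationCatalogue
    expression: ExpressionMatrix
    regions: pd.DataFrame
    region_values: pd.DataFrame
    locations: pd.DataFrame
    ppi_edges: pd.DataFrame
    annotation_sets: dict[str, frozenset[str]]
    patient_expr: ExpressionMatrix
    phenotypes: pd.Series
    survival_cohorts: list[tuple[str, ExpressionMatrix, pd.DataFrame]]
    truth: GroundTruth


def generate_all(config: SyntheticConfig) -> SyntheticBundle:
    """Run every generator with consistent identifiers."""
    config.validate()
    catalogue = generate_catalogue(config)
    expr, (regions, region_values), locations, truth = generate_cell_line_data(
        catalogue, config)
    ppi = generate_ppi(truth, config)
    sets = generate_annotation_sets(catalogue, truth, config)
    genes = list(expr.genes)
    patient_expr, phenotypes = generate_patient_cohort(genes, truth, config)
    cohorts = []
    for i in range(config.n_cohorts):
        label = f"C{i + 1}"
        cexpr, clin = generate_survival_cohort(genes, truth, config, label)
        cohorts.append((label, cexpr, clin))
    return SyntheticBundle(config=config, catalogue=catalogue, expression=expr,
                           regions=regions, region_values=region_values,
                           locations=locations, ppi_edges=ppi,
                           annotation_sets=sets, patient_expr=patient_expr,
                           phenotypes=phenotypes, survival_cohorts=cohorts,
                           truth=truth)


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Key-value manifest of the planted sets (for inspection and tests)."""
    lines = [
        "driver_tfs\t" + ",".join(sorted(truth.driver_tfs)),
        "module_nodes\t" + ",".join(sorted(truth.module_nodes)),
        "cancer_specific_genes\t" + ",".join(sorted(truth.cancer_specific_genes)),
        "decoy_genes\t" + ",".join(sorted(truth.decoy_genes)),
        "unmapped_tfs\t" + ",".join(sorted(truth.unmapped_tfs)),
        "survival_genes\t" + ",".join(
            f"{g}:{c}:{b:.6g}" for g in sorted(truth.survival_genes)
            for c, b in sorted(truth.survival_genes[g].items())),
    ]
    Path(path).write_text("\n".join(lines) + "\n")
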