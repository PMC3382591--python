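"""Gene-level CNV matrix from a GISTIC-style significant-region table.

Significant regions (q <= 0.25 by default) are normalized by taking, per
region and sample, the median over the region's peak values; every gene
overlapping a significant region inherits that region's per-sample
median, and genes outside all significant regions carry the no-alteration
sentinel 0 (log2-ratio of no change). Chromosomes X and Y are excluded
by default.
"""

from __future__ import annotations

import logging

import pandas as pd

from .errors import ContractError

log = logging.getLogger(__name__)

SEX_CHROMOSOMES = frozenset({"chrX", "chrY", "X", "Y"})


def filter_significant_regions(regions: pd.DataFrame, q_max: float = 0.25) -> pd.DataFrame:
    """Rows with q <= ``q_max`` (boundary inclusive), original order kept."""
    if "q" not in regions.columns:
        raise ContractError("region table has no q column")
    kept = regions[regions["q"] <= q_max].copy()
    if kept.empty:
        log.warning("no region passes q <= %g", q_max)
    return kept


def region_medians(regions: pd.DataFrame, values: pd.DataFrame) -> pd.DataFrame:
    """Per-region, per-sample median over the region's peak rows.

    ``values`` has one row per peak (region_id column + sample columns);
    a region with a single peak contributes that peak's value unchanged.
    Missing per-sample values propagate as NaN.
    """
    sub = values[values["region_id"].isin(regions["region_id"])]
    return sub.groupby("region_id").median()


def gene_cnv_matrix(regions: pd.DataFrame, medians: pd.DataFrame,
                    locations: pd.DataFrame, samples: list[str],
                    assignment: str = "overlap",
                    exclude_sex_chromosomes: bool = True) -> pd.DataFrame:
    """Genes x samples matrix of median-normalized log2 CNV.

    A gene overlapping a significant region (any shared base by default;
    ``assignment='midpoint'`` requires the gene midpoint inside the
    region) receives the region's per-sample median. Conflicts between
    several overlapping regions are resolved by smallest q, then larger
    absolute median (across samples), then lexicographic region id.
    Genes overlapping nothing get an all-zero row.
    """
    if assignment not in ("overlap", "midpoint"):
        raise ContractError(f"unknown assignment mode {assignment!r}")
    regs = regions
    if exclude_sex_chromosomes:
        regs = regs[~regs["chrom"].isin(SEX_CHROMOSOMES)]
    out = pd.DataFrame(0.0, index=list(locations["gene"]), columns=samples)
    if regs.empty:
        return out
    med = medians.reindex(columns=samples)
    # scalar tie-break key per region: |median across samples of its medians|
    abs_med = med.median(axis=1).abs()
    by_chrom = {c: g for c, g in regs.groupby("chrom")}
    for _, row in locations.iterrows():
        g, chrom, gs, ge = row["gene"], row["chrom"], row["start"], row["end"]
        cand = by_chrom.get(chrom)
        if cand is None:
            continue
        if assignment == "overlap":
            hit = cand[(cand["start"] < ge) & (cand["end"] > gs)]
        else:
            mid = (gs + ge) // 2
            hit = cand[(cand["start"] <= mid) & (mid < cand["end"])]
        if hit.empty:
            continue
        best = min(
            hit.itertuples(),
            key=lambda r: (r.q, -abs_med.get(r.region_id, 0.0), r.region_id),
        )
        vals = med.loc[best.region_id]
        out.loc[g] = vals.to_numpy(dtype=float)
    n_alt = int((out != 0).any(axis=1).sum())
    log.info("gene_cnv_matrix: %d/%d genes in altered regions", n_alt, len(out))
    return out
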