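"""Accessible cancer-specific biomarker calling on patient cohorts.

The candidate genes are the pooled targets of the most central MCN TFs,
restricted to genes annotated as encoding secreted or transmembrane
proteins ("accessible"). On a mixed patient cohort (cancer /
inflammation / healthy), expression is standardized per gene by median
subtraction and inter-quartile-range division, and a gene is called
cancer-specific when it is differentially expressed in cancer vs the
rest (Benjamini-Hochberg q <= alpha) but NOT in inflammation vs the rest
— the second contrast removes genes that merely track inflammation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .activity import set_enrichment
from .catalogue import RegulationCatalogue
from .errors import ContractError, PreconditionError, UnknownIdentifierError
from .matrices import ExpressionMatrix

log = logging.getLogger(__name__)

PHENOTYPES = ("cancer", "inflammation", "healthy")


def central_tf_targets(tfs: Iterable[str], catalogue: RegulationCatalogue) -> frozenset[str]:
    """Deduplicated union of the catalogue target sets of ``tfs``."""
    return catalogue.targets_of_many(tfs)  # raises UnknownIdentifierError


def annotation_filter(genes: Iterable[str], sets: Mapping[str, frozenset[str]],
                      universe: Iterable[str],
                      set_names: Iterable[str] = ("secreted", "transmembrane"),
                      ) -> tuple[frozenset[str], dict[str, tuple[int, float]]]:
    """Restrict ``genes`` to members of the named annotation sets.

    Returns the filtered gene set and, per set, the (overlap, p) from the
    hypergeometric enrichment of ``genes`` in that set — reported for
    transparency only, not used as a filter.
    """
    genes = frozenset(genes)
    universe = frozenset(universe)
    union: set[str] = set()
    enrich: dict[str, tuple[int, float]] = {}
    for name in set_names:
        if name not in sets:
            raise UnknownIdentifierError(f"annotation set {name!r} not provided")
        members = sets[name] & universe
        union |= members
        enrich[name] = set_enrichment(genes, members, universe)
    return genes & union, enrich


def iqr(x: np.ndarray) -> float:
    """Inter-quartile range with linear-interpolation quartiles (type 7)."""
    q1, q3 = np.quantile(x, [0.25, 0.75])
    return float(q3 - q1)


def normalize_patient_expression(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene (x - median) / IQR standardization.

    Rows with zero IQR carry no rankable signal and are dropped (logged).
    """
    vals = expr.values.to_numpy(dtype=float)
    med = np.median(vals, axis=1, keepdims=True)
    q1 = np.quantile(vals, 0.25, axis=1, keepdims=True)
    q3 = np.quantile(vals, 0.75, axis=1, keepdims=True)
    iqrs = (q3 - q1).ravel()
    keep = iqrs > 0
    if not keep.any():
        raise ContractError("every gene has zero IQR; nothing to normalize")
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("normalize_patient_expression: dropped %d zero-IQR genes", n_drop)
    normed = (vals[keep] - med[keep]) / (q3 - q1)[keep]
    out = pd.DataFrame(normed, index=expr.values.index[keep], columns=expr.values.columns)
    return ExpressionMatrix(out, expr.sample_to_line)


@dataclass
class SpecificityResult:
    genes: frozenset[str]  # cancer-specific calls
    table: pd.DataFrame    # per candidate: p/q per contrast, fold-change sign


def cancer_specific_genes(norm_expr: ExpressionMatrix, phenotypes: pd.Series,
                          candidate_genes: Iterable[str],
                          alpha_bh: float = 0.05) -> SpecificityResult:
    """Dual-contrast cancer specificity call.

    Contrast A tests cancer vs (inflammation + healthy); contrast B asks
    whether the gene is also regulated by inflammation, comparing
    inflammation against healthy samples (the cancer samples are excluded
    from B's reference: with cancer the large majority of the cohort, a
    pooled reference would be dominated by the cancer shift itself and
    the contrast would flag cancer-only genes instead of inflammation
    ones). Each contrast uses a per-gene two-sample Welch t-test on the
    standardized values, with Benjamini-Hochberg correction across the
    candidate genes within each contrast. A gene is cancer-specific when
    q_A <= alpha_bh and q_B > alpha_bh. The returned table also carries
    the cancer-vs-rest mean difference (fold change on the log scale).
    """
    phenotypes = phenotypes.loc[[c for c in norm_expr.values.columns if c in phenotypes.index]]
    for ph in PHENOTYPES:
        if (phenotypes == ph).sum() < 2:
            raise PreconditionError(f"phenotype {ph!r} has < 2 samples")
    candidates = [g for g in candidate_genes]
    missing = set(candidates) - set(norm_expr.values.index)
    if missing:
        log.info("cancer_specific_genes: %d candidates not measured (skipped)", len(missing))
        candidates = [g for g in candidates if g not in missing]
    if not candidates:
        raise PreconditionError("no candidate gene is present in the expression matrix")
    vals = norm_expr.values.loc[candidates, phenotypes.index].to_numpy(dtype=float)
    in_cancer = (phenotypes == "cancer").to_numpy()
    in_inflam = (phenotypes == "inflammation").to_numpy()
    in_healthy = (phenotypes == "healthy").to_numpy()

    def contrast(mask: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        a, b = vals[:, mask], vals[:, ref]
        t = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.where(np.isfinite(t.pvalue), t.pvalue, 1.0)
        return p, a.mean(axis=1) - b.mean(axis=1)

    p_a, fc = contrast(in_cancer, ~in_cancer)
    p_b, _ = contrast(in_inflam, in_healthy)
    q_a = multipletests(p_a, method="fdr_bh")[1]
    q_b = multipletests(p_b, method="fdr_bh")[1]
    hit = (q_a <= alpha_bh) & (q_b > alpha_bh)
    table = pd.DataFrame({
        "p_cancer": p_a, "q_cancer": q_a,
        "p_inflammation": p_b, "q_inflammation": q_b,
        "fold_change": fc, "direction": np.sign(fc).astype(int),
        "cancer_specific": hit,
    }, index=pd.Index(candidates, name="gene"))
    return SpecificityResult(genes=frozenset(table.index[hit]), table=table)
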