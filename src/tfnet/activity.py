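"""Per-cell-line regulated-gene calling and TF regulation scoring.

The scoring follows the catalogue-enrichment idea: a TF is called
regulated in a cell line when its known target genes are over-represented
among the genes differentially expressed in that line. Differential genes
are called per line with a two-sample Kolmogorov-Smirnov test of the
line's replicate values against the pooled values of all other lines;
enrichment uses the one-sided hypergeometric (Fisher) upper tail. Both
stages use e-values (p times the number of tests) rather than raw
p-values, and a TF's regulation score is max(0, -log10(e-value)), so a
strictly positive score means e < 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .catalogue import RegulationCatalogue
from .errors import ContractError, PreconditionError
from .matrices import ExpressionMatrix

log = logging.getLogger(__name__)

# exact two-sample KS below this total sample size; the replicate group has
# only 2-3 points, where the asymptotic tail is unreliable
KS_EXACT_MAX_N = 25

# p-values are floored here before -log10 so scores stay finite
_P_FLOOR = 1e-300


def _ks_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    method = "exact" if (len(x) + len(y)) <= KS_EXACT_MAX_N else "asymp"
    return float(stats.ks_2samp(x, y, method=method).pvalue)


def differential_genes(expr: ExpressionMatrix, line: str,
                       evalue_max: float = 10.0) -> frozenset[str]:
    """Genes differentially expressed in ``line`` vs the pool of all others.

    Per gene, a two-sample KS test compares the line's replicate values
    with the pooled values of every other column; the e-value is the KS
    p-value multiplied by the number of genes tested, and genes with
    e-value <= ``evalue_max`` are returned.
    """
    cols = expr.line_columns(line)  # raises UnknownIdentifierError
    if len(cols) < 2:
        raise PreconditionError(f"line {line!r} has {len(cols)} replicate column(s); need >= 2")
    other_lines = set(expr.lines) - {line}
    if len(other_lines) < 2:
        raise PreconditionError("need at least 2 other cell lines to pool against")
    other_cols = [c for c in expr.values.columns if c not in cols]
    n_genes = expr.values.shape[0]
    own = expr.values[cols].to_numpy(dtype=float)
    pool = expr.values[other_cols].to_numpy(dtype=float)
    hits = [
        gene
        for i, gene in enumerate(expr.genes)
        if _ks_pvalue(own[i], pool[i]) * n_genes <= evalue_max
    ]
    return frozenset(hits)


def set_enrichment(query: Iterable[str], target_set: Iterable[str],
                   universe: Iterable[str]) -> tuple[int, float]:
    """Over-representation of ``target_set`` in ``query`` within ``universe``.

    Returns ``(overlap, p)`` where p is the hypergeometric upper tail
    P(X >= overlap) with population = universe, successes = target_set,
    draws = query (the one-sided Fisher exact test).
    """
    query, target_set, universe = frozenset(query), frozenset(target_set), frozenset(universe)
    if not universe:
        raise ContractError("empty universe")
    stray = query - universe
    if stray:
        raise ContractError(f"query ids outside universe: {sorted(stray)[:10]}")
    stray = target_set - universe
    if stray:
        raise ContractError(f"target ids outside universe: {sorted(stray)[:10]}")
    overlap = len(query & target_set)
    p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(target_set), len(query)))
    return overlap, min(p, 1.0)


@dataclass
class TFScoreMatrix:
    """TFs x cell lines regulation scores (-log10 e-value, floored at 0)."""

    scores: pd.DataFrame
    n_tested: Mapping[str, int] = field(default_factory=dict)
    never_significant: frozenset[str] = frozenset()

    @property
    def significant_somewhere(self) -> frozenset[str]:
        """TFs with a positive score in at least one cell line."""
        return frozenset(self.scores.index) - self.never_significant


def tf_scores(catalogue: RegulationCatalogue,
              regulated_lists: Mapping[str, Iterable[str]],
              universe: Iterable[str],
              multiplier: str = "per_query") -> TFScoreMatrix:
    """Score every TF in every cell line by target-set enrichment.

    ``regulated_lists`` maps cell line -> regulated gene set (the output
    of :func:`differential_genes`). Catalogue targets outside ``universe``
    are dropped (logged); TFs left with no in-universe target are not
    tested. The e-value multiplier is the number of TFs actually tested
    (``per_query``, the default) or the full catalogue TF count
    (``catalogue``).
    """
    if multiplier not in ("per_query", "catalogue"):
        raise ContractError(f"unknown multiplier mode {multiplier!r}")
    universe = frozenset(universe)
    testable: dict[str, frozenset[str]] = {}
    n_dropped = 0
    for tf in sorted(catalogue.tfs):
        inside = catalogue.targets_of(tf) & universe
        n_dropped += len(catalogue.targets_of(tf)) - len(inside)
        if inside:
            testable[tf] = inside
    if n_dropped:
        log.info("tf_scores: dropped %d catalogue targets outside the universe", n_dropped)
    if not testable:
        raise ContractError("no catalogue TF has a target inside the universe")

    m = len(testable) if multiplier == "per_query" else len(catalogue.tfs)
    lines = list(regulated_lists)
    mat = np.zeros((len(testable), len(lines)))
    tf_ids = list(testable)
    for j, line in enumerate(lines):
        query = frozenset(regulated_lists[line]) & universe
        if not query:
            log.info("tf_scores: empty regulated list for line %s; all scores 0", line)
            continue
        for i, tf in enumerate(tf_ids):
            k = len(query & testable[tf])
            p = float(stats.hypergeom.sf(k - 1, len(universe), len(testable[tf]), len(query)))
            e = max(p, _P_FLOOR) * m
            mat[i, j] = max(0.0, -math.log10(e))
    scores = pd.DataFrame(mat, index=tf_ids, columns=lines)
    never = frozenset(scores.index[(scores <= 0).all(axis=1)])
    if never:
        log.info("tf_scores: %d TFs never significant in any line", len(never))
    return TFScoreMatrix(scores=scores, n_tested={line: m for line in lines},
                         never_significant=never)
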