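"""Tertile Kaplan-Meier survival screening.

Per gene and per cohort, the standardized expression vector is split at
its empirical tertiles into low / mid / high groups, three Kaplan-Meier
curves are fitted, and the groups are compared with a k-group log-rank
test. A gene is survival-associated when the log-rank p-value is <= 0.05
in at least one cohort; no cross-cohort multiplicity correction is
applied, so the screen's per-gene pass rate under the null grows with
the number of cohorts (documented, quantified in the tests).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .biomarker import iqr
from .errors import PreconditionError
from .matrices import ExpressionMatrix

log = logging.getLogger(__name__)

TERTILE_LABELS = ("low", "mid", "high")


def tertile_groups(values: Sequence[float]) -> np.ndarray:
    """Rank-based tertile labels ('low'|'mid'|'high') per patient.

    Split points are the 1/3 and 2/3 empirical quantiles (linear
    interpolation); ties on a boundary go to the lower group, so with
    distinct values group sizes differ by at most one.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise PreconditionError(f"tertile split needs >= 3 patients, got {len(values)}")
    q1, q2 = np.quantile(values, [1 / 3, 2 / 3])
    labels = np.where(values <= q1, "low", np.where(values <= q2, "mid", "high"))
    return labels


@dataclass
class KMCurve:
    """Product-limit survival estimate as a right-continuous step function."""

    times: np.ndarray      # event times where the curve steps
    survival: np.ndarray   # S(t) just after each step

    def at(self, t: float) -> float:
        """S(t); S(0) = 1 and the curve is flat between event times."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_curve(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Kaplan-Meier product-limit estimator with right censoring."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise PreconditionError("empty group: no curve")
    if (times <= 0).any():
        raise PreconditionError("times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    t = sf.index.to_numpy(dtype=float)
    s = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = t > 0
    return KMCurve(times=t[keep], survival=s[keep])


def logrank_test(groups: Sequence[tuple[Sequence[float], Sequence[int]]]
                 ) -> tuple[float, float]:
    """k-group log-rank test; returns (chi-square statistic, p).

    Empty groups are dropped (logged); with every event unobserved the
    curves are indistinguishable and (0.0, 1.0) is returned.
    """
    groups = [(np.asarray(t, dtype=float), np.asarray(e, dtype=int))
              for t, e in groups if len(t) > 0]
    if len(groups) < 2:
        raise PreconditionError("log-rank needs >= 2 non-empty groups")
    times = np.concatenate([t for t, _ in groups])
    events = np.concatenate([e for _, e in groups])
    labels = np.concatenate([np.full(len(t), i) for i, (t, _) in enumerate(groups)])
    if events.sum() == 0:
        return 0.0, 1.0
    res = multivariate_logrank_test(times, labels, events)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class SurvivalScreenResult:
    pvalues: pd.DataFrame               # genes x cohorts log-rank p (NaN = untestable)
    significant_in: dict[str, frozenset[str]]  # gene -> cohorts with p <= alpha
    passing: frozenset[str]             # genes significant in >= 1 cohort


def survival_screen(genes: Iterable[str],
                    cohorts: Sequence[tuple[str, ExpressionMatrix, pd.DataFrame]],
                    alpha: float = 0.05) -> SurvivalScreenResult:
    """Screen genes for tertile survival association across cohorts.

    ``cohorts`` is a list of (label, expression, clinical) triples; the
    clinical table is indexed by patient with ``time`` and ``event``
    columns. Per gene and cohort the expression vector over the shared
    patients is standardized (median/IQR), tertiled, and the resulting
    groups compared with a log-rank test. Genes constant in a cohort are
    untestable there (NaN); cohorts sharing no patients with the
    expression matrix are skipped with a warning.
    """
    genes = [g for g in genes]
    usable: list[tuple[str, pd.DataFrame, pd.DataFrame]] = []
    for label, expr, clinical in cohorts:
        shared = [p for p in expr.values.columns if p in clinical.index]
        if not shared:
            log.warning("survival_screen: cohort %s shares no patients; skipped", label)
            continue
        usable.append((label, expr.values[shared], clinical.loc[shared]))
    pvals = pd.DataFrame(np.nan, index=pd.Index(genes, name="gene"),
                         columns=[label for label, _, _ in usable])
    for label, vals, clin in usable:
        t = clin["time"].to_numpy(dtype=float)
        e = clin["event"].to_numpy(dtype=int)
        for gene in genes:
            if gene not in vals.index:
                continue
            x = vals.loc[gene].to_numpy(dtype=float)
            spread = iqr(x)
            if spread == 0:
                log.info("survival_screen: %s constant in cohort %s; untestable", gene, label)
                continue
            z = (x - np.median(x)) / spread
            labels = tertile_groups(z)
            grp = [(t[labels == g], e[labels == g]) for g in TERTILE_LABELS]
            grp = [g for g in grp if len(g[0]) > 0]
            if len(grp) < 2:
                log.info("survival_screen: %s yields < 2 tertile groups in %s", gene, label)
                continue
            _, p = logrank_test(grp)
            pvals.loc[gene, label] = p
    sig = {g: frozenset(pvals.columns[pvals.loc[g] <= alpha]) for g in genes}
    passing = frozenset(g for g, s in sig.items() if s)
    return SurvivalScreenResult(pvalues=pvals, significant_in=sig, passing=passing)
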