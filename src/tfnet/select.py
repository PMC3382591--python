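"""Correlation-profile regression for selecting correlatively regulated TFs.

For each TF we build three profile vectors — its Pearson correlations
with every other TF computed within the regulation-score matrix (R), the
expression matrix (E) and the CNV matrix (C) — and fit, by ordinary least
squares,

    R = b0 + b1*E + b2*C

across the other TFs. A TF whose expression and copy-number co-variation
jointly explain its inferred regulation shows significant b1 AND b2
(two-sided t-tests, both p <= alpha); these TFs are called correlatively
regulated. No multiplicity correction is applied across TFs by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import PreconditionError, UnknownIdentifierError

log = logging.getLogger(__name__)


@dataclass
class TFCorrProfiles:
    """Three symmetric TF x TF Pearson correlation matrices (R, E, C).

    Entries are NaN where either row had zero variance; the diagonal is
    1 by construction and is excluded from every regression.
    """

    R: pd.DataFrame
    E: pd.DataFrame
    C: pd.DataFrame
    zero_variance: Mapping[str, frozenset[str]] = None

    @property
    def roster(self) -> list[str]:
        return list(self.R.index)


@dataclass
class RegressionFit:
    tf: str
    b0: float = np.nan
    b1: float = np.nan
    b2: float = np.nan
    se1: float = np.nan
    se2: float = np.nan
    p1: float = np.nan
    p2: float = np.nan
    n_points: int = 0
    status: str = "degenerate"

    def slope_ci(self, which: int = 1, level: float = 0.95) -> tuple[float, float]:
        """Two-sided t confidence interval for slope 1 (E) or 2 (C)."""
        from scipy import stats as _st
        b = self.b1 if which == 1 else self.b2
        se = self.se1 if which == 1 else self.se2
        tcrit = float(_st.t.ppf(0.5 + level / 2, self.n_points - 3))
        return b - tcrit * se, b + tcrit * se


def _corr_matrix(df: pd.DataFrame) -> tuple[pd.DataFrame, frozenset[str]]:
    vals = df.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    flat = frozenset(df.index[sd == 0])
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(vals)
    corr[np.array([r in flat for r in df.index]), :] = np.nan
    corr[:, np.array([r in flat for r in df.index])] = np.nan
    return pd.DataFrame(corr, index=df.index, columns=df.index), flat


def correlation_profiles(scores: pd.DataFrame, expr: pd.DataFrame,
                         cnv: pd.DataFrame, roster: Iterable[str]) -> TFCorrProfiles:
    """Pairwise Pearson correlations of TF rows within each matrix.

    All three inputs are TFs x cell-lines; they are restricted to
    ``roster`` (TFs significantly regulated in at least one line) and to
    their shared cell-line columns. Zero-variance rows yield NaN
    correlations and the TF is flagged.
    """
    roster = [tf for tf in roster]
    for name, df in (("scores", scores), ("expression", expr), ("cnv", cnv)):
        missing = set(roster) - set(df.index)
        if missing:
            raise UnknownIdentifierError(
                f"roster TFs absent from {name} matrix: {sorted(missing)[:5]}")
    shared = [c for c in scores.columns if c in set(expr.columns) & set(cnv.columns)]
    if len(shared) < 3:
        raise PreconditionError(
            f"only {len(shared)} shared cell lines; need >= 3 for correlations")
    flags = {}
    mats = {}
    for key, df in (("R", scores), ("E", expr), ("C", cnv)):
        corr, flat = _corr_matrix(df.loc[roster, shared])
        mats[key] = corr
        flags[key] = flat
        if flat:
            log.info("correlation_profiles: %d zero-variance rows in %s", len(flat), key)
    return TFCorrProfiles(R=mats["R"], E=mats["E"], C=mats["C"], zero_variance=flags)


def fit_tf_model(profiles: TFCorrProfiles, tf: str) -> RegressionFit:
    """OLS of one TF's R-profile on its E- and C-profiles.

    The self-correlation entry is removed and any other TF with a missing
    value in R, E or C is dropped pairwise. Fits with fewer than 4 points,
    a rank-deficient design, or a constant response are returned with
    status ``degenerate`` (never silently dropped).
    """
    if tf not in profiles.R.index:
        raise UnknownIdentifierError(f"TF {tf!r} not in profiles")
    others = [t for t in profiles.roster if t != tf]
    r = profiles.R.loc[tf, others].to_numpy(dtype=float)
    e = profiles.E.loc[tf, others].to_numpy(dtype=float)
    c = profiles.C.loc[tf, others].to_numpy(dtype=float)
    keep = np.isfinite(r) & np.isfinite(e) & np.isfinite(c)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.debug("fit_tf_model(%s): dropped %d incomplete profile points", tf, n_dropped)
    r, e, c = r[keep], e[keep], c[keep]
    n = len(r)
    if n < 4:
        return RegressionFit(tf=tf, n_points=n)
    X = sm.add_constant(np.column_stack([e, c]), has_constant="add")
    if np.linalg.matrix_rank(X) < 3 or np.ptp(r) == 0:
        return RegressionFit(tf=tf, n_points=n)
    res = sm.OLS(r, X).fit()
    return RegressionFit(tf=tf, b0=float(res.params[0]), b1=float(res.params[1]),
                         b2=float(res.params[2]), se1=float(res.bse[1]),
                         se2=float(res.bse[2]), p1=float(res.pvalues[1]),
                         p2=float(res.pvalues[2]), n_points=n, status="ok")


def fit_all(profiles: TFCorrProfiles) -> list[RegressionFit]:
    return [fit_tf_model(profiles, tf) for tf in profiles.roster]


def select_tfs(fits: Iterable[RegressionFit], alpha: float = 0.05,
               correct: Optional[str] = None) -> frozenset[str]:
    """TFs with status ok and both slope p-values <= ``alpha`` (inclusive).

    ``correct='fdr_bh'`` optionally applies Benjamini-Hochberg across TFs
    to each slope's p-values before thresholding; the default applies the
    raw threshold twice, with no multiplicity correction.
    """
    fits = list(fits)
    ok = [f for f in fits if f.status == "ok"]
    if correct is None:
        return frozenset(f.tf for f in ok if f.p1 <= alpha and f.p2 <= alpha)
    from statsmodels.stats.multitest import multipletests
    if not ok:
        return frozenset()
    q1 = multipletests([f.p1 for f in ok], method=correct)[1]
    q2 = multipletests([f.p2 for f in ok], method=correct)[1]
    return frozenset(f.tf for f, a, b in zip(ok, q1, q2) if a <= alpha and b <= alpha)


def fits_table(fits: Iterable[RegressionFit]) -> pd.DataFrame:
    """TSV-ready table: tf, b0, b1, b2, p1, p2, n, status."""
    return pd.DataFrame(
        [(f.tf, f.b0, f.b1, f.b2, f.se1, f.se2, f.p1, f.p2, f.n_points, f.status)
         for f in fits],
        columns=["tf", "b0", "b1", "b2", "se1", "se2", "p1", "p2", "n", "status"],
    )
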