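"""ROC biomarker evaluation, age correlation, and confounder adjustment.

The biomarker question: can a per-case epithelial summary (for example the
mean number of cells within secretory cell expansions) separate fallopian
tubes bearing a STIC lesion from Benign and NoSTIC tubes pooled together?

* :func:`roc_analysis` builds the empirical ROC over all observed
  thresholds, computes the AUC through the rank (Mann-Whitney)
  formulation with ties counted one half, a 95% CI by DeLong's method
  (seeded bootstrap available), and the operating cutoff that maximizes
  Youden's J = sensitivity + specificity - 1 (ties broken toward higher
  specificity, i.e. the larger cutoff).
* :func:`spearman_corr` is the tie-aware Spearman rank correlation, with
  an exact permutation p-value for n <= 9 and the t approximation
  otherwise.
* :func:`adjusted_regression` fits an ordinary least squares model of the
  log-transformed outcome on a group indicator plus clinical confounders
  (age, menopausal status, BRCA status, prior chemotherapy).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ROCCurve",
    "RegressionFit",
    "roc_analysis",
    "auc_mann_whitney",
    "delong_ci",
    "spearman_corr",
    "adjusted_regression",
]


@dataclass(frozen=True)
class ROCCurve:
    """Empirical ROC sweep with AUC, CI and Youden-optimal cutoff.

    The positive call at threshold ``t`` is ``value >= t``; by convention
    high biomarker values indicate the positive class (STIC).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    ci95: Tuple[float, float]
    optimal_cutoff: Optional[float]
    sens_at_cutoff: Optional[float]
    spec_at_cutoff: Optional[float]
    n_pos: int
    n_neg: int
    positive_class: str = "STIC"


@dataclass(frozen=True)
class RegressionFit:
    """OLS coefficient table for the confounder-adjusted model."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    log_outcome: bool
    zero_offset: float  # half the smallest positive outcome, 0 if unused
    n_obs: int

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
            }
        )


def auc_mann_whitney(values: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the probability a positive outranks a negative, ties count 1/2."""
    pos = values[labels == 1]
    neg = values[labels == 0]
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def _delong_components(values: np.ndarray, labels: np.ndarray):
    pos = values[labels == 1]
    neg = values[labels == 0]
    # placement values: for each positive, fraction of negatives it beats
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / len(neg) for p in pos])
    v01 = np.array([(np.sum(pos > n) + 0.5 * np.sum(pos == n)) / len(pos) for n in neg])
    return v10, v01


def delong_ci(values: np.ndarray, labels: np.ndarray, level: float = 0.95) -> Tuple[float, float]:
    """DeLong variance-based Wald CI for the AUC, clipped to [0, 1]."""
    auc = auc_mann_whitney(values, labels)
    v10, v01 = _delong_components(values, labels)
    var = 0.0
    if len(v10) > 1:
        var += np.var(v10, ddof=1) / len(v10)
    if len(v01) > 1:
        var += np.var(v01, ddof=1) / len(v01)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(var)
    return (max(0.0, auc - half), min(1.0, auc + half))


def bootstrap_ci(
    values: np.ndarray,
    labels: np.ndarray,
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
) -> Tuple[float, float]:
    """Stratified percentile bootstrap CI for the AUC (seeded)."""
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        pi = rng.choice(pos_idx, size=len(pos_idx), replace=True)
        ni = rng.choice(neg_idx, size=len(neg_idx), replace=True)
        idx = np.concatenate([pi, ni])
        aucs[b] = auc_mann_whitney(values[idx], labels[idx])
    lo, hi = np.quantile(aucs, [0.5 - level / 2.0, 0.5 + level / 2.0])
    return float(lo), float(hi)


def roc_analysis(
    values: Sequence[float],
    labels: Sequence[int],
    positive_class: str = "STIC",
    ci_method: str = "delong",
    seed: int = 0,
) -> ROCCurve:
    """Empirical ROC analysis of one per-case biomarker.

    Missing values are dropped pairwise.  Candidate thresholds are the
    sorted unique observed values plus a sentinel above the maximum, so
    the sweep covers "call everything positive" through "call nothing
    positive".  When every value is tied the AUC is 0.5 and no cutoff is
    defined.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=float)
    keep = np.isfinite(v) & np.isfinite(y)
    v, y = v[keep], y[keep].astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC analysis requires both classes to be non-empty")

    uniq = np.unique(v)
    thresholds = np.concatenate([uniq, [uniq[-1] + 1.0]])
    # positive call: value >= threshold
    sens = np.array([(v[y == 1] >= t).mean() for t in thresholds])
    spec = np.array([(v[y == 0] < t).mean() for t in thresholds])

    auc = auc_mann_whitney(v, y)
    if ci_method == "delong":
        ci = delong_ci(v, y)
    elif ci_method == "bootstrap":
        ci = bootstrap_ci(v, y, seed=seed)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    if uniq.size == 1:
        cutoff = s_at = p_at = None
    else:
        j = sens + spec - 1.0
        # tie toward higher specificity = larger threshold: scan from the top
        best = len(j) - 1 - int(np.argmax(j[::-1]))
        cutoff = float(thresholds[best])
        s_at = float(sens[best])
        p_at = float(spec[best])

    return ROCCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        ci95=ci,
        optimal_cutoff=cutoff,
        sens_at_cutoff=s_at,
        spec_at_cutoff=p_at,
        n_pos=n_pos,
        n_neg=n_neg,
        positive_class=positive_class,
    )


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Tie-aware Spearman correlation with p-value.

    rho is the Pearson correlation of mid-ranks.  For n <= 9 the p-value
    is exact, from the full permutation distribution of the rank pairing;
    otherwise the usual t approximation is used.  Zero rank variance in
    either variable makes the correlation undefined (returns NaN, NaN
    with a warning).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    keep = np.isfinite(xa) & np.isfinite(ya)
    xa, ya = xa[keep], ya[keep]
    n = len(xa)
    if n < 3:
        raise ValueError("Spearman correlation requires n >= 3 complete pairs")
    rx = stats.rankdata(xa)
    ry = stats.rankdata(ya)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        warnings.warn("zero rank variance: Spearman correlation undefined", stacklevel=2)
        return math.nan, math.nan
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 9:
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = math.sqrt((rx_c**2).sum() * (ry_c**2).sum())
        obs = abs(rx_c @ ry_c)
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            s = abs(rx_c @ ry_c[list(perm)])
            count += s >= obs - 1e-12
            total += 1
        return rho, count / total
    t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho**2))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return rho, float(min(1.0, p))


def adjusted_regression(
    outcome: Sequence[float],
    covariates: pd.DataFrame,
    log_transform: bool = True,
) -> RegressionFit:
    """OLS of the (log-transformed) outcome on group and clinical confounders.

    Categorical covariates are expanded to indicator columns (first level
    dropped).  Zero outcomes cannot be log-transformed; half the smallest
    positive observed value is added as an offset, and the fit is flagged
    through ``zero_offset``.  A rank-deficient design raises an error
    naming the collinear columns.
    """
    y = np.asarray(outcome, dtype=float)
    x = pd.get_dummies(covariates, drop_first=True, dtype=float)
    keep = np.isfinite(y) & np.isfinite(x.to_numpy()).all(axis=1)
    y, x = y[keep], x.loc[keep]

    offset = 0.0
    if log_transform:
        if np.any(y < 0):
            raise ValueError("outcome must be non-negative for the log transform")
        if np.any(y == 0):
            positive = y[y > 0]
            if positive.size == 0:
                raise ValueError("all outcomes are zero; log transform undefined")
            offset = float(positive.min() / 2.0)
        y = np.log(y + offset)

    design = sm.add_constant(x)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # identify columns that do not increase the rank
        bad = []
        cols = []
        for c in design.columns:
            cols.append(c)
            if np.linalg.matrix_rank(design[cols].to_numpy()) < len(cols):
                bad.append(c)
                cols.pop()
        raise ValueError(f"design matrix rank deficient; collinear columns: {bad}")
    if len(y) <= design.shape[1]:
        raise ValueError("need more observations than parameters")

    fit = sm.OLS(y, design).fit()
    return RegressionFit(
        params=fit.params,
        bse=fit.bse,
        tvalues=fit.tvalues,
        pvalues=fit.pvalues,
        log_outcome=log_transform,
        zero_offset=offset,
        n_obs=int(fit.nobs),
    )
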