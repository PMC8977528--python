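"""Case-level aggregation and the four-group differential-feature screen.

Per-tile feature vectors are aggregated to one median vector per case per
group, z-scored across rows, screened feature-by-feature with one-way
ANOVA at a Bonferroni-corrected threshold (family alpha divided by the
number of features), and followed up with Tukey-Kramer pairwise
comparisons between the four stromal groups.  A 2-D UMAP embedding of the
z-scored matrix visualizes the global structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .texture import FeatureVector

__all__ = [
    "CohortMatrix",
    "ScreenResult",
    "aggregate_case_medians",
    "zscore_features",
    "anova_screen",
    "tukey_kramer_pairs",
    "embed_umap",
]


@dataclass
class CohortMatrix:
    """Rows are case-by-group median feature profiles; columns are features."""

    values: np.ndarray  # (n_rows, n_features)
    feature_names: Tuple[str, ...]
    case_ids: Tuple[str, ...]
    groups: Tuple[str, ...]
    constant_features: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n, p = self.values.shape
        if not (len(self.case_ids) == len(self.groups) == n):
            raise ValueError("row metadata length mismatch")
        if len(self.feature_names) != p:
            raise ValueError("feature name length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cohort matrix must have no missing values")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.feature_names))
        df.insert(0, "group", self.groups)
        df.insert(0, "case_id", self.case_ids)
        return df


@dataclass
class ScreenResult:
    """Per-feature ANOVA statistics and the Bonferroni-significant set."""

    f_stat: np.ndarray
    p_value: np.ndarray
    bonferroni_alpha: float
    significant: Tuple[str, ...]
    feature_names: Tuple[str, ...]
    groups_used: Tuple[str, ...]
    pairwise_counts: Dict[Tuple[str, str], int] = field(default_factory=dict)


def aggregate_case_medians(features: Iterable[FeatureVector]) -> CohortMatrix:
    """Median feature vector per case-group combination.

    Each case contributes one row per group present in that case; tile
    order is irrelevant.  Case-group combinations with no tiles are simply
    absent (there is nothing to aggregate).
    """
    features = list(features)
    if not features:
        raise ValueError("no feature vectors to aggregate")
    names = features[0].names
    rows = {}
    for fv in features:
        if fv.names != names:
            raise ValueError("inconsistent feature names across tiles")
        rows.setdefault((fv.case_id, fv.group), []).append(fv.values)
    keys = sorted(rows)
    values = np.vstack([np.median(np.vstack(rows[k]), axis=0) for k in keys])
    return CohortMatrix(
        values=values,
        feature_names=names,
        case_ids=tuple(k[0] for k in keys),
        groups=tuple(k[1] for k in keys),
    )


def zscore_features(m: CohortMatrix) -> CohortMatrix:
    """Standardize each feature column to mean 0, sample SD 1.

    Columns with zero spread cannot be standardized; they are set to zero
    and recorded in ``constant_features``.
    """
    if m.values.shape[0] < 2:
        raise ValueError("z-scoring requires at least 2 rows")
    mean = m.values.mean(axis=0)
    sd = m.values.std(axis=0, ddof=1)
    flagged = sd == 0
    out = np.zeros_like(m.values, dtype=float)
    np.divide(m.values - mean, sd, out=out, where=~flagged)
    constant = tuple(np.array(m.feature_names)[flagged])
    if constant:
        warnings.warn(f"{len(constant)} constant feature(s) set to zero", stacklevel=2)
    return CohortMatrix(
        values=out,
        feature_names=m.feature_names,
        case_ids=m.case_ids,
        groups=m.groups,
        constant_features=constant,
    )


def _group_arrays(m: CohortMatrix) -> Dict[str, np.ndarray]:
    groups: Dict[str, np.ndarray] = {}
    garr = np.asarray(m.groups)
    for g in sorted(set(m.groups)):
        sub = m.values[garr == g]
        if sub.shape[0] < 2:
            warnings.warn(f"group {g!r} has <2 rows; excluded from screen", stacklevel=3)
            continue
        groups[g] = sub
    return groups


def anova_screen(m: CohortMatrix, family_alpha: float = 0.05) -> ScreenResult:
    """One-way ANOVA per feature with a Bonferroni-corrected threshold.

    The per-feature threshold is ``family_alpha / n_features`` (0.05/1114
    = 4.488e-5 for the full panel).  Groups with fewer than 2 rows are
    excluded with a warning.  F statistics are computed for all features
    at once.
    """
    groups = _group_arrays(m)
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups with >= 2 rows")
    arrays = list(groups.values())
    k = len(arrays)
    ns = np.array([a.shape[0] for a in arrays])
    n_tot = ns.sum()
    grand = np.vstack(arrays).mean(axis=0)
    means = np.stack([a.mean(axis=0) for a in arrays])
    ss_between = (ns[:, None] * (means - grand) ** 2).sum(axis=0)
    ss_within = np.stack(
        [((a - mu) ** 2).sum(axis=0) for a, mu in zip(arrays, means)]
    ).sum(axis=0)
    df_b, df_w = k - 1, n_tot - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_b) / (ss_within / df_w)
    f = np.where(np.isfinite(f), f, 0.0)
    p = stats.f.sf(f, df_b, df_w)
    alpha = family_alpha / m.values.shape[1]
    sig_mask = p < alpha
    return ScreenResult(
        f_stat=f,
        p_value=p,
        bonferroni_alpha=alpha,
        significant=tuple(np.array(m.feature_names)[sig_mask]),
        feature_names=m.feature_names,
        groups_used=tuple(groups),
    )


def tukey_kramer_p(
    mean_i: float, mean_j: float, n_i: int, n_j: int, mse: float, k: int, df: int
) -> float:
    """Tukey-Kramer adjusted p for one pairwise comparison.

    The studentized-range statistic uses the Kramer adjustment for unequal
    group sizes: ``q = |m_i - m_j| / sqrt(mse/2 * (1/n_i + 1/n_j))``.
    """
    if mse <= 0:
        return 1.0 if mean_i == mean_j else 0.0
    q = abs(mean_i - mean_j) / np.sqrt(mse / 2.0 * (1.0 / n_i + 1.0 / n_j))
    return float(stats.studentized_range.sf(q, k, df))


def tukey_kramer_pairs(
    m: CohortMatrix,
    screen: ScreenResult,
    pair_alpha: Optional[float] = None,
    features: Optional[Sequence[str]] = None,
) -> Dict[Tuple[str, str], int]:
    """Count screen-significant features that separate each group pair.

    For each of the unordered group pairs, counts features whose
    Tukey-Kramer adjusted p falls below ``pair_alpha``.  The default
    threshold is ``0.05 / |significant set|`` — an interpretation of the
    post-hoc cut applied after the ANOVA screen; configurable.
    """
    if features is None:
        features = screen.significant
    if pair_alpha is None:
        pair_alpha = 0.05 / max(len(features), 1)
    groups = _group_arrays(m)
    name_idx = {n: i for i, n in enumerate(m.feature_names)}
    idx = [name_idx[f] for f in features]
    arrays = {g: a[:, idx] for g, a in groups.items()}
    k = len(arrays)
    df = sum(a.shape[0] for a in arrays.values()) - k
    means = {g: a.mean(axis=0) for g, a in arrays.items()}
    sse = sum(((a - means[g]) ** 2).sum(axis=0) for g, a in arrays.items())
    mse = sse / df if df > 0 else np.zeros(len(idx))
    counts: Dict[Tuple[str, str], int] = {}
    for gi, gj in combinations(sorted(arrays), 2):
        ni, nj = arrays[gi].shape[0], arrays[gj].shape[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            denom = np.sqrt(mse / 2.0 * (1.0 / ni + 1.0 / nj))
            q = np.abs(means[gi] - means[gj]) / denom
        q = np.where(np.isfinite(q), q, 0.0)
        p = stats.studentized_range.sf(q, k, df)
        counts[(gi, gj)] = int((p < pair_alpha).sum())
    screen.pairwise_counts = counts
    return counts


def embed_umap(
    m: CohortMatrix, seed: int = 0, n_neighbors: int = 15, min_dist: float = 0.1
) -> np.ndarray:
    """2-D UMAP embedding of the cohort rows, deterministic given the seed.

    ``n_neighbors`` is reduced (with a warning) when the cohort has fewer
    rows than requested neighbors.
    """
    import umap  # deferred: heavy import

    n = m.values.shape[0]
    if n < 4:
        raise ValueError("UMAP embedding needs at least 4 rows")
    if n_neighbors >= n:
        warnings.warn(f"n_neighbors reduced from {n_neighbors} to {n - 1}", stacklevel=2)
        n_neighbors = n - 1
    reducer = umap.UMAP(
        n_components=2, n_neighbors=n_neighbors, min_dist=min_dist, random_state=seed
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = reducer.fit_transform(m.values)
    return np.asarray(coords)
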