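"""Epithelial run-length topology: secretory and ciliated cell expansions.

A slide's epithelium is recorded as ordered sequences of cell-type labels
(secretory or ciliated) along monolayer regions of interest (ROIs).  A
secretory cell expansion (SCE) is a maximal contiguous run of more than
10 secretory cells uninterrupted by a ciliated cell; a ciliated cell
expansion (CCE) is the ciliated counterpart.  Two reuse thresholds are
exposed: 12 (the p53-signature length convention) and 30 (SCOUT).

Per-slide summaries pool all ROIs: the relative number of SCE/CCE is the
expansion count divided by the total number of epithelial cells in all
ROIs, and the mean expansion size averages the lengths of qualifying runs
(undefined — reported as missing, never zero — when there are none).

Runs never span ROI boundaries; ROIs are separate selections on the
slide.  Runs touching an ROI end are counted in full, although the true
run may extend beyond the selection (an acknowledged truncation bias).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import groupby
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SECRETORY",
    "CILIATED",
    "SCE_THRESHOLD",
    "P53_SIGNATURE_THRESHOLD",
    "SCOUT_THRESHOLD",
    "ROISequence",
    "SlideEpithelium",
    "Run",
    "ExpansionSummary",
    "find_runs",
    "call_expansions",
    "summarize_slide",
    "summaries_frame",
    "group_compare",
    "read_cells_csv",
]

SECRETORY = "secretory"
CILIATED = "ciliated"
_VALID_LABELS = frozenset({SECRETORY, CILIATED})

SCE_THRESHOLD = 10  # expansions: runs of > 10 cells
P53_SIGNATURE_THRESHOLD = 12  # p53 signature length convention: > 12 cells
SCOUT_THRESHOLD = 30  # secretory cell outgrowth: > 30 cells


@dataclass(frozen=True)
class ROISequence:
    """Ordered cell-type labels along one epithelial monolayer ROI."""

    roi_id: str
    labels: Tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError(f"ROI {self.roi_id!r} is empty")
        bad = set(self.labels) - _VALID_LABELS
        if bad:
            raise ValueError(f"ROI {self.roi_id!r} has invalid labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class SlideEpithelium:
    """All ROIs of one slide plus clinical covariates.

    Cells inside STIC lesions are excluded upstream by the annotation
    protocol; the sequences here contain ordinary epithelium only.
    """

    case_id: str
    region: str
    group: str
    rois: Tuple[ROISequence, ...]
    age: Optional[float] = None
    menopausal: Optional[bool] = None
    brca: Optional[bool] = None
    chemotherapy: Optional[bool] = None

    def __post_init__(self) -> None:
        if not self.rois:
            raise ValueError("slide must have at least one ROI")


@dataclass(frozen=True)
class Run:
    """One maximal homogeneous run of cells within an ROI."""

    cell_type: str
    length: int
    roi_id: str
    start: int


@dataclass(frozen=True)
class ExpansionSummary:
    """Per-slide SCE/CCE counts, relative numbers and mean expansion sizes."""

    case_id: str
    region: str
    group: str
    total_cells: int
    n_sce: int
    n_cce: int
    relative_sce: float
    relative_cce: float
    mean_cells_in_sce: Optional[float]  # None when n_sce == 0
    mean_cells_in_cce: Optional[float]


def find_runs(s: ROISequence) -> List[Run]:
    """Maximal homogeneous runs of ``s`` in order; lengths sum to len(s)."""
    runs = []
    pos = 0
    for label, grp in groupby(s.labels):
        n = sum(1 for _ in grp)
        runs.append(Run(cell_type=label, length=n, roi_id=s.roi_id, start=pos))
        pos += n
    return runs


def call_expansions(
    runs: Iterable[Run], threshold: int = SCE_THRESHOLD, cell_type: str = SECRETORY
) -> List[Run]:
    """Runs of ``cell_type`` strictly longer than ``threshold`` cells.

    The expansion definition is a strict inequality: a run of exactly
    ``threshold`` cells does not qualify.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    return [r for r in runs if r.cell_type == cell_type and r.length > threshold]


def summarize_slide(e: SlideEpithelium, threshold: int = SCE_THRESHOLD) -> ExpansionSummary:
    """Pool runs over all ROIs of a slide into an expansion summary."""
    runs: List[Run] = []
    total = 0
    for roi in e.rois:
        runs.extend(find_runs(roi))
        total += len(roi)
    sce = call_expansions(runs, threshold, SECRETORY)
    cce = call_expansions(runs, threshold, CILIATED)
    return ExpansionSummary(
        case_id=e.case_id,
        region=e.region,
        group=e.group,
        total_cells=total,
        n_sce=len(sce),
        n_cce=len(cce),
        relative_sce=len(sce) / total,
        relative_cce=len(cce) / total,
        mean_cells_in_sce=float(np.mean([r.length for r in sce])) if sce else None,
        mean_cells_in_cce=float(np.mean([r.length for r in cce])) if cce else None,
    )


def summaries_frame(summaries: Iterable[ExpansionSummary]) -> pd.DataFrame:
    """Tabulate summaries, with missing means as NaN (never zero)."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "case_id": s.case_id,
                "region": s.region,
                "group": s.group,
                "total_cells": s.total_cells,
                "n_sce": s.n_sce,
                "n_cce": s.n_cce,
                "relative_sce": s.relative_sce,
                "relative_cce": s.relative_cce,
                "mean_cells_in_sce": math.nan if s.mean_cells_in_sce is None else s.mean_cells_in_sce,
                "mean_cells_in_cce": math.nan if s.mean_cells_in_cce is None else s.mean_cells_in_cce,
            }
        )
    return pd.DataFrame(rows)


def group_compare(
    groups: Dict[str, Sequence[float]],
    paired: bool = False,
) -> Tuple[float, float]:
    """Compare a metric across patient groups; returns (statistic, p).

    Dispatch follows the standard nonparametric toolkit: Kruskal-Wallis
    (tie-corrected) for three or more independent groups, Mann-Whitney for
    two, Wilcoxon signed-rank for two paired samples.  Missing values are
    dropped per group.  When every value is tied across groups the test is
    uninformative and (0, 1) is returned.
    """
    cleaned = {}
    for g, vals in groups.items():
        arr = np.asarray(list(vals), dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size:
            cleaned[g] = arr
    if len(cleaned) < 2:
        raise ValueError("need at least 2 groups with non-missing values")
    arrays = [cleaned[g] for g in sorted(cleaned)]
    flat = np.concatenate(arrays)
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    if paired:
        if len(arrays) != 2 or len(arrays[0]) != len(arrays[1]):
            raise ValueError("paired comparison requires two equal-length groups")
        stat, p = stats.wilcoxon(arrays[0], arrays[1])
        return float(stat), float(p)
    if len(arrays) == 2:
        stat, p = stats.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
        return float(stat), float(p)
    stat, p = stats.kruskal(*arrays)
    return float(stat), float(p)


def fisher_exact_table(table: Sequence[Sequence[int]]) -> Tuple[float, float]:
    """Fisher's exact test for a 2x2 categorical table; (odds ratio, p)."""
    odds, p = stats.fisher_exact(np.asarray(table))
    return float(odds), float(p)


def read_cells_csv(path, covariates_path=None) -> List[SlideEpithelium]:
    """Parse the exported cell table into slide objects.

    Expected columns: ``case_id, region, group, roi_id, position,
    cell_type``.  Rows whose ``cell_type`` is not secretory/ciliated are
    rejected.  Cells are ordered by ``position`` within each ROI.  An
    optional covariate table keyed by ``case_id`` supplies ``age,
    menopausal, brca, chemotherapy``.
    """
    df = pd.read_csv(path)
    required = {"case_id", "region", "group", "roi_id", "position", "cell_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cells CSV missing columns: {sorted(missing)}")
    bad = set(df["cell_type"]) - _VALID_LABELS
    if bad:
        raise ValueError(f"invalid cell_type values: {sorted(bad)}")

    cov = {}
    if covariates_path is not None:
        cdf = pd.read_csv(covariates_path).set_index("case_id")
        for cid, row in cdf.iterrows():
            cov[str(cid)] = {
                "age": row.get("age"),
                "menopausal": _to_bool(row.get("menopausal")),
                "brca": _to_bool(row.get("brca")),
                "chemotherapy": _to_bool(row.get("chemotherapy")),
            }

    slides = []
    for (cid, region, group), sub in df.groupby(["case_id", "region", "group"], sort=True):
        rois = []
        for roi_id, roi_df in sub.groupby("roi_id", sort=True):
            roi_df = roi_df.sort_values("position")
            rois.append(ROISequence(roi_id=str(roi_id), labels=tuple(roi_df["cell_type"])))
        kw = cov.get(str(cid), {})
        slides.append(
            SlideEpithelium(
                case_id=str(cid), region=str(region), group=str(group), rois=tuple(rois), **kw
            )
        )
    return slides


def _to_bool(v):
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    if isinstance(v, str):
        return v.strip().lower() in {"1", "true", "yes", "y"}
    return bool(v)
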