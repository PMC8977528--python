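"""Synthetic fallopian-tube cohorts with known ground truth.

Nothing in this package requires real slides: the generator emulates the
two data streams the pipeline consumes.

**Epithelium.**  Cell-type sequences along a monolayer are modeled as a
two-state Markov chain over {secretory, ciliated} with per-step
persistence probabilities ``p_ss`` and ``p_cc``.  Run lengths of state
``k`` are then geometric with success probability ``1 - p_kk``, which
gives closed-form ground truth: ``P(run length >= m) = p**(m-1)`` and the
mean length of runs longer than 10 cells is ``10 + 1/(1 - p)``.  Age and
STIC status act linearly on the logits of the persistence probabilities,
so older cases and STIC cases develop longer secretory runs (and fewer
ciliated ones), mirroring the direction of the observed biology.

**Stroma.**  H&E-like tiles are rendered from smooth stain-concentration
fields: Gaussian random fields synthesized by spectral filtering of
seeded white noise (an elliptical spectral envelope encodes correlation
length and anisotropy), plus elliptical hematoxylin-rich nuclear blobs
and white noise, pushed through the Beer-Lambert transform with the
package's stain matrix.  Groups differ only in texture parameters — not
gross color — so differences are invisible to the eye but measurable by
the descriptor panel, with a configurable graded effect from Benign
through NearSTIC.

Everything is bit-reproducible given (config, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .stain import Group, RGBTile, RUIFROK_HE, rgb_from_od
from .topology import CILIATED, SECRETORY, ROISequence, SlideEpithelium

__all__ = [
    "EpitheliumModel",
    "StromaModel",
    "CohortConfig",
    "simulate_epithelium",
    "recover_persistence",
    "render_concentrations",
    "render_stromal_tile",
    "simulate_cohort",
    "gaussian_random_field",
]


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


@dataclass
class EpitheliumModel:
    """Two-state Markov model of the epithelial monolayer.

    ``p_ss`` / ``p_cc`` are the persistence probabilities at the reference
    age (60 years) in a non-STIC tube.  ``beta_age_*`` act on the logit per
    decade of age above the reference; ``beta_stic_ss`` is the STIC shift
    on the secretory logit.  Defaults are calibrated so Benign slides have
    a mean SCE size below 15 cells and STIC slides above 15 — the cutoff
    neighborhood the ROC stage should rediscover on synthetic cohorts.
    """

    p_ss: float = 0.75
    p_cc: float = 0.70
    beta_age_ss: float = 0.25
    beta_age_cc: float = -0.25
    beta_stic_ss: float = 1.35
    beta_stic_cc: float = 0.0
    cells_per_roi: int = 150
    rois_per_slide: int = 12
    reference_age: float = 60.0

    def __post_init__(self) -> None:
        for name in ("p_ss", "p_cc"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {p}")

    def persistence(self, age: Optional[float], stic: bool) -> Tuple[float, float]:
        """Per-case (p_ss, p_cc) after the age and group linkage."""
        decades = 0.0 if age is None else (age - self.reference_age) / 10.0
        lss = _logit(self.p_ss) + self.beta_age_ss * decades + self.beta_stic_ss * stic
        lcc = _logit(self.p_cc) + self.beta_age_cc * decades + self.beta_stic_cc * stic
        return _expit(lss), _expit(lcc)


def simulate_epithelium(
    model: EpitheliumModel,
    case_id: str,
    group: str,
    region: str = "fimbria",
    age: Optional[float] = None,
    menopausal: Optional[bool] = None,
    brca: Optional[bool] = None,
    chemotherapy: Optional[bool] = None,
    seed: int = 0,
) -> SlideEpithelium:
    """Simulate one slide's ROI sequences from the Markov model.

    Each ROI is an independent chain whose initial state is drawn from the
    stationary distribution.  Deterministic given the seed.
    """
    p_ss, p_cc = model.persistence(age, stic=(group == "STIC"))
    rng = np.random.default_rng(seed)
    pi_s = (1.0 - p_cc) / ((1.0 - p_ss) + (1.0 - p_cc))
    rois = []
    for r in range(model.rois_per_slide):
        n = model.cells_per_roi
        u = rng.random(n)
        states = np.empty(n, dtype=bool)  # True = secretory
        states[0] = u[0] < pi_s
        for i in range(1, n):
            stay = p_ss if states[i - 1] else p_cc
            states[i] = states[i - 1] ^ (u[i] >= stay)
        labels = tuple(SECRETORY if s else CILIATED for s in states)
        rois.append(ROISequence(roi_id=f"{case_id}-roi{r:02d}", labels=labels))
    return SlideEpithelium(
        case_id=case_id,
        region=region,
        group=group,
        rois=tuple(rois),
        age=age,
        menopausal=menopausal,
        brca=brca,
        chemotherapy=chemotherapy,
    )


def recover_persistence(e: SlideEpithelium) -> Tuple[Optional[float], Optional[float]]:
    """Estimate (p_ss, p_cc) from observed run structure.

    For a geometric run-length distribution the maximum-likelihood
    persistence estimate is ``1 - (number of runs of that type) / (number
    of cells of that type)``.  A type absent from the slide yields a
    missing estimate.
    """
    from .topology import find_runs

    n_cells = {SECRETORY: 0, CILIATED: 0}
    n_runs = {SECRETORY: 0, CILIATED: 0}
    for roi in e.rois:
        for run in find_runs(roi):
            n_runs[run.cell_type] += 1
            n_cells[run.cell_type] += run.length
    out = []
    for t in (SECRETORY, CILIATED):
        out.append(1.0 - n_runs[t] / n_cells[t] if n_cells[t] else None)
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Stromal tiles
# ---------------------------------------------------------------------------


def gaussian_random_field(
    rng: np.random.Generator,
    size: int,
    corr_len: float,
    anisotropy_ratio: float = 1.0,
    anisotropy_angle: float = 0.0,
) -> np.ndarray:
    """Unit-variance Gaussian random field via spectral filtering.

    White noise is filtered in the Fourier domain with a Gaussian envelope
    whose principal axes are ``corr_len * ratio`` and ``corr_len / ratio``
    rotated by ``anisotropy_angle`` (radians).
    """
    white = rng.standard_normal((size, size))
    fx = np.fft.fftfreq(size)[:, None]
    fy = np.fft.fftfreq(size)[None, :]
    ca, sa = math.cos(anisotropy_angle), math.sin(anisotropy_angle)
    fu = fx * ca + fy * sa
    fv = -fx * sa + fy * ca
    lu = corr_len * anisotropy_ratio
    lv = corr_len / anisotropy_ratio
    envelope = np.exp(-2.0 * np.pi**2 * ((lu * fu) ** 2 + (lv * fv) ** 2))
    field_ = np.fft.ifft2(np.fft.fft2(white) * np.sqrt(envelope)).real
    sd = field_.std()
    if sd == 0:
        return np.zeros_like(field_)
    return (field_ - field_.mean()) / sd


@dataclass
class StromaModel:
    """Per-group texture parameters of the stromal tile renderer.

    ``group_corr_len`` sets the Gaussian-field correlation length (pixels)
    per stromal group; the graded Benign < NoSTIC < AwaySTIC < NearSTIC
    ordering is the generative analogue of the gradual architectural
    differences the panel is meant to detect.  ``effect_scale`` scales
    every group's deviation from the Benign baseline, so parameter
    distance between groups is monotone in it.
    """

    group_corr_len: Dict[str, float] = field(
        default_factory=lambda: {
            "Benign": 4.0,
            "NoSTIC": 5.0,
            "AwaySTIC": 6.5,
            "NearSTIC": 9.0,
        }
    )
    group_anisotropy: Dict[str, float] = field(
        default_factory=lambda: {
            "Benign": 1.0,
            "NoSTIC": 1.1,
            "AwaySTIC": 1.25,
            "NearSTIC": 1.5,
        }
    )
    effect_scale: float = 1.0
    nuclear_density: float = 2.0e-3  # nuclei per pixel
    nucleus_amplitude: float = 0.7  # OD added at a nucleus center
    hema_base: float = 0.25
    hema_spread: float = 0.10
    eosin_base: float = 0.55
    eosin_spread: float = 0.18
    noise_sd: float = 0.02
    max_od: float = 1.5
    tile_size: int = 256

    def params_for(self, group: str) -> Tuple[float, float]:
        base_cl = self.group_corr_len["Benign"]
        base_an = self.group_anisotropy["Benign"]
        cl = base_cl + self.effect_scale * (self.group_corr_len[group] - base_cl)
        an = base_an + self.effect_scale * (self.group_anisotropy[group] - base_an)
        return cl, an


def render_concentrations(
    model: StromaModel, group: str, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Ground-truth hematoxylin and eosin OD concentration fields."""
    size = model.tile_size
    cl, an = model.params_for(group)
    angle = rng.uniform(0, np.pi)
    eosin = model.eosin_base + model.eosin_spread * gaussian_random_field(
        rng, size, cl, an, angle
    )
    hema = model.hema_base + model.hema_spread * gaussian_random_field(
        rng, size, cl * 0.6, an, angle + np.pi / 2
    )

    # scatter elliptical nuclei into the hematoxylin field
    n_nuclei = rng.poisson(model.nuclear_density * size * size)
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(n_nuclei):
        cy, cx = rng.uniform(0, size, 2)
        a = rng.uniform(2.5, 5.0)
        b = rng.uniform(1.5, 3.5)
        theta = rng.uniform(0, np.pi)
        dy, dx = yy - cy, xx - cx
        u = dy * math.cos(theta) + dx * math.sin(theta)
        v = -dy * math.sin(theta) + dx * math.cos(theta)
        hema += model.nucleus_amplitude * np.exp(-0.5 * ((u / a) ** 2 + (v / b) ** 2))

    hema += model.noise_sd * rng.standard_normal((size, size))
    eosin += model.noise_sd * rng.standard_normal((size, size))
    return (
        np.clip(hema, 0.0, model.max_od),
        np.clip(eosin, 0.0, model.max_od),
    )


def tile_from_concentrations(
    hema: np.ndarray,
    eosin: np.ndarray,
    case_id: str = "synthetic",
    group: Group = Group.BENIGN,
    stain_matrix: Optional[np.ndarray] = None,
) -> RGBTile:
    """Render concentration fields to an 8-bit RGB tile via Beer-Lambert."""
    s = RUIFROK_HE if stain_matrix is None else np.asarray(stain_matrix, dtype=float)
    od = hema[..., None] * s[0] + eosin[..., None] * s[1]
    return RGBTile(rgb_from_od(od), case_id=case_id, group=group)


def render_stromal_tile(
    model: StromaModel, group: str, seed: int, case_id: str = "synthetic"
) -> RGBTile:
    """Render one H&E-like stromal tile for the given group (seeded)."""
    rng = np.random.default_rng(seed)
    hema, eosin = render_concentrations(model, group, rng)
    return tile_from_concentrations(hema, eosin, case_id=case_id, group=Group(group))


# ---------------------------------------------------------------------------
# Whole-cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Study design of a simulated cohort.

    Group sizes default to the study design the pipeline targets: 39/13/25
    fimbria cases for the epithelial analysis and 43/38/34 cases for the
    stromal tile analysis (each STIC case contributes both AwaySTIC and
    NearSTIC tiles).  Ages are uniform on 40-80 years; menopausal status
    thresholds age 51 with 10% label noise; BRCA and chemotherapy rates
    are Bernoulli per group.
    """

    epithelium_groups: Dict[str, int] = field(
        default_factory=lambda: {"Benign": 39, "NoSTIC": 13, "STIC": 25}
    )
    tile_cases: Dict[str, int] = field(
        default_factory=lambda: {"Benign": 43, "NoSTIC": 38, "STIC": 34}
    )
    tiles_per_case: int = 10
    age_range: Tuple[float, float] = (40.0, 80.0)
    menopause_age: float = 51.0
    menopause_noise: float = 0.10
    brca_rate: Dict[str, float] = field(
        default_factory=lambda: {"Benign": 0.10, "NoSTIC": 0.45, "STIC": 0.45}
    )
    chemo_rate: Dict[str, float] = field(
        default_factory=lambda: {"Benign": 0.0, "NoSTIC": 0.5, "STIC": 0.5}
    )
    epithelium: EpitheliumModel = field(default_factory=EpitheliumModel)
    stroma: StromaModel = field(default_factory=StromaModel)
    render_tiles: bool = True


def simulate_cohort(
    config: Optional[CohortConfig] = None,
    seed: int = 0,
    outdir: Optional[Path] = None,
):
    """Simulate a full cohort: cells, covariates, tiles and ground truth.

    Returns ``(manifest, cells, covariates, truth)`` where the first three
    are DataFrames in the pipeline's input formats and ``truth`` is a
    per-case record of the generative parameters.  With ``outdir`` set,
    writes ``manifest.csv``, ``cells.csv``, ``covariates.csv``,
    ``truth.json`` and the rendered PNG tiles.
    """
    config = config or CohortConfig()
    for sizes in (config.epithelium_groups, config.tile_cases):
        for g, n in sizes.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs >= 2 cases, got {n}")
    rng = np.random.default_rng(seed)
    if outdir is not None:
        outdir = Path(outdir)
        (outdir / "tiles").mkdir(parents=True, exist_ok=True)

    cov_rows: List[dict] = []
    cell_rows: List[dict] = []
    truth: List[dict] = []

    def draw_covariates(case_id: str, group: str) -> dict:
        age = float(rng.uniform(*config.age_range))
        meno = age >= config.menopause_age
        if rng.random() < config.menopause_noise:
            meno = not meno
        return {
            "case_id": case_id,
            "group": group,
            "age": round(age, 1),
            "menopausal": bool(meno),
            "brca": bool(rng.random() < config.brca_rate[group]),
            "chemotherapy": bool(rng.random() < config.chemo_rate[group]),
        }

    # epithelial arm
    case_no = 0
    for group, n_cases in config.epithelium_groups.items():
        for _ in range(n_cases):
            case_no += 1
            case_id = f"E{case_no:03d}"
            cov = draw_covariates(case_id, group)
            cov_rows.append(cov)
            slide = simulate_epithelium(
                config.epithelium,
                case_id=case_id,
                group=group,
                region="fimbria",
                age=cov["age"],
                menopausal=cov["menopausal"],
                brca=cov["brca"],
                chemotherapy=cov["chemotherapy"],
                seed=int(rng.integers(2**31)),
            )
            p_ss, p_cc = config.epithelium.persistence(cov["age"], group == "STIC")
            truth.append(
                {"case_id": case_id, "arm": "epithelium", "group": group,
                 "p_ss": p_ss, "p_cc": p_cc}
            )
            for roi in slide.rois:
                for pos, label in enumerate(roi.labels):
                    cell_rows.append(
                        {
                            "case_id": case_id,
                            "region": slide.region,
                            "group": group,
                            "roi_id": roi.roi_id,
                            "position": pos,
                            "cell_type": label,
                        }
                    )

    # stromal arm
    manifest_rows: List[dict] = []
    for group, n_cases in config.tile_cases.items():
        tile_groups = ["AwaySTIC", "NearSTIC"] if group == "STIC" else [group]
        for _ in range(n_cases):
            case_no += 1
            case_id = f"S{case_no:03d}"
            cov_rows.append(draw_covariates(case_id, group))
            for tg in tile_groups:
                cl, an = config.stroma.params_for(tg)
                truth.append(
                    {"case_id": case_id, "arm": "stroma", "group": tg,
                     "corr_len": cl, "anisotropy": an}
                )
                for t in range(config.tiles_per_case):
                    tile_seed = int(rng.integers(2**31))
                    path = f"tiles/{case_id}_{tg}_{t:02d}.png"
                    manifest_rows.append(
                        {
                            "tile_path": path,
                            "case_id": case_id,
                            "group": tg,
                            "region": "unspecified",
                            "seed": tile_seed,
                        }
                    )
                    if outdir is not None and config.render_tiles:
                        from PIL import Image

                        tile = render_stromal_tile(
                            config.stroma, tg, seed=tile_seed, case_id=case_id
                        )
                        Image.fromarray(tile.pixels).save(outdir / path)

    manifest = pd.DataFrame(manifest_rows)
    cells = pd.DataFrame(cell_rows)
    covariates = pd.DataFrame(cov_rows)
    if outdir is not None:
        manifest.to_csv(outdir / "manifest.csv", index=False)
        cells.to_csv(outdir / "cells.csv", index=False)
        covariates.to_csv(outdir / "covariates.csv", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1)
    return manifest, cells, covariates, truth
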