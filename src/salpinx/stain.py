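"""H&E color normalization and stain deconvolution.

Tiles are small RGB crops of stroma from scanned fallopian-tube sections.
Before texture features are computed, each tile is (optionally) color
normalized against a cohort reference tile and separated into hematoxylin
and eosin optical-density maps.

Normalization follows the Reinhard recipe: match per-channel mean and
standard deviation in the CIELAB color space to those of a designated
reference tile.  Deconvolution uses the Beer-Lambert model: per-pixel
optical density ``OD = -log10((I + eps) / 255)`` is projected onto a basis
of unit stain vectors (Ruifrok-Johnston H&E vectors by default) via least
squares, with negative concentrations clamped to zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
from skimage.color import lab2rgb, rgb2lab

__all__ = [
    "Group",
    "Region",
    "RGBTile",
    "StainChannels",
    "NormalizationReference",
    "RUIFROK_HE",
    "OD_EPS",
    "fit_reference",
    "normalize_color",
    "deconvolve_he",
    "od_from_rgb",
    "rgb_from_od",
]

#: Intensity offset in the optical-density transform, avoids log(0).
OD_EPS = 1.0

#: Lab channel spread below this counts as zero (numerical noise floor).
_SPREAD_TOL = 1e-8


class Group(str, Enum):
    """Cohort group of a stromal tile.

    ``AWAY_STIC`` marks stroma annotated as more than 2 mm from a STIC
    lesion; ``NEAR_STIC`` marks stroma subjacent to it.  Both labels are a
    manifest contract from the annotation step — the package never measures
    distances on whole slides.
    """

    BENIGN = "Benign"
    NO_STIC = "NoSTIC"
    AWAY_STIC = "AwaySTIC"
    NEAR_STIC = "NearSTIC"


class Region(str, Enum):
    FIMBRIA = "fimbria"
    AMPULLA = "ampulla"
    UNSPECIFIED = "unspecified"


def _ruifrok_he() -> np.ndarray:
    """Standard Ruifrok-Johnston hematoxylin/eosin stain vectors (unit rows)."""
    m = np.array(
        [
            [0.650, 0.704, 0.286],  # hematoxylin
            [0.070, 0.990, 0.110],  # eosin
        ]
    )
    return m / np.linalg.norm(m, axis=1, keepdims=True)


RUIFROK_HE = _ruifrok_he()


@dataclass(frozen=True)
class RGBTile:
    """One square H&E tile plus its manifest metadata."""

    pixels: np.ndarray  # (H, W, 3) uint8
    case_id: str
    group: Group
    region: Region = Region.UNSPECIFIED

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"tile pixels must be (H, W, 3), got {px.shape}")
        if px.shape[0] != px.shape[1]:
            raise ValueError("tiles must be square")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("pixel intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def size(self) -> int:
        return self.pixels.shape[0]

    def with_pixels(self, pixels: np.ndarray) -> "RGBTile":
        return RGBTile(pixels, self.case_id, self.group, self.region)


@dataclass(frozen=True)
class StainChannels:
    """Hematoxylin and eosin concentration maps (optical-density units, >= 0)."""

    hematoxylin: np.ndarray
    eosin: np.ndarray
    case_id: str = ""

    def __post_init__(self) -> None:
        if self.hematoxylin.shape != self.eosin.shape:
            raise ValueError("channel shapes differ")
        for name in ("hematoxylin", "eosin"):
            ch = getattr(self, name)
            if not np.all(np.isfinite(ch)) or ch.min() < 0:
                raise ValueError(f"{name} channel must be finite and non-negative")


@dataclass(frozen=True)
class NormalizationReference:
    """Per-channel CIELAB mean and standard deviation of a reference tile."""

    mean: np.ndarray  # (3,)
    std: np.ndarray  # (3,)
    zero_spread: bool = False


def fit_reference(tile: RGBTile) -> NormalizationReference:
    """Compute CIELAB channel statistics of ``tile`` for Reinhard matching.

    A degenerate tile whose pixels are all identical yields zero spread on
    every channel; the reference is returned flagged so that normalization
    against it passes channels through unchanged.
    """
    lab = rgb2lab(tile.pixels / 255.0)
    mean = lab.reshape(-1, 3).mean(axis=0)
    std = lab.reshape(-1, 3).std(axis=0)
    std[std < _SPREAD_TOL] = 0.0
    return NormalizationReference(mean=mean, std=std, zero_spread=bool(np.all(std == 0)))


def normalize_color(tile: RGBTile, ref: NormalizationReference) -> RGBTile:
    """Reinhard color normalization of ``tile`` against ``ref``.

    Each CIELAB channel is recentered and rescaled to the reference mean and
    standard deviation.  Channels with zero spread in either the source tile
    or the reference cannot be rescaled meaningfully and pass through
    unchanged.  Output is clamped back to [0, 255].
    """
    lab = rgb2lab(tile.pixels / 255.0)
    src_mean = lab.reshape(-1, 3).mean(axis=0)
    src_std = lab.reshape(-1, 3).std(axis=0)
    out = lab.copy()
    for c in range(3):
        if src_std[c] < _SPREAD_TOL or ref.std[c] < _SPREAD_TOL:
            continue  # degenerate channel: pass through
        out[..., c] = (lab[..., c] - src_mean[c]) / src_std[c] * ref.std[c] + ref.mean[c]
    rgb = lab2rgb(out)
    px = np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)
    return tile.with_pixels(px)


def od_from_rgb(pixels: np.ndarray, eps: float = OD_EPS) -> np.ndarray:
    """Per-pixel optical density ``-log10((I + eps)/255)`` of an RGB array."""
    return -np.log10((pixels.astype(float) + eps) / 255.0)


def rgb_from_od(od: np.ndarray, eps: float = OD_EPS) -> np.ndarray:
    """Inverse Beer-Lambert transform back to 8-bit RGB intensities."""
    intensity = 255.0 * np.power(10.0, -od) - eps
    return np.clip(np.rint(intensity), 0, 255).astype(np.uint8)


def deconvolve_he(
    tile: RGBTile, stain_matrix: Optional[np.ndarray] = None, eps: float = OD_EPS
) -> StainChannels:
    """Separate an H&E tile into hematoxylin and eosin concentration maps.

    Parameters
    ----------
    tile
        Source RGB tile.
    stain_matrix
        Rows are unit stain vectors in optical-density space (2 or 3 rows,
        3 columns).  Defaults to the Ruifrok-Johnston H&E pair.  Rows must
        be linearly independent.

    Concentrations are the least-squares projection of the per-pixel OD
    vector onto the stain basis; negative values are clamped to zero.
    """
    if stain_matrix is None:
        stain_matrix = RUIFROK_HE
    s = np.asarray(stain_matrix, dtype=float)
    if s.ndim != 2 or s.shape[1] != 3 or s.shape[0] not in (2, 3):
        raise ValueError("stain matrix must have 2 or 3 rows of 3 components")
    if np.linalg.matrix_rank(s) < s.shape[0]:
        raise ValueError("stain matrix is singular (stain vectors not independent)")
    norms = np.linalg.norm(s, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("stain vectors must be unit length")

    od = od_from_rgb(tile.pixels, eps=eps).reshape(-1, 3)
    conc, *_ = np.linalg.lstsq(s.T, od.T, rcond=None)
    conc = np.clip(conc.T, 0.0, None).reshape(tile.pixels.shape[0], tile.pixels.shape[1], -1)
    return StainChannels(
        hematoxylin=conc[..., 0], eosin=conc[..., 1], case_id=tile.case_id
    )
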