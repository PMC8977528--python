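"""Stromal texture panel: SFTA, LPQ and BSIF descriptors per stain channel.

The panel characterizes the texture of a hematoxylin or eosin concentration
map with three descriptor families:

* **SFTA** (segmentation-based fractal texture analysis) — the channel is
  decomposed into binary images by multi-level Otsu thresholding; with
  ``n`` thresholds the two-threshold decomposition yields ``2n - 1`` binary
  images (``n - 1`` band images between consecutive thresholds plus ``n``
  upper-threshold images).  Each binary image contributes three features:
  the box-counting fractal dimension of its region boundaries, the mean
  gray level inside the regions, and the region pixel count.  The default
  of ``n = 8`` thresholds gives 15 binary images and 45 features.
* **LPQ** (local phase quantization) — the local Fourier phase at the four
  lowest non-zero frequencies is estimated in a sliding window; the signs
  of the real and imaginary parts form an 8-bit code per pixel, and the
  256-bin code histogram (normalized to sum 1) is the descriptor.
* **BSIF** (binarized statistical image features) — the channel is
  filtered with a fixed bank of 8 zero-mean linear filters; the signs of
  the responses form an 8-bit code and the normalized 256-bin histogram is
  the descriptor.

Applied to both stain channels of one tile, the panel yields
45 + 256 + 256 = 557 features per channel and 1114 in total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import List, Optional

import numpy as np
from scipy.signal import convolve2d

from .stain import RGBTile, NormalizationReference, deconvolve_he, normalize_color

__all__ = [
    "FeaturePanelConfig",
    "FeatureVector",
    "sfta_features",
    "lpq_features",
    "bsif_features",
    "extract_panel",
    "feature_names",
    "load_default_bsif_bank",
    "N_SFTA",
    "N_LPQ",
    "N_BSIF",
    "N_PER_CHANNEL",
    "N_TOTAL",
]

N_SFTA = 45
N_LPQ = 256
N_BSIF = 256
N_PER_CHANNEL = N_SFTA + N_LPQ + N_BSIF
N_TOTAL = 2 * N_PER_CHANNEL


def load_default_bsif_bank() -> np.ndarray:
    """Load the shipped deterministic 8-filter 7x7 BSIF bank.

    The bank was learned once by independent component analysis on patches
    from a seeded synthetic texture corpus and is stored as a plain-text
    data file, so feature values are reproducible without downloads.
    Filters are re-centered to exactly zero mean at load time.
    """
    with resources.files("salpinx.data").joinpath("bsif_7x7_8.csv").open() as fh:
        flat = np.loadtxt(fh, delimiter=",")
    bank = flat.reshape(8, 7, 7)
    bank -= bank.mean(axis=(1, 2), keepdims=True)
    return bank


@dataclass
class FeaturePanelConfig:
    """Configuration of the three descriptor families.

    Defaults follow the classic published settings of each descriptor:
    8 Otsu thresholds (the decomposition size that yields 45 SFTA
    features), a 7x7 uniform LPQ window with decorrelation at correlation
    coefficient 0.9, and the shipped 8-filter 7x7 BSIF bank.
    """

    sfta_threshold_count: int = 8
    lpq_window: int = 7
    lpq_decorrelation: bool = True
    lpq_rho: float = 0.9
    bsif_filterbank: Optional[np.ndarray] = None
    normalize: bool = True
    reference: Optional[NormalizationReference] = None
    stain_matrix: Optional[np.ndarray] = None

    def bank(self) -> np.ndarray:
        if self.bsif_filterbank is None:
            self.bsif_filterbank = load_default_bsif_bank()
        return self.bsif_filterbank


@dataclass(frozen=True)
class FeatureVector:
    """Named 1114-dimensional texture descriptor of one tile."""

    values: np.ndarray
    names: tuple
    case_id: str = ""
    group: str = ""
    region: str = ""

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError("values and names length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")


def feature_names(config: Optional[FeaturePanelConfig] = None) -> List[str]:
    """Stable feature identifiers ``channel.family.index``.

    Hematoxylin features come first, then eosin; within a channel the order
    is SFTA (45), LPQ (256), BSIF (256).
    """
    names = []
    for channel in ("hematoxylin", "eosin"):
        for i in range(N_SFTA):
            names.append(f"{channel}.sfta.{i:03d}")
        for i in range(N_LPQ):
            names.append(f"{channel}.lpq.{i:03d}")
        for i in range(N_BSIF):
            names.append(f"{channel}.bsif.{i:03d}")
    return names


# ---------------------------------------------------------------------------
# SFTA
# ---------------------------------------------------------------------------


def _multiotsu_thresholds(channel: np.ndarray, n_thresh: int, nbins: int = 256) -> np.ndarray:
    """Multi-level Otsu thresholds by exact dynamic programming.

    Maximizes the between-class variance sum(w_k * mu_k**2) over all
    placements of ``n_thresh`` thresholds on a ``nbins``-bin histogram in
    O(n_thresh * nbins**2) time, which stays exact and fast even for the
    8-threshold decomposition the panel uses.  Returned thresholds are in
    the intensity units of ``channel``.
    """
    lo, hi = float(channel.min()), float(channel.max())
    hist, edges = np.histogram(channel, bins=nbins, range=(lo, hi))
    p = hist / hist.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0
    cw = np.concatenate([[0.0], np.cumsum(p)])
    cm = np.concatenate([[0.0], np.cumsum(p * centers)])
    # cost[i, j]: w * mu^2 of one class spanning bins i..j inclusive
    w = cw[None, 1:] - cw[:-1, None]
    m = cm[None, 1:] - cm[:-1, None]
    cost = np.where(w > 0, m**2 / np.where(w > 0, w, 1.0), 0.0)
    ii, jj = np.indices(cost.shape)
    cost = np.where(jj >= ii, cost, -np.inf)

    k = n_thresh + 1  # number of classes
    value = cost[0].copy()  # bins 0..j as a single class
    back = np.zeros((k, nbins), dtype=int)
    for c in range(1, k):
        prev = np.concatenate([[-np.inf], value[:-1]])  # prev[i] = V_{c-1}[i-1]
        cand = prev[:, None] + cost  # cand[i, j]: class c starts at bin i
        back[c] = np.argmax(cand, axis=0)
        value = np.max(cand, axis=0)

    cuts = []
    j = nbins - 1
    for c in range(k - 1, 0, -1):
        i = int(back[c][j])
        cuts.append(i)
        j = i - 1
    cuts.sort()
    return np.array([edges[i] for i in cuts])


def _box_counting_dimension(border: np.ndarray) -> float:
    """Box-counting fractal dimension of a binary boundary image.

    Counts occupied boxes at dyadic box sizes and fits the slope of
    log(count) against log(1/size) by least squares.  Returns 0.0 when the
    boundary is empty or only one scale is available.
    """
    if not border.any():
        return 0.0
    h, w = border.shape
    max_exp = int(np.floor(np.log2(min(h, w))))
    sizes = [2**k for k in range(0, max_exp)]
    counts = []
    for s in sizes:
        nh, nw = int(np.ceil(h / s)), int(np.ceil(w / s))
        padded = np.zeros((nh * s, nw * s), dtype=bool)
        padded[:h, :w] = border
        blocks = padded.reshape(nh, s, nw, s).any(axis=(1, 3))
        counts.append(blocks.sum())
    sizes_arr = np.array(sizes, dtype=float)
    counts_arr = np.array(counts, dtype=float)
    keep = counts_arr > 0
    if keep.sum() < 2:
        return 0.0
    slope, _ = np.polyfit(np.log(1.0 / sizes_arr[keep]), np.log(counts_arr[keep]), 1)
    return float(slope)


def _region_borders(binary: np.ndarray) -> np.ndarray:
    """Pixels of a binary image that touch the background (4-connectivity).

    Image-edge pixels of a region count as borders: the region may extend
    beyond the crop and its visible outline is what box counting measures.
    """
    padded = np.pad(binary, 1, mode="constant", constant_values=False)
    interior = (
        padded[:-2, 1:-1]
        & padded[2:, 1:-1]
        & padded[1:-1, :-2]
        & padded[1:-1, 2:]
    )
    return binary & ~interior


def _binary_decomposition(channel: np.ndarray, thresholds: np.ndarray) -> List[np.ndarray]:
    """Two-threshold binary decomposition: n-1 band images + n upper images."""
    t = np.asarray(thresholds, dtype=float)
    images = []
    for lo, hi in zip(t[:-1], t[1:]):
        images.append((channel > lo) & (channel <= hi))
    for lo in t:
        images.append(channel > lo)
    return images


def sfta_features(channel: np.ndarray, config: Optional[FeaturePanelConfig] = None) -> np.ndarray:
    """45 segmentation-based fractal texture analysis features.

    For each binary image of the Otsu decomposition, in fixed order, three
    values are emitted: boundary box-counting dimension, mean gray level of
    the region, and region pixel count.  A constant channel has no Otsu
    thresholds; the defined fallback emits dimension 0, the constant as the
    mean, and the count the degenerate decomposition produces, with a
    warning.
    """
    config = config or FeaturePanelConfig()
    n_thresh = config.sfta_threshold_count
    channel = np.asarray(channel, dtype=float)
    lo, hi = channel.min(), channel.max()
    if lo == hi:
        warnings.warn("constant channel: SFTA thresholds are degenerate", stacklevel=2)
        thresholds = np.full(n_thresh, lo)
    else:
        thresholds = _multiotsu_thresholds(channel, n_thresh)
    feats = np.empty(3 * (2 * n_thresh - 1))
    for k, binary in enumerate(_binary_decomposition(channel, thresholds)):
        count = int(binary.sum())
        if count:
            dim = _box_counting_dimension(_region_borders(binary))
            mean = float(channel[binary].mean())
        else:
            dim, mean = 0.0, float(lo) if lo == hi else 0.0
        feats[3 * k : 3 * k + 3] = (dim, mean, count)
    return feats


def _tie_tol(resp: np.ndarray) -> float:
    """Threshold below which a response counts as exactly zero.

    Responses that are zero in exact arithmetic (constant inputs, symmetric
    cancellations) come out as ~1e-16 noise in floating point; they must
    code as bit 0 deterministically, so anything within machine-precision
    reach of the response scale is snapped to zero.
    """
    scale = float(np.abs(resp).max()) if resp.size else 0.0
    return 1e-9 * max(scale, 1.0)


# ---------------------------------------------------------------------------
# LPQ
# ---------------------------------------------------------------------------


def _lpq_basis(window: int) -> np.ndarray:
    """The 8 real-valued window functionals behind the LPQ code bits.

    Rows are the flattened real/imaginary parts of the 2-D complex
    exponentials exp(-2*pi*i * u . y) over the window, for the four lowest
    non-zero frequencies u in {(a,0), (0,a), (a,a), (a,-a)} with
    a = 1/window.  Row order matches the bit order of the code.
    """
    r = window // 2
    a = 1.0 / window
    y = np.arange(-r, r + 1)
    rows = []
    for u in ((a, 0.0), (0.0, a), (a, a), (a, -a)):
        k = np.exp(-2j * np.pi * (u[0] * y[:, None] + u[1] * y[None, :]))
        rows.append(k.real.ravel())
        rows.append(k.imag.ravel())
    return np.array(rows)


def _lpq_whitening(window: int, rho: float) -> np.ndarray:
    """Decorrelating transform for the 8 filter responses.

    Model: pixel covariance decays as rho**d with Euclidean distance d.
    The response covariance D = M C M' is diagonalized by SVD and the
    transform V' whitens the responses before sign quantization.  A tiny
    graded diagonal perturbation breaks eigenvalue ties deterministically.
    """
    m = _lpq_basis(window)
    xx, yy = np.meshgrid(np.arange(window), np.arange(window), indexing="ij")
    pos = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
    c = rho**d
    dmat = m @ c @ m.T
    a = np.diag(1.000007 ** np.arange(8))
    _, _, vt = np.linalg.svd(a @ dmat @ a)
    return vt


def lpq_features(channel: np.ndarray, config: Optional[FeaturePanelConfig] = None) -> np.ndarray:
    """256-bin local phase quantization histogram, normalized to sum 1.

    Codes are computed only where the full window fits inside the image
    (no padding); responses exactly zero quantize to bit 0.
    """
    config = config or FeaturePanelConfig()
    w = config.lpq_window
    if w < 3 or w % 2 == 0:
        raise ValueError("LPQ window must be odd and >= 3")
    channel = np.asarray(channel, dtype=float)
    if channel.shape[0] < w or channel.shape[1] < w:
        raise ValueError(f"image smaller than LPQ window {w}")

    r = w // 2
    a = 1.0 / w
    y = np.arange(-r, r + 1)
    e = np.exp(-2j * np.pi * a * y)  # 1-D exponential at frequency a
    ones = np.ones(w)

    def corr_sep(krow: np.ndarray, kcol: np.ndarray) -> np.ndarray:
        # valid-mode correlation with separable kernel k(y1,y2)=krow[y1]*kcol[y2]
        tmp = convolve2d(channel, krow[::-1].reshape(-1, 1), mode="valid")
        return convolve2d(tmp, kcol[::-1].reshape(1, -1), mode="valid")

    f1 = corr_sep(e, ones)          # u = (a, 0)
    f2 = corr_sep(ones, e)          # u = (0, a)
    f3 = corr_sep(e, e)             # u = (a, a)
    f4 = corr_sep(e, e.conj())      # u = (a, -a)

    resp = np.stack(
        [f1.real, f1.imag, f2.real, f2.imag, f3.real, f3.imag, f4.real, f4.imag],
        axis=-1,
    )
    if config.lpq_decorrelation:
        vt = _lpq_whitening(w, config.lpq_rho)
        resp = resp @ vt.T
    bits = resp > _tie_tol(resp)
    codes = np.zeros(resp.shape[:2], dtype=np.int64)
    for i in range(8):
        codes += bits[..., i] << i
    hist = np.bincount(codes.ravel(), minlength=256).astype(float)
    return hist / hist.sum()


# ---------------------------------------------------------------------------
# BSIF
# ---------------------------------------------------------------------------


def bsif_features(channel: np.ndarray, config: Optional[FeaturePanelConfig] = None) -> np.ndarray:
    """256-bin binarized statistical image feature histogram (sum 1).

    The channel is correlated (valid mode) with each of the 8 zero-mean
    filters; response > 0 sets the corresponding code bit.  Responses that
    are exactly zero — e.g. every response on a constant input — code as
    bit 0, deterministically placing all mass in bin 0 in that case.
    """
    config = config or FeaturePanelConfig()
    bank = np.asarray(config.bank(), dtype=float)
    if bank.ndim != 3 or bank.shape[0] != 8:
        raise ValueError("BSIF bank must contain exactly 8 filters (256 bins need 8 bits)")
    channel = np.asarray(channel, dtype=float)
    resp = np.stack(
        [convolve2d(channel, bank[i][::-1, ::-1], mode="valid") for i in range(8)],
        axis=-1,
    )
    bits = resp > _tie_tol(resp)
    codes = np.zeros(resp.shape[:2], dtype=np.int64)
    for i in range(8):
        codes += bits[..., i].astype(np.int64) << i
    hist = np.bincount(codes.ravel(), minlength=256).astype(float)
    return hist / hist.sum()


# ---------------------------------------------------------------------------
# Full panel
# ---------------------------------------------------------------------------


def extract_panel(tile: RGBTile, config: Optional[FeaturePanelConfig] = None) -> FeatureVector:
    """Compute the full 1114-feature descriptor for one tile.

    Pipeline: optional Reinhard normalization, H&E deconvolution, then
    per-channel SFTA + LPQ + BSIF, hematoxylin first.
    """
    config = config or FeaturePanelConfig()
    try:
        if config.normalize and config.reference is not None:
            tile = normalize_color(tile, config.reference)
        channels = deconvolve_he(tile, stain_matrix=config.stain_matrix)
        parts = []
        for ch in (channels.hematoxylin, channels.eosin):
            parts.append(sfta_features(ch, config))
            parts.append(lpq_features(ch, config))
            parts.append(bsif_features(ch, config))
    except Exception as exc:
        raise RuntimeError(f"feature extraction failed for tile {tile.case_id!r}") from exc
    values = np.concatenate(parts)
    return FeatureVector(
        values=values,
        names=tuple(feature_names(config)),
        case_id=tile.case_id,
        group=tile.group.value,
        region=tile.region.value,
    )
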