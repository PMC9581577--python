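"""Phase-contrast image quantification of cell-cluster formation.

Dense cell clusters absorb light and appear as red-shifted (brownish)
blobs over a paler background, with electrodes as near-black discs.
The pipeline is: inpaint electrode pixels, map each pixel to a
red/blue "hue" ratio, band-pass the map spatially (difference of
Gaussians) to reject single cells and illumination gradients, threshold
at mean + 1.4 SD, erode, and summarize as the MEA-wide cluster ratio
plus a Gaussian-weighted per-electrode clusterness score.

Images are RGB float arrays in [0, 1] (uint8 inputs are converted).
The pixel scale in um/px is required metadata and never guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import color, util

from .model import ElectrodeLayout

__all__ = [
    "HueMap",
    "ClusterMap",
    "inpaint_electrodes",
    "hue_map",
    "segment_clusters",
    "cluster_ratio",
    "normalize_cluster_ratio",
    "electrode_clusterness",
]

#: grayscale floor used when a denominator channel is 0 (1 unit of uint8)
_DENOM_FLOOR = 1.0 / 255.0
#: per-electrode window is 31 x 31 um with the Gaussian edge at 1 SD
CLUSTERNESS_WINDOW_UM = 31.0
CLUSTERNESS_SIGMA_UM = CLUSTERNESS_WINDOW_UM / 2.0


@dataclass
class HueMap:
    """Band-passed red/blue ratio field; clusters score high."""

    values: np.ndarray
    um_per_px: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("hue map must be finite")
        if self.um_per_px <= 0:
            raise ValueError("pixel scale must be positive")


@dataclass
class ClusterMap:
    mask: np.ndarray
    cluster_ratio: float
    per_electrode_scores: dict[str, float] = field(default_factory=dict)


def _as_float_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an RGB image (H, W, 3)")
    return util.img_as_float(img)


def inpaint_electrodes(img: np.ndarray, dilate_px: int = 2,
                       tol: float = 1e-5, max_iter: int = 20000) -> np.ndarray:
    """Replace electrode pixels by iterative neighborhood averaging.

    Electrode pixels are those with grayscale exactly 0 or below one SD
    under the image mean; the mask is dilated by ``dilate_px`` to catch
    dark rims.  Masked pixels are filled per channel by repeated
    4-neighbor averaging until convergence (a discrete harmonic fill, so
    filled values obey the maximum principle: they stay within the range
    of the surrounding boundary values).
    """
    img = _as_float_rgb(img)
    gray = color.rgb2gray(img)
    mask = (gray == 0) | (gray < gray.mean() - gray.std())
    if dilate_px > 0:
        off = np.arange(-dilate_px, dilate_px + 1)
        dy, dx = np.meshgrid(off, off, indexing="ij")
        disk = dx**2 + dy**2 <= dilate_px**2
        mask = ndimage.binary_dilation(mask, structure=disk)
    if not mask.any():
        return img.copy()
    if mask.all():
        raise ValueError("every pixel is masked; nothing to inpaint from")

    h, w = gray.shape
    out = img.copy()
    ii, jj = np.nonzero(mask)
    # clamped 4-neighbor indices of each masked pixel
    nb_i = np.stack([np.clip(ii - 1, 0, h - 1), np.clip(ii + 1, 0, h - 1), ii, ii])
    nb_j = np.stack([jj, jj, np.clip(jj - 1, 0, w - 1), np.clip(jj + 1, 0, w - 1)])
    for c in range(3):
        ch = out[:, :, c]
        ch[ii, jj] = ch[~mask].mean()  # neutral start
        for _ in range(max_iter):
            new = ch[nb_i, nb_j].mean(axis=0)
            delta = np.abs(new - ch[ii, jj]).max()
            ch[ii, jj] = new
            if delta < tol:
                break
    return out


def hue_map(img: np.ndarray, um_per_px: float, sigma_low_um: float = 15.0,
            sigma_high_um: float = 300.0, red_over_blue: bool = True) -> HueMap:
    """Band-passed per-pixel channel ratio highlighting cell clusters.

    The ratio is red/blue by default so that red-shifted clusters score
    high and above-mean segmentation picks them out; ``red_over_blue=
    False`` inverts the ratio for the opposite convention.  The spatial
    band-pass is a difference of Gaussians: sigma_low rejects features
    at the single-cell scale, sigma_high rejects illumination gradients.
    """
    img = _as_float_rgb(img)
    if um_per_px <= 0:
        raise ValueError("pixel scale must be positive")
    num, den = (img[:, :, 0], img[:, :, 2]) if red_over_blue else \
               (img[:, :, 2], img[:, :, 0])
    ratio = num / np.maximum(den, _DENOM_FLOOR)
    s_lo = sigma_low_um / um_per_px
    s_hi = sigma_high_um / um_per_px
    band = ndimage.gaussian_filter(ratio, s_lo) - ndimage.gaussian_filter(ratio, s_hi)
    return HueMap(values=band, um_per_px=um_per_px)


def segment_clusters(hue: HueMap, k: float = 1.4, erode: bool = True) -> np.ndarray:
    """Threshold the hue map at mean + k SD; optionally erode once (3x3).

    Erosion removes isolated suprathreshold speckle.  A zero-variance
    map yields an empty mask.
    """
    v = hue.values
    sd = v.std()
    if sd == 0:
        return np.zeros(v.shape, dtype=bool)
    mask = v > v.mean() + k * sd
    if erode:
        mask = ndimage.binary_erosion(mask, structure=np.ones((3, 3), bool))
    return mask


def cluster_ratio(mask: np.ndarray) -> float:
    """Fraction of pixels segmented as cluster."""
    mask = np.asarray(mask, dtype=bool)
    return float(mask.sum() / mask.size)


def normalize_cluster_ratio(series: np.ndarray) -> np.ndarray:
    """Divide a cluster-ratio time series by its first-day value."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty series")
    if series[0] <= 0:
        raise ValueError("first-day cluster ratio is zero; normalization undefined")
    return series / series[0]


def electrode_clusterness(hue: HueMap, layout: ElectrodeLayout,
                          origin_um: tuple[float, float] = (0.0, 0.0),
                          window_um: float = CLUSTERNESS_WINDOW_UM,
                          sigma_um: float = CLUSTERNESS_SIGMA_UM
                          ) -> dict[str, float]:
    """Gaussian-weighted local hue average around each electrode centre.

    The window is ``window_um`` square with the Gaussian truncated at
    the window edge, which lies at one SD.  Electrodes whose window
    falls outside the image score NaN.
    """
    v = hue.values
    h, w = v.shape
    half_px = window_um / 2.0 / hue.um_per_px
    r = int(round(half_px))
    off = np.arange(-r, r + 1)
    dy, dx = np.meshgrid(off, off, indexing="ij")
    sig_px = sigma_um / hue.um_per_px
    weights = np.exp(-(dx**2 + dy**2) / (2 * sig_px**2))
    weights /= weights.sum()

    scores: dict[str, float] = {}
    x0, y0 = origin_um
    for eid, ex, ey in zip(layout.electrode_ids, layout.x, layout.y):
        cx = int(round((ex - x0) / hue.um_per_px))
        cy = int(round((ey - y0) / hue.um_per_px))
        if cy - r < 0 or cy + r >= h or cx - r < 0 or cx + r >= w:
            scores[eid] = float("nan")
            continue
        patch = v[cy - r:cy + r + 1, cx - r:cx + r + 1]
        scores[eid] = float(np.sum(patch * weights))
    return scores
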