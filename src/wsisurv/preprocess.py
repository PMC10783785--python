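"""Tissue masking, foreground/ROI construction and stain separation.

The chain mirrors standard H&E slide preprocessing: Otsu thresholding of
the gray-level histogram to find stained tissue, selection of the most
tissue-dense foreground block, area-average shrinking of that block to a
global gray ROI, and Ruifrok–Johnston color deconvolution of RGB optical
densities into hematoxylin / eosin / residual (HEO) concentration channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.morphology import closing, disk
from skimage.transform import downscale_local_mean, resize

from .errors import DegenerateHistogramError, NoForegroundError
from .slides import HE_STAIN_MATRIX

__all__ = [
    "StainChannels",
    "otsu_threshold",
    "luminance",
    "tissue_mask",
    "select_foreground_block",
    "make_gray_roi",
    "color_deconvolution",
]


def otsu_threshold(histogram: np.ndarray) -> int:
    """Otsu's threshold of a 256-bin gray-level histogram.

    Returns the level ``t`` maximizing the between-class variance of the
    split ``{levels <= t} / {levels > t}``; ties are broken by the lowest
    level.  Raises :class:`DegenerateHistogramError` when fewer than two
    bins are occupied (constant image).
    """
    hist = np.asarray(histogram, dtype=float)
    if hist.ndim != 1 or hist.size != 256:
        raise ValueError("expected a 256-bin histogram")
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("degenerate histogram: fewer than two occupied bins")

    levels = np.arange(256, dtype=float)
    total = hist.sum()
    w0 = np.cumsum(hist) / total  # weight of class {<= t}
    mu_t = np.cumsum(hist * levels) / total
    mu = mu_t[-1]
    w1 = 1.0 - w0
    valid = (w0 > 0) & (w1 > 0)
    between = np.zeros(256)
    between[valid] = (mu * w0[valid] - mu_t[valid]) ** 2 / (w0[valid] * w1[valid])
    return int(np.argmax(between))  # argmax returns the first (lowest) maximizer


def luminance(image: np.ndarray) -> np.ndarray:
    """ITU-R 601 luma of an 8-bit RGB image, rounded back to uint8."""
    img = np.asarray(image, dtype=float)
    gray = 0.299 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2]
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def tissue_mask(image: np.ndarray, closing_radius: int = 3) -> np.ndarray:
    """Binary mask of the stained (darker) tissue class.

    Luma-convert, Otsu-threshold the histogram, keep the darker class and
    close small pinholes.  A constant image raises
    :class:`DegenerateHistogramError`.
    """
    gray = luminance(image)
    hist = np.bincount(gray.ravel(), minlength=256)
    t = otsu_threshold(hist)
    mask = gray <= t
    if closing_radius > 0:
        mask = closing(mask, disk(closing_radius))
    return mask


def select_foreground_block(
    mask: np.ndarray, block_size: int, stride: int | None = None
) -> tuple[int, int]:
    """Top-left corner of the block with maximal tissue coverage.

    Candidate positions lie on a row-major stride grid (stride defaults to
    ``block_size // 4``), extended so the bottom/right edges are reachable;
    the first maximum wins.  Raises :class:`NoForegroundError` if the mask
    is empty.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    if block_size > min(h, w):
        raise ValueError("block_size exceeds image size")
    if not mask.any():
        raise NoForegroundError("no foreground: tissue mask is empty")
    if stride is None:
        stride = max(1, block_size // 4)

    # summed-area table for O(1) coverage queries
    integral = np.zeros((h + 1, w + 1), dtype=np.int64)
    integral[1:, 1:] = np.cumsum(np.cumsum(mask, axis=0), axis=1)

    def coverage(r: int, c: int) -> int:
        return int(
            integral[r + block_size, c + block_size]
            - integral[r, c + block_size]
            - integral[r + block_size, c]
            + integral[r, c]
        )

    rows = sorted(set(range(0, h - block_size + 1, stride)) | {h - block_size})
    cols = sorted(set(range(0, w - block_size + 1, stride)) | {w - block_size})
    best, best_pos = -1, (0, 0)
    for r in rows:
        for c in cols:
            cov = coverage(r, c)
            if cov > best:
                best, best_pos = cov, (r, c)
    return best_pos


def make_gray_roi(block: np.ndarray, roi_size: int) -> np.ndarray:
    """Shrink an RGB block to a square 8-bit gray ROI by area averaging."""
    gray = luminance(block).astype(float)
    h, w = gray.shape
    side = min(h, w)
    roi_size = min(roi_size, side)
    gray = gray[:side, :side]
    if side % roi_size == 0:
        small = downscale_local_mean(gray, (side // roi_size, side // roi_size))
    else:
        small = resize(gray, (roi_size, roi_size), anti_aliasing=True, preserve_range=True)
    return np.clip(np.rint(small), 0, 255).astype(np.uint8)


@dataclass
class StainChannels:
    """Per-stain optical-density concentration images (H, E, residual)."""

    H: np.ndarray
    E: np.ndarray
    O: np.ndarray


def color_deconvolution(
    image: np.ndarray, stain_matrix: np.ndarray = HE_STAIN_MATRIX, clip: bool = True
) -> StainChannels:
    """Unmix an RGB image into H/E/residual concentration channels.

    Optical density is ``OD = -log10((I + 1) / 256)`` per channel; the
    concentration of each stain solves ``OD = C @ stain_matrix`` where the
    matrix rows are unit-normalized stain OD vectors.  Negative
    concentrations are clipped to zero unless ``clip`` is False.
    """
    M = np.asarray(stain_matrix, dtype=float)
    if M.shape != (3, 3):
        raise ValueError("stain_matrix must be 3x3")
    if abs(np.linalg.det(M)) < 1e-8:
        raise ValueError("singular stain matrix")
    od = -np.log10((np.asarray(image, dtype=float) + 1.0) / 256.0)
    conc = od @ np.linalg.inv(M)
    if clip:
        conc = np.clip(conc, 0.0, None)
    return StainChannels(H=conc[..., 0], E=conc[..., 1], O=conc[..., 2])
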