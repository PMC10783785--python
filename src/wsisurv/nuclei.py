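"""Nuclei segmentation and per-nucleus shape description.

Segmentation works on the hematoxylin concentration channel: a Laplacian
sharpening step boosts blob contrast, Otsu thresholding finds candidate
nuclei, a local-mean adaptive threshold refines their outline, and
morphology (opening + hole filling) cleans the mask before connected
components are extracted.  Each surviving component is described by a fixed
panel of 27 strictly positive shape descriptors computed jointly from the
pixel mask, a least-squares ellipse fit to the contour, and the convex
hull; the mask itself is never altered by the fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.filters import threshold_local
from skimage.measure import EllipseModel, find_contours, label as sk_label, regionprops
from skimage.morphology import disk, opening

from .preprocess import color_deconvolution, otsu_threshold
from .slides import HE_STAIN_MATRIX

__all__ = [
    "SegmentationParams",
    "NucleusRegion",
    "segment_nuclei",
    "nucleus_descriptors",
    "DESCRIPTOR_NAMES",
]

#: canonical order of the 27 per-nucleus shape descriptors
DESCRIPTOR_NAMES = (
    "area",
    "perimeter",
    "perimeter_area_ratio",
    "equivalent_diameter",
    "circularity",
    "convex_area",
    "solidity",
    "convexity",
    "extent",
    "eccentricity",
    "major_axis",
    "minor_axis",
    "aspect_ratio",
    "ellipse_residual",
    "feret_max",
    "feret_min",
    "feret_ratio",
    "bbox_aspect",
    "compactness",
    "sphericity",
    "hu_1",
    "hu_2",
    "hu_3",
    "hu_4",
    "hu_5",
    "hu_6",
    "hu_7",
)

# floor keeping every descriptor strictly positive (mrate needs min > 0)
_POS_FLOOR = 1e-6
# shift making log10-magnitude Hu moments positive (|hu| + 1e-12 >= 1e-12)
_HU_EPS = 1e-12
_HU_SHIFT = 13.0


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the nuclei segmentation chain.

    ``adaptive_window`` / ``adaptive_offset`` parametrize the local
    Gaussian-weighted-mean refinement (offset in 8-bit gray levels a pixel
    must exceed its neighborhood mean by); ``min_area`` drops debris
    components at the working scale.
    """

    min_area: int = 40
    adaptive_window: int = 51
    adaptive_offset: float = 2.0
    opening_radius: int = 1
    gaussian_sigma: float = 1.0
    # a true nucleus must actually carry hematoxylin: mean H optical density
    # of a component below this floor marks background texture, not chromatin
    min_mean_h: float = 0.15
    # drop components clipped by the block border (their shape is truncated)
    exclude_border: bool = True
    stain_matrix: np.ndarray = field(default_factory=lambda: HE_STAIN_MATRIX.copy())


@dataclass
class NucleusRegion:
    """One segmented nucleus: mask, contour, ellipse fit and convex hull."""

    label: int
    bbox: tuple[int, int, int, int]  # (r0, c0, r1, c1), half-open
    mask: np.ndarray  # local binary mask within bbox
    area: float
    centroid: tuple[float, float]
    contour: np.ndarray  # (N, 2) global coordinates
    perimeter: float
    convex_area: float
    hull_perimeter: float
    hull_vertices: np.ndarray  # (K, 2) global coordinates
    eccentricity: float
    major_axis: float  # full axis lengths from the ellipse fit
    minor_axis: float
    ellipse_center: tuple[float, float]
    ellipse_rotation: float
    ellipse_residual: float
    extent: float
    feret_max: float
    feret_min: float
    moments_hu: np.ndarray


_LAPLACIAN_3X3 = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])


def _sharpen(channel: np.ndarray, sigma: float) -> np.ndarray:
    smooth = ndimage.gaussian_filter(channel, sigma=sigma)
    return smooth - ndimage.convolve(smooth, _LAPLACIAN_3X3, mode="nearest")


def _to_uint8_scale(x: np.ndarray) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    if hi - lo < 1e-12:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo) * 255.0


def _min_feret(points: np.ndarray, hull: ConvexHull) -> float:
    """Minimal projection width of a convex polygon (attained at an edge)."""
    verts = points[hull.vertices]
    edges = np.diff(np.vstack([verts, verts[:1]]), axis=0)
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    keep = lengths > 0
    normals = np.stack([-edges[keep, 1], edges[keep, 0]], axis=1) / lengths[keep, None]
    proj = verts @ normals.T
    widths = proj.max(axis=0) - proj.min(axis=0)
    return float(widths.min())


def _fit_ellipse(contour: np.ndarray, prop) -> tuple[tuple[float, float], float, float, float, float]:
    """Least-squares ellipse fit; falls back to the moments ellipse."""
    model = None
    if len(contour) >= 5:
        model = EllipseModel.from_estimate(contour[:, ::-1])  # (x, y) order
    if model:
        xc, yc = model.center
        a, b = model.axis_lengths
        if a > 0 and b > 0:
            resid = float(np.abs(model.residuals(contour[:, ::-1])).mean())
            major, minor = (2 * a, 2 * b) if a >= b else (2 * b, 2 * a)
            return (yc, xc), major, minor, float(model.theta), resid
    major = float(prop.axis_major_length)
    minor = float(prop.axis_minor_length)
    return tuple(prop.centroid), major, minor, float(prop.orientation), _POS_FLOOR


def segment_nuclei(
    block: np.ndarray, params: Optional[SegmentationParams] = None
) -> list[NucleusRegion]:
    """Segment nuclei in an RGB block.

    Pipeline: color deconvolution -> hematoxylin channel -> 3x3 Laplacian
    sharpening of the lightly smoothed channel -> Otsu on the sharpened
    channel (bright class = nuclei) -> local-mean adaptive refinement
    intersected with the Otsu mask -> opening + hole filling -> connected
    components with a minimum-area filter -> ellipse fit and convex hull
    per component.  An empty result is legal (e.g. an eosin-only block).
    """
    if params is None:
        params = SegmentationParams()

    channels = color_deconvolution(block, params.stain_matrix)
    sharp = _to_uint8_scale(_sharpen(channels.H, params.gaussian_sigma))

    hist = np.bincount(np.clip(np.rint(sharp), 0, 255).astype(np.uint8).ravel(), minlength=256)
    try:
        t = otsu_threshold(hist)
    except Exception:
        return []
    otsu_mask = sharp > t

    local = threshold_local(
        sharp, block_size=params.adaptive_window, method="gaussian",
        offset=-params.adaptive_offset,
    )
    mask = otsu_mask & (sharp > local)

    if params.opening_radius > 0:
        mask = opening(mask, disk(params.opening_radius))
    mask = ndimage.binary_fill_holes(mask)

    labels = sk_label(mask, connectivity=2)
    regions: list[NucleusRegion] = []
    H = channels.H
    nrows, ncols = labels.shape
    for prop in regionprops(labels):
        if prop.area < params.min_area:
            continue
        if H[tuple(prop.coords.T)].mean() < params.min_mean_h:
            continue
        r0_, c0_, r1_, c1_ = prop.bbox
        if params.exclude_border and (r0_ == 0 or c0_ == 0 or r1_ == nrows or c1_ == ncols):
            continue
        r0, c0, r1, c1 = prop.bbox
        local_mask = prop.image
        padded = np.pad(local_mask.astype(float), 1)
        contours = find_contours(padded, 0.5)
        if not contours:
            continue
        contour = max(contours, key=len) + np.array([r0 - 1, c0 - 1])
        if len(contour) < 5:
            continue
        coords = prop.coords.astype(float)
        try:
            hull = ConvexHull(coords)
        except QhullError:
            continue
        hull_vertices = coords[hull.vertices]
        # planar hull: "volume" is the polygon area, "area" its perimeter
        hull_perimeter = float(hull.area)
        convex_area = float(prop.area_convex)
        feret_min = _min_feret(coords, hull)
        centroid, major, minor, theta, resid = _fit_ellipse(contour, prop)

        regions.append(
            NucleusRegion(
                label=int(prop.label),
                bbox=(r0, c0, r1, c1),
                mask=local_mask,
                area=float(prop.area),
                centroid=tuple(prop.centroid),
                contour=contour,
                perimeter=float(prop.perimeter),
                convex_area=convex_area,
                hull_perimeter=hull_perimeter,
                hull_vertices=hull_vertices,
                eccentricity=float(prop.eccentricity),
                major_axis=major,
                minor_axis=minor,
                ellipse_center=centroid,
                ellipse_rotation=float(theta),
                ellipse_residual=resid,
                extent=float(prop.extent),
                feret_max=float(prop.feret_diameter_max),
                feret_min=feret_min,
                moments_hu=np.asarray(prop.moments_hu, dtype=float),
            )
        )
    return regions


def nucleus_descriptors(region: NucleusRegion) -> dict[str, float]:
    """The fixed 27-descriptor panel of one nucleus.

    All values are strictly positive: ratios are built from positive
    lengths/areas, near-zero quantities (eccentricity of a circle, residual
    of an exact ellipse) are floored at 1e-6, and Hu-moment magnitudes are
    exported as ``log10(|hu| + 1e-12) + 13``.
    """
    A = region.area
    P = region.perimeter
    r0, c0, r1, c1 = region.bbox
    bb_h, bb_w = r1 - r0, c1 - c0
    feret_max = region.feret_max
    feret_min = region.feret_min
    major = region.major_axis
    minor = region.minor_axis

    values = {
        "area": A,
        "perimeter": P,
        "perimeter_area_ratio": P / A,
        "equivalent_diameter": np.sqrt(4.0 * A / np.pi),
        "circularity": 4.0 * np.pi * A / P**2,
        "convex_area": region.convex_area,
        "solidity": A / region.convex_area,
        "convexity": region.hull_perimeter / P,
        "extent": region.extent,
        "eccentricity": region.eccentricity,
        "major_axis": major,
        "minor_axis": minor,
        "aspect_ratio": major / max(minor, _POS_FLOOR),
        "ellipse_residual": region.ellipse_residual,
        "feret_max": feret_max,
        "feret_min": feret_min,
        "feret_ratio": feret_max / max(feret_min, _POS_FLOOR),
        "bbox_aspect": max(bb_h, bb_w) / max(min(bb_h, bb_w), 1),
        "compactness": np.sqrt(4.0 * A / np.pi) / max(feret_max, _POS_FLOOR),
        "sphericity": 2.0 * np.sqrt(np.pi * A) / P,
    }
    for k, hu in enumerate(region.moments_hu, start=1):
        values[f"hu_{k}"] = np.log10(abs(float(hu)) + _HU_EPS) + _HU_SHIFT
    return {name: float(max(values[name], _POS_FLOOR)) for name in DESCRIPTOR_NAMES}
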