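"""Synthetic H&E-like tiles with known nuclei.

The generator paints rotated ellipses ("nuclei") in a hematoxylin tone over
an eosin-toned, softly textured background, producing tiles that exercise
the same processing chain as real H&E histology: tissue masking, color
deconvolution into stain channels, nuclei segmentation and shape
description.  Every nucleus is recorded in a ground-truth table (center,
semi-axes, rotation) so downstream segmentation and shape features can be
scored against analytic values.

Nucleus semi-axes are drawn log-normally around a target mean with a
controllable coefficient of variation ``heterogeneity``; log-normal keeps
every descriptor strictly positive, so the min/max-rate contrast statistic
is always well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from skimage.draw import ellipse as _draw_ellipse

from ._rng import substream

__all__ = [
    "HE_STAIN_MATRIX",
    "SlideSimParams",
    "StainParams",
    "SyntheticSlide",
    "PlacementError",
    "generate_slide",
    "ground_truth_descriptors",
    "rgb_from_od",
]

# Ruifrok–Johnston H&E stain vectors (rows: hematoxylin, eosin, residual),
# each row unit-normalized; the residual row completes an orthogonal basis.
_H = np.array([0.650, 0.704, 0.286])
_E = np.array([0.072, 0.990, 0.105])
_R = np.cross(_H / np.linalg.norm(_H), _E / np.linalg.norm(_E))
HE_STAIN_MATRIX = np.stack(
    [
        _H / np.linalg.norm(_H),
        _E / np.linalg.norm(_E),
        _R / np.linalg.norm(_R),
    ]
)


def rgb_from_od(od: np.ndarray) -> np.ndarray:
    """Map per-channel optical densities to 8-bit RGB intensities.

    Inverse of the transmission model ``OD = -log10((I + 1) / 256)`` used by
    the deconvolution step, so synthetic stains round-trip exactly.
    """
    od = np.asarray(od, dtype=float)
    return np.clip(256.0 * np.power(10.0, -od) - 1.0, 0.0, 255.0)


class PlacementError(RuntimeError):
    """Raised when non-overlapping nucleus placement fails."""


@dataclass(frozen=True)
class StainParams:
    """Mean RGB tones for nuclei and background plus pixel noise.

    Defaults are the pure-hematoxylin and pure-eosin colors implied by the
    standard H&E stain vectors at moderate stain concentrations, so the
    deconvolution step recovers a clean H channel.
    """

    hematoxylin_rgb: tuple[float, float, float] = tuple(rgb_from_od(0.85 * HE_STAIN_MATRIX[0]))
    eosin_rgb: tuple[float, float, float] = tuple(rgb_from_od(0.25 * HE_STAIN_MATRIX[1]))
    noise_sd: float = 3.0


@dataclass(frozen=True)
class SlideSimParams:
    """Parameters of one synthetic tile.

    Parameters
    ----------
    image_size : int
        Pixels per side (square tile), at least 64.
    n_nuclei : int
        Number of nuclei to place.
    axis_mean : (float, float)
        Mean major and minor semi-axis in pixels.
    heterogeneity : float
        Coefficient of variation of the log-normal semi-axis distribution;
        0 gives identical nuclei.
    stain : StainParams
        Nucleus/background tones and pixel noise.
    overlap_allowed : bool
        If False, placement rejects overlapping candidates (bounded retries).
    texture_amplitude : float
        Gray-level amplitude of the low-frequency background texture.
    seed : int
        Master seed; placement and stain noise use named substreams.
    """

    image_size: int = 512
    n_nuclei: int = 60
    axis_mean: tuple[float, float] = (12.0, 8.0)
    heterogeneity: float = 0.2
    stain: StainParams = field(default_factory=StainParams)
    overlap_allowed: bool = False
    texture_amplitude: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 64:
            raise ValueError("image_size must be at least 64")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be nonnegative")
        if min(self.axis_mean) <= 0:
            raise ValueError("axis means must be positive")
        if self.heterogeneity < 0:
            raise ValueError("heterogeneity must be nonnegative")


@dataclass
class SyntheticSlide:
    """A generated tile: RGB image, integer label mask and truth table."""

    image: np.ndarray  # (H, W, 3) uint8
    label_mask: np.ndarray  # (H, W) uint16, 0 = background
    truth_table: pd.DataFrame  # nucleus_id, center_row, center_col, semi_major, semi_minor, rotation
    params: Optional[SlideSimParams] = None


def _lognormal_axes(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    if cv == 0:
        return np.full(n, mean)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)


_MAX_ATTEMPTS_PER_NUCLEUS = 200


def generate_slide(params: SlideSimParams) -> SyntheticSlide:
    """Generate a tile; deterministic given ``params.seed``.

    Raises
    ------
    PlacementError
        If ``overlap_allowed`` is False and a nucleus cannot be placed
        without overlap within a bounded number of attempts.
    """
    size = params.image_size
    place_rng = substream(params.seed, "placement")
    noise_rng = substream(params.seed, "stain-noise")

    n = params.n_nuclei
    a = _lognormal_axes(place_rng, params.axis_mean[0], params.heterogeneity, n)
    b = _lognormal_axes(place_rng, params.axis_mean[1], params.heterogeneity, n)
    # keep the major/minor labelling honest if the draws cross
    major = np.maximum(a, b)
    minor = np.minimum(a, b)
    rotation = place_rng.uniform(0.0, np.pi, size=n)

    label = np.zeros((size, size), dtype=np.uint16)
    rows = []
    for i in range(n):
        margin = float(np.ceil(major[i])) + 2.0
        if 2 * margin >= size:
            raise PlacementError(f"nucleus {i + 1} does not fit in a {size}px tile")
        placed = False
        for _ in range(_MAX_ATTEMPTS_PER_NUCLEUS):
            cr = place_rng.uniform(margin, size - margin)
            cc = place_rng.uniform(margin, size - margin)
            rr, cc_px = _draw_ellipse(cr, cc, major[i], minor[i], shape=label.shape,
                                      rotation=rotation[i])
            if rr.size == 0:
                continue
            if not params.overlap_allowed and np.any(label[rr, cc_px] != 0):
                continue
            label[rr, cc_px] = i + 1
            rows.append((i + 1, cr, cc, major[i], minor[i], rotation[i]))
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"placement failure: could not place nucleus {i + 1} of {n} "
                f"without overlap after {_MAX_ATTEMPTS_PER_NUCLEUS} attempts"
            )

    truth = pd.DataFrame(
        rows,
        columns=["nucleus_id", "center_row", "center_col", "semi_major", "semi_minor", "rotation"],
    )

    # background: eosin tone plus a low-frequency luminance texture so the
    # global gray-level features are non-degenerate
    from scipy.ndimage import gaussian_filter

    texture = noise_rng.normal(0.0, 1.0, size=(size, size))
    texture = gaussian_filter(texture, sigma=size / 16.0)
    tsd = texture.std()
    if tsd > 0:
        texture = texture / tsd * params.texture_amplitude

    image = np.empty((size, size, 3), dtype=float)
    image[:] = np.asarray(params.stain.eosin_rgb)
    image += texture[..., None]
    image[label > 0] = np.asarray(params.stain.hematoxylin_rgb)
    image += noise_rng.normal(0.0, params.stain.noise_sd, size=image.shape)
    image = np.clip(image, 0, 255).astype(np.uint8)

    return SyntheticSlide(image=image, label_mask=label, truth_table=truth, params=params)


def ground_truth_descriptors(slide: SyntheticSlide) -> pd.DataFrame:
    """Analytic per-nucleus descriptors from the truth table.

    Area is the exact ellipse area pi*a*b, the perimeter uses Ramanujan's
    approximation, and eccentricity/aspect follow from the semi-axes.  This
    table is the oracle the pixel-level shape pipeline is scored against.
    """
    t = slide.truth_table
    a = t["semi_major"].to_numpy(dtype=float)
    b = t["semi_minor"].to_numpy(dtype=float)
    perimeter = np.pi * (3.0 * (a + b) - np.sqrt((3.0 * a + b) * (a + 3.0 * b)))
    return pd.DataFrame(
        {
            "nucleus_id": t["nucleus_id"].to_numpy(),
            "area": np.pi * a * b,
            "perimeter": perimeter,
            "major_axis": 2.0 * a,
            "minor_axis": 2.0 * b,
            "aspect_ratio": a / b,
            "eccentricity": np.sqrt(1.0 - (b / a) ** 2),
        }
    )
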