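"""Slide-level feature extraction: 18 + 135 = 153 features per slide.

Global texture is summarized by the standard first-order radiomics panel
(18 statistics of the gray ROI histogram).  Nucleus morphology is
summarized by aggregating the 27 per-nucleus shape descriptors over all
nuclei sampled from a slide with five statistics each — mean, sd, min, max
and the min/max rate ("mrate") — giving 135 shape features.  The mrate of a
descriptor lies in (0, 1]; smaller values mean greater nucleus-to-nucleus
morphological heterogeneity, and it equals 1 exactly when the descriptor is
constant across the sampled nuclei.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._rng import substream
from .errors import NoNucleiError
from .nuclei import DESCRIPTOR_NAMES, SegmentationParams, nucleus_descriptors, segment_nuclei
from .preprocess import make_gray_roi, select_foreground_block, tissue_mask

__all__ = [
    "GLOBAL_FEATURE_NAMES",
    "AGGREGATIONS",
    "FeatureConfig",
    "SlideFeatureVector",
    "global_gray_features",
    "aggregate_shape_features",
    "extract_slide_features",
    "shape_feature_names",
]

#: first-order statistics of the global gray ROI, in canonical order
GLOBAL_FEATURE_NAMES = (
    "energy",
    "total_energy",
    "entropy",
    "minimum",
    "percentile10",
    "percentile90",
    "maximum",
    "mean",
    "median",
    "interquartile_range",
    "range",
    "mean_absolute_deviation",
    "robust_mean_absolute_deviation",
    "root_mean_squared",
    "skewness",
    "kurtosis",
    "variance",
    "uniformity",
)

AGGREGATIONS = ("mean", "sd", "min", "max", "mrate")


def shape_feature_names() -> list[str]:
    """The 135 aggregated shape-feature names (descriptor x aggregation)."""
    return [f"{d}_{agg}" for d in DESCRIPTOR_NAMES for agg in AGGREGATIONS]


def global_gray_features(roi: np.ndarray, bin_width: int = 25) -> pd.Series:
    """First-order statistics of an 8-bit gray ROI.

    Histogram-based statistics (entropy in bits, uniformity) discretize the
    gray range with a fixed bin width of 25 levels.  Skewness and kurtosis
    of a constant ROI are reported as 0.
    """
    x = np.asarray(roi, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")
    if x.min() < 0 or x.max() > 255:
        raise ValueError("ROI values must lie in [0, 255]")

    edges = np.arange(0, 256 + bin_width, bin_width, dtype=float)
    counts, _ = np.histogram(x, bins=edges)
    p = counts[counts > 0] / x.size

    mean = x.mean()
    var = x.var()
    sd = np.sqrt(var)
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    inner = x[(x >= p10) & (x <= p90)]

    if sd > 0:
        skew = np.mean((x - mean) ** 3) / sd**3
        kurt = np.mean((x - mean) ** 4) / var**2
    else:
        skew = 0.0
        kurt = 0.0

    energy = float(np.sum(x**2))
    values = {
        "energy": energy,
        # unit pixel spacing: the volume-weighted energy coincides with energy
        "total_energy": energy,
        "entropy": float(-np.sum(p * np.log2(p))),
        "minimum": float(x.min()),
        "percentile10": float(p10),
        "percentile90": float(p90),
        "maximum": float(x.max()),
        "mean": float(mean),
        "median": float(p50),
        "interquartile_range": float(p75 - p25),
        "range": float(x.max() - x.min()),
        "mean_absolute_deviation": float(np.mean(np.abs(x - mean))),
        "robust_mean_absolute_deviation": float(np.mean(np.abs(inner - inner.mean()))),
        "root_mean_squared": float(np.sqrt(np.mean(x**2))),
        "skewness": float(skew),
        "kurtosis": float(kurt),
        "variance": float(var),
        "uniformity": float(np.sum(p**2)),
    }
    return pd.Series(values, index=list(GLOBAL_FEATURE_NAMES), dtype=float)


def aggregate_shape_features(per_nucleus: pd.DataFrame) -> pd.Series:
    """Aggregate a nuclei x 27 descriptor table into 135 slide features.

    Per descriptor: mean, sd (population sd, hence 0 for a single nucleus),
    min, max and mrate = min / max.  Requires at least one nucleus row.
    """
    if len(per_nucleus) == 0:
        raise NoNucleiError("no nuclei sampled")
    missing = [d for d in DESCRIPTOR_NAMES if d not in per_nucleus.columns]
    if missing:
        raise ValueError(f"missing descriptor columns: {missing}")

    out: dict[str, float] = {}
    for d in DESCRIPTOR_NAMES:
        col = per_nucleus[d].to_numpy(dtype=float)
        if np.any(col <= 0):
            raise ValueError(f"descriptor {d!r} must be strictly positive")
        out[f"{d}_mean"] = float(col.mean())
        out[f"{d}_sd"] = float(col.std(ddof=0))
        out[f"{d}_min"] = float(col.min())
        out[f"{d}_max"] = float(col.max())
        out[f"{d}_mrate"] = float(col.min() / col.max())
    return pd.Series(out, index=shape_feature_names(), dtype=float)


@dataclass(frozen=True)
class FeatureConfig:
    """Extraction geometry; defaults target full-scale slides and shrink
    automatically for smaller synthetic tiles.

    ``block_size`` is the foreground block side (default: the slide side,
    capped at 4000 px); ``roi_size`` the global gray ROI side (never
    upscaled); ``sample_block_size`` the side of the randomly sampled
    nuclei blocks; ``n_blocks`` x ``nuclei_per_block`` bounds the nucleus
    sample pooled per slide (20 x 20 = 400 by default).
    """

    block_size: Optional[int] = None
    roi_size: int = 1000
    sample_block_size: int = 1000
    n_blocks: int = 20
    nuclei_per_block: int = 20
    bin_width: int = 25
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)


@dataclass
class SlideFeatureVector:
    """18 global + 135 shape features of one slide, with provenance."""

    global_features: pd.Series
    shape_features: pd.Series
    provenance: dict

    def to_series(self) -> pd.Series:
        return pd.concat(
            [self.global_features.add_prefix("gray_"), self.shape_features]
        )

    def __len__(self) -> int:
        return len(self.global_features) + len(self.shape_features)


def extract_slide_features(
    image: np.ndarray, config: Optional[FeatureConfig] = None, seed: int = 0
) -> SlideFeatureVector:
    """End-to-end feature extraction for one slide image.

    Tissue mask -> coverage-maximizing foreground block -> global gray ROI
    -> 18 first-order features; then ``n_blocks`` random blocks inside the
    foreground, nuclei segmentation per block, a random sample of up to
    ``nuclei_per_block`` nuclei per block (all, if fewer), descriptor
    computation and aggregation into 135 shape features.  Deterministic
    given ``seed`` (substream "wsi-sampling").
    """
    if config is None:
        config = FeatureConfig()
    img = np.asarray(image)
    h, w = img.shape[:2]

    mask = tissue_mask(img)
    block_size = config.block_size if config.block_size is not None else min(h, w, 4000)
    block_size = min(block_size, h, w)
    r0, c0 = select_foreground_block(mask, block_size)
    block = img[r0 : r0 + block_size, c0 : c0 + block_size]

    roi = make_gray_roi(block, config.roi_size)
    global_feats = global_gray_features(roi, bin_width=config.bin_width)

    rng = substream(seed, "wsi-sampling")
    sbs = min(config.sample_block_size, block_size)
    rows: list[dict[str, float]] = []
    for _ in range(config.n_blocks):
        br = int(rng.integers(0, block_size - sbs + 1))
        bc = int(rng.integers(0, block_size - sbs + 1))
        sub = block[br : br + sbs, bc : bc + sbs]
        regions = segment_nuclei(sub, config.segmentation)
        if len(regions) > config.nuclei_per_block:
            keep = rng.choice(len(regions), size=config.nuclei_per_block, replace=False)
            regions = [regions[i] for i in keep]
        rows.extend(nucleus_descriptors(r) for r in regions)

    if not rows:
        raise NoNucleiError("no nuclei sampled from any block")
    per_nucleus = pd.DataFrame(rows)
    shape_feats = aggregate_shape_features(per_nucleus)

    return SlideFeatureVector(
        global_features=global_feats,
        shape_features=shape_feats,
        provenance={
            "seed": seed,
            "foreground_block": (r0, c0, block_size),
            "n_nuclei_sampled": len(per_nucleus),
        },
    )
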