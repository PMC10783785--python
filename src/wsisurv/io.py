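"""Plain-text / PNG round-tripping of slides, cohorts and feature tables."""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .cohorts import Cohort, CohortSimParams
from .slides import SlideSimParams, StainParams, SyntheticSlide

__all__ = [
    "write_slide",
    "read_slide",
    "write_cohort",
    "read_cohort",
    "write_feature_matrix",
    "read_feature_matrix",
    "params_to_yaml",
    "slide_params_from_yaml",
    "cohort_params_from_yaml",
]


def write_slide(slide: SyntheticSlide, directory, stem: str = "slide") -> dict[str, Path]:
    """Write image (8-bit RGB PNG), label mask (16-bit PNG) and truth CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": directory / f"{stem}.png",
        "mask": directory / f"{stem}_mask.png",
        "truth": directory / f"{stem}_truth.csv",
    }
    iio.imwrite(paths["image"], slide.image)
    iio.imwrite(paths["mask"], slide.label_mask.astype(np.uint16))
    slide.truth_table.to_csv(paths["truth"], index=False)
    return paths


def read_slide(directory, stem: str = "slide") -> SyntheticSlide:
    directory = Path(directory)
    return SyntheticSlide(
        image=iio.imread(directory / f"{stem}.png"),
        label_mask=iio.imread(directory / f"{stem}_mask.png").astype(np.uint16),
        truth_table=pd.read_csv(directory / f"{stem}_truth.csv"),
    )


def write_cohort(cohort: Cohort, directory) -> dict[str, Path]:
    """Cohort table as CSV, expression and image features as TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    core = cohort.covariates.copy()
    core.insert(0, "time", cohort.time)
    core.insert(1, "event", cohort.event)
    paths = {"cohort": directory / "cohort.csv", "expression": directory / "expression.tsv"}
    core.to_csv(paths["cohort"], index_label="patient_id")
    cohort.expression.to_csv(paths["expression"], sep="\t", index_label="patient_id")
    if cohort.image_features is not None:
        paths["image_features"] = directory / "image_features.tsv"
        cohort.image_features.to_csv(paths["image_features"], sep="\t", index_label="patient_id")
    return paths


def read_cohort(directory) -> Cohort:
    directory = Path(directory)
    core = pd.read_csv(directory / "cohort.csv", index_col="patient_id").rename_axis(None)
    expression = pd.read_csv(
        directory / "expression.tsv", sep="\t", index_col="patient_id"
    ).rename_axis(None)
    img_path = directory / "image_features.tsv"
    image_features = (
        pd.read_csv(img_path, sep="\t", index_col="patient_id").rename_axis(None)
        if img_path.exists()
        else None
    )
    return Cohort(
        time=core["time"].to_numpy(dtype=float),
        event=core["event"].to_numpy(dtype=int),
        covariates=core.drop(columns=["time", "event"]),
        expression=expression,
        image_features=image_features,
    )


def write_feature_matrix(features: pd.DataFrame, path) -> Path:
    """Feature matrix as TSV: rows = slides, named feature columns."""
    path = Path(path)
    features.to_csv(path, sep="\t", index_label="slide_id")
    return path


def read_feature_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="slide_id").rename_axis(None)


def _clean(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return [_clean(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _clean(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def params_to_yaml(params, path) -> Path:
    """Serialize SlideSimParams / CohortSimParams to a YAML config."""
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump({type(params).__name__: _clean(dataclasses.asdict(params))}, fh)
    return path


def slide_params_from_yaml(path) -> SlideSimParams:
    with open(path) as fh:
        raw = yaml.safe_load(fh)["SlideSimParams"]
    stain = raw.pop("stain", None)
    kwargs = dict(raw)
    if "axis_mean" in kwargs:
        kwargs["axis_mean"] = tuple(kwargs["axis_mean"])
    if stain is not None:
        kwargs["stain"] = StainParams(
            hematoxylin_rgb=tuple(stain["hematoxylin_rgb"]),
            eosin_rgb=tuple(stain["eosin_rgb"]),
            noise_sd=stain["noise_sd"],
        )
    return SlideSimParams(**kwargs)


def cohort_params_from_yaml(path) -> CohortSimParams:
    with open(path) as fh:
        raw = yaml.safe_load(fh)["CohortSimParams"]
    if raw.get("gene_cov") is not None:
        raw["gene_cov"] = np.asarray(raw["gene_cov"], dtype=float)
    return CohortSimParams(**raw)
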