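"""Simulated patient cohorts with known survival structure.

A cohort carries recurrence-free-survival (RFS) follow-up (time in days,
event indicator), clinicopathologic covariates, a log-scale marker-gene
expression matrix with configurable covariance, and an image-feature matrix
(either simulated as correlated Gaussians or extracted from synthetic
tiles).  Event times follow a Cox model with Weibull baseline hazard

    h(t | x) = (k / lam) * (t / lam)**(k - 1) * exp(beta' x_c),

with x_c the covariates centered at their sample means, so ``true_beta`` is
the log-hazard ratio per unit of a (unit-variance, by default) feature.
Censoring is the minimum of an independent exponential time (loss to
follow-up) and an administrative cap (study end); the default rate yields a
realized event fraction near 53% at the default effect sizes, the scale of
event rates seen in resected hepatocellular carcinoma cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .slides import SyntheticSlide

__all__ = [
    "CohortSimParams",
    "Cohort",
    "ar1_cov",
    "generate_cohort",
    "default_true_beta",
]

DOMAINS = ("clin", "image", "genes")


def ar1_cov(n: int, rho: float = 0.4, sigma: float = 1.0) -> np.ndarray:
    """AR(1) covariance ``sigma^2 * rho**|i-j|`` — a simple stand-in for the
    banded correlation structure of co-regulated marker genes."""
    idx = np.arange(n)
    return sigma**2 * rho ** np.abs(idx[:, None] - idx[None, :])


@dataclass(frozen=True)
class CohortSimParams:
    """Simulation parameters for one cohort.

    ``censor_rate`` is the exponential loss-to-follow-up rate per day;
    ``admin_censor_time`` the administrative cap in days.  ``true_beta``
    maps feature names (gene or image columns) to log-hazard coefficients;
    ``None`` selects a sparse default of three genes and one image feature.
    """

    n_patients: int = 231
    n_genes: int = 66
    gene_cov: Optional[np.ndarray] = None
    gene_mean: float = 2.0
    n_image_features: int = 20
    image_rho: float = 0.3
    true_beta: Optional[Mapping[str, float]] = None
    baseline_shape: float = 1.1
    baseline_scale: float = 900.0
    censor_rate: float = 1.0 / 1080.0
    admin_censor_time: float = 3650.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be at least 2")
        if self.baseline_shape <= 0 or self.baseline_scale <= 0:
            raise ValueError("Weibull baseline parameters must be positive")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be nonnegative")
        if self.gene_cov is not None:
            cov = np.asarray(self.gene_cov, dtype=float)
            if cov.shape != (self.n_genes, self.n_genes):
                raise ValueError("gene_cov shape must be (n_genes, n_genes)")
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise ValueError("gene_cov must be symmetric")
            if np.linalg.eigvalsh(cov).min() < -1e-8:
                raise ValueError("gene_cov must be positive semi-definite")


@dataclass
class Cohort:
    """Per-patient follow-up plus the three covariate domains."""

    time: np.ndarray  # days, > 0
    event: np.ndarray  # 1 = recurrence, 0 = censored
    covariates: pd.DataFrame  # clinicopathologic variables (numeric)
    expression: pd.DataFrame  # patients x genes, log(FPKM + 1)-like scale
    image_features: Optional[pd.DataFrame] = None
    truth: Optional[dict] = None  # linear_predictor, true_beta, event_time
    params: Optional[CohortSimParams] = None

    @property
    def n_patients(self) -> int:
        return len(self.time)

    def domain(self, name: str) -> pd.DataFrame:
        """Feature matrix of one input domain: 'clin', 'image' or 'genes'."""
        if name == "clin":
            return self.covariates
        if name == "genes":
            return self.expression
        if name == "image":
            if self.image_features is None:
                raise ValueError("cohort has no image features")
            return self.image_features
        raise KeyError(f"unknown domain {name!r}; expected one of {DOMAINS}")

    def subset(self, idx: np.ndarray) -> "Cohort":
        idx = np.asarray(idx)
        return Cohort(
            time=self.time[idx],
            event=self.event[idx],
            covariates=self.covariates.iloc[idx],
            expression=self.expression.iloc[idx],
            image_features=None if self.image_features is None else self.image_features.iloc[idx],
            truth=None,
            params=self.params,
        )


def default_true_beta(gene_names: Sequence[str], image_names: Sequence[str]) -> dict[str, float]:
    """Sparse default effects: three genes and one image feature.

    Signs mirror a plausible immune/morphology story: two protective
    markers, one hazardous marker, and a protective nucleus-contrast image
    feature (less morphological heterogeneity, lower recurrence hazard).
    """
    beta: dict[str, float] = {}
    genes = list(gene_names)
    beta[genes[5 % len(genes)]] = 0.45
    beta[genes[12 % len(genes)]] = -0.45
    beta[genes[33 % len(genes)]] = 0.40
    images = list(image_names)
    if images:
        preferred = "area_mrate" if "area_mrate" in images else images[7 % len(images)]
        beta[preferred] = -0.55
    return beta


def _simulate_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age": rng.normal(60.0, 10.0, size=n).round(1),
            "bmi": rng.normal(26.0, 4.0, size=n).round(1),
            "male": rng.integers(0, 2, size=n),
            "grade": rng.integers(1, 5, size=n),
            "stage": rng.integers(1, 5, size=n),
        }
    )


def generate_cohort(
    params: CohortSimParams,
    slides: Optional[Sequence[SyntheticSlide]] = None,
    feature_config=None,
) -> Cohort:
    """Simulate a cohort; deterministic given ``params.seed``.

    If ``slides`` are given (one per patient), image features are extracted
    from them with the pixel pipeline; otherwise they are simulated as
    correlated Gaussians.  Event times are inverted from the Weibull
    cumulative hazard: with U ~ Uniform(0,1),

        T = lam * (-log(U) * exp(-beta' x_c)) ** (1 / k).
    """
    n = params.n_patients
    ids = [f"P{i:04d}" for i in range(n)]

    expr_rng = substream(params.seed, "expression")
    gene_names = [f"gene_{i:02d}" for i in range(params.n_genes)]
    cov = params.gene_cov if params.gene_cov is not None else ar1_cov(params.n_genes)
    expression = pd.DataFrame(
        expr_rng.multivariate_normal(
            np.full(params.n_genes, params.gene_mean), cov, size=n, method="eigh"
        ),
        index=ids,
        columns=gene_names,
    )

    if slides is not None:
        if len(slides) != n:
            raise ValueError("need exactly one slide per patient")
        from .features import extract_slide_features

        vecs = []
        for i, slide in enumerate(slides):
            seed = slide.params.seed if slide.params is not None else i
            vecs.append(extract_slide_features(slide.image, config=feature_config, seed=seed).to_series())
        image_features = pd.DataFrame(vecs, index=ids)
    else:
        img_rng = substream(params.seed, "image-features")
        img_names = [f"img_{i:02d}" for i in range(params.n_image_features)]
        image_features = pd.DataFrame(
            img_rng.multivariate_normal(
                np.zeros(params.n_image_features),
                ar1_cov(params.n_image_features, rho=params.image_rho),
                size=n,
                method="eigh",
            ),
            index=ids,
            columns=img_names,
        )

    cov_rng = substream(params.seed, "covariates")
    covariates = _simulate_covariates(cov_rng, n)
    covariates.index = pd.Index(ids)

    beta = params.true_beta
    if beta is None:
        beta = default_true_beta(expression.columns, image_features.columns)
    beta = pd.Series(beta, dtype=float)
    pool = pd.concat([image_features, expression, covariates], axis=1)
    missing = [name for name in beta.index if name not in pool.columns]
    if missing:
        raise KeyError(f"true_beta names not among cohort features: {missing}")
    X = pool[beta.index]
    lp = ((X - X.mean()) @ beta).to_numpy(dtype=float)

    surv_rng = substream(params.seed, "survival")
    u = surv_rng.uniform(size=n)
    k, lam = params.baseline_shape, params.baseline_scale
    event_time = lam * (-np.log(u) * np.exp(-lp)) ** (1.0 / k)
    if params.censor_rate > 0:
        c_lost = surv_rng.exponential(1.0 / params.censor_rate, size=n)
    else:
        c_lost = np.full(n, np.inf)
    censor_time = np.minimum(c_lost, params.admin_censor_time)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    time = np.maximum(time, 1e-8)

    return Cohort(
        time=time,
        event=event,
        covariates=covariates,
        expression=expression,
        image_features=image_features,
        truth={"linear_predictor": lp, "true_beta": beta, "event_time": event_time},
        params=params,
    )
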