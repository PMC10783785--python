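"""Median-split risk stratification and survival comparison.

Patients are split at the sample median of the risk score ("at or below"
-> lower risk, "above" -> higher risk), the two arms are compared with
Kaplan–Meier curves (Greenwood log(-log) 95% bands, Brookmeyer–Crowley
median CI) and a two-group log-rank test, and the continuous score's
per-unit hazard ratio comes from a univariate Cox fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "KMEstimate",
    "StratificationResult",
    "median_split",
    "kaplan_meier",
    "logrank_test",
    "score_hazard_ratio",
    "stratify_by_score",
    "plot_km",
]

LOWER, HIGHER = "lower", "higher"


def median_split(scores) -> np.ndarray:
    """Labels 'lower' (score <= sample median) / 'higher' (above).

    The median is the midpoint of the two central order statistics for even
    n, so with all-distinct scores the groups differ in size by at most one
    and ties at the median all fall in the lower-risk arm.
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 patients to split")
    med = np.median(s)
    return np.where(s <= med, LOWER, HIGHER)


@dataclass
class KMEstimate:
    """Product-limit survival estimate with 95% bands and median RFS."""

    times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    median: float  # np.inf when not reached
    median_ci: tuple[float, float]
    n: int
    n_events: int

    @property
    def median_reached(self) -> bool:
        return np.isfinite(self.median)


def kaplan_meier(time, event, alpha: float = 0.05) -> KMEstimate:
    """Kaplan–Meier estimate with Greenwood log(-log) confidence bands.

    The median is the first time the estimate drops to 0.5 or below
    (infinite when never reached); its CI inverts the confidence band
    (Brookmeyer–Crowley style).
    """
    from lifelines import KaplanMeierFitter
    from lifelines.utils import median_survival_times

    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(time, event_observed=event)
    ci = kmf.confidence_interval_
    med = float(kmf.median_survival_time_)
    med_ci_df = median_survival_times(ci)
    lo, hi = float(med_ci_df.iloc[0, 0]), float(med_ci_df.iloc[0, 1])
    return KMEstimate(
        times=kmf.survival_function_.index.to_numpy(dtype=float),
        survival=kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float),
        ci_lower=ci.iloc[:, 0].to_numpy(dtype=float),
        ci_upper=ci.iloc[:, 1].to_numpy(dtype=float),
        median=med,
        median_ci=(lo, hi),
        n=len(time),
        n_events=int(event.sum()),
    )


def logrank_test(time, event, groups) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    from lifelines.statistics import logrank_test as _lr

    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {len(labels)}")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    a = groups == labels[0]
    res = _lr(time[a], time[~a], event_observed_A=event[a], event_observed_B=event[~a])
    return float(res.test_statistic), float(res.p_value)


def score_hazard_ratio(score, time, event) -> dict:
    """Per-unit hazard ratio of a continuous score (univariate Cox).

    Returns hr, ci_lower, ci_upper (95% Wald), p_value and log_hr.
    """
    from lifelines import CoxPHFitter

    score = np.asarray(score, dtype=float)
    if score.std() == 0:
        raise ValueError("score has zero variance")
    df = pd.DataFrame(
        {"score": score, "_time": np.asarray(time, float), "_event": np.asarray(event, int)}
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph = CoxPHFitter()
        cph.fit(df, duration_col="_time", event_col="_event")
    beta = float(cph.params_["score"])
    se = float(cph.standard_errors_["score"])
    return {
        "hr": float(np.exp(beta)),
        "ci_lower": float(np.exp(beta - 1.959963984540054 * se)),
        "ci_upper": float(np.exp(beta + 1.959963984540054 * se)),
        "p_value": float(cph.summary.loc["score", "p"]),
        "log_hr": beta,
    }


@dataclass
class StratificationResult:
    """Everything the median-split analysis produces."""

    labels: np.ndarray
    km: dict[str, KMEstimate]
    logrank_statistic: float
    logrank_p: float
    hazard_ratio: dict

    @property
    def group_sizes(self) -> dict[str, int]:
        return {g: int((self.labels == g).sum()) for g in (LOWER, HIGHER)}

    def summary(self) -> dict:
        return {
            "group_sizes": self.group_sizes,
            "median_rfs": {g: self.km[g].median for g in self.km},
            "median_rfs_ci": {g: self.km[g].median_ci for g in self.km},
            "logrank_statistic": self.logrank_statistic,
            "logrank_p": self.logrank_p,
            "hazard_ratio": self.hazard_ratio,
        }


def stratify_by_score(score, time, event) -> StratificationResult:
    """Run the full stratification: split, KM per arm, log-rank, per-unit HR."""
    labels = median_split(score)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    km = {
        g: kaplan_meier(time[labels == g], event[labels == g])
        for g in (LOWER, HIGHER)
        if (labels == g).any()
    }
    stat, p = logrank_test(time, event, labels)
    hr = score_hazard_ratio(score, time, event)
    return StratificationResult(
        labels=labels, km=km, logrank_statistic=stat, logrank_p=p, hazard_ratio=hr
    )


def plot_km(result: StratificationResult, ax=None, path: Optional[str] = None):
    """Kaplan–Meier curves per risk arm with shaded 95% bands."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    colors = {LOWER: "tab:blue", HIGHER: "tab:red"}
    for g, est in result.km.items():
        ax.step(est.times, est.survival, where="post",
                label=f"{g}-risk (n={est.n})", color=colors.get(g))
        ax.fill_between(est.times, est.ci_lower, est.ci_upper, step="post",
                        alpha=0.2, color=colors.get(g))
    ax.set_xlabel("days since diagnosis")
    ax.set_ylabel("recurrence-free survival")
    ax.set_ylim(0, 1.02)
    ax.legend()
    ax.set_title(f"log-rank p = {result.logrank_p:.2g}")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
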