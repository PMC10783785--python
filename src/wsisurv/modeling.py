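"""Lasso-Cox risk scores, stacked integration and repeated-split evaluation.

The modeling framework mirrors a common multi-domain prognostic design:

* per input domain (clinicopathologic variables, image features, marker-gene
  expression) an L1-penalized Cox model is fitted on the training split, the
  penalty tuned by 3-fold cross-validated partial-likelihood deviance;
* a risk score is the linear combination ``s = X beta`` (no intercept);
* domains are integrated either by pooling their features into one
  Lasso-Cox fit, or by *stacking*: an unpenalized Cox model over the
  domain-wise training scores produces a composite score;
* performance is the Harrell C-index (and time-dependent AUC with
  censoring weights) on the held-out third, averaged over 20 random 2:1
  splits;
* the final model is the simplest one among those whose test C-index lies
  between the median and the upper quartile of the split distribution;
* significance is assessed against a permutation null: outcomes are
  reshuffled against covariates, the full pipeline re-run, and a normal
  distribution fitted to the null mean C-indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream, substream_seed
from .cohorts import Cohort
from .errors import DegenerateNullError

__all__ = [
    "RiskModel",
    "IntegrationSpec",
    "SplitEvaluation",
    "PermutationResult",
    "fit_lasso_cox",
    "risk_score",
    "harrell_cindex",
    "time_dependent_auc",
    "default_time_grid",
    "split_cohort",
    "evaluate_integration",
    "mean_cindex",
    "select_final_model",
    "permutation_test",
]


# ---------------------------------------------------------------------------
# risk models


@dataclass
class RiskModel:
    """A sparse linear Cox risk score over named features.

    ``coefficients`` are on the original feature scale (features are
    standardized internally during fitting only).
    """

    feature_names: list[str]
    coefficients: pd.Series
    penalty: float
    domain: str = "pooled"
    cv_deviance: Optional[pd.Series] = None  # mean CV deviance per penalty

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.coefficients.to_numpy()))


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


def _breslow_loglik(LP: np.ndarray, time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Breslow partial log-likelihood for each column of ``LP`` (n x k)."""
    order = np.argsort(time, kind="stable")
    LP = LP[order]
    t = time[order]
    e = event[order]
    # suffix log-sum-exp of the linear predictors = log risk-set sums
    suffix = np.logaddexp.accumulate(LP[::-1], axis=0)[::-1]
    first = np.searchsorted(t, t, side="left")  # tie groups share a risk set
    ev = e == 1
    return (LP[ev] - suffix[first[ev]]).sum(axis=0)


def fit_lasso_cox(
    X,
    time: np.ndarray,
    event: np.ndarray,
    n_folds: int = 3,
    alphas: Optional[Sequence[float]] = None,
    n_alphas: int = 100,
    alpha_min_ratio: float = 0.001,
    seed: int = 0,
    domain: str = "pooled",
) -> RiskModel:
    """Fit an L1-penalized Cox model with cross-validated penalty choice.

    The penalty grid is 100 log-spaced values from the smallest penalty
    giving the null model down to 0.001 of it (glmnet convention); the
    selected penalty minimizes the mean cross-validated partial-likelihood
    deviance (Verweij–van Houwelingen), computed over ``n_folds`` folds
    drawn from the seeded substream "cv-folds".  Features are standardized
    internally; coefficients are reported on the original scale.
    """
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    X = _as_frame(X)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < 2:
        raise ValueError("need at least 2 events to fit a Cox model")

    sd = X.std(ddof=0)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(f"dropping constant feature columns: {constant}", stacklevel=2)
        X = X.drop(columns=constant)
        sd = sd.drop(constant)
    if X.shape[1] == 0:
        raise ValueError("no non-constant features to fit")

    mu = X.mean()
    Xs = ((X - mu) / sd).to_numpy(dtype=float)
    y = Surv.from_arrays(event=event.astype(bool), time=time)

    def make_model(grid=None):
        kwargs = dict(l1_ratio=1.0, fit_baseline_model=False, max_iter=200_000)
        if grid is None:
            return CoxnetSurvivalAnalysis(
                n_alphas=n_alphas, alpha_min_ratio=alpha_min_ratio, **kwargs
            )
        return CoxnetSurvivalAnalysis(alphas=list(grid), **kwargs)

    path = make_model(alphas).fit(Xs, y)
    grid = np.asarray(path.alphas_, dtype=float)

    cv_dev = None
    if len(grid) > 1 and n_folds >= 2:
        rng = substream(seed, "cv-folds")
        perm = rng.permutation(len(time))
        folds = np.array_split(perm, n_folds)
        dev = np.zeros(len(grid))
        used = 0
        for fold in folds:
            train = np.setdiff1d(perm, fold)
            if event[train].sum() < 2:
                continue
            fm = make_model(grid).fit(Xs[train], y[train])
            coefs = np.asarray(fm.coef_)  # (p, k)
            k = coefs.shape[1]
            ll_all = _breslow_loglik(Xs @ coefs, time, event)
            ll_train = _breslow_loglik(Xs[train] @ coefs, time[train], event[train])
            dev[:k] += -2.0 * (ll_all - ll_train)
            dev[k:] += np.inf  # penalties the fold path did not reach
            used += 1
        if used == 0:
            raise ValueError("no usable cross-validation folds (too few events)")
        cv_dev = pd.Series(dev / used, index=grid)
        best_idx = int(np.argmin(cv_dev.to_numpy()))  # ties -> larger penalty
    else:
        best_idx = len(grid) - 1 if alphas is None else int(np.argmin(grid))

    best_alpha = float(grid[best_idx])
    beta_std = np.asarray(path.coef_)[:, best_idx]
    beta = pd.Series(beta_std / sd.to_numpy(), index=X.columns, dtype=float)

    return RiskModel(
        feature_names=list(X.columns),
        coefficients=beta,
        penalty=best_alpha,
        domain=domain,
        cv_deviance=cv_dev,
    )


def risk_score(model: RiskModel, X) -> np.ndarray:
    """Linear risk score ``s = X beta`` over the model's named features."""
    X = _as_frame(X)
    missing = [f for f in model.feature_names if f not in X.columns]
    if missing:
        raise KeyError(f"missing feature columns: {missing}")
    return X[model.feature_names].to_numpy(dtype=float) @ model.coefficients.to_numpy()


# ---------------------------------------------------------------------------
# evaluation metrics


def harrell_cindex(scores, time, event) -> float:
    """Harrell's concordance index.

    Comparable pairs are those where the shorter observed time ends in an
    event; a pair is concordant when the earlier failure has the higher
    score, tied scores count one half.  Raises if no pair is comparable.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    earlier = (t[:, None] < t[None, :]) & (e[:, None] == 1)
    n_comp = earlier.sum()
    if n_comp == 0:
        raise ValueError("C-index undefined: no comparable pairs")
    conc = (earlier & (s[:, None] > s[None, :])).sum()
    ties = (earlier & (s[:, None] == s[None, :])).sum()
    return float((conc + 0.5 * ties) / n_comp)


def default_time_grid(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Deciles of the observed event times lying between the 10th and 80th
    percentiles of follow-up."""
    time = np.asarray(time, dtype=float)
    lo, hi = np.percentile(time, [10, 80])
    ev = time[(np.asarray(event) == 1) & (time >= lo) & (time <= hi)]
    if ev.size == 0:
        return np.array([])
    return np.unique(np.percentile(ev, np.arange(10, 100, 10)))


def time_dependent_auc(
    scores,
    train_time,
    train_event,
    test_time,
    test_event,
    time_grid,
) -> tuple[np.ndarray, float]:
    """Cumulative/dynamic time-dependent AUC over a time grid.

    Censoring is handled by inverse-probability-of-censoring weights
    estimated from the *training* data (Kaplan–Meier of the censoring
    distribution).  Returns the AUC(t) curve and its unweighted mean over
    the grid.  Grid points beyond the last observed test time are rejected.
    """
    from sksurv.metrics import cumulative_dynamic_auc
    from sksurv.util import Surv

    grid = np.atleast_1d(np.asarray(time_grid, dtype=float))
    test_time = np.asarray(test_time, dtype=float)
    if grid.size == 0:
        raise ValueError("empty time grid")
    if grid.max() >= test_time.max():
        raise ValueError("time grid extends beyond the last observed test time")
    surv_train = Surv.from_arrays(np.asarray(train_event).astype(bool), np.asarray(train_time))
    surv_test = Surv.from_arrays(np.asarray(test_event).astype(bool), test_time)
    auc, _ = cumulative_dynamic_auc(surv_train, surv_test, np.asarray(scores, float), grid)
    return auc, float(np.mean(auc))


def split_cohort(
    n: int,
    train_frac: float = 2.0 / 3.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Random 2:1 split: |train| = round(train_frac * n), no stratification."""
    if n < 3:
        raise ValueError("need at least 3 subjects to split")
    if rng is None:
        rng = substream(0 if seed is None else seed, "splits")
    k = int(round(train_frac * n))
    perm = rng.permutation(n)
    return np.sort(perm[:k]), np.sort(perm[k:])


# ---------------------------------------------------------------------------
# integration over repeated splits


@dataclass(frozen=True)
class IntegrationSpec:
    """Which domains participate and how they are combined.

    mode: 'single' (one domain), 'pooled' (features concatenated into one
    Lasso-Cox fit) or 'stacked' (unpenalized Cox over domain-wise risk
    scores).  ``include_interactions`` adds pairwise products of domain
    scores in stacked mode.
    """

    mode: str
    domains: tuple[str, ...]
    include_interactions: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("single", "pooled", "stacked"):
            raise ValueError(f"unknown integration mode {self.mode!r}")
        if self.mode == "single" and len(self.domains) != 1:
            raise ValueError("single-domain integration takes exactly one domain")
        if self.mode == "stacked" and len(self.domains) < 2:
            raise ValueError("stacked integration requires at least 2 domains")


@dataclass
class SplitEvaluation:
    """One train/test replicate: fitted model(s) and test metrics."""

    split_id: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    domain_models: dict[str, RiskModel]
    stack_coefficients: Optional[pd.Series]
    cindex: float
    auc_times: np.ndarray = field(default_factory=lambda: np.array([]))
    auc_values: np.ndarray = field(default_factory=lambda: np.array([]))
    mean_auc: float = float("nan")
    n_nonzero: int = 0


def _fit_second_level(scores: pd.DataFrame, time, event) -> pd.Series:
    """Unpenalized Cox over the domain-score columns (Efron ties)."""
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    keep = scores.columns[scores.std(ddof=0) > 1e-12]
    if len(keep) == 0:
        return pd.Series(0.0, index=scores.columns)
    df = scores[keep].copy()
    df["_time"] = np.asarray(time, dtype=float)
    df["_event"] = np.asarray(event, dtype=int)
    for penalizer in (0.0, 0.1):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph = CoxPHFitter(penalizer=penalizer)
                cph.fit(df, duration_col="_time", event_col="_event")
            coefs = cph.params_
            break
        except (ConvergenceError, ValueError):
            continue
    else:
        coefs = pd.Series(0.0, index=keep)
    return coefs.reindex(scores.columns, fill_value=0.0)


def _evaluate_one_split(
    cohort: Cohort,
    spec: IntegrationSpec,
    split_id: int,
    train: np.ndarray,
    test: np.ndarray,
    seed: int,
    compute_auc: bool,
    lasso_kwargs: dict,
) -> SplitEvaluation:
    time, event = cohort.time, cohort.event
    domain_models: dict[str, RiskModel] = {}
    stack_coefs: Optional[pd.Series] = None

    if spec.mode in ("single", "pooled"):
        X = pd.concat([cohort.domain(d) for d in spec.domains], axis=1)
        model = fit_lasso_cox(
            X.iloc[train], time[train], event[train],
            seed=substream_seed(seed, "cv", split_id),
            domain="+".join(spec.domains), **lasso_kwargs,
        )
        domain_models["+".join(spec.domains)] = model
        test_scores = risk_score(model, X.iloc[test])
        n_nonzero = model.n_nonzero
    else:  # stacked
        train_scores, test_score_cols = {}, {}
        for i, d in enumerate(spec.domains):
            Xd = cohort.domain(d)
            m = fit_lasso_cox(
                Xd.iloc[train], time[train], event[train],
                seed=substream_seed(seed, f"cv-{d}", split_id),
                domain=d, **lasso_kwargs,
            )
            domain_models[d] = m
            train_scores[d] = risk_score(m, Xd.iloc[train])
            test_score_cols[d] = risk_score(m, Xd.iloc[test])
        S_train = pd.DataFrame(train_scores)
        S_test = pd.DataFrame(test_score_cols)
        if spec.include_interactions:
            for i, d1 in enumerate(spec.domains):
                for d2 in spec.domains[i + 1 :]:
                    S_train[f"{d1}*{d2}"] = S_train[d1] * S_train[d2]
                    S_test[f"{d1}*{d2}"] = S_test[d1] * S_test[d2]
        stack_coefs = _fit_second_level(S_train, time[train], event[train])
        test_scores = S_test.to_numpy() @ stack_coefs.to_numpy()
        n_nonzero = sum(m.n_nonzero for m in domain_models.values()) + int(
            np.count_nonzero(stack_coefs.to_numpy())
        )

    cindex = harrell_cindex(test_scores, time[test], event[test])

    auc_times = np.array([])
    auc_values = np.array([])
    mean_auc = float("nan")
    if compute_auc:
        grid = default_time_grid(time[train], event[train])
        tmin, tmax = time[test].min(), time[test].max()
        grid = grid[(grid > tmin) & (grid < tmax)]
        if grid.size > 0:
            try:
                auc_values, mean_auc = time_dependent_auc(
                    test_scores, time[train], event[train], time[test], event[test], grid
                )
                auc_times = grid
            except ValueError:
                pass

    return SplitEvaluation(
        split_id=split_id,
        train_idx=train,
        test_idx=test,
        domain_models=domain_models,
        stack_coefficients=stack_coefs,
        cindex=cindex,
        auc_times=auc_times,
        auc_values=auc_values,
        mean_auc=mean_auc,
        n_nonzero=n_nonzero,
    )


def evaluate_integration(
    cohort: Cohort,
    spec: IntegrationSpec,
    n_splits: int = 20,
    seed: int = 0,
    compute_auc: bool = True,
    lasso_kwargs: Optional[dict] = None,
) -> list[SplitEvaluation]:
    """Evaluate one integration mode over repeated random 2:1 splits."""
    lasso_kwargs = dict(lasso_kwargs or {})
    rng = substream(seed, "splits")
    out = []
    for split_id in range(n_splits):
        train, test = split_cohort(cohort.n_patients, rng=rng)
        out.append(
            _evaluate_one_split(
                cohort, spec, split_id, train, test, seed, compute_auc, lasso_kwargs
            )
        )
    return out


def mean_cindex(evaluations: Sequence[SplitEvaluation]) -> float:
    return float(np.mean([e.cindex for e in evaluations]))


def select_final_model(evaluations: Sequence[SplitEvaluation]) -> SplitEvaluation:
    """The simplest model among those with C-index in [median, Q3].

    Quartiles are linear-interpolation quantiles of the split C-indices,
    both ends inclusive.  Simplicity = total nonzero coefficients (stacked
    models count both levels); ties go to the higher C-index, then the
    lowest split id.
    """
    if len(evaluations) == 0:
        raise ValueError("no evaluations to select from")
    C = np.array([e.cindex for e in evaluations])
    med, q3 = np.percentile(C, [50, 75])
    eps = 1e-12
    eligible = [e for e in evaluations if med - eps <= e.cindex <= q3 + eps]
    return min(eligible, key=lambda e: (e.n_nonzero, -e.cindex, e.split_id))


# ---------------------------------------------------------------------------
# permutation significance


@dataclass
class PermutationResult:
    """Observed mean C-index against a permutation null with normal fit."""

    observed: float
    null_means: np.ndarray
    mu: float
    sigma: float
    p_value: float

    @property
    def n_perm(self) -> int:
        return len(self.null_means)


def _shuffle_outcome(cohort: Cohort, rng: np.random.Generator) -> Cohort:
    idx = rng.permutation(cohort.n_patients)
    return Cohort(
        time=cohort.time[idx],
        event=cohort.event[idx],
        covariates=cohort.covariates,
        expression=cohort.expression,
        image_features=cohort.image_features,
        params=cohort.params,
    )


def permutation_test(
    cohort: Cohort,
    spec: IntegrationSpec,
    n_perm: int = 100,
    n_splits: int = 20,
    seed: int = 0,
    lasso_kwargs: Optional[dict] = None,
) -> PermutationResult:
    """Permutation significance of the mean test C-index.

    Each permutation jointly reshuffles the (time, event) rows against the
    covariates — preserving the marginal censoring pattern — reruns the
    whole evaluation, and records the mean test C-index.  A normal
    distribution is moment-matched to the null sample and the one-sided
    p-value is ``1 - Phi((observed - mu) / sigma)``.
    """
    observed = mean_cindex(
        evaluate_integration(
            cohort, spec, n_splits=n_splits,
            seed=substream_seed(seed, "observed-eval"),
            compute_auc=False, lasso_kwargs=lasso_kwargs,
        )
    )
    rng = substream(seed, "permutation")
    null = np.empty(n_perm)
    for b in range(n_perm):
        shuffled = _shuffle_outcome(cohort, rng)
        null[b] = mean_cindex(
            evaluate_integration(
                shuffled, spec, n_splits=n_splits,
                seed=substream_seed(seed, "perm-eval", b),
                compute_auc=False, lasso_kwargs=lasso_kwargs,
            )
        )
    mu = float(null.mean())
    sigma = float(null.std(ddof=0))
    if sigma == 0:
        raise DegenerateNullError("degenerate null: permutation means have zero variance")
    p = float(stats.norm.sf((observed - mu) / sigma))
    return PermutationResult(observed=observed, null_means=null, mu=mu, sigma=sigma, p_value=p)
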