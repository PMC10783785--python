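"""Median split, Kaplan-Meier, log-rank and continuous-score hazard ratio."""

import numpy as np
import pytest

import wsisurv as w
from wsisurv.stratify import HIGHER, LOWER, stratify_by_score


# ---------------------------------------------------------------------------
# median split


def test_median_split_231_distinct_scores():
    rng = np.random.default_rng(0)
    scores = rng.permutation(231).astype(float)  # all distinct
    labels = w.median_split(scores)
    assert (labels == LOWER).sum() == 116
    assert (labels == HIGHER).sum() == 115


def test_median_split_small_cases_and_invariance():
    labels = w.median_split([1.0, 2.0, 3.0, 4.0])
    assert list(labels) == [LOWER, LOWER, HIGHER, HIGHER]
    assert (w.median_split([2.0] * 5) == LOWER).all()
    rng = np.random.default_rng(1)
    s = rng.normal(size=51)
    assert (w.median_split(s) == w.median_split(np.exp(s))).all()


# ---------------------------------------------------------------------------
# Kaplan-Meier


def test_km_four_distinct_events():
    est = w.kaplan_meier([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
    surv = dict(zip(est.times, est.survival))
    assert surv[1.0] == pytest.approx(0.75)
    assert surv[2.0] == pytest.approx(0.50)
    assert surv[3.0] == pytest.approx(0.25)
    assert est.median == 2.0  # first time S drops to 0.5


def test_km_equals_empirical_survival_without_censoring():
    rng = np.random.default_rng(3)
    t = rng.exponential(10, size=200)
    est = w.kaplan_meier(t, np.ones(200, dtype=int))
    emp = 1 - np.searchsorted(np.sort(t), est.times, side="right") / 200
    obs = est.survival[np.isin(est.times, t)]
    assert np.allclose(est.survival[1:], emp[1:], atol=1e-12)


def test_km_exponential_median_closed_form():
    rng = np.random.default_rng(2)
    lam = 1 / 500.0
    t = rng.exponential(1 / lam, size=5000)
    est = w.kaplan_meier(t, np.ones(5000, dtype=int))
    assert est.median == pytest.approx(np.log(2) / lam, rel=0.05)


def test_km_all_censored_median_not_reached():
    est = w.kaplan_meier([5.0, 6.0, 7.0], [0, 0, 0])
    assert np.all(est.survival == 1.0)
    assert not est.median_reached


# ---------------------------------------------------------------------------
# log-rank


def logrank_oracle(time, event, groups):
    """Hand-computed observed-minus-expected chi-square (hypergeometric var)."""
    labels = np.unique(groups)
    O = E = V = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == labels[0])).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (groups == labels[0])).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


def test_logrank_identical_groups_is_null():
    t = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
    e = np.array([1, 1, 0, 1, 1, 0])
    g = np.array(["a"] * 3 + ["b"] * 3)
    stat, p = w.logrank_test(t, e, g)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_matches_hand_computed_table():
    t = np.array([2.0, 3.0, 5.0, 1.0, 4.0, 6.0])
    e = np.array([1, 1, 0, 1, 1, 1])
    g = np.array(["a", "a", "a", "b", "b", "b"])
    stat, _ = w.logrank_test(t, e, g)
    assert stat == pytest.approx(logrank_oracle(t, e, g))
    # invariance to swapping group labels
    stat2, _ = w.logrank_test(t, e, np.where(g == "a", "b", "a"))
    assert stat2 == pytest.approx(stat)


def test_logrank_power_at_hazard_ratio_three():
    for seed in range(3):
        rng = np.random.default_rng(seed)
        t1 = rng.exponential(300, 200)
        t2 = rng.exponential(100, 200)
        t = np.concatenate([t1, t2])
        e = np.ones(400, dtype=int)
        g = np.array(["lo"] * 200 + ["hi"] * 200)
        _, p = w.logrank_test(t, e, g)
        assert p < 0.001


def test_logrank_rejects_single_group():
    with pytest.raises(ValueError, match="2 groups"):
        w.logrank_test([1.0, 2.0], [1, 1], ["a", "a"])


# ---------------------------------------------------------------------------
# continuous-score hazard ratio


def test_hazard_ratio_recovery_at_reported_effect_size():
    """A score with true per-unit log-hazard ln(1.913) is recovered."""
    rng = np.random.default_rng(5)
    n = 2000
    s = rng.normal(size=n)
    t = rng.exponential(np.exp(-np.log(1.913) * s))
    res = w.score_hazard_ratio(s, t, np.ones(n, dtype=int))
    assert res["hr"] == pytest.approx(1.913, rel=0.10)
    assert res["ci_lower"] < res["hr"] < res["ci_upper"]


def test_hazard_ratio_reparameterization():
    rng = np.random.default_rng(6)
    n = 500
    s = rng.normal(size=n)
    t = rng.exponential(np.exp(-0.8 * s))
    e = np.ones(n, dtype=int)
    r1 = w.score_hazard_ratio(s, t, e)
    r2 = w.score_hazard_ratio(2 * s, t, e)
    assert r2["log_hr"] == pytest.approx(r1["log_hr"] / 2, rel=1e-4)


def test_hazard_ratio_null_coverage():
    covered = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        s = rng.normal(size=300)
        t = rng.exponential(1.0, size=300)
        res = w.score_hazard_ratio(s, t, np.ones(300, dtype=int))
        covered += res["ci_lower"] <= 1.0 <= res["ci_upper"]
    assert covered >= 17  # ~95% nominal coverage


def test_zero_variance_score_rejected():
    with pytest.raises(ValueError, match="variance"):
        w.score_hazard_ratio([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [1, 1, 1])


# ---------------------------------------------------------------------------
# end-to-end stratification


def test_stratification_orders_risk_groups(cohort231):
    lp = cohort231.truth["linear_predictor"]
    res = stratify_by_score(lp, cohort231.time, cohort231.event)
    assert res.group_sizes[LOWER] + res.group_sizes[HIGHER] == 231
    assert res.logrank_p < 0.01
    assert res.hazard_ratio["hr"] > 1
    # higher-risk arm has stochastically shorter RFS: compare curves on the
    # common event-time grid
    lo, hi = res.km[LOWER], res.km[HIGHER]
    common = np.linspace(50, min(lo.times.max(), hi.times.max()), 20)
    s_lo = np.interp(common, lo.times, lo.survival)
    s_hi = np.interp(common, hi.times, hi.survival)
    assert (s_lo >= s_hi - 1e-9).all()
    summary = res.summary()
    assert set(summary) >= {"group_sizes", "median_rfs", "logrank_p", "hazard_ratio"}


def test_km_plot_writes_png(tmp_path, cohort231):
    pytest.importorskip("matplotlib")
    res = stratify_by_score(
        cohort231.truth["linear_predictor"], cohort231.time, cohort231.event
    )
    out = tmp_path / "km.png"
    w.plot_km(res, path=str(out))
    assert out.stat().st_size > 0
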