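"""Lasso-Cox fitting, C-index, tdAUC, splits, integration and permutation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wsisurv as w
from wsisurv.errors import DegenerateNullError
from wsisurv.modeling import SplitEvaluation, mean_cindex

from conftest import FAST_LASSO


# ---------------------------------------------------------------------------
# fit_lasso_cox


def _toy_survival(n=120, p=6, beta=None, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"f{i}" for i in range(p)])
    lp = X.to_numpy() @ (beta if beta is not None else np.zeros(p))
    t = rng.exponential(np.exp(-lp))
    c = rng.exponential(1.5, size=n)
    return X, np.minimum(t, c), (t <= c).astype(int)


def test_full_shrinkage_at_huge_penalty():
    X, t, e = _toy_survival(seed=1)
    m = w.fit_lasso_cox(X, t, e, alphas=[1e6])
    assert m.n_nonzero == 0
    assert (w.risk_score(m, X) == 0).all()


def test_unpenalized_limit_recovers_single_coefficient():
    """At vanishing penalty the Lasso-Cox estimate approaches the Cox MLE."""
    rng = np.random.default_rng(3)
    n = 2000
    X = pd.DataFrame({"x": rng.normal(size=n)})
    t = rng.exponential(np.exp(-0.65 * X["x"].to_numpy()))
    m = w.fit_lasso_cox(X, t, np.ones(n, dtype=int), alphas=[1e-6])
    assert m.coefficients["x"] == pytest.approx(0.65, rel=0.10)


def test_all_censored_rejected():
    X, t, _ = _toy_survival(seed=2)
    with pytest.raises(ValueError, match="events"):
        w.fit_lasso_cox(X, t, np.zeros(len(t), dtype=int))


def test_constant_columns_dropped_with_warning():
    X, t, e = _toy_survival(seed=4)
    X["const"] = 5.0
    with pytest.warns(UserWarning, match="constant"):
        m = w.fit_lasso_cox(X, t, e, **FAST_LASSO)
    assert "const" not in m.feature_names


def test_lasso_path_support_nonincreasing_in_penalty():
    beta = np.array([1.0, -1.0, 0.8, 0, 0, 0])
    X, t, e = _toy_survival(n=200, beta=beta, seed=5)
    grid = np.geomspace(1.0, 1e-3, 12)
    sizes = [w.fit_lasso_cox(X, t, e, alphas=[a]).n_nonzero for a in grid]
    assert all(a <= b for a, b in zip(sizes, sizes[1:]))  # grid is decreasing


def test_support_recovery_with_strong_effects():
    p = w.CohortSimParams(
        n_patients=800, n_genes=100, n_image_features=4,
        true_beta={"gene_10": 0.8, "gene_50": -0.8, "img_02": -0.7}, seed=0,
    )
    c = w.generate_cohort(p)
    X = pd.concat([c.image_features, c.expression], axis=1)
    m = w.fit_lasso_cox(X, c.time, c.event, seed=0, **FAST_LASSO)
    nz = m.coefficients[m.coefficients != 0]
    for name, b in c.truth["true_beta"].items():
        assert name in nz.index
        assert np.sign(nz[name]) == np.sign(b)


# ---------------------------------------------------------------------------
# risk_score


def test_risk_score_linearity_and_hand_check():
    m = w.RiskModel(feature_names=["a", "b"], coefficients=pd.Series({"a": 1.0, "b": -2.0}), penalty=0.0)
    X = pd.DataFrame({"a": [3.0], "b": [1.0]})
    assert w.risk_score(m, X)[0] == pytest.approx(1.0)
    m2 = w.RiskModel(feature_names=["a", "b"], coefficients=2 * m.coefficients, penalty=0.0)
    assert w.risk_score(m2, X)[0] == pytest.approx(2.0)
    m0 = w.RiskModel(feature_names=["a", "b"], coefficients=0 * m.coefficients, penalty=0.0)
    assert (w.risk_score(m0, X) == 0).all()
    with pytest.raises(KeyError, match="missing"):
        w.risk_score(m, pd.DataFrame({"a": [1.0]}))


# ---------------------------------------------------------------------------
# Harrell C-index


def cindex_oracle(scores, time, event):
    """O(n^2) enumeration of comparable pairs."""
    num = den = 0.0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i] == 1:
                den += 1
                if scores[i] > scores[j]:
                    num += 1
                elif scores[i] == scores[j]:
                    num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


def test_cindex_perfect_and_constant():
    t = np.array([1.0, 2.0, 3.0])
    e = np.ones(3, dtype=int)
    assert w.harrell_cindex([3, 2, 1], t, e) == 1.0
    assert w.harrell_cindex([1, 1, 1], t, e) == 0.5


def test_cindex_fixture_matches_pair_enumeration():
    t = np.array([2.0, 4.0, 6.0, 8.0])
    e = np.array([1, 1, 0, 1])
    s = np.array([5.0, 1.0, 4.0, 2.0])
    assert w.harrell_cindex(s, t, e) == pytest.approx(cindex_oracle(s, t, e))


def test_cindex_undefined_without_comparable_pairs():
    with pytest.raises(ValueError, match="undefined"):
        w.harrell_cindex([1.0, 2.0], [5.0, 6.0], [0, 0])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(4, 50))
def test_cindex_fuzz_against_oracle_and_monotone_invariance(seed, n):
    rng = np.random.default_rng(seed)
    t = rng.integers(1, 10, size=n).astype(float)  # ties likely
    e = rng.integers(0, 2, size=n)
    s = rng.integers(-3, 4, size=n).astype(float)  # score ties likely
    try:
        expected = cindex_oracle(s, t, e)
    except ValueError:
        with pytest.raises(ValueError):
            w.harrell_cindex(s, t, e)
        return
    got = w.harrell_cindex(s, t, e)
    assert got == pytest.approx(expected)
    assert w.harrell_cindex(np.exp(s), t, e) == pytest.approx(expected)


def test_cindex_agrees_with_sksurv_on_distinct_times():
    from sksurv.metrics import concordance_index_censored

    rng = np.random.default_rng(7)
    n = 80
    t = rng.permutation(np.arange(1, n + 1)).astype(float)
    e = rng.integers(0, 2, size=n).astype(bool)
    e[0] = True
    s = rng.normal(size=n)
    ours = w.harrell_cindex(s, t, e.astype(int))
    ref = concordance_index_censored(e, t, s)[0]
    assert ours == pytest.approx(ref, abs=1e-12)


# ---------------------------------------------------------------------------
# time-dependent AUC


def test_tdauc_constant_score_is_random():
    rng = np.random.default_rng(0)
    t_tr, e_tr = rng.exponential(100, 200), rng.integers(0, 2, 200)
    t_te, e_te = rng.exponential(100, 100), rng.integers(0, 2, 100)
    grid = np.percentile(t_te, [20, 40, 60])
    auc, mean_auc = w.time_dependent_auc(np.ones(100), t_tr, e_tr, t_te, e_te, grid)
    assert np.allclose(auc, 0.5)
    assert mean_auc == 0.5


def test_tdauc_antitone_score_flips():
    rng = np.random.default_rng(1)
    t_tr, e_tr = rng.exponential(100, 200), rng.integers(0, 2, 200)
    t_te, e_te = rng.exponential(100, 100), rng.integers(0, 2, 100)
    grid = np.percentile(t_te, [25, 50])
    s = rng.normal(size=100)
    a1, _ = w.time_dependent_auc(s, t_tr, e_tr, t_te, e_te, grid)
    a2, _ = w.time_dependent_auc(-s, t_tr, e_tr, t_te, e_te, grid)
    assert np.allclose(a1, 1 - a2)


def test_tdauc_approaches_one_for_strong_uncensored_effect():
    rng = np.random.default_rng(2)
    n = 1000
    x = rng.normal(size=n)
    t = rng.exponential(np.exp(-3.0 * x))
    e = np.ones(n, dtype=int)
    grid = np.percentile(t, [30, 50, 70])
    auc, mean_auc = w.time_dependent_auc(x[500:], t[:500], e[:500], t[500:], e[500:], grid)
    assert mean_auc >= 0.95


def test_tdauc_rejects_grid_beyond_follow_up():
    t = np.linspace(1, 50, 40)
    e = np.ones(40, dtype=int)
    with pytest.raises(ValueError, match="beyond"):
        w.time_dependent_auc(np.zeros(40), t, e, t, e, [60.0])


# ---------------------------------------------------------------------------
# splits


def test_split_sizes_match_two_to_one_design():
    train, test = w.split_cohort(231, seed=0)
    assert len(train) == 154 and len(test) == 77
    train, test = w.split_cohort(3, seed=0)
    assert len(train) == 2 and len(test) == 1


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(3, 500), st.integers(0, 2**31 - 1))
def test_split_is_a_partition(n, seed):
    train, test = w.split_cohort(n, seed=seed)
    assert len(np.intersect1d(train, test)) == 0
    assert np.array_equal(np.union1d(train, test), np.arange(n))
    assert len(train) == int(round(2 * n / 3))


# ---------------------------------------------------------------------------
# integration / selection / permutation


def test_null_cohort_evaluates_near_chance():
    c = w.generate_cohort(w.CohortSimParams(true_beta={}, seed=5))
    evals = w.evaluate_integration(
        c, w.IntegrationSpec("single", ("genes",)), n_splits=20, seed=0,
        compute_auc=False, lasso_kwargs=FAST_LASSO,
    )
    assert mean_cindex(evals) == pytest.approx(0.5, abs=0.05)


def test_stacked_integration_beats_singles_on_independent_signals(cohort231):
    kwargs = dict(n_splits=10, seed=4, compute_auc=False, lasso_kwargs=FAST_LASSO)
    stacked = mean_cindex(
        w.evaluate_integration(cohort231, w.IntegrationSpec("stacked", ("image", "genes")), **kwargs)
    )
    pooled = mean_cindex(
        w.evaluate_integration(cohort231, w.IntegrationSpec("pooled", ("image", "genes")), **kwargs)
    )
    img = mean_cindex(
        w.evaluate_integration(cohort231, w.IntegrationSpec("single", ("image",)), **kwargs)
    )
    genes = mean_cindex(
        w.evaluate_integration(cohort231, w.IntegrationSpec("single", ("genes",)), **kwargs)
    )
    assert stacked >= pooled - 0.02
    assert stacked >= img and stacked >= genes


def test_single_split_evaluation_degenerates_cleanly(cohort231):
    evals = w.evaluate_integration(
        cohort231, w.IntegrationSpec("stacked", ("image", "genes")),
        n_splits=1, seed=1, lasso_kwargs=FAST_LASSO,
    )
    assert len(evals) == 1
    assert 0 <= evals[0].cindex <= 1
    assert evals[0].stack_coefficients is not None


def _fake_eval(split_id, cindex, size):
    return SplitEvaluation(
        split_id=split_id, train_idx=np.array([]), test_idx=np.array([]),
        domain_models={}, stack_coefficients=None, cindex=cindex, n_nonzero=size,
    )


def selection_oracle(evals):
    C = np.array([e.cindex for e in evals])
    med, q3 = np.percentile(C, [50, 75])
    eligible = [e for e in evals if med - 1e-12 <= e.cindex <= q3 + 1e-12]
    return sorted(eligible, key=lambda e: (e.n_nonzero, -e.cindex, e.split_id))[0]


def test_final_model_selection_matches_exhaustive_rule():
    rng = np.random.default_rng(0)
    for _ in range(20):
        evals = [
            _fake_eval(i, float(rng.integers(40, 80)) / 100, int(rng.integers(1, 12)))
            for i in range(20)
        ]
        assert w.select_final_model(evals) is selection_oracle(evals)
        # invariance to ordering
        shuffled = list(evals)
        rng.shuffle(shuffled)
        assert w.select_final_model(shuffled) is selection_oracle(evals)


def test_final_model_selection_edge_cases():
    equal = [_fake_eval(i, 0.6, size) for i, size in enumerate([5, 2, 9])]
    assert w.select_final_model(equal).n_nonzero == 2
    single = [_fake_eval(0, 0.7, 3)]
    assert w.select_final_model(single) is single[0]


def test_permutation_normal_fit_and_centering(monkeypatch):
    """p = 0.5 when the observed statistic sits at the null mean, and a
    zero-variance null is flagged as degenerate."""
    c = w.generate_cohort(w.CohortSimParams(n_patients=30, seed=0))
    spec = w.IntegrationSpec("single", ("genes",))

    null_values = iter([0.6] + [0.45, 0.55, 0.5, 0.65, 0.35, 0.5, 0.52, 0.48])

    def fake_eval(cohort, spec, n_splits=20, seed=0, compute_auc=True, lasso_kwargs=None):
        return [_fake_eval(0, next(null_values), 1)]

    monkeypatch.setattr(w.modeling, "evaluate_integration", fake_eval)
    res = w.modeling.permutation_test(c, spec, n_perm=8, n_splits=1, seed=0)
    assert res.mu == pytest.approx(0.5)
    assert res.observed == pytest.approx(0.6)
    # observed at the null mean gives p = 1/2 under the fitted normal
    from scipy import stats

    assert stats.norm.sf((res.mu - res.mu) / res.sigma) == 0.5

    constant = iter([0.5] * 9)
    monkeypatch.setattr(
        w.modeling, "evaluate_integration",
        lambda *a, **k: [_fake_eval(0, next(constant), 1)],
    )
    with pytest.raises(DegenerateNullError):
        w.modeling.permutation_test(c, spec, n_perm=8, n_splits=1, seed=0)


def test_informative_cohort_is_significant(cohort231):
    res = w.permutation_test(
        cohort231, w.IntegrationSpec("pooled", ("image", "genes")),
        n_perm=10, n_splits=3, seed=2, lasso_kwargs=FAST_LASSO,
    )
    assert res.p_value < 0.01
    assert 0 <= res.p_value <= 1
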