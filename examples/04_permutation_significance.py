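"""Permutation significance of the integrated model (reduced scale).

Outcome rows (time, event) are jointly reshuffled against the covariates,
the whole repeated-split evaluation is re-run per permutation, and a normal
distribution is fitted to the null mean C-indices.
"""

import warnings

import wsisurv as w

warnings.filterwarnings("ignore")

cohort = w.generate_cohort(w.CohortSimParams(seed=1))
res = w.permutation_test(
    cohort,
    w.IntegrationSpec("pooled", ("image", "genes")),
    n_perm=20, n_splits=5, seed=7,
    lasso_kwargs=dict(n_alphas=30, alpha_min_ratio=0.01),
)
print(f"observed mean test C-index: {res.observed:.3f}")
print(f"permutation null: mean {res.mu:.3f}, sd {res.sigma:.3f} ({res.n_perm} permutations)")
print(f"one-sided p-value: {res.p_value:.2e}")
# The null mean sits at 0.5: once the covariate-outcome correspondence is
# destroyed, no model retains predictive capacity.
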