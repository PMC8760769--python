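"""Independent oracles for the mixed-model machinery.

These deliberately use a different computational route from the package:
closed-form balanced one-way ANOVA estimators, and a brute-force grid search
over the variance ratio evaluating the restricted likelihood with dense
full-matrix linear algebra.
"""

import numpy as np


def balanced_anova_components(y: np.ndarray, groups: np.ndarray):
    """Method-of-moments variance components for balanced one-way data.

    Returns (v_between, v_within, icc) with v_between truncated at 0; icc is
    the classical intraclass correlation (MSB - MSW) / (MSB + (m-1) MSW).
    """
    y = np.asarray(y, dtype=float)
    labels = np.unique(groups)
    gmeans = np.array([y[groups == g].mean() for g in labels])
    m = len(y) // len(labels)
    assert all((groups == g).sum() == m for g in labels), "not balanced"
    grand = y.mean()
    msb = m * np.sum((gmeans - grand) ** 2) / (len(labels) - 1)
    msw = sum(np.sum((y[groups == g] - y[groups == g].mean()) ** 2)
              for g in labels) / (len(labels) * (m - 1))
    v_b = max((msb - msw) / m, 0.0)
    icc = (msb - msw) / (msb + (m - 1) * msw)
    return v_b, msw, max(icc, 0.0)


def dense_neg2_reml(y: np.ndarray, X: np.ndarray, groups: np.ndarray,
                    lam: float):
    """Profiled -2 restricted log-likelihood via dense n x n algebra."""
    n, p = X.shape
    same = (groups[:, None] == groups[None, :]).astype(float)
    V = np.eye(n) + lam * same
    Vi = np.linalg.inv(V)
    _, logdetV = np.linalg.slogdet(V)
    A = X.T @ Vi @ X
    _, logdetA = np.linalg.slogdet(A)
    b = X.T @ Vi @ y
    beta = np.linalg.solve(A, b)
    rss = float(y @ Vi @ y - b @ beta)
    s2 = rss / (n - p)
    crit = logdetV + logdetA + (n - p) * (1.0 + np.log(2.0 * np.pi * s2))
    return crit, s2


def grid_search_reml(y: np.ndarray, X: np.ndarray, groups: np.ndarray):
    """Brute-force REML over the variance ratio by staged grid refinement.

    Returns (v_between, v_within) to about 1e-4 relative resolution in the
    ratio.
    """
    lo, hi = -30.0, 30.0
    best_t = None
    for stage in range(4):
        ts = np.linspace(lo, hi, 81)
        vals = [dense_neg2_reml(y, X, groups, np.exp(t))[0] for t in ts]
        k = int(np.argmin(vals))
        best_t = ts[k]
        lo = ts[max(0, k - 1)]
        hi = ts[min(len(ts) - 1, k + 1)]
    crit_best, s2 = dense_neg2_reml(y, X, groups, np.exp(best_t))
    crit_zero, s2_zero = dense_neg2_reml(y, X, groups, 0.0)
    if crit_zero <= crit_best:
        return 0.0, s2_zero
    lam = float(np.exp(best_t))
    return s2 * lam, s2
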