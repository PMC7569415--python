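"""Statistical procedures used throughout the analysis.

* a two-level-error t-test for grouped single-cell data, where the error
  of one cell is modelled as cell-to-cell variation plus experiment-to-
  experiment variation (eps_i = eps_cell + eps_exp): each experiment's
  variance of the mean (from its single-cell sample) is added to the
  variance across experiment means, with a Welch/Satterthwaite reference
  distribution;
* Benjamini-Hochberg step-up FDR control;
* partial least squares regression (NIPALS) reporting the variance-
  explained curve over component counts and predictor weights, with
  per-predictor significance bounds from a scrambled-data (permutation)
  null;
* Tjur's coefficient of discrimination for binary responses; and
* Pearson correlation summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError


# --------------------------------------------------------------------------
# two-level t-test
# --------------------------------------------------------------------------

def _group_moments(group: Sequence[np.ndarray]) -> tuple[float, float, int]:
    """Mean and variance-of-the-mean of one group of experiments.

    Each experiment contributes its cell mean m_j and the within-experiment
    variance of that mean v_j = s_j^2 / n_j; the group mean is mean(m_j)
    and its variance var(m_j)/J + mean(v_j)/J, the additive two-level error
    model.
    """
    if len(group) < 2:
        raise ValidationError("each group needs >= 2 experiments")
    m, v = [], []
    for exp in group:
        x = np.asarray(exp, dtype=float)
        x = x[np.isfinite(x)]
        if x.size < 2:
            raise ValidationError("each experiment needs >= 2 cells")
        m.append(x.mean())
        v.append(x.var(ddof=1) / x.size)
    m = np.asarray(m)
    j = m.size
    var_mean = m.var(ddof=1) / j + float(np.mean(v)) / j
    return float(m.mean()), var_mean, j


def hierarchical_ttest(
    group_a: Sequence[np.ndarray], group_b: Sequence[np.ndarray]
) -> tuple[float, float, float]:
    """Welch-style t-test under the two-level (cell + experiment) error model.

    Returns (t, two-sided p, Satterthwaite df).  Each group is a list of
    per-experiment arrays of single-cell values.
    """
    ma, va, ja = _group_moments(group_a)
    mb, vb, jb = _group_moments(group_b)
    se2 = va + vb
    if se2 == 0:
        return 0.0, 1.0, float(ja + jb - 2)
    t = (ma - mb) / np.sqrt(se2)
    df = se2**2 / (va**2 / (ja - 1) + vb**2 / (jb - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(p), float(df)


def bh_fdr(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure.

    Returns (reject flags, monotone adjusted p-values).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p_adj


# --------------------------------------------------------------------------
# PLSR with permutation null
# --------------------------------------------------------------------------

@dataclass
class PLSRResult:
    """PLSR fit summary.

    ``variance_explained`` is the percent of Y variance explained at each
    component count 1..max_components (non-decreasing); ``weights`` are the
    standardized regression coefficients at ``n_components_reported``;
    ``null_bounds`` (when computed) are per-predictor (2.5th, 97.5th)
    percentiles of the scrambled-data null weight distribution, and a
    weight is significant iff it falls outside its bounds.
    """

    variance_explained: np.ndarray
    weights: np.ndarray
    predictors: list
    n_components_reported: int
    null_bounds: np.ndarray | None = None
    significant: np.ndarray | None = None


def _standardize(x: np.ndarray, names=None) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        which = [names[i] for i in bad] if names is not None else list(bad)
        raise ValidationError(f"constant column(s) cannot be standardized: {which}")
    return (x - mu) / sd


def _nipals_coefs(x: np.ndarray, y: np.ndarray, n_comp: int):
    """NIPALS PLS1 on pre-standardized data.

    Returns (coefficients at each component count, cumulative fraction of
    Y variance explained).  With one response the per-component weight is
    X'y normalized, followed by deflation of X and y.
    """
    n, p = x.shape
    xk = x.copy()
    yk = y.copy()
    ss_tot = float(y @ y)
    w_mat = np.empty((p, n_comp))
    p_mat = np.empty((p, n_comp))
    q = np.empty(n_comp)
    coefs = np.empty((p, n_comp))
    r2 = np.empty(n_comp)
    for k in range(n_comp):
        w = xk.T @ yk
        norm = np.linalg.norm(w)
        if norm == 0:  # residual orthogonal to X: no further structure
            for kk in range(k, n_comp):
                coefs[:, kk] = coefs[:, k - 1] if k else 0.0
                r2[kk] = r2[k - 1] if k else 0.0
            return coefs, r2
        w /= norm
        t = xk @ w
        tt = float(t @ t)
        pk = xk.T @ t / tt
        qk = float(yk @ t) / tt
        xk = xk - np.outer(t, pk)
        yk = yk - qk * t
        w_mat[:, k], p_mat[:, k], q[k] = w, pk, qk
        # coefficients in the original (standardized) X basis
        pw = p_mat[:, : k + 1].T @ w_mat[:, : k + 1]
        coefs[:, k] = w_mat[:, : k + 1] @ np.linalg.solve(pw, q[: k + 1])
        r2[k] = 1.0 - float(yk @ yk) / ss_tot
    return coefs, r2


def plsr_fit(
    x: np.ndarray,
    y: np.ndarray,
    max_components: int = 4,
    predictors: list | None = None,
    n_components_reported: int = 2,
) -> PLSRResult:
    """Partial least squares regression of one response on standardized
    predictors.

    Columns are standardized internally (zero mean, unit SD) so the fit is
    invariant to affine rescaling of any predictor; y is standardized too,
    making weights comparable across responses.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if x.ndim != 2 or x.shape[0] != y.size or x.shape[0] < 2:
        raise ValidationError("X must be 2-D with >= 2 rows matching y")
    predictors = list(predictors) if predictors is not None else [
        f"x{i}" for i in range(x.shape[1])
    ]
    max_components = min(max_components, x.shape[1], x.shape[0] - 1)
    n_rep = min(n_components_reported, max_components)
    xs = _standardize(x, predictors)
    ys = _standardize(y[:, None], ["y"]).ravel()
    coefs, r2 = _nipals_coefs(xs, ys, max_components)
    return PLSRResult(
        variance_explained=100.0 * r2,
        weights=coefs[:, n_rep - 1],
        predictors=predictors,
        n_components_reported=n_rep,
    )


def plsr_null_bounds(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    n_components: int = 2,
    predictors: list | None = None,
    level: float = 0.05,
) -> PLSRResult:
    """Per-predictor significance bounds from a scrambled-data null.

    Rows of y are permuted relative to X ``n_perm`` times, the PLSR refit
    at ``n_components``, and the (level/2, 1-level/2) percentiles of each
    predictor's null weight distribution become its bounds.  A weight is
    flagged significant iff it lies outside its own bounds.
    """
    import warnings

    if n_perm < 100:
        warnings.warn("n_perm < 100 gives unstable percentile bounds", stacklevel=2)
    res = plsr_fit(x, y, max_components=n_components, predictors=predictors,
                   n_components_reported=n_components)
    xs = _standardize(np.asarray(x, dtype=float), res.predictors)
    ys = _standardize(np.asarray(y, dtype=float).ravel()[:, None], ["y"]).ravel()
    n_comp = res.n_components_reported
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, xs.shape[1]))
    for i in range(n_perm):
        coefs, _ = _nipals_coefs(xs, rng.permutation(ys), n_comp)
        null[i] = coefs[:, n_comp - 1]
    # order-statistic (outward) interpolation keeps the achieved level at or
    # below nominal for moderate n_perm; linear interpolation is anti-
    # conservative there
    lo = np.percentile(null, 100 * level / 2, axis=0, method="lower")
    hi = np.percentile(null, 100 * (1 - level / 2), axis=0, method="higher")
    res.null_bounds = np.column_stack([lo, hi])
    res.significant = (res.weights < lo) | (res.weights > hi)
    return res


# --------------------------------------------------------------------------
# Tjur's coefficient of discrimination
# --------------------------------------------------------------------------

def tjur_discrimination(
    baseline_values, responder_flags
) -> tuple[float, dict]:
    """Tjur's D for a logistic fit of response on a single covariate.

    D is the difference in mean fitted probability between responders and
    non-responders — a correlation-coefficient analogue for a binary
    response.  Under (quasi-)separation the maximum-likelihood fit
    diverges; an L2-penalized fallback is used and flagged.
    """
    import statsmodels.api as sm

    x = np.asarray(baseline_values, dtype=float)
    flags = np.asarray(responder_flags, dtype=bool)
    if x.size != flags.size or x.size < 2:
        raise ValidationError("need matched baseline values and flags")
    if flags.all() or not flags.any():
        raise ValidationError("both responder classes must be present")
    design = sm.add_constant(x)
    fitted = None
    penalized = False
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Logit(flags.astype(float), design)
            fit = model.fit(disp=0, maxiter=200)
            params = np.asarray(fit.params, dtype=float)
            if np.all(np.isfinite(params)) and np.max(np.abs(params[1:] * x.std())) < 50:
                fitted = fit.predict(design)
    except Exception:
        fitted = None
    if fitted is None:
        from sklearn.linear_model import LogisticRegression

        penalized = True
        clf = LogisticRegression(C=1000.0, solver="lbfgs", max_iter=2000)
        clf.fit(x[:, None], flags)
        fitted = clf.predict_proba(x[:, None])[:, 1]
    d = float(np.mean(fitted[flags]) - np.mean(fitted[~flags]))
    return d, {"penalized": penalized}


def pearson_summary(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValidationError("need >= 3 matched points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero-variance input: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
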