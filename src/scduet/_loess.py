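"""Local linear regression (LOESS, degree 1, tricube weights) with pointwise
standard errors.

Used both for the expression-vs-concentration trend curves and for the
mean-variance fit of variance-stabilized gene selection. The smoother is the
classic one: at each evaluation point the nearest ``span`` fraction of the data
is given tricube weights on distance scaled by the furthest included neighbour,
and a weighted straight line is fitted. The variance of the fitted value is
sigma^2 * ||l(x0)||^2 with l the equivalent-kernel weights and sigma^2 the
residual variance estimated from the fit at the observed points.
"""
from __future__ import annotations

import numpy as np


def _tricube(u: np.ndarray) -> np.ndarray:
    out = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return out


def _local_weights(x: np.ndarray, x0: float, span: float) -> np.ndarray:
    n = len(x)
    k = max(int(np.ceil(span * n)), 2)
    d = np.abs(x - x0)
    h = np.sort(d)[min(k, n) - 1]
    if h == 0:
        h = np.max(d)
        if h == 0:  # all points coincide
            return np.ones(n) / n
    return _tricube(d / h)


def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    x_eval: np.ndarray,
    span: float = 0.75,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit y on x locally and evaluate at ``x_eval``.

    Returns (fitted values, pointwise standard errors). Degenerate local
    designs (all x equal within the window) fall back to the weighted mean.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x_eval = np.asarray(x_eval, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations for a local fit")

    def eval_point(x0: float) -> tuple[float, float]:
        w = _local_weights(x, x0, span)
        sw = w.sum()
        xm = (w * x).sum() / sw
        sxx = (w * (x - xm) ** 2).sum()
        if sxx <= 1e-12 * max(1.0, xm * xm):
            l = w / sw
        else:
            # equivalent kernel of the local linear estimator at x0
            l = w / sw + (x0 - xm) * w * (x - xm) / sxx
        return float(l @ y), float(l @ l)

    fit_obs = np.empty(n)
    lsq_obs = np.empty(n)
    for i, xi in enumerate(x):
        fit_obs[i], lsq_obs[i] = eval_point(xi)
    resid = y - fit_obs
    # effective residual dof: n - trace of the smoother (approximated by the
    # sum of self-weights); clipped to stay positive on tiny samples
    trace = float(np.sum(lsq_obs))
    dof = max(n - trace, 1.0)
    sigma2 = float(resid @ resid) / dof

    fitted = np.empty(len(x_eval))
    se = np.empty(len(x_eval))
    for j, x0 in enumerate(x_eval):
        f, lsq = eval_point(float(x0))
        fitted[j] = f
        se[j] = np.sqrt(sigma2 * lsq)
    return fitted, se
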