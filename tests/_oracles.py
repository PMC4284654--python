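"""Independent reference implementations used only by the test suite.

Everything here is deliberately written on a different route from the
package: pure-python segment walks, scipy general-purpose optimizers
and explicit enumeration, so the tests compare two independent paths.
"""

import itertools
import math

import numpy as np
from scipy.optimize import minimize, minimize_scalar


def curve_eval(knot_x, knot_y, x):
    """Piecewise-linear evaluation by explicit segment walk (exact at knots)."""
    for j in range(4):
        if x == knot_x[j]:
            return knot_y[j]
    for j in range(3):
        x0, x1 = knot_x[j], knot_x[j + 1]
        if x0 < x < x1:
            t = (x - x0) / (x1 - x0)
            return knot_y[j] + t * (knot_y[j + 1] - knot_y[j])
    raise ValueError(f"{x} outside curve domain")


def consistent_by_walk(knot_x, knot_y, n_dense=801):
    """Theory-consistency by dense evaluation walk along the curve.

    Samples the curve on a fine grid (knots included), finds the global
    minimum and where it first occurs, and checks the U-shape
    definition: the curve drops strictly below its starting value and
    later rises strictly above its minimum.
    """
    xs = sorted(set(np.linspace(-1.0, 1.0, n_dense)) | set(knot_x))
    ys = [curve_eval(knot_x, knot_y, x) for x in xs]
    m = min(ys)
    i0 = ys.index(m)
    return (m < ys[0]) and any(v > m for v in ys[i0 + 1 :])


def profiled_loglik(knot_x, knot_y, events, outcomes, bound=20.0):
    """Maximized fractional-Bernoulli log-likelihood via scipy Brent search."""

    deltas = [sum(curve_eval(knot_x, knot_y, e) for e in row) for row in events]

    def neg_ll(b0):
        total = 0.0
        for d, y in zip(deltas, outcomes):
            p = 1.0 / (1.0 + math.exp(-(b0 + d)))
            p = min(max(p, 1e-12), 1 - 1e-12)
            total += y * math.log(p) + (1 - y) * math.log(1 - p)
        return -total

    res = minimize_scalar(neg_ll, bounds=(-bound, bound), method="bounded", options={"xatol": 1e-12})
    return -res.fun


def enumerate_grid_curves(x_points, y_levels):
    """All 3-segment curves on a coarse knot grid: (knot_x, knot_y) arrays.

    Interior knot pairs are strictly increasing and strictly inside
    (-1, 1), so every curve has three genuine segments (zero-width
    segments make the U-shape ill-defined as a property of the graph).
    """
    kx, ky = [], []
    for x1, x2 in itertools.combinations(x_points, 2):
        for ys in itertools.product(y_levels, repeat=4):
            kx.append((-1.0, x1, x2, 1.0))
            ky.append(ys)
    return np.asarray(kx, float), np.asarray(ky, float)


def grid_posterior(knot_x, knot_y, events, outcomes):
    """Exact posterior over an enumerated curve grid.

    Returns (log-likelihoods, normalized weights, consistency labels,
    log Bayes factor) computed entirely with pure-python loops and
    scipy's bounded scalar optimizer.
    """
    lls = np.array([profiled_loglik(kx, ky, events, outcomes) for kx, ky in zip(knot_x, knot_y)])
    w = np.exp(lls - lls.max())
    w /= w.sum()
    labels = np.array([consistent_by_walk(kx, ky) for kx, ky in zip(knot_x, knot_y)])
    post_c, post_i = w[labels].sum(), w[~labels].sum()
    n_c, n_i = labels.sum(), (~labels).sum()
    lbf = math.log(post_c / post_i) - math.log(n_c / n_i)
    return lls, w, labels, lbf


def penalized_logistic_min(X, y, lam):
    """Brute-force minimum of the penalized logistic objective (BFGS)."""

    def obj(params):
        w, b = params[:-1], params[-1]
        z = X @ w + b
        yq = 2.0 * y - 1.0
        return np.logaddexp(0.0, -yq * z).sum() + 0.5 * lam * np.dot(w, w)

    res = minimize(obj, np.zeros(X.shape[1] + 1), method="BFGS", options={"gtol": 1e-10, "maxiter": 5000})
    return res.fun
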