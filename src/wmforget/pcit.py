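"""Probabilistic curve induction and testing (P-CIT) by importance sampling.

Estimates the posterior distribution over piecewise-linear "plasticity
curves" :math:`f` mapping neural evidence (rescaled to ``[-1, 1]``) to a
change in memory strength, and scores the non-monotonic plasticity
hypothesis (NMPH): moderate activation weakens a memory while strong
activation strengthens it, predicting a U-shaped curve.

Model
-----
Each item *i* (one Phase 2 scene) carries one or more learning events
with evidence values :math:`e_{im}` and a graded recognition outcome
:math:`y_i \\in \\{0, 1/3, 2/3, 1\\}`.  For a candidate curve the event
effects are summed, :math:`\\Delta_i = \\sum_m f(e_{im})`, and passed
through a logistic link with a nuisance intercept :math:`\\beta_0`:

.. math:: p_i = \\sigma(\\beta_0 + \\Delta_i)

The item log-likelihood uses the fractional-Bernoulli form
:math:`y_i \\log p_i + (1 - y_i) \\log(1 - p_i)`, which reduces to the
Bernoulli likelihood for binary outcomes.  Curves are drawn from a
uniform prior (interior knot abscissae are order statistics of two
Uniform(-1, 1) draws; the four knot heights are i.i.d. Uniform(-1, 1)),
weighted by their profiled maximized likelihood (the intercept is
profiled out per curve by a 1-D concave maximization), and the prior-
corrected posterior mass on theory-consistent (U-shaped) versus
inconsistent curves yields the log Bayes factor.  There is no free
slope on :math:`\\Delta`: curve amplitude is identified by the bounded
knot heights.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp
from scipy.stats import chi2 as chi2_dist

__all__ = [
    "PcitError",
    "PlasticityCurve",
    "PcitResult",
    "sample_curves",
    "evaluate_curves",
    "label_consistency",
    "label_consistency_batch",
    "rescale_evidence",
    "item_log_likelihood",
    "profile_intercept",
    "importance_weights",
    "summarize_posterior",
    "log_bayes_factor",
    "predictive_chi2",
    "partial_out",
    "fit_pcit",
    "read_items",
    "write_items",
]

#: Likelihood clamp: predicted probabilities are clipped to [EPS, 1 - EPS].
EPS = 1e-12

#: Bound for the profiled intercept search (logit scale).
BETA0_BOUND = 20.0

DEFAULT_GRID = np.linspace(-1.0, 1.0, 101)


class PcitError(ValueError):
    """Raised for domain violations and degenerate inputs."""


@dataclass(frozen=True)
class PlasticityCurve:
    """A 3-segment piecewise-linear curve on the evidence domain [-1, 1].

    ``knot_x`` is ``(-1, x1, x2, 1)`` with ``-1 <= x1 <= x2 <= 1`` and
    ``knot_y`` holds the four knot heights, each in ``[-1, 1]``.
    """

    knot_x: tuple[float, float, float, float]
    knot_y: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        kx, ky = self.knot_x, self.knot_y
        if len(kx) != 4 or len(ky) != 4:
            raise PcitError("a plasticity curve has exactly four knots")
        if kx[0] != -1.0 or kx[3] != 1.0:
            raise PcitError("knot abscissae must span [-1, 1]")
        if not all(a <= b for a, b in zip(kx, kx[1:])):
            raise PcitError("knot abscissae must be non-decreasing")
        if any(y < -1.0 or y > 1.0 for y in ky):
            raise PcitError("knot heights must lie in [-1, 1]")

    def __call__(self, x):
        """Evaluate the curve; exact at knots, error outside [-1, 1]."""
        x = np.asarray(x, dtype=float)
        if np.any(x < -1.0) or np.any(x > 1.0):
            raise PcitError("evidence outside the curve domain [-1, 1]")
        return np.interp(x, self.knot_x, self.knot_y)


def sample_curves(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` curves from the prior; returns ``(knot_x, knot_y)`` arrays (n, 4)."""
    interior = np.sort(rng.uniform(-1.0, 1.0, size=(n, 2)), axis=1)
    knot_x = np.empty((n, 4))
    knot_x[:, 0] = -1.0
    knot_x[:, 1:3] = interior
    knot_x[:, 3] = 1.0
    knot_y = rng.uniform(-1.0, 1.0, size=(n, 4))
    return knot_x, knot_y


def evaluate_curves(knot_x: np.ndarray, knot_y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Vectorized evaluation of many curves at shared abscissae.

    Parameters are ``(n_curves, 4)`` knot arrays and a 1-D ``x`` in
    [-1, 1]; returns ``(n_curves, len(x))``.  Segments are treated as
    half-open except the last, so knots evaluate exactly.
    """
    knot_x = np.atleast_2d(np.asarray(knot_x, float))
    knot_y = np.atleast_2d(np.asarray(knot_y, float))
    x = np.asarray(x, dtype=float).ravel()
    if np.any(x < -1.0) or np.any(x > 1.0):
        raise PcitError("evidence outside the curve domain [-1, 1]")
    xb = x[None, :]
    # Per-curve segment slopes/intercepts (n, 3); a degenerate segment
    # (zero span) contributes its left knot height with zero slope.
    span = np.diff(knot_x, axis=1)
    rise = np.diff(knot_y, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(span > 0, rise / np.where(span > 0, span, 1.0), 0.0)
    b = knot_y[:, :3] - a * knot_x[:, :3]
    # Segment index per (curve, point): number of interior knots <= x,
    # so knots evaluate on their right segment (exact either way).
    seg = (xb >= knot_x[:, 1, None]).astype(np.intp)
    seg += xb >= knot_x[:, 2, None]
    return np.take_along_axis(a, seg, axis=1) * xb + np.take_along_axis(b, seg, axis=1)


def label_consistency(curve: PlasticityCurve) -> bool:
    """True iff the curve is theory consistent (U-shaped).

    A curve supports the NMPH when it drops strictly below its starting
    height and later rises strictly above its minimum: with knot heights
    ``y`` and minimum ``m``, ``m < y[0]`` and some knot after the first
    minimizing knot exceeds ``m``.
    """
    return bool(label_consistency_batch(np.asarray(curve.knot_y, float)[None, :])[0])


def label_consistency_batch(knot_y: np.ndarray) -> np.ndarray:
    """Vectorized consistency labels for an ``(n, 4)`` knot-height array."""
    y = np.atleast_2d(np.asarray(knot_y, float))
    m = y.min(axis=1)
    drops = m < y[:, 0]
    first_min = np.argmax(y == m[:, None], axis=1)
    after = np.arange(y.shape[1])[None, :] > first_min[:, None]
    rises = np.any(after & (y > m[:, None]), axis=1)
    return drops & rises


def rescale_evidence(scores) -> np.ndarray:
    """Affine map sending the pooled minimum to -1 and maximum to +1.

    Applied once per analysis over all scores entering it (the
    supersubject pool), so the curve domain always spans the data.
    """
    scores = np.asarray(scores, dtype=float)
    lo, hi = np.min(scores), np.max(scores)
    if hi <= lo:
        raise PcitError("cannot rescale constant evidence scores")
    return 2.0 * (scores - lo) / (hi - lo) - 1.0


def item_log_likelihood(curve: PlasticityCurve, events, outcome: float, beta0: float) -> float:
    """Fractional-Bernoulli log-likelihood of one item under one curve.

    ``events`` are the item's rescaled evidence values; their curve
    effects are summed and passed through ``expit(beta0 + delta)``.
    Probabilities are clamped to ``[EPS, 1 - EPS]``.
    """
    delta = float(np.sum(curve(np.asarray(events, dtype=float))))
    p = float(np.clip(expit(beta0 + delta), EPS, 1.0 - EPS))
    y = float(outcome)
    return y * np.log(p) + (1.0 - y) * np.log1p(-p)


def profile_intercept(
    delta: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 80,
    bound: float = BETA0_BOUND,
) -> tuple[np.ndarray, np.ndarray]:
    """Profile out the intercept per curve by 1-D maximum likelihood.

    ``delta`` is ``(n_curves, n_items)``; returns the maximizing
    ``beta0`` per curve (bounded to ``[-bound, bound]``) and the
    maximized total log-likelihood.  The objective is concave in
    ``beta0`` so a safeguarded Newton iteration converges; the score is
    ``sum(y - p)`` and the negative curvature ``sum(p (1 - p))``.
    """
    delta = np.atleast_2d(np.asarray(delta, float))
    y = np.asarray(y, dtype=float)
    ybar = float(np.clip(y.mean(), 1e-6, 1.0 - 1e-6))
    b = np.full(delta.shape[0], np.log(ybar / (1.0 - ybar)))
    for _ in range(max_iter):
        p = expit(b[:, None] + delta)
        g = (y[None, :] - p).sum(axis=1)
        h = (p * (1.0 - p)).sum(axis=1)
        step = np.clip(g / np.maximum(h, 1e-12), -5.0, 5.0)
        b = np.clip(b + step, -bound, bound)
        if np.max(np.abs(step)) < tol:
            break
    p = np.clip(expit(b[:, None] + delta), EPS, 1.0 - EPS)
    ll = (y[None, :] * np.log(p) + (1.0 - y[None, :]) * np.log1p(-p)).sum(axis=1)
    return b, ll


def _event_deltas(knot_x, knot_y, events) -> np.ndarray:
    """Summed curve effects: (n_curves, n_items) from (n_items, n_events)."""
    events = np.atleast_2d(np.asarray(events, float))
    n_items, n_events = events.shape
    vals = evaluate_curves(knot_x, knot_y, events.ravel())
    return vals.reshape(-1, n_items, n_events).sum(axis=2)


def importance_weights(
    knot_x: np.ndarray,
    knot_y: np.ndarray,
    events: np.ndarray,
    outcomes: np.ndarray,
    chunk_size: int = 4096,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Log importance weights for a curve sample against the item data.

    Per curve the intercept is profiled out and the log-weight is the
    maximized total log-likelihood; weights are then normalized by
    log-sum-exp.  Work is chunked over curves to bound memory.
    Returns ``(log_weights_normalized, log_likelihoods, beta0)``.
    """
    events = np.atleast_2d(np.asarray(events, float))
    outcomes = np.asarray(outcomes, dtype=float)
    if events.shape[0] == 0:
        raise PcitError("importance weighting requires at least one item")
    if events.shape[0] != outcomes.shape[0]:
        raise PcitError("events and outcomes disagree on the number of items")
    n = np.atleast_2d(knot_x).shape[0]
    ll = np.empty(n)
    b0 = np.empty(n)
    for start in range(0, n, chunk_size):
        sl = slice(start, min(start + chunk_size, n))
        delta = _event_deltas(knot_x[sl], knot_y[sl], events)
        b0[sl], ll[sl] = profile_intercept(delta, outcomes)
    log_w = ll - logsumexp(ll)
    return log_w, ll, b0


def summarize_posterior(
    knot_x: np.ndarray,
    knot_y: np.ndarray,
    log_weights: np.ndarray,
    grid: np.ndarray = DEFAULT_GRID,
    band: tuple[float, float] = (0.05, 0.95),
    chunk_size: int = 4096,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise posterior mean curve and credible band on a grid.

    The band is the pointwise weighted (5th, 95th) percentile by
    default, i.e. a 90% credible interval.
    Returns ``(mean, lo, hi)`` arrays over ``grid``.
    """
    grid = np.asarray(grid, dtype=float)
    n = np.atleast_2d(knot_x).shape[0]
    vals = np.empty((n, grid.size))
    for start in range(0, n, chunk_size):
        sl = slice(start, min(start + chunk_size, n))
        vals[sl] = evaluate_curves(knot_x[sl], knot_y[sl], grid)
    w = np.exp(log_weights - logsumexp(log_weights))
    mean = w @ vals
    order = np.argsort(vals, axis=0)
    sorted_vals = np.take_along_axis(vals, order, axis=0)
    cum = np.cumsum(w[order], axis=0)
    lo_idx = np.argmax(cum >= band[0], axis=0)
    hi_idx = np.argmax(cum >= band[1], axis=0)
    cols = np.arange(grid.size)
    return mean, sorted_vals[lo_idx, cols], sorted_vals[hi_idx, cols]


def log_bayes_factor(
    log_weights: np.ndarray,
    consistency: np.ndarray,
    cap: float = 10.0,
) -> tuple[float, bool]:
    """Prior-corrected log posterior-odds for theory-consistent curves.

    ``log(post_consistent / post_inconsistent) - log(prior_c / prior_i)``
    with the prior masses estimated from the same sample's unweighted
    labels.  If either class is absent from the sample the value is
    capped at ``+/-cap`` and flagged.  Returns ``(value, capped)``.
    """
    consistency = np.asarray(consistency, dtype=bool)
    n_c = int(consistency.sum())
    n_i = int(consistency.size - n_c)
    if n_c == 0:
        return -float(cap), True
    if n_i == 0:
        return float(cap), True
    log_post_c = logsumexp(log_weights[consistency])
    log_post_i = logsumexp(log_weights[~consistency])
    lbf = (log_post_c - log_post_i) - (np.log(n_c) - np.log(n_i))
    if not np.isfinite(lbf):
        return float(np.sign(lbf) * cap), True
    return float(lbf), False


def predictive_chi2(
    events: np.ndarray,
    outcomes: np.ndarray,
    grid: np.ndarray,
    mean_curve: np.ndarray,
    df: int = 1,
) -> tuple[float, float]:
    """Likelihood-ratio test of the posterior-mean curve against the null.

    Statistic: ``2 (LL[mean curve, profiled intercept] - LL[intercept
    only])``, floored at zero and referred to a chi-square distribution
    with ``df`` degrees of freedom (the net curve effect treated as one
    induced predictor by default).  The null maximum is attained at
    ``p = mean(y)`` in closed form.
    """
    events = np.atleast_2d(np.asarray(events, float))
    if events.shape[0] == 0:
        raise PcitError("predictive test requires at least one item")
    y = np.asarray(outcomes, dtype=float)
    delta = np.interp(events, grid, mean_curve).sum(axis=1)
    _, ll_model = profile_intercept(delta[None, :], y)
    ybar = float(np.clip(y.mean(), EPS, 1.0 - EPS))
    ll_null = y.size * (ybar * np.log(ybar) + (1.0 - ybar) * np.log1p(-ybar))
    stat = max(0.0, 2.0 * (float(ll_model[0]) - ll_null))
    return stat, float(chi2_dist.sf(stat, df))


def partial_out(target_scores, covariate_scores) -> np.ndarray:
    """Residualize one evidence score on another, then rescale to [-1, 1].

    Ordinary least-squares residuals of target on covariate (with
    intercept).  A constant covariate degrades to plain centering; a
    constant residual (e.g. target == covariate) surfaces as the
    rescaling error for constant scores.
    """
    t = np.asarray(target_scores, dtype=float)
    c = np.asarray(covariate_scores, dtype=float)
    if t.shape != c.shape or t.ndim != 1 or t.size < 3:
        raise PcitError("partial_out requires two equal-length 1-D arrays of length >= 3")
    if np.ptp(c) == 0:
        resid = t - t.mean()
    else:
        X = np.column_stack([np.ones_like(c), c])
        coef, *_ = np.linalg.lstsq(X, t, rcond=None)
        resid = t - X @ coef
    if np.ptp(resid) <= 1e-10 * max(np.ptp(t), 1.0):
        raise PcitError("cannot rescale constant evidence scores (residuals are numerically constant)")
    return rescale_evidence(resid)


@dataclass
class PcitResult:
    """Posterior summary, hypothesis score and fit diagnostics."""

    grid: np.ndarray
    mean_curve: np.ndarray
    band_lo: np.ndarray
    band_hi: np.ndarray
    log_bayes_factor: float
    lbf_capped: bool
    chi2: float
    chi2_p: float
    chi2_df: int
    prior_consistent_fraction: float
    posterior_consistent_fraction: float
    n_samples: int
    n_items: int
    ess: float
    event_cols: tuple[str, ...]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("grid", "mean_curve", "band_lo", "band_hi"):
            d[key] = np.asarray(d[key]).tolist()
        d["event_cols"] = list(self.event_cols)
        return d

    def curve_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"evidence": self.grid, "mean": self.mean_curve, "lo90": self.band_lo, "hi90": self.band_hi}
        )


def _resolve_event_cols(items: pd.DataFrame, event_cols) -> tuple[str, ...]:
    if event_cols is not None:
        return tuple(event_cols)
    if "ev_pre" in items.columns and "ev_post" in items.columns:
        return ("ev_pre", "ev_post")
    if "ev" in items.columns:
        return ("ev",)
    raise PcitError("cannot infer event columns; pass event_cols explicitly")


def fit_pcit(
    items: pd.DataFrame,
    event_cols=None,
    n_samples: int = 100_000,
    seed=None,
    rng: np.random.Generator | None = None,
    grid: np.ndarray = DEFAULT_GRID,
    rescale: bool = True,
    cap: float = 10.0,
    chi2_df: int = 1,
    summarize: bool = True,
    ess_floor: float = 50.0,
    chunk_size: int = 4096,
) -> PcitResult:
    """Run the full curve-induction analysis on an item table.

    ``items`` holds one row per item with an ``outcome`` column (graded
    memory strength in [0, 1]) and one or more evidence event columns
    (default ``ev_pre``/``ev_post`` for the combined analysis, or a
    single ``ev``).  With ``rescale`` the pooled event scores are mapped
    affinely onto [-1, 1] before weighting (the supersubject
    convention); otherwise they must already lie in the domain.

    With ``summarize=False`` only the log Bayes factor machinery runs
    (used by the permutation and bootstrap wrappers); the posterior mean
    curve, credible band and predictive chi-square are skipped.
    """
    cols = _resolve_event_cols(items, event_cols)
    events = items.loc[:, list(cols)].to_numpy(dtype=float)
    if events.shape[0] == 0:
        raise PcitError("empty item table")
    outcomes = items["outcome"].to_numpy(dtype=float)
    if np.any(outcomes < 0) or np.any(outcomes > 1):
        raise PcitError("outcomes must lie in [0, 1]")
    if rescale:
        events = rescale_evidence(events.ravel()).reshape(events.shape)
    elif np.any(events < -1.0) or np.any(events > 1.0):
        raise PcitError("evidence outside [-1, 1]; pass rescale=True or rescale first")

    if rng is None:
        rng = np.random.default_rng(seed)
    knot_x, knot_y = sample_curves(n_samples, rng)
    log_w, _, _ = importance_weights(knot_x, knot_y, events, outcomes, chunk_size=chunk_size)
    cons = label_consistency_batch(knot_y)
    lbf, capped = log_bayes_factor(log_w, cons, cap=cap)
    w = np.exp(log_w)
    ess = float(1.0 / np.sum(w**2))
    if ess < ess_floor:
        warnings.warn(f"posterior effective sample size {ess:.1f} below floor {ess_floor}", stacklevel=2)
    prior_frac = float(np.mean(cons))
    post_frac = float(np.sum(w[cons]))

    if summarize:
        grid = np.asarray(grid, dtype=float)
        mean, lo, hi = summarize_posterior(knot_x, knot_y, log_w, grid, chunk_size=chunk_size)
        chi2, chi2_p = predictive_chi2(events, outcomes, grid, mean, df=chi2_df)
    else:
        grid = np.asarray(grid, dtype=float)
        mean = lo = hi = np.full(grid.shape, np.nan)
        chi2 = chi2_p = float("nan")

    return PcitResult(
        grid=grid,
        mean_curve=mean,
        band_lo=lo,
        band_hi=hi,
        log_bayes_factor=lbf,
        lbf_capped=capped,
        chi2=chi2,
        chi2_p=chi2_p,
        chi2_df=chi2_df,
        prior_consistent_fraction=prior_frac,
        posterior_consistent_fraction=post_frac,
        n_samples=int(n_samples),
        n_items=int(events.shape[0]),
        ess=ess,
        event_cols=cols,
    )


def read_items(path) -> pd.DataFrame:
    """Read an item table (tab-separated; item_id, participant_id, events, outcome)."""
    return pd.read_csv(path, sep="\t")


def write_items(items: pd.DataFrame, path) -> None:
    items.to_csv(path, sep="\t", index=False)


def plot_posterior(result: PcitResult, ax=None, **kwargs):
    """Plot the posterior mean curve with its 90% credible ribbon."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.fill_between(result.grid, result.band_lo, result.band_hi, alpha=0.3, label="90% credible interval")
    ax.plot(result.grid, result.mean_curve, lw=2, label="posterior mean", **kwargs)
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("classifier evidence (rescaled)")
    ax.set_ylabel("change in memory strength")
    ax.legend()
    return ax
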