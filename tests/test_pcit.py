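"""Curve induction: prior, evaluation, labeling, weighting, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logsumexp

from wmforget import pcit
from wmforget.pcit import PcitError, PlasticityCurve

from _oracles import consistent_by_walk, curve_eval, profiled_loglik


# -- curve object and prior ----------------------------------------------


def test_curve_validation():
    with pytest.raises(PcitError):
        PlasticityCurve((-1, 0.5, 0.2, 1), (0, 0, 0, 0))  # unsorted
    with pytest.raises(PcitError):
        PlasticityCurve((-1, 0, 0.5, 1), (0, 2, 0, 0))  # height out of range
    with pytest.raises(PcitError):
        PlasticityCurve((0, 0.2, 0.5, 1), (0, 0, 0, 0))  # does not span [-1, 1]


def test_sample_curves_respects_prior_support(rng):
    kx, ky = pcit.sample_curves(2000, rng)
    assert np.all(np.diff(kx, axis=1) >= 0)
    assert np.all(kx[:, 0] == -1) and np.all(kx[:, 3] == 1)
    assert np.all((ky >= -1) & (ky <= 1))


def test_sample_curves_deterministic_under_seed():
    a = pcit.sample_curves(50, np.random.default_rng(5))
    b = pcit.sample_curves(50, np.random.default_rng(5))
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


def test_prior_consistent_fraction_stable_across_seeds():
    # The consistent fraction is a fixed property of the sampler; two
    # independent 1e5-sample estimates agree within +/-0.01.
    fracs = []
    for seed in (0, 1):
        _, ky = pcit.sample_curves(100_000, np.random.default_rng(seed))
        fracs.append(pcit.label_consistency_batch(ky).mean())
    assert abs(fracs[0] - fracs[1]) < 0.01


# -- evaluation -----------------------------------------------------------


def test_evaluate_exact_at_knots_and_flat_zero():
    c = PlasticityCurve((-1, -0.2, 0.4, 1), (0.3, -0.8, 0.1, 0.9))
    for x, y in zip(c.knot_x, c.knot_y):
        assert c(x) == pytest.approx(y, abs=1e-12)
    flat = PlasticityCurve((-1, 0, 0.5, 1), (0, 0, 0, 0))
    assert np.all(flat(np.linspace(-1, 1, 17)) == 0)


def test_evaluate_segment_midpoint_is_endpoint_mean():
    c = PlasticityCurve((-1, 0.0, 0.5, 1), (0.4, -0.6, 0.2, 0.8))
    assert c(-0.5) == pytest.approx((0.4 - 0.6) / 2)
    assert c(0.25) == pytest.approx((-0.6 + 0.2) / 2)
    assert c(0.75) == pytest.approx((0.2 + 0.8) / 2)


def test_evaluate_rejects_out_of_domain():
    c = PlasticityCurve((-1, 0, 0, 1), (0, 0, 0, 0))
    with pytest.raises(PcitError, match="domain"):
        c(1.5)
    with pytest.raises(PcitError, match="domain"):
        pcit.evaluate_curves(np.array([c.knot_x]), np.array([c.knot_y]), np.array([-1.2]))


def test_batch_evaluation_matches_interp_and_walk_oracle(rng):
    kx, ky = pcit.sample_curves(300, rng)
    x = np.sort(rng.uniform(-1, 1, 97))
    got = pcit.evaluate_curves(kx, ky, x)
    ref = np.array([np.interp(x, kx[i], ky[i]) for i in range(300)])
    assert np.abs(got - ref).max() < 1e-12
    # spot-check a few points against the pure-python segment walk
    for i in (0, 7, 42):
        for xx in (-1.0, x[3], x[50], 1.0):
            assert abs(pcit.evaluate_curves(kx[i : i + 1], ky[i : i + 1], [xx])[0, 0]
                       - curve_eval(kx[i], ky[i], xx)) < 1e-12


# -- consistency labeling -------------------------------------------------


@pytest.mark.parametrize(
    "ky,expected",
    [
        ((0.5, 0.5, 0.5, 0.5), False),  # flat: never drops below start
        ((1, -1, 1, 1), True),  # dips below start then rises
        ((1, 0.5, 0, -1), False),  # monotone decreasing: never rises after min
        ((0, -0.5, -0.5, 0.2), True),  # plateau minimum then rise
        ((0, 0.2, 0.5, 1), False),  # monotone increasing: never drops
        ((0.5, -0.2, -0.2, -0.2), False),  # drops but never recovers
    ],
)
def test_label_consistency_examples(ky, expected):
    c = PlasticityCurve((-1, -0.3, 0.3, 1), ky)
    assert pcit.label_consistency(c) is expected


def test_label_consistency_matches_walk_oracle_on_random_curves():
    kx, ky = pcit.sample_curves(10_000, np.random.default_rng(42))
    got = pcit.label_consistency_batch(ky)
    ref = np.array([consistent_by_walk(kx[i], ky[i]) for i in range(len(ky))])
    assert np.array_equal(got, ref)


# -- rescaling ------------------------------------------------------------


def test_rescale_examples():
    assert np.allclose(pcit.rescale_evidence([0, 0.5, 1]), [-1, 0, 1])
    assert np.allclose(pcit.rescale_evidence([2, 3, 5]), [-1, -1 / 3, 1])


@given(st.lists(st.floats(-100, 100), min_size=2, unique=True))
@settings(deadline=None, max_examples=50)
def test_rescale_maps_extremes_exactly(scores):
    out = pcit.rescale_evidence(scores)
    assert out.min() == -1.0 and out.max() == 1.0
    # order preserved (monotone affine map)
    assert np.all(np.diff(out[np.argsort(np.asarray(scores))]) >= 0)


def test_rescale_constant_rejected():
    with pytest.raises(PcitError, match="constant"):
        pcit.rescale_evidence([0.4, 0.4, 0.4])


# -- likelihood and weights ----------------------------------------------


def test_item_log_likelihood_flat_curve_is_log_half():
    flat = PlasticityCurve((-1, 0, 0, 1), (0, 0, 0, 0))
    for y in (0, 1 / 3, 2 / 3, 1):
        assert pcit.item_log_likelihood(flat, [0.2, -0.7], y, beta0=0.0) == pytest.approx(np.log(0.5))


def test_item_log_likelihood_saturates_toward_zero():
    up = PlasticityCurve((-1, 0, 0, 1), (1, 1, 1, 1))
    ll = pcit.item_log_likelihood(up, [1.0, 1.0], 1.0, beta0=15.0)
    assert -1e-6 < ll <= 0.0


def test_three_item_loglik_matches_hand_computation():
    c = PlasticityCurve((-1, -0.5, 0.5, 1), (0.2, -0.6, 0.0, 0.8))
    events = [(-0.75, 0.25), (0.0, 1.0), (-1.0, -0.5)]
    outcomes = [1.0, 1 / 3, 0.0]
    beta0 = 0.4
    total = sum(pcit.item_log_likelihood(c, ev, y, beta0) for ev, y in zip(events, outcomes))
    hand = 0.0
    for (e1, e2), y in zip(events, outcomes):
        d = curve_eval(c.knot_x, c.knot_y, e1) + curve_eval(c.knot_x, c.knot_y, e2)
        p = 1 / (1 + np.exp(-(beta0 + d)))
        hand += y * np.log(p) + (1 - y) * np.log(1 - p)
    assert total == pytest.approx(hand, abs=1e-12)


def test_profile_intercept_matches_scalar_oracle(rng):
    kx, ky = pcit.sample_curves(20, rng)
    events = rng.uniform(-1, 1, (15, 2))
    y = rng.integers(0, 4, 15) / 3.0
    _, _, _ = pcit.importance_weights(kx, ky, events, y)
    _, ll = pcit.profile_intercept(pcit._event_deltas(kx, ky, events), y)
    for i in range(20):
        ref = profiled_loglik(kx[i], ky[i], events, y)
        assert ll[i] == pytest.approx(ref, abs=1e-7)


def test_identical_curves_get_identical_weights(rng):
    kx = np.repeat([[-1, -0.2, 0.3, 1]], 4, axis=0)
    ky = np.repeat([[0.5, -0.5, 0.1, 0.9]], 4, axis=0)
    events = rng.uniform(-1, 1, (10, 2))
    y = rng.integers(0, 2, 10).astype(float)
    logw, ll, _ = pcit.importance_weights(kx, ky, events, y)
    assert np.ptp(logw) == 0
    assert np.allclose(logw, -np.log(4))


def test_flat_curve_weight_equals_intercept_only_likelihood(rng):
    # a zero curve reduces the model to the best intercept-only fit
    kx = np.array([[-1, 0, 0, 1.0]])
    ky = np.zeros((1, 4))
    y = np.array([1.0, 1.0, 0.0, 1 / 3, 2 / 3])
    events = rng.uniform(-1, 1, (5, 1))
    _, ll, _ = pcit.importance_weights(kx, ky, events, y)
    ybar = y.mean()
    null_ll = y.size * (ybar * np.log(ybar) + (1 - ybar) * np.log(1 - ybar))
    assert ll[0] == pytest.approx(null_ll, abs=1e-8)


def test_u_curve_items_upweight_consistent_curves(rng):
    # generate outcomes from a U-shaped truth; consistent curves should
    # carry more posterior weight on average than inconsistent ones
    truth = PlasticityCurve((-1, -0.3, 0.3, 1), (0.3, -0.9, -0.3, 0.9))
    events = rng.uniform(-1, 1, (300, 2))
    p = expit(0.2 + truth(events[:, 0]) + truth(events[:, 1]))
    y = np.round(np.clip(p + rng.normal(0, 0.08, 300), 0, 1) * 3) / 3
    kx, ky = pcit.sample_curves(3000, rng)
    logw, _, _ = pcit.importance_weights(kx, ky, events, y)
    cons = pcit.label_consistency_batch(ky)
    w = np.exp(logw)
    assert w[cons].mean() > w[~cons].mean()


# -- posterior summaries --------------------------------------------------


def test_all_weight_on_one_curve_collapses_band(rng):
    kx, ky = pcit.sample_curves(40, rng)
    logw = np.full(40, -1e6)
    logw[17] = 0.0
    logw -= logsumexp(logw)
    grid = np.linspace(-1, 1, 21)
    mean, lo, hi = pcit.summarize_posterior(kx, ky, logw, grid)
    winner = pcit.evaluate_curves(kx[17:18], ky[17:18], grid)[0]
    assert np.allclose(mean, winner)
    assert np.allclose(lo, winner) and np.allclose(hi, winner)


def test_uniform_weights_over_symmetric_prior_average_to_zero():
    kx, ky = pcit.sample_curves(20_000, np.random.default_rng(8))
    logw = np.full(20_000, -np.log(20_000))
    grid = np.linspace(-1, 1, 11)
    mean, lo, hi = pcit.summarize_posterior(kx, ky, logw, grid)
    assert np.abs(mean).max() < 0.02  # prior is symmetric about y = 0
    assert np.all(lo <= mean) and np.all(mean <= hi)


def test_band_contains_weighted_median(rng):
    kx, ky = pcit.sample_curves(500, rng)
    logw = rng.normal(0, 1, 500)
    logw -= logsumexp(logw)
    grid = np.linspace(-1, 1, 15)
    _, lo, hi = pcit.summarize_posterior(kx, ky, logw, grid)
    vals = pcit.evaluate_curves(kx, ky, grid)
    w = np.exp(logw)
    for j in range(grid.size):
        order = np.argsort(vals[:, j])
        med = vals[order, j][np.searchsorted(np.cumsum(w[order]), 0.5)]
        assert lo[j] <= med <= hi[j]


# -- log Bayes factor -----------------------------------------------------


def test_no_items_flat_likelihood_gives_near_zero_lbf(rng):
    # uniform weights: posterior equals prior, so the score vanishes
    kx, ky = pcit.sample_curves(5000, rng)
    logw = np.full(5000, -np.log(5000))
    lbf, capped = pcit.log_bayes_factor(logw, pcit.label_consistency_batch(ky))
    assert not capped and lbf == pytest.approx(0.0, abs=1e-9)


def test_single_class_sample_is_capped():
    logw = np.full(10, -np.log(10))
    lbf, capped = pcit.log_bayes_factor(logw, np.ones(10, bool))
    assert capped and lbf == 10.0
    lbf, capped = pcit.log_bayes_factor(logw, np.zeros(10, bool))
    assert capped and lbf == -10.0


def test_lbf_matches_hand_enumeration_on_20_curves(rng):
    logw = rng.normal(0, 2, 20)
    logw -= logsumexp(logw)
    labels = rng.random(20) < 0.4
    if labels.sum() in (0, 20):
        labels[:3] = [True, False, True]
    w = np.exp(logw)
    hand = np.log(w[labels].sum() / w[~labels].sum()) - np.log(labels.sum() / (~labels).sum())
    got, capped = pcit.log_bayes_factor(logw, labels)
    assert not capped and got == pytest.approx(hand, abs=1e-12)


# -- predictive chi-square ------------------------------------------------


def test_predictive_chi2_zero_items_rejected():
    with pytest.raises(PcitError):
        pcit.predictive_chi2(np.empty((0, 2)), np.empty(0), np.linspace(-1, 1, 5), np.zeros(5))


def test_predictive_chi2_flat_curve_is_zero(rng):
    events = rng.uniform(-1, 1, (30, 2))
    y = rng.integers(0, 4, 30) / 3
    grid = np.linspace(-1, 1, 5)
    stat, p = pcit.predictive_chi2(events, y, grid, np.zeros(5))
    assert stat == pytest.approx(0.0, abs=1e-9) and p == pytest.approx(1.0)


# -- partialing out -------------------------------------------------------


def test_partial_out_orthogonal_covariate_just_centers():
    t = np.array([1.0, -1.0, 2.0, -2.0])
    c = np.array([1.0, 1.0, -1.0, -1.0])  # orthogonal to t and to centering
    got = pcit.partial_out(t, c)
    assert np.allclose(got, pcit.rescale_evidence(t - t.mean()))
    # constant covariate: documented fallback to plain centering
    assert np.allclose(pcit.partial_out(t, np.ones(4)), pcit.rescale_evidence(t - t.mean()))


def test_partial_out_identical_target_surfaces_constant_error():
    t = np.array([0.2, 0.4, 0.6, 0.9])
    with pytest.raises(PcitError, match="constant"):
        pcit.partial_out(t, t)


def test_partial_out_matches_hand_ols():
    t = np.array([1.0, 2.0, 2.0, 4.0])
    c = np.array([0.0, 1.0, 2.0, 3.0])
    beta = np.cov(c, t, bias=True)[0, 1] / np.var(c)
    resid = t - (t.mean() + beta * (c - c.mean()))
    assert np.allclose(pcit.partial_out(t, c), pcit.rescale_evidence(resid), atol=1e-10)


# -- fit_pcit end-to-end ---------------------------------------------------


def _items(rng, n=100, truth=None, beta0=0.2, noise=0.1):
    ev = rng.uniform(-1, 1, (n, 2))
    if truth is None:
        p = np.full(n, 0.5)
    else:
        p = expit(beta0 + truth(ev[:, 0]) + truth(ev[:, 1]))
    y = np.round(np.clip(p + rng.normal(0, noise, n), 0, 1) * 3) / 3
    return pd.DataFrame({"item_id": np.arange(n), "participant_id": 0,
                         "ev_pre": ev[:, 0], "ev_post": ev[:, 1], "outcome": y})


def test_fit_pcit_reproducible_and_bands_bracket_mean(rng):
    items = _items(np.random.default_rng(3))
    a = pcit.fit_pcit(items, n_samples=2000, seed=11)
    b = pcit.fit_pcit(items, n_samples=2000, seed=11)
    assert a.log_bayes_factor == b.log_bayes_factor
    assert np.array_equal(a.mean_curve, b.mean_curve)
    assert np.all(a.band_lo <= a.mean_curve) and np.all(a.mean_curve <= a.band_hi)
    assert 0 < a.prior_consistent_fraction < 1


def test_fit_pcit_more_samples_shrink_monte_carlo_error():
    # split-half spread of the log BF shrinks as the sample grows
    items = _items(np.random.default_rng(4), truth=PlasticityCurve((-1, -0.3, 0.3, 1), (0.3, -0.9, -0.3, 0.9)))
    spreads = []
    for n in (1000, 10_000):
        vals = [pcit.fit_pcit(items, n_samples=n, seed=s, summarize=False).log_bayes_factor for s in range(6)]
        spreads.append(np.std(vals))
    assert spreads[1] < spreads[0]


def test_fit_pcit_requires_valid_inputs(rng):
    items = _items(np.random.default_rng(5), n=20)
    with pytest.raises(PcitError, match="empty"):
        pcit.fit_pcit(items.iloc[:0], n_samples=10)
    bad = items.copy()
    bad["ev_pre"] = bad["ev_pre"] + 5
    with pytest.raises(PcitError, match="outside"):
        pcit.fit_pcit(bad, n_samples=10, rescale=False)
    bad2 = items.copy()
    bad2["outcome"] = 2.0
    with pytest.raises(PcitError, match="outcomes"):
        pcit.fit_pcit(bad2, n_samples=10)
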