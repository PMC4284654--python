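"""Behavioural coding and analysis.

Graded recognition coding (sure old = 1, unsure old = 2/3, unsure new =
1/3, sure new = 0; exact thirds internally, 0.667/0.333 are display
roundings), recognition-memory sensitivity as ROC area, and the
logistic regression relating classifier evidence to working-memory
probe accuracy with percentile-bootstrap confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import statsmodels.api as sm
from scipy.stats import mannwhitneyu


class BehaviorError(ValueError):
    """Raised for unknown response labels and degenerate regressions."""


#: Graded memory strength per response: the fixed monotone image onto [0, 1].
STRENGTH_OF_RESPONSE = {
    "sure_new": Fraction(0),
    "unsure_new": Fraction(1, 3),
    "unsure_old": Fraction(2, 3),
    "sure_old": Fraction(1),
}

#: Bound on |slope| used to report complete separation instead of diverging.
SLOPE_CAP = 25.0


def code_memory_strength(response: str) -> Fraction:
    """Map a recognition response to its graded strength (exact rational)."""
    try:
        return STRENGTH_OF_RESPONSE[response]
    except KeyError:
        raise BehaviorError(
            f"unknown response {response!r}; expected one of {sorted(STRENGTH_OF_RESPONSE)}"
        ) from None


def roc_auc(old_scores, new_scores) -> float:
    """Probability a random old item outscores a random new item.

    Mann-Whitney formulation; ties count one half.  Chance is 0.5 and
    perfect separation is 1.0.
    """
    old = np.asarray(old_scores, dtype=float)
    new = np.asarray(new_scores, dtype=float)
    if old.size == 0 or new.size == 0:
        raise BehaviorError("both score lists must be non-empty")
    u = mannwhitneyu(old, new, alternative="two-sided").statistic
    return float(u / (old.size * new.size))


@dataclass
class WmRegressionResult:
    """Logistic slope of probe accuracy on evidence, with bootstrap CI."""

    beta1: float
    ci95: tuple[float, float]
    n_boot: int
    predictor_name: str
    significant: bool
    separation: bool
    beta0: float

    def to_dict(self) -> dict:
        return {
            "beta1": self.beta1,
            "ci95": list(self.ci95),
            "n_boot": self.n_boot,
            "predictor_name": self.predictor_name,
            "significant": self.significant,
            "separation": self.separation,
            "beta0": self.beta0,
        }


def _fit_slope(evidence: np.ndarray, accuracy: np.ndarray) -> tuple[float, float, bool]:
    """ML logistic fit; on complete separation the slope is capped and flagged."""
    X = sm.add_constant(evidence)
    try:
        res = sm.Logit(accuracy, X).fit(disp=0, method="lbfgs", maxiter=500)
        b0, b1 = float(res.params[0]), float(res.params[1])
    except Exception:
        b0, b1 = 0.0, np.inf * (1 if np.corrcoef(evidence, accuracy)[0, 1] >= 0 else -1)
    if not np.isfinite(b1) or abs(b1) > SLOPE_CAP:
        sign = np.sign(b1) if np.isfinite(b1) and b1 != 0 else np.sign(np.corrcoef(evidence, accuracy)[0, 1])
        return b0 if np.isfinite(b0) else 0.0, float(sign * SLOPE_CAP), True
    return b0, b1, False


def wm_logistic(
    evidence,
    accuracy,
    n_boot: int = 1000,
    seed=None,
    rng: np.random.Generator | None = None,
    predictor_name: str = "evidence",
) -> WmRegressionResult:
    """Regress binary probe accuracy on a per-trial evidence scalar.

    The slope is the maximum-likelihood logistic coefficient; the 95%
    CI is a seeded percentile bootstrap over trials.  Degenerate
    resamples (a single outcome class) are dropped; if more than 10%
    are degenerate the data are too sparse and an error is raised.
    """
    evidence = np.asarray(evidence, dtype=float)
    accuracy = np.asarray(accuracy, dtype=float)
    if evidence.shape != accuracy.shape or evidence.ndim != 1:
        raise BehaviorError("evidence and accuracy must be equal-length 1-D arrays")
    if evidence.size < 10:
        raise BehaviorError("need at least 10 trials")
    if len(np.unique(accuracy)) < 2:
        raise BehaviorError("accuracy outcomes are all identical; the slope is undefined")
    if n_boot < 1:
        raise BehaviorError("n_boot must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)

    beta0, beta1, separation = _fit_slope(evidence, accuracy)

    n = evidence.size
    slopes = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        acc = accuracy[idx]
        if acc.min() == acc.max():
            continue
        _, b1, _ = _fit_slope(evidence[idx], acc)
        slopes.append(b1)
    if len(slopes) < 0.9 * n_boot:
        raise BehaviorError("too many degenerate bootstrap resamples; data too sparse")
    lo, hi = np.percentile(slopes, [2.5, 97.5])
    return WmRegressionResult(
        beta1=beta1,
        ci95=(float(lo), float(hi)),
        n_boot=int(n_boot),
        predictor_name=predictor_name,
        significant=bool(lo > 0 or hi < 0),
        separation=separation,
        beta0=beta0,
    )
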