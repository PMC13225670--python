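"""Empirical-Bayes prior-variance machinery for single-effect regressions.

A single-effect regression (SER) of a residual r on columns x_j with prior
b ~ N(0, V) and selection weights w_j has log evidence (up to a V-free
constant) log sum_j w_j BF_j(V) with

    log BF_j(V) = -0.5 log(1 + V d_j / s2) + 0.5 V (x_j'r / s2)^2 / (1 + V d_j / s2),

where d_j = x_j'x_j and s2 the residual variance.  The prior variance of each
effect is set to the evidence-maximizing V, collapsed to exactly 0 unless the
optimum beats the null model by a margin (in nats); collapsed effects carry
no signal.  The collapse rule keeps effects from diffusely tracking noise,
which would otherwise compound into spurious inclusion probabilities across
the L effects.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

NULL_EVIDENCE_MARGIN = 0.5  # nats the optimum must beat V = 0 by
ACTIVE_V_TOL = 1e-9  # prior variances at or below this count as collapsed


def ser_log_evidence(
    V: float, score: np.ndarray, prec: np.ndarray, log_w: np.ndarray | None = None
) -> float:
    """Log evidence of the SER at prior variance V, relative to V = 0.

    ``score`` is x_j'r / s2, ``prec`` is d_j / s2, and ``log_w`` optional
    log selection-prior weights (need not be normalized; uniform when None).
    Returns 0 at V <= 0 by construction.
    """
    if V <= 0:
        return 0.0
    log_bf = -0.5 * np.log1p(V * prec) + 0.5 * V * score**2 / (1.0 + V * prec)
    if log_w is None:
        m = log_bf.max()
        return float(m + np.log(np.mean(np.exp(log_bf - m))))
    logw = log_w - _logsumexp(log_w)
    return float(_logsumexp(logw + log_bf))


def _logsumexp(x: np.ndarray) -> float:
    m = np.max(x)
    if not np.isfinite(m):
        return float(m)
    return float(m + np.log(np.sum(np.exp(x - m))))


def optimize_prior_variance(
    score: np.ndarray,
    prec: np.ndarray,
    v_max: float,
    log_w: np.ndarray | None = None,
    margin: float = NULL_EVIDENCE_MARGIN,
) -> float:
    """Evidence-maximizing prior variance of one single effect, or 0.

    Collapses to 0 unless the optimized evidence exceeds ``margin`` nats.
    """
    res = minimize_scalar(
        lambda logv: -ser_log_evidence(np.exp(logv), score, prec, log_w),
        bounds=(np.log(1e-10), np.log(max(v_max, 1e-8))),
        method="bounded",
        options={"xatol": 1e-6},
    )
    v_opt = float(np.exp(res.x))
    return v_opt if ser_log_evidence(v_opt, score, prec, log_w) > margin else 0.0
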