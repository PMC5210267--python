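"""The four multiple-testing procedures.

Three classical procedures and the Bon-EV procedure built from them:

* **Benjamini-Hochberg (BH)** — the step-up FDR procedure: reject the k
  smallest p-values where k is the largest i with p_(i) <= (i/m) alpha.
* **Storey q-values** — the same step-up rule with the threshold relaxed
  by an estimate of the true-null proportion: p_(i) <= (i / (m pi0_hat)) alpha.
  Equivalently, q = min(1, pi0_hat * BH-adjusted p).
* **Bonferroni E(V) control** — single-step: reject p_i <= gamma / m,
  which bounds the *expected number* of false discoveries by gamma.
* **Bon-EV** — a single-step pFDR rule: reject p_i <= alpha * r_hat / pi0_hat,
  where r_hat estimates Pr(P* <= alpha) by the fraction of hypotheses
  whose BH-adjusted p-value P* falls at or below alpha, and pi0_hat comes
  from Storey's tail estimator.  The pi0_hat divisor buys power over BH;
  anchoring the cutoff to the BH rejection fraction reins in the false
  discoveries (and the replicate-to-replicate variability) of Storey's
  procedure.

With pi0_hat capped at 1 the rejection sets nest:
BH ⊆ Bon-EV ⊆ Storey, at every alpha.
"""

from __future__ import annotations

import numpy as np

from .pi0 import DEFAULT_LAMBDA, DEFAULT_LAMBDA_GRID, estimate_pi0
from .types import AdjustmentResult, Pi0Estimate, Pi0Method, Procedure, PValueVector

__all__ = [
    "bh_adjust",
    "bh_reject",
    "storey_qvalues",
    "storey_reject",
    "bonferroni_ev_reject",
    "estimate_rejection_fraction",
    "bonev_adjust",
]


def _check_alpha(alpha: float) -> None:
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie strictly in (0, 1), got {alpha}")


def _stepup_adjust(p: np.ndarray, scale: float) -> np.ndarray:
    """Adjusted p-values for the step-up rule p_(i) <= i * alpha / scale.

    Sort ascending, compute p_(i) * scale / i, take the running minimum
    from the largest index downward, cap at 1, restore input order.
    Ties are handled stably: equal raw p-values get equal adjusted values.
    """
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * scale / np.arange(1, m + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = adj
    return out


def bh_adjust(pvals: PValueVector) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values P*, in input order.

    Thresholding the result at any alpha reproduces the BH step-up rule
    at that alpha.
    """
    return _stepup_adjust(pvals.p, float(pvals.m))


def bh_reject(pvals: PValueVector, alpha: float) -> AdjustmentResult:
    """Apply the BH step-up procedure at nominal FDR level ``alpha``."""
    _check_alpha(alpha)
    adjusted = bh_adjust(pvals)
    rejected = adjusted <= alpha
    k = int(np.count_nonzero(rejected))
    # realized threshold (i/m) alpha at the step-up index k
    cutoff = k * alpha / pvals.m
    return AdjustmentResult(
        procedure=Procedure.BH,
        alpha=alpha,
        ids=pvals.ids,
        adjusted=adjusted,
        rejected=rejected,
        cutoff=cutoff,
    )


def storey_qvalues(pvals: PValueVector, pi0: Pi0Estimate | float) -> np.ndarray:
    """Storey q-values: the step-up adjustment with the pi0_hat factor.

    q_(i) = min over j >= i of pi0_hat * m * p_(j) / j, capped at 1;
    elementwise this equals ``min(1, pi0_hat * bh_adjust(p))``.
    """
    pi0_val = pi0.pi0 if isinstance(pi0, Pi0Estimate) else float(pi0)
    if pi0_val <= 0.0:
        raise ValueError(f"pi0 must be positive, got {pi0_val}")
    return _stepup_adjust(pvals.p, pi0_val * pvals.m)


def storey_reject(
    pvals: PValueVector,
    alpha: float,
    pi0_method: str | Pi0Method = Pi0Method.FIXED_LAMBDA,
    lam: float = DEFAULT_LAMBDA,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    pi0: Pi0Estimate | None = None,
) -> AdjustmentResult:
    """Storey's q-value procedure at level ``alpha``.

    ``pi0`` may be supplied to reuse an estimate already computed on the
    same vector; otherwise it is estimated here per ``pi0_method``.
    """
    _check_alpha(alpha)
    if pi0 is None:
        pi0 = estimate_pi0(pvals, method=pi0_method, lam=lam, lambda_grid=lambda_grid)
    q = storey_qvalues(pvals, pi0)
    rejected = q <= alpha
    k = int(np.count_nonzero(rejected))
    cutoff = k * alpha / (pvals.m * pi0.pi0)
    return AdjustmentResult(
        procedure=Procedure.STOREY,
        alpha=alpha,
        ids=pvals.ids,
        adjusted=q,
        rejected=rejected,
        pi0_hat=pi0.pi0,
        cutoff=cutoff,
        pi0_estimate=pi0,
    )


def bonferroni_ev_reject(pvals: PValueVector, gamma: float) -> AdjustmentResult:
    """Bonferroni control of the expected number of false discoveries.

    Rejects exactly ``{i : p_i <= gamma / m}``.  Under independent
    uniform nulls E(V) = m0 * gamma / m <= gamma, for any dependence in
    fact, since the bound is a union-free sum of marginal probabilities.
    ``gamma`` is a budget of expected false discoveries (>= 0), not a
    probability; the reported ``adjusted`` values are min(1, p_i * m / gamma).
    """
    if gamma < 0:
        raise ValueError(f"gamma must be non-negative, got {gamma}")
    cutoff = gamma / pvals.m
    rejected = pvals.p <= cutoff
    if gamma > 0:
        adjusted = np.minimum(1.0, pvals.p * pvals.m / gamma)
    else:
        # gamma = 0: only exact zeros are rejected
        adjusted = np.where(pvals.p == 0.0, 0.0, 1.0)
    return AdjustmentResult(
        procedure=Procedure.BONFERRONI_EV,
        alpha=gamma,
        ids=pvals.ids,
        adjusted=adjusted,
        rejected=rejected,
        cutoff=cutoff,
    )


def estimate_rejection_fraction(pvals: PValueVector, alpha: float) -> float:
    """Plug-in estimate of Pr(P* <= alpha): the BH rejection fraction.

    Returns ``#{BH-adjusted p <= alpha} / m``.
    """
    _check_alpha(alpha)
    return float(np.count_nonzero(bh_adjust(pvals) <= alpha) / pvals.m)


def bonev_adjust(
    pvals: PValueVector,
    alpha: float,
    pi0_method: str | Pi0Method = Pi0Method.FIXED_LAMBDA,
    lam: float = DEFAULT_LAMBDA,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    pi0: Pi0Estimate | None = None,
) -> AdjustmentResult:
    """The Bon-EV procedure at nominal pFDR level ``alpha``.

    Computes pi0_hat, the BH rejection fraction r_hat, the single-step
    cutoff ``c = alpha * r_hat / pi0_hat``, and rejects ``{i : p_i <= c}``.
    Adjusted p-values are ``min(1, p_i * pi0_hat / r_hat)`` when r_hat > 0
    (so thresholding at alpha reproduces the rule) and all 1 when
    r_hat = 0, where the cutoff is 0 and nothing but an exact zero could
    be rejected.

    Parameters
    ----------
    pvals
        Raw p-values.
    alpha
        Nominal pFDR level in (0, 1).
    pi0_method, lam, lambda_grid
        Passed to :func:`bonev.pi0.estimate_pi0` unless ``pi0`` is given.
    pi0
        Optional precomputed estimate, to share with Storey's procedure.
    """
    _check_alpha(alpha)
    if pi0 is None:
        pi0 = estimate_pi0(pvals, method=pi0_method, lam=lam, lambda_grid=lambda_grid)
    r_hat = estimate_rejection_fraction(pvals, alpha)
    cutoff = alpha * r_hat / pi0.pi0
    if r_hat > 0.0:
        adjusted = np.minimum(1.0, pvals.p * pi0.pi0 / r_hat)
        rejected = adjusted <= alpha
    else:
        # cutoff is 0 and no p-value can be 0 here (a zero would force a
        # BH rejection, hence r_hat >= 1/m): nothing is rejected
        adjusted = np.ones(pvals.m)
        rejected = np.zeros(pvals.m, dtype=bool)
    return AdjustmentResult(
        procedure=Procedure.BONEV,
        alpha=alpha,
        ids=pvals.ids,
        adjusted=adjusted,
        rejected=rejected,
        pi0_hat=pi0.pi0,
        rejection_fraction_hat=r_hat,
        cutoff=cutoff,
        pi0_estimate=pi0,
    )
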