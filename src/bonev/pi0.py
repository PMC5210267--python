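"""Estimators of the true-null proportion pi0 = m0 / m.

Both estimators are built on the tail-count statistic
``#{p_i > lambda} / ((1 - lambda) m)``: under the complete null the
p-values are Uniform(0, 1) and the statistic has expectation 1, while
alternatives concentrate near 0 and inflate only the denominator, so the
estimator is conservatively biased upward toward pi0 <= E(pi0_hat).

The fixed-lambda estimator evaluates the statistic at a single lambda
(default 0.5).  The smoother variant evaluates it on a grid of lambdas,
fits a cubic least-squares polynomial to pi0_hat(lambda), and reads off
the fit at the largest grid point, where the mixture's alternative
component has mostly decayed.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .types import Pi0Estimate, Pi0Method, PValueVector

DEFAULT_LAMBDA = 0.5
DEFAULT_LAMBDA_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))


def _clip(raw: float, m: int) -> float:
    # floor at 1/m prevents division blow-up in the Bon-EV cutoff;
    # cap at 1 preserves the BH ⊆ Bon-EV ⊆ Storey nesting
    return float(min(1.0, max(1.0 / m, raw)))


def _tail_fraction(p: np.ndarray, lam: float) -> float:
    return float(np.count_nonzero(p > lam) / ((1.0 - lam) * p.size))


def pi0_fixed_lambda(pvals: PValueVector, lam: float = DEFAULT_LAMBDA) -> Pi0Estimate:
    """Estimate pi0 as ``#{p_i > lambda} / ((1 - lambda) m)``.

    Parameters
    ----------
    pvals
        The raw p-values.
    lam
        Tail threshold, strictly inside (0, 1).

    Returns
    -------
    Pi0Estimate
        The formula value, floored at ``1/m`` and capped at 1; the raw
        value is kept in ``pi0_raw``.
    """
    if not (0.0 < lam < 1.0):
        raise ValueError(f"lambda must lie strictly in (0, 1), got {lam}")
    raw = _tail_fraction(pvals.p, lam)
    return Pi0Estimate(
        pi0=_clip(raw, pvals.m), pi0_raw=raw, lam=lam, method=Pi0Method.FIXED_LAMBDA
    )


def pi0_smoother(
    pvals: PValueVector, lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID
) -> Pi0Estimate:
    """Estimate pi0 by smoothing pi0_hat(lambda) over a lambda grid.

    Computes the fixed-lambda estimate at every grid point, fits a cubic
    polynomial by least squares, and evaluates the fit at the largest
    lambda.  The cubic fit is the deterministic smoothing choice: it has
    no free smoothing parameter, so results are machine-reproducible.

    Parameters
    ----------
    pvals
        The raw p-values.
    lambda_grid
        Strictly increasing values in (0, 1), at least 4 of them
        (a cubic needs 4 points).
    """
    grid = np.asarray(lambda_grid, dtype=float)
    if grid.size < 4:
        raise ValueError(f"lambda grid needs at least 4 points, got {grid.size}")
    if (np.diff(grid) <= 0).any():
        raise ValueError("lambda grid must be strictly increasing")
    if grid[0] <= 0.0 or grid[-1] >= 1.0:
        raise ValueError("lambda grid values must lie strictly in (0, 1)")

    pi0_at = np.array([_tail_fraction(pvals.p, lam) for lam in grid])
    coefs = np.polynomial.polynomial.polyfit(grid, pi0_at, deg=3)
    raw = float(np.polynomial.polynomial.polyval(grid[-1], coefs))
    return Pi0Estimate(
        pi0=_clip(raw, pvals.m),
        pi0_raw=raw,
        lam=tuple(float(x) for x in grid),
        method=Pi0Method.SMOOTHER,
    )


def estimate_pi0(
    pvals: PValueVector,
    method: str | Pi0Method = Pi0Method.FIXED_LAMBDA,
    lam: float = DEFAULT_LAMBDA,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
) -> Pi0Estimate:
    """Dispatch to the chosen pi0 estimator."""
    method = Pi0Method(method)
    if method is Pi0Method.FIXED_LAMBDA:
        return pi0_fixed_lambda(pvals, lam=lam)
    return pi0_smoother(pvals, lambda_grid=lambda_grid)
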