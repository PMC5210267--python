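"""Bootstrap stability of multiple-testing procedures on a two-group matrix.

Mirrors the resampling design used to compare procedures on real
expression data: samples are drawn with replacement *within* each group,
preserving the original group sizes, the per-feature test is rerun, each
procedure is applied at the nominal level, and the total number of
rejections R is recorded.  Stability is the standard deviation of R over
the B resamples (sample n-1 denominator); smaller is more stable.

Everything — pi0_hat and the BH rejection fraction included — is
re-estimated on every resample, so the distribution of R reflects the
full pipeline's variability.

The per-feature test is pluggable; the built-in default is the pooled
two-sample t-test.  (Real RNA-Seq studies would plug in count-model
p-values; any callable with the same signature works.)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .pi0 import DEFAULT_LAMBDA, estimate_pi0
from .procedures import bh_reject, bonev_adjust, storey_reject
from .types import Pi0Method, PValueVector

TestFunction = Callable[[np.ndarray, np.ndarray], PValueVector]

DEFAULT_PROCEDURES = ("bh", "bonev", "storey")


@dataclass(frozen=True)
class StabilityResult:
    """Per-procedure distribution of the rejection count over B resamples."""

    B: int
    alpha: float
    R: dict[str, np.ndarray]

    def sd(self, procedure: str) -> float:
        """SD of R (sample, n-1 denominator) — the stability measure."""
        return float(self.R[procedure].std(ddof=1))

    def mean(self, procedure: str) -> float:
        return float(self.R[procedure].mean())


def _default_test(control: np.ndarray, treatment: np.ndarray) -> PValueVector:
    from .simulation import two_sample_t_pvalues

    return two_sample_t_pvalues(control, treatment, equal_var=True)


def bootstrap_stability(
    data: np.ndarray,
    groups: Sequence,
    B: int = 1000,
    alpha: float = 0.05,
    procedures: Sequence[str] = DEFAULT_PROCEDURES,
    seed: int | np.random.SeedSequence | None = None,
    test: TestFunction | None = None,
    pi0_method: Pi0Method | str = Pi0Method.FIXED_LAMBDA,
    pi0_lambda: float = DEFAULT_LAMBDA,
) -> StabilityResult:
    """Bootstrap the rejection count of each procedure.

    Parameters
    ----------
    data
        Samples-by-features matrix.
    groups
        Length-n label vector with exactly two levels; each level needs
        at least 2 samples.
    B
        Number of bootstrap resamples (>= 2).
    alpha
        Nominal FDR / pFDR level passed to every procedure.
    procedures
        Subset of {"bh", "bonev", "storey"}.
    seed
        Seed for the resampling stream.
    test
        Per-feature two-group test, ``(control, treatment) -> PValueVector``;
        defaults to the pooled t-test.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError(f"data must be samples x features, got shape {data.shape}")
    groups = np.asarray(groups)
    if groups.size != data.shape[0]:
        raise ValueError("group labels must match the number of samples (rows)")
    levels = np.unique(groups)
    if levels.size != 2:
        raise ValueError(f"need exactly two group levels, got {levels.tolist()}")
    idx_a = np.flatnonzero(groups == levels[0])
    idx_b = np.flatnonzero(groups == levels[1])
    if idx_a.size < 2 or idx_b.size < 2:
        raise ValueError("each group needs at least 2 samples")
    if B < 2:
        raise ValueError("B must be >= 2")
    unknown = set(procedures) - set(DEFAULT_PROCEDURES)
    if unknown or not procedures:
        raise ValueError(f"procedures must be a non-empty subset of {DEFAULT_PROCEDURES}")

    test = test or _default_test
    rng = np.random.default_rng(seed)
    counts: dict[str, list[int]] = {proc: [] for proc in procedures}

    for _ in range(B):
        # resample with replacement within each group, sizes preserved
        take_a = rng.choice(idx_a, size=idx_a.size, replace=True)
        take_b = rng.choice(idx_b, size=idx_b.size, replace=True)
        pvals = test(data[take_a], data[take_b])

        pi0 = estimate_pi0(pvals, method=pi0_method, lam=pi0_lambda)
        for proc in procedures:
            if proc == "bh":
                res = bh_reject(pvals, alpha)
            elif proc == "storey":
                res = storey_reject(pvals, alpha, pi0=pi0)
            else:
                res = bonev_adjust(pvals, alpha, pi0=pi0)
            counts[proc].append(res.n_rejected)

    return StabilityResult(
        B=B,
        alpha=alpha,
        R={proc: np.asarray(c, dtype=int) for proc, c in counts.items()},
    )
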