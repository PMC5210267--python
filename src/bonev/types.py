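"""Core data containers shared by every procedure.

The universal input is a :class:`PValueVector` — an ordered collection of
raw p-values with unique string identifiers.  Procedures return an
:class:`AdjustmentResult` holding per-hypothesis adjusted p-values and
rejection flags together with the intermediate estimates (``pi0_hat``,
``rejection_fraction_hat``, the realized cutoff) that produced them.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


class Procedure(str, enum.Enum):
    """The four multiple-testing procedures implemented here."""

    BH = "bh"
    STOREY = "storey"
    BONFERRONI_EV = "bonferroni_ev"
    BONEV = "bonev"


class Pi0Method(str, enum.Enum):
    """How the true-null proportion pi0 was estimated."""

    FIXED_LAMBDA = "fixed_lambda"
    SMOOTHER = "smoother"


@dataclass(frozen=True)
class PValueVector:
    """Raw p-values ``p_i``, i = 1..m, with unique identifiers.

    Parameters
    ----------
    ids
        Unique string identifiers, one per hypothesis.
    p
        Raw p-values in ``[0, 1]``.  Exact 0 and 1 are legal (discrete
        tests produce them); missing values are not — drop them before
        construction (see :func:`bonev.io.read_pvalues`).

    Raises
    ------
    ValueError
        On empty input, duplicated ids, a length mismatch, NaN, or any
        p-value outside ``[0, 1]``.
    """

    ids: tuple[str, ...]
    p: np.ndarray

    def __init__(self, ids: Sequence[str], p: Sequence[float]) -> None:
        ids_t = tuple(str(i) for i in ids)
        p_arr = np.asarray(p, dtype=float)
        if p_arr.ndim != 1:
            raise ValueError(f"p must be one-dimensional, got shape {p_arr.shape}")
        if p_arr.size == 0:
            raise ValueError("p-value vector must contain at least one entry")
        if len(ids_t) != p_arr.size:
            raise ValueError(
                f"length mismatch: {len(ids_t)} ids vs {p_arr.size} p-values"
            )
        if len(set(ids_t)) != len(ids_t):
            raise ValueError("identifiers must be unique")
        if np.isnan(p_arr).any():
            bad = [ids_t[i] for i in np.flatnonzero(np.isnan(p_arr))[:5]]
            raise ValueError(f"missing p-values (e.g. at {bad}); drop them first")
        if (p_arr < 0).any() or (p_arr > 1).any():
            i = int(np.argmax((p_arr < 0) | (p_arr > 1)))
            raise ValueError(
                f"p-value out of [0, 1] at id {ids_t[i]!r}: {p_arr[i]!r}"
            )
        p_arr = p_arr.copy()
        p_arr.flags.writeable = False
        object.__setattr__(self, "ids", ids_t)
        object.__setattr__(self, "p", p_arr)

    def __len__(self) -> int:
        return self.p.size

    @property
    def m(self) -> int:
        """Number of hypotheses tested simultaneously."""
        return self.p.size


@dataclass(frozen=True)
class Pi0Estimate:
    """An estimate of the true-null proportion pi0.

    ``pi0`` is floored at ``1/m`` and capped at 1; ``pi0_raw`` is the
    uncapped formula value ``#{p_i > lambda} / ((1 - lambda) m)`` (or the
    smoother's fitted value), which may exceed 1 or hit 0.
    """

    pi0: float
    pi0_raw: float
    lam: float | tuple[float, ...]
    method: Pi0Method

    def __post_init__(self) -> None:
        if not (0.0 < self.pi0 <= 1.0):
            raise ValueError(f"pi0 must lie in (0, 1], got {self.pi0}")


@dataclass(frozen=True)
class AdjustmentResult:
    """Per-hypothesis output of one procedure at one nominal level.

    Invariants (enforced by the producing procedures, property-tested):

    * ``rejected[i]`` iff ``adjusted[i] <= alpha`` for BH, Storey and
      Bon-EV;
    * ``adjusted`` is monotone in the raw p-values and lies in [0, 1].
    """

    procedure: Procedure
    alpha: float
    ids: tuple[str, ...]
    adjusted: np.ndarray
    rejected: np.ndarray
    pi0_hat: Optional[float] = None
    rejection_fraction_hat: Optional[float] = None
    cutoff: Optional[float] = None
    pi0_estimate: Optional[Pi0Estimate] = field(default=None, repr=False)

    @property
    def n_rejected(self) -> int:
        """Total number of rejections R."""
        return int(np.count_nonzero(self.rejected))
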