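"""Monte-Carlo study of FDR, power, and stability on correlated expression data.

Each simulation cell draws two groups of samples over ``m`` genes from a
multivariate normal model: unit variances, control means 0, and the first
``round(m * pi1)`` genes mean-shifted in the treatment group by effect
sizes equally spaced from ``mu_lo`` to ``mu_hi``.  Gene-gene correlation
comes from a latent-factor construction:

* equicorrelated mode — every pair shares correlation ``rho``:
  ``x = sqrt(rho) * w + sqrt(1 - rho) * eps`` with one ``w`` per sample;
* random mode — per-gene loadings ``b_j ~ Uniform(0, sqrt(0.8))`` drawn
  once per dataset give pairwise correlations ``b_j * b_k`` in (0, 0.8),
  positive semidefinite by construction.

Each iteration tests every gene with a two-sample t-test, applies BH,
Storey and Bon-EV at the nominal level, and records R (rejections),
V (false), S (true) and the false-discovery proportion V/R (0 when
R = 0).  Per cell the summary reports the estimated FDR (mean FDP),
power (mean S / (m - m0)), stability (SD of R across iterations, sample
``n - 1`` denominator) and mean R, per procedure.

Two shipped profiles: ``desk`` (m = 2,000 genes, 300 iterations) for
interactive work and ``paper`` (m = 10,000, 1,000 iterations), the full
study scale.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pi0 import DEFAULT_LAMBDA, estimate_pi0
from .procedures import bh_reject, bonev_adjust, storey_reject
from .types import Pi0Method, PValueVector

logger = logging.getLogger(__name__)

PROCEDURES = ("bh", "bonev", "storey")

# pi1 grid of the full study
PI1_GRID = (0.005, 0.01, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.40, 0.50, 0.60, 0.75, 0.80)

RANDOM_RHO_HI = 0.8  # pairwise correlations b_j * b_k fall in (0, 0.8)


@dataclass(frozen=True)
class SimulationConfig:
    """One simulation cell.

    ``rho`` is the common pairwise gene correlation in equicorrelated
    mode (``rho_mode="equicorrelated"``) and is ignored in
    ``rho_mode="random_uniform"``, where pairwise correlations are
    products of per-dataset Uniform(0, sqrt(0.8)) loadings.
    """

    m: int = 2000
    n_per_group: int = 5
    rho_mode: str = "equicorrelated"
    rho: float = 0.0
    pi1: float = 0.2
    mu_lo: float = 1.0
    mu_hi: float = 3.0
    alpha: float = 0.05
    iterations: int = 300
    seed: int = 0
    pi0_method: Pi0Method = Pi0Method.FIXED_LAMBDA
    pi0_lambda: float = DEFAULT_LAMBDA
    equal_var: bool = True  # pooled-variance t-test; False for Welch

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not (0.0 <= self.pi1 < 1.0):
            raise ValueError(f"pi1 must lie in [0, 1), got {self.pi1}")
        if self.rho_mode not in ("equicorrelated", "random_uniform"):
            raise ValueError(f"unknown rho_mode {self.rho_mode!r}")
        if self.rho_mode == "equicorrelated" and not (0.0 <= self.rho < 1.0):
            raise ValueError(f"rho must lie in [0, 1), got {self.rho}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")

    @property
    def n_effects(self) -> int:
        """Number of non-true-null genes, round(m * pi1)."""
        return int(round(self.m * self.pi1))


#: m = 2,000 genes, 300 iterations — tractable on one CPU in minutes.
DESK_PROFILE = SimulationConfig(m=2000, iterations=300)
#: m = 10,000 genes, 1,000 iterations — the full study scale.
PAPER_PROFILE = SimulationConfig(m=10000, iterations=1000)


@dataclass(frozen=True)
class IterationOutcome:
    """Per-procedure counts from one simulated dataset."""

    R: dict[str, int]
    V: dict[str, int]
    S: dict[str, int]
    fdp: dict[str, float]


@dataclass(frozen=True)
class SimulationSummary:
    """Aggregate of one cell: per-procedure FDR, power, stability, mean R."""

    config: SimulationConfig
    fdr_hat: dict[str, float]
    fdr_se: dict[str, float]
    power_hat: dict[str, float]
    stability: dict[str, float]
    mean_R: dict[str, float]
    iterations: int
    rows: pd.DataFrame = field(repr=False)


def effect_means(config: SimulationConfig) -> np.ndarray:
    """Treatment mean shifts: equally spaced mu_lo..mu_hi over the effect genes.

    A single effect gene gets ``mu_lo``.
    """
    k = config.n_effects
    if k == 0:
        return np.empty(0)
    if k == 1:
        return np.array([config.mu_lo])
    return np.linspace(config.mu_lo, config.mu_hi, k)


def generate_dataset(
    config: SimulationConfig, rng: np.random.Generator | int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw one control/treatment dataset.

    Returns
    -------
    control, treatment
        Arrays of shape (n_per_group, m), unit gene variances.
    truth
        Boolean mask of length m, True for the effect genes (the first
        ``round(m * pi1)`` positions).
    """
    rng = np.random.default_rng(rng)
    n, m = config.n_per_group, config.m

    if config.rho_mode == "equicorrelated":
        loadings = np.full(m, np.sqrt(config.rho))
    else:
        loadings = rng.uniform(0.0, np.sqrt(RANDOM_RHO_HI), size=m)
    resid = np.sqrt(1.0 - loadings**2)

    def draw(n_samples: int) -> np.ndarray:
        w = rng.standard_normal((n_samples, 1))
        eps = rng.standard_normal((n_samples, m))
        return w * loadings + eps * resid

    control = draw(n)
    treatment = draw(n)
    truth = np.zeros(m, dtype=bool)
    k = config.n_effects
    if k:
        truth[:k] = True
        treatment[:, :k] += effect_means(config)
    return control, treatment, truth


def two_sample_t_pvalues(
    control: np.ndarray,
    treatment: np.ndarray,
    equal_var: bool = True,
    ids: Sequence[str] | None = None,
) -> PValueVector:
    """Per-gene two-sided two-sample t-test p-values.

    Pooled variance by default (df = n1 + n2 - 2); ``equal_var=False``
    switches to Welch.  A gene with zero pooled variance gets p = 1 with
    a warning when the group means agree, and raises otherwise — such
    constant data cannot arise from the normal generator, so this guards
    external inputs only.
    """
    control = np.atleast_2d(np.asarray(control, dtype=float))
    treatment = np.atleast_2d(np.asarray(treatment, dtype=float))
    if control.shape[1] != treatment.shape[1]:
        raise ValueError("control and treatment must cover the same genes")
    if control.shape[0] < 2 or treatment.shape[0] < 2:
        raise ValueError("need at least 2 samples per group")

    degenerate = (control.var(axis=0) == 0) & (treatment.var(axis=0) == 0)
    if degenerate.any():
        mean_gap = control.mean(axis=0) - treatment.mean(axis=0)
        if (degenerate & (mean_gap != 0)).any():
            n_bad = int((degenerate & (mean_gap != 0)).sum())
            raise ValueError(
                f"zero pooled variance with unequal means for {n_bad} gene(s)"
            )
        logger.warning(
            "%d gene(s) with zero variance and equal means: p set to 1",
            int(degenerate.sum()),
        )

    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(control, treatment, axis=0, equal_var=equal_var)
        p = np.asarray(res.pvalue, dtype=float)
    p = np.where(degenerate, 1.0, p)

    if ids is None:
        ids = [f"g{j}" for j in range(p.size)]
    return PValueVector(ids, p)


def evaluate_iteration(
    pvals: PValueVector,
    truth: np.ndarray,
    alpha: float,
    pi0_method: Pi0Method | str = Pi0Method.FIXED_LAMBDA,
    pi0_lambda: float = DEFAULT_LAMBDA,
) -> IterationOutcome:
    """Apply BH, Storey and Bon-EV at ``alpha``; count V, S, R per procedure.

    The false-discovery proportion is V/R with the convention 0 when
    R = 0.  The pi0 estimate is computed once and shared by Storey and
    Bon-EV, matching how the procedures are compared.
    """
    truth = np.asarray(truth, dtype=bool)
    if truth.size != pvals.m:
        raise ValueError("truth mask length must match the p-value vector")

    pi0 = estimate_pi0(pvals, method=pi0_method, lam=pi0_lambda)
    results = {
        "bh": bh_reject(pvals, alpha),
        "storey": storey_reject(pvals, alpha, pi0=pi0),
        "bonev": bonev_adjust(pvals, alpha, pi0=pi0),
    }
    R, V, S, fdp = {}, {}, {}, {}
    for name, res in results.items():
        rej = res.rejected
        R[name] = int(rej.sum())
        S[name] = int((rej & truth).sum())
        V[name] = R[name] - S[name]
        fdp[name] = V[name] / R[name] if R[name] > 0 else 0.0
    return IterationOutcome(R=R, V=V, S=S, fdp=fdp)


def iteration_seed_sequence(
    base_seed: int, cell_index: int, iteration: int
) -> np.random.SeedSequence:
    """Counter-derived seed: cells and iterations are independently reproducible."""
    return np.random.SeedSequence(entropy=base_seed, spawn_key=(cell_index, iteration))


def run_cell(config: SimulationConfig, cell_index: int = 0) -> SimulationSummary:
    """Run all iterations of one simulation cell and aggregate."""
    m0 = config.m - config.n_effects
    outcomes = []
    for it in range(config.iterations):
        rng = np.random.default_rng(
            iteration_seed_sequence(config.seed, cell_index, it)
        )
        control, treatment, truth = generate_dataset(config, rng)
        pvals = two_sample_t_pvalues(control, treatment, equal_var=config.equal_var)
        outcomes.append(
            evaluate_iteration(
                pvals, truth, config.alpha, config.pi0_method, config.pi0_lambda
            )
        )

    fdr_hat, fdr_se, power_hat, stability, mean_R = {}, {}, {}, {}, {}
    records = []
    for proc in PROCEDURES:
        Rs = np.array([o.R[proc] for o in outcomes], dtype=float)
        Ss = np.array([o.S[proc] for o in outcomes], dtype=float)
        fdps = np.array([o.fdp[proc] for o in outcomes])
        fdr_hat[proc] = float(fdps.mean())
        fdr_se[proc] = (
            float(fdps.std(ddof=1) / np.sqrt(config.iterations))
            if config.iterations > 1
            else float("nan")
        )
        power_hat[proc] = float((Ss / (config.m - m0)).mean()) if m0 < config.m else float("nan")
        stability[proc] = float(Rs.std(ddof=1)) if config.iterations > 1 else 0.0
        mean_R[proc] = float(Rs.mean())
        records.append(
            {
                "m": config.m,
                "n_per_group": config.n_per_group,
                "rho_mode": config.rho_mode,
                "rho": config.rho if config.rho_mode == "equicorrelated" else float("nan"),
                "pi1": config.pi1,
                "alpha": config.alpha,
                "iterations": config.iterations,
                "procedure": proc,
                "fdr_hat": fdr_hat[proc],
                "fdr_se": fdr_se[proc],
                "power_hat": power_hat[proc],
                "stability": stability[proc],
                "mean_R": mean_R[proc],
            }
        )
    return SimulationSummary(
        config=config,
        fdr_hat=fdr_hat,
        fdr_se=fdr_se,
        power_hat=power_hat,
        stability=stability,
        mean_R=mean_R,
        iterations=config.iterations,
        rows=pd.DataFrame.from_records(records),
    )


def run_grid(configs: Iterable[SimulationConfig]) -> pd.DataFrame:
    """Run every cell and return a tidy table, one row per procedure x cell."""
    configs = list(configs)
    if not configs:
        raise ValueError("need at least one simulation cell")
    frames = []
    for idx, cfg in enumerate(configs):
        logger.info(
            "cell %d/%d: m=%d n=%d rho_mode=%s rho=%s pi1=%g (%d iterations)",
            idx + 1, len(configs), cfg.m, cfg.n_per_group, cfg.rho_mode, cfg.rho,
            cfg.pi1, cfg.iterations,
        )
        frames.append(run_cell(cfg, cell_index=idx).rows)
    return pd.concat(frames, ignore_index=True)


def expand_grid(
    base: SimulationConfig,
    n_per_group: Sequence[int] | None = None,
    rho: Sequence[float] | None = None,
    pi1: Sequence[float] | None = None,
) -> list[SimulationConfig]:
    """Cartesian expansion of grid axes around a base configuration."""
    ns = n_per_group if n_per_group is not None else [base.n_per_group]
    rhos = rho if rho is not None else [base.rho]
    pi1s = pi1 if pi1 is not None else [base.pi1]
    return [
        replace(base, n_per_group=int(n), rho=float(r), pi1=float(p1))
        for n, r, p1 in itertools.product(ns, rhos, pi1s)
    ]
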