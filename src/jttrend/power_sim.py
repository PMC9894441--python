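"""Monte-Carlo power engine for the trend tests under penetrance models.

Case genotype counts are drawn trinomial(R, tau) and control counts
trinomial(S, upsilon), independently, under a balanced design R = S = N/2
by default.  Empirical power is the proportion of replicates whose
p-value falls at or below the significance level.

Replicates on which a test is degenerate (e.g. a zero score variance when
N*q is tiny and a genotype column empties) count as non-rejections rather
than being discarded — discarding would bias power upward — and their
number is reported in a diagnostics counter.

All replicates of a setting are evaluated through the vectorized
statistic paths in :mod:`jttrend.trend_tests`, so a 10,000-replicate
setting costs milliseconds, not minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .contingency import GenotypeTable, SCORE_PRESETS
from .genetic_model import CellProbabilities, GeneticModelSpec, cell_probabilities
from .trend_tests import ca_statistic_many, chisq1_upper_tail, jt_statistic_many
from scipy import stats

__all__ = [
    "SimulationConfig",
    "PowerEstimate",
    "simulate_table",
    "empirical_power",
    "power_curve",
    "AVAILABLE_TESTS",
]

AVAILABLE_TESTS = ("jt", "ca_additive", "ca_dominant", "ca_recessive", "allelic")


@dataclass(frozen=True)
class SimulationConfig:
    """One Monte-Carlo setting: model, design, replicate count, seed.

    ``R`` and ``S`` default to the balanced split R = floor(N/2),
    S = N - R.  ``tests`` selects which statistics to evaluate on each
    replicate.
    """

    spec: GeneticModelSpec
    N: int
    reps: int = 10_000
    alpha: float = 0.05
    seed: int | np.random.SeedSequence = 0
    tests: tuple[str, ...] = ("jt", "ca_additive")
    R: int | None = None
    S: int | None = None

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        unknown = set(self.tests) - set(AVAILABLE_TESTS)
        if unknown:
            raise ValueError(f"unknown tests {sorted(unknown)}; available: {AVAILABLE_TESTS}")
        R = self.N // 2 if self.R is None else self.R
        S = self.N - R if self.S is None else self.S
        if R < 1 or S < 1:
            raise ValueError("need R >= 1 and S >= 1")
        if R + S != self.N:
            raise ValueError(f"R + S = {R + S} must equal N = {self.N}")
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "S", S)


@dataclass(frozen=True)
class PowerEstimate:
    """Empirical rejection proportion for one test at one setting."""

    test: str
    power: float
    reps: int
    alpha: float
    seed: int | None
    degenerate: int = 0
    extra: dict = field(default_factory=dict, compare=False)

    @property
    def se(self) -> float:
        """Binomial Monte-Carlo standard error sqrt(p(1-p)/reps)."""
        return float(np.sqrt(self.power * (1.0 - self.power) / self.reps))


def simulate_table(
    probs: CellProbabilities,
    R: int,
    S: int,
    rng: np.random.Generator,
    label: str = "",
) -> GenotypeTable:
    """Draw one case-control table: r ~ trinomial(R, tau), s ~ trinomial(S, upsilon)."""
    if R < 1 or S < 1:
        raise ValueError("need R >= 1 and S >= 1")
    r = rng.multinomial(R, probs.tau)
    s = rng.multinomial(S, probs.upsilon)
    return GenotypeTable(tuple(int(v) for v in r), tuple(int(v) for v in s), label=label)


def _statistic_block(test: str, r: np.ndarray, s: np.ndarray) -> np.ndarray:
    if test == "jt":
        return jt_statistic_many(r, s)
    if test.startswith("ca_"):
        return ca_statistic_many(r, s, SCORE_PRESETS[test[3:]])
    if test == "allelic":
        # collapse to allele counts and apply the Pearson 2x2 chi-square
        a_case = np.stack([2 * r[:, 0] + r[:, 1], r[:, 1] + 2 * r[:, 2]], axis=1).astype(float)
        a_ctrl = np.stack([2 * s[:, 0] + s[:, 1], s[:, 1] + 2 * s[:, 2]], axis=1).astype(float)
        col = a_case + a_ctrl
        rowR = a_case.sum(axis=1)
        rowS = a_ctrl.sum(axis=1)
        tot = rowR + rowS
        with np.errstate(divide="ignore", invalid="ignore"):
            exp_case = np.outer(rowR / tot, np.ones(2)) * col
            exp_ctrl = col - exp_case
            stat = ((a_case - exp_case) ** 2 / exp_case).sum(axis=1) + (
                (a_ctrl - exp_ctrl) ** 2 / exp_ctrl
            ).sum(axis=1)
        bad = (col <= 0).any(axis=1) | (rowR <= 0) | (rowS <= 0)
        stat[bad] = np.nan
        return stat
    raise ValueError(f"unknown test {test!r}")


def empirical_power(cfg: SimulationConfig) -> dict[str, PowerEstimate]:
    """Empirical power of each requested test at one model setting.

    Returns a dict mapping test name to :class:`PowerEstimate`.  NaN
    statistics (degenerate replicates) are non-rejections and are tallied
    in ``PowerEstimate.degenerate``.
    """
    probs = cell_probabilities(cfg.spec)
    seed = cfg.seed if isinstance(cfg.seed, np.random.SeedSequence) else np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(seed)
    r = rng.multinomial(cfg.R, probs.tau, size=cfg.reps)
    s = rng.multinomial(cfg.S, probs.upsilon, size=cfg.reps)
    crit = float(stats.chi2.isf(cfg.alpha, df=1))
    out: dict[str, PowerEstimate] = {}
    seed_entropy = seed.entropy if isinstance(seed.entropy, int) else None
    for test in cfg.tests:
        t = _statistic_block(test, r, s)
        degenerate = int(np.isnan(t).sum())
        # p <= alpha  <=>  statistic >= critical value; NaN compares False
        reject = int(np.nansum(t >= crit))
        out[test] = PowerEstimate(
            test=test,
            power=reject / cfg.reps,
            reps=cfg.reps,
            alpha=cfg.alpha,
            seed=seed_entropy,
            degenerate=degenerate,
        )
    return out


def power_curve(
    base_cfg: SimulationConfig,
    theta_prime_grid: list[float] | np.ndarray,
) -> pd.DataFrame:
    """Empirical power along a grid of theta' = theta/pi values.

    A master seed derived from ``base_cfg.seed`` spawns one independent
    RNG substream per grid point, so the full curve is bit-reproducible
    and individual points could be recomputed in any order.

    Returns a tidy frame with columns
    (theta_prime, test, power, se, reps, degenerate, seed).
    """
    grid = [float(tp) for tp in theta_prime_grid]
    for tp in grid:
        if not 0.25 - 1e-12 <= tp <= 0.5 + 1e-12:
            raise ValueError(f"theta_prime {tp} outside [0.25, 0.5]")
    master = (
        base_cfg.seed
        if isinstance(base_cfg.seed, np.random.SeedSequence)
        else np.random.SeedSequence(base_cfg.seed)
    )
    master_entropy = master.entropy if isinstance(master.entropy, int) else None
    rows = []
    for tp, child in zip(grid, master.spawn(len(grid))):
        spec = replace(base_cfg.spec, theta=tp * np.pi)
        cfg = replace(base_cfg, spec=spec, seed=child)
        for test, est in empirical_power(cfg).items():
            rows.append(
                {
                    "theta_prime": tp,
                    "test": test,
                    "power": est.power,
                    "se": est.se,
                    "reps": est.reps,
                    "degenerate": est.degenerate,
                    "seed": master_entropy,
                }
            )
    return pd.DataFrame(rows)
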