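"""Cochran-Armitage and Jonckheere-Terpstra trend tests for 2x3 tables.

Both tests target the ordered alternative pi_0 <= pi_1 <= pi_2 (or the
reverse) for the case probability pi_i within genotype group G_i, and both
squared statistics are referred to a chi-square distribution with 1 df.

The Cochran-Armitage (CA) statistic with scores x = (x0, x1, x2)::

    T_CA = N * (N*sum(r_i x_i) - R*sum(n_i x_i))**2
           / ( R*S * [N*sum(n_i x_i**2) - (sum(x_i n_i))**2] )

The Jonckheere-Terpstra (JT) statistic is built from the Mann-Whitney
aggregate U over all ordered genotype-group pairs, with the phenotype
coded control = 0 < case = 1 and ties scoring 1/2.  U is evaluated in
closed form over the cell counts (never by enumerating individuals):
a pair of groups (i, i') with i < i' contributes

    s_i * r_i' + 0.5 * (r_i * r_i' + s_i * s_i').

The null moments use the tie-corrected variance

    E(U)   = (N**2 - sum(n_i**2)) / 4
    Var(U) = A/72 + B/(36 N (N-1) (N-2)) + C/(8 N (N-1))

with the standard tie components A, B, C for ties of sizes n_i in the
grouping variable and R, S in the phenotype.  T_JT = (U - E(U))**2/Var(U).

Scalar entry points return :class:`~jttrend.contingency.TestResult`; the
``*_statistic_many`` helpers evaluate the same formulas over whole arrays
of tables at once for the Monte-Carlo power engine.

All arithmetic is in float64: the variance components grow like N**6 and
overflow 64-bit integers for N in the few-thousand range, while float64
carries them to ~1e-15 relative accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .contingency import GenotypeTable, ScoreVector, TestResult, SCORE_PRESETS

__all__ = [
    "ADDITIVE_SCORES",
    "DOMINANT_SCORES",
    "RECESSIVE_SCORES",
    "JTMoments",
    "DegenerateTableError",
    "ca_trend_test",
    "jt_u_statistic",
    "jt_null_moments",
    "jt_trend_test",
    "chisq1_upper_tail",
    "ca_statistic_many",
    "jt_statistic_many",
]

ADDITIVE_SCORES = SCORE_PRESETS["additive"]
DOMINANT_SCORES = SCORE_PRESETS["dominant"]
RECESSIVE_SCORES = SCORE_PRESETS["recessive"]


class DegenerateTableError(ValueError):
    """Raised when a table carries no contrast for the requested test."""


@dataclass(frozen=True)
class JTMoments:
    """Observed U with its null mean/variance and tie components A, B, C."""

    U: float
    EU: float
    VarU: float
    A: float
    B: float
    C: float


def chisq1_upper_tail(x: float) -> float:
    """P(chi-square_1 >= x), the two-sided p-value for a squared statistic."""
    if x < 0:
        raise ValueError(f"chi-square statistic must be >= 0, got {x}")
    return float(stats.chi2.sf(x, df=1))


# -- Cochran-Armitage ------------------------------------------------------

def ca_trend_test(table: GenotypeTable, scores: ScoreVector | None = None) -> TestResult:
    """Cochran-Armitage trend test with arbitrary non-decreasing scores.

    Defaults to the additive scores (0, 0.5, 1).  The statistic is
    invariant under affine rescaling of the scores, so (0, 1, 2) gives
    identical results.  Fractional tables are accepted.

    Raises
    ------
    DegenerateTableError
        If R = 0 or S = 0 (no case/control contrast), or if all weight
        sits on a single score value (zero score variance).
    """
    if scores is None:
        scores = ADDITIVE_SCORES
    r = np.asarray(table.r, dtype=float)
    s = np.asarray(table.s, dtype=float)
    x = np.asarray(scores.x, dtype=float)
    n = r + s
    R, S = r.sum(), s.sum()
    N = R + S
    if R <= 0 or S <= 0:
        raise DegenerateTableError("need both cases and controls (R > 0 and S > 0)")
    denom_score = N * float(n @ x**2) - float(n @ x) ** 2
    if denom_score <= 0:
        raise DegenerateTableError(
            "zero score variance: all observations fall on a single score value"
        )
    num = N * (N * float(r @ x) - R * float(n @ x)) ** 2
    t = num / (R * S * denom_score)
    return TestResult(
        statistic=t,
        df=1,
        p_value=chisq1_upper_tail(t),
        test_name="cochran-armitage",
        notes=f"scores={scores.x}",
    )


# -- Jonckheere-Terpstra ---------------------------------------------------

def jt_u_statistic(table: GenotypeTable) -> float:
    """Mann-Whitney aggregate U over ordered genotype-group pairs.

    Closed form over the counts, O(1) in N; proven equal to the
    individual-level triple sum by the test suite's brute-force oracle.
    """
    r = np.asarray(table.r, dtype=float)
    s = np.asarray(table.s, dtype=float)
    u = 0.0
    for i in range(3):
        for j in range(i + 1, 3):
            u += s[i] * r[j] + 0.5 * (r[i] * r[j] + s[i] * s[j])
    return u


def jt_null_moments(table: GenotypeTable) -> JTMoments:
    """Null mean and tie-corrected variance of U, with components exposed.

    Ties come from the genotype groups (sizes n_i) and from the binary
    phenotype (group sizes R, S).

    Raises
    ------
    DegenerateTableError
        If N < 3 (the B term's denominator vanishes) or Var(U) <= 0
        (fewer than two non-empty genotype groups, or an empty phenotype
        group).
    """
    r = np.asarray(table.r, dtype=float)
    s = np.asarray(table.s, dtype=float)
    n = r + s
    R, S = r.sum(), s.sum()
    N = R + S
    if N < 3:
        raise DegenerateTableError(f"need N >= 3 for the tie-corrected variance, got N={N}")

    EU = (N**2 - float(n @ n)) / 4.0

    A = (
        N * (N - 1) * (2 * N + 5)
        - float(np.sum(n * (n - 1) * (2 * n + 5)))
        - S * (S - 1) * (2 * S + 5)
        - R * (R - 1) * (2 * R + 5)
    )
    B = float(np.sum(n * (n - 1) * (n - 2))) * (
        S * (S - 1) * (S - 2) + R * (R - 1) * (R - 2)
    )
    C = float(np.sum(n * (n - 1))) * (S * (S - 1) + R * (R - 1))
    VarU = A / 72.0 + B / (36.0 * N * (N - 1) * (N - 2)) + C / (8.0 * N * (N - 1))
    if VarU <= 0:
        raise DegenerateTableError(
            "Var(U) <= 0: need at least two non-empty genotype groups and both "
            "phenotype groups non-empty"
        )
    return JTMoments(U=jt_u_statistic(table), EU=EU, VarU=VarU, A=A, B=B, C=C)


def jt_trend_test(table: GenotypeTable) -> TestResult:
    """Jonckheere-Terpstra trend test: T_JT = (U - E(U))**2 / Var(U).

    Accepts fractional tables (expected-table mode).  The chi-square(1)
    reference is asymptotic; no minimum-cell-count cutoff is enforced,
    but the smallest group size is recorded in the result notes.
    """
    m = jt_null_moments(table)
    t = (m.U - m.EU) ** 2 / m.VarU
    n_min = min(table.n)
    return TestResult(
        statistic=t,
        df=1,
        p_value=chisq1_upper_tail(t),
        test_name="jonckheere-terpstra",
        notes=f"asymptotic chi2(1); min group size={n_min:g}",
        extra={"U": m.U, "EU": m.EU, "VarU": m.VarU},
    )


# -- vectorized paths for the Monte-Carlo engine ---------------------------

def ca_statistic_many(r: np.ndarray, s: np.ndarray, scores: ScoreVector | None = None) -> np.ndarray:
    """CA statistics for stacked tables; r, s have shape (reps, 3).

    Degenerate replicates (zero score variance) yield NaN rather than an
    error so the caller can count them.
    """
    if scores is None:
        scores = ADDITIVE_SCORES
    r = np.asarray(r, dtype=float)
    s = np.asarray(s, dtype=float)
    x = np.asarray(scores.x, dtype=float)
    n = r + s
    R = r.sum(axis=1)
    S = s.sum(axis=1)
    N = R + S
    denom = R * S * (N * (n @ x**2) - (n @ x) ** 2)
    num = N * (N * (r @ x) - R * (n @ x)) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, num / denom, np.nan)
    return t


def jt_statistic_many(r: np.ndarray, s: np.ndarray) -> np.ndarray:
    """JT statistics for stacked tables; r, s have shape (reps, 3).

    Degenerate replicates (Var(U) <= 0) yield NaN.
    """
    r = np.asarray(r, dtype=float)
    s = np.asarray(s, dtype=float)
    n = r + s
    R = r.sum(axis=1)
    S = s.sum(axis=1)
    N = R + S

    u = np.zeros(len(r))
    for i in range(3):
        for j in range(i + 1, 3):
            u += s[:, i] * r[:, j] + 0.5 * (r[:, i] * r[:, j] + s[:, i] * s[:, j])
    EU = (N**2 - np.sum(n**2, axis=1)) / 4.0
    A = (
        N * (N - 1) * (2 * N + 5)
        - np.sum(n * (n - 1) * (2 * n + 5), axis=1)
        - S * (S - 1) * (2 * S + 5)
        - R * (R - 1) * (2 * R + 5)
    )
    B = np.sum(n * (n - 1) * (n - 2), axis=1) * (
        S * (S - 1) * (S - 2) + R * (R - 1) * (R - 2)
    )
    C = np.sum(n * (n - 1), axis=1) * (S * (S - 1) + R * (R - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        VarU = A / 72.0 + B / (36.0 * N * (N - 1) * (N - 2)) + C / (8.0 * N * (N - 1))
        t = np.where(VarU > 0, (u - EU) ** 2 / VarU, np.nan)
    return t
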