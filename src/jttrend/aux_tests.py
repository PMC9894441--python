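"""Supporting association checks: exact Hardy-Weinberg test and allelic test.

The Hardy-Weinberg equilibrium (HWE) exact test screens for genotyping
error within a phenotype group; the allelic test collapses the 2x3
genotype table to a 2x2 allele-count table and applies Pearson's
chi-square, which is valid under HWE.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .contingency import GenotypeTable, TestResult
from .trend_tests import DegenerateTableError

__all__ = ["hwe_exact_test", "allelic_test"]


def hwe_exact_test(n0: int, n1: int, n2: int) -> float:
    """Exact two-sided Hardy-Weinberg equilibrium p-value for one sample.

    Conditions on the observed allele counts nA = n1 + 2*n2 and
    na = n1 + 2*n0 and enumerates every heterozygote count ``h`` of the
    same parity as nA.  The two-sided p-value is the sum of conditional
    probabilities P(het = h | allele counts) over all configurations no
    more probable than the observed one (the "sum of less-likely
    outcomes" convention).  Returns 1.0 when only one configuration
    exists (e.g. a monomorphic sample).

    Probabilities are computed in log space so factorials of large
    samples do not overflow.

    Parameters
    ----------
    n0, n1, n2 : int
        Genotype counts for (aa, Aa, AA).  Must be non-negative integers;
        the exact test is undefined for fractional counts.
    """
    for name, v in (("n0", n0), ("n1", n1), ("n2", n2)):
        if not float(v).is_integer():
            raise ValueError(f"{name} must be an integer count, got {v!r}")
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    n0, n1, n2 = int(n0), int(n1), int(n2)
    n = n0 + n1 + n2
    if n < 1:
        raise ValueError("need at least one subject")

    nA = n1 + 2 * n2  # minor allele count
    na = n1 + 2 * n0
    n_rare = min(nA, na)

    # log P(het = h | allele counts), up to the common constant:
    #   log n! - log n0! - log h! - log n2! + h*log 2
    # with n0 = (na - h)/2, n2 = (nA - h)/2 for the candidate h.
    hs = list(range(n_rare % 2, n_rare + 1, 2))

    def logp(h: int) -> float:
        a0 = (na - h) // 2
        a2 = (nA - h) // 2
        return (
            -math.lgamma(a0 + 1)
            - math.lgamma(h + 1)
            - math.lgamma(a2 + 1)
            + h * math.log(2.0)
        )

    logs = np.array([logp(h) for h in hs])
    logs -= logs.max()
    probs = np.exp(logs)
    probs /= probs.sum()
    p_obs = probs[hs.index(n1)]
    # 1e-12 relative slack absorbs float round-off in the "<= observed" cut
    p = float(probs[probs <= p_obs * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


def allelic_test(table: GenotypeTable) -> TestResult:
    """Allele-count association test on the collapsed 2x2 table.

    Cases contribute (2*r0 + r1) copies of allele a and (r1 + 2*r2) of
    allele A, similarly for controls; the statistic is Pearson's
    chi-square with 1 df, no continuity correction, matching the
    asymptotic framework of the trend tests.

    Raises
    ------
    DegenerateTableError
        If any row or column margin of the 2x2 allele table is zero.
    """
    t = table.as_integer()
    r0, r1, r2 = t.r
    s0, s1, s2 = t.s
    table22 = np.array(
        [
            [2 * r0 + r1, r1 + 2 * r2],
            [2 * s0 + s1, s1 + 2 * s2],
        ],
        dtype=float,
    )
    if (table22.sum(axis=0) == 0).any() or (table22.sum(axis=1) == 0).any():
        raise DegenerateTableError("allele-count 2x2 table has a zero margin")
    res = stats.chi2_contingency(table22, correction=False)
    return TestResult(
        statistic=float(res.statistic),
        df=1,
        p_value=float(res.pvalue),
        test_name="allelic",
        notes="Pearson chi2 on allele counts, no continuity correction",
    )
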