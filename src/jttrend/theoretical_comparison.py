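"""Theoretical comparison of the trend statistics on expected tables.

For a model spec and balanced total sample size N, the expected
case-control table has fractional cells E(r_i) = tau_i * N/2 and
E(s_i) = upsilon_i * N/2.  Evaluating both trend statistics directly on
this fractional table gives "theoretical" values whose percent
difference

    delta_T = (T_JT - T_CA) / T_CA * 100

serves as a deterministic proxy for the relative power of the two tests:
positive when the Jonckheere-Terpstra test is favoured, negative when the
Cochran-Armitage additive test is.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .contingency import GenotypeTable
from .genetic_model import GeneticModelSpec, MODEL_THETAS, cell_probabilities
from .trend_tests import ADDITIVE_SCORES, ca_trend_test, jt_trend_test

__all__ = ["DeltaTResult", "expected_table", "delta_t", "table2_report", "format_table2"]


@dataclass(frozen=True)
class DeltaTResult:
    """Theoretical statistics on an expected table and their percent difference."""

    spec: GeneticModelSpec
    N: int
    T_JT_expected: float
    T_CA_expected: float
    delta_t_percent: float


def expected_table(spec: GeneticModelSpec, N: int) -> GenotypeTable:
    """Fractional table of expected counts under a balanced design R = S = N/2."""
    probs = cell_probabilities(spec)
    half = N / 2.0
    return GenotypeTable(
        tuple(t * half for t in probs.tau),
        tuple(u * half for u in probs.upsilon),
        label=f"expected(K={spec.K},q={spec.q},lam={spec.lam},theta'={spec.theta_prime:.4f},N={N})",
    )


def delta_t(spec: GeneticModelSpec, N: int) -> DeltaTResult:
    """Percent difference between T_JT and T_CA(additive) on the expected table.

    Undefined at the null (lam = 0), where both statistics vanish.
    """
    if spec.is_null:
        raise ValueError("delta_t is undefined at the null (lam = 0): T_CA = 0")
    table = expected_table(spec, N)
    t_jt = jt_trend_test(table).statistic
    t_ca = ca_trend_test(table, ADDITIVE_SCORES).statistic
    if t_ca <= 0:
        raise ValueError("T_CA on the expected table is zero; delta_t undefined")
    return DeltaTResult(
        spec=spec,
        N=N,
        T_JT_expected=t_jt,
        T_CA_expected=t_ca,
        delta_t_percent=(t_jt - t_ca) / t_ca * 100.0,
    )


def table2_report(
    N_list: list[int] = (200, 500, 1000),
    q_list: list[float] = (0.05, 0.1, 0.2, 0.3),
    K: float = 0.1,
    lam: float = 1.0,
) -> pd.DataFrame:
    """Grid of delta_T over sample sizes, MAFs and the three named models.

    Returns a tidy frame with one row per (N, q) and one delta_T column
    per model (dominant, additive, recessive), in percent.
    """
    rows = []
    for N in N_list:
        for q in q_list:
            row: dict[str, float] = {"N": N, "maf": q}
            for model, theta in MODEL_THETAS.items():
                spec = GeneticModelSpec(K=K, q=q, lam=lam, theta=theta)
                row[model] = delta_t(spec, N).delta_t_percent
            rows.append(row)
    return pd.DataFrame(rows)


def format_table2(df: pd.DataFrame) -> str:
    """Render a table2_report frame as fixed-width text with two decimals."""
    lines = [f"{'N':>6} {'MAF':>5} {'Dominant':>10} {'Additive':>10} {'Recessive':>10}"]
    for _, row in df.iterrows():
        lines.append(
            f"{int(row['N']):>6} {row['maf']:>5g} "
            f"{row['dominant']:>9.2f}% {row['additive']:>9.2f}% {row['recessive']:>9.2f}%"
        )
    return "\n".join(lines)
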