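"""Independent brute-force oracles shared by the test modules.

These deliberately re-derive every quantity from first principles —
enumerating individuals, label permutations or genotype configurations —
and never call the closed-form paths they are used to check.
"""

import itertools
import math

import numpy as np

from jttrend import GenotypeTable


def u_brute_force(table: GenotypeTable) -> float:
    """Individual-level triple-sum U: enumerate subjects, score all pairs.

    Phenotype coded control = 0 < case = 1; pairs of subjects from
    genotype groups i < i' score 1 / 0.5 / 0 for < / = / >.
    """
    t = table.as_integer()
    groups = [
        [0] * int(si) + [1] * int(ri)  # phenotype values within group i
        for ri, si in zip(t.r, t.s)
    ]
    u = 0.0
    for i, j in itertools.combinations(range(3), 2):
        for yi in groups[i]:
            for yj in groups[j]:
                u += 1.0 if yi < yj else (0.5 if yi == yj else 0.0)
    return u


def u_permutation_moments(table: GenotypeTable) -> tuple[float, float]:
    """Exact null mean/variance of U over all phenotype-label permutations.

    Group sizes n_i and the number of cases R are fixed; enumerate every
    split (a0, a1, a2) of the R case labels across groups, weighted by
    the multivariate-hypergeometric count C(n0,a0)C(n1,a1)C(n2,a2).
    U for each split is itself computed by pairwise counting, not via the
    package's closed form.
    """
    t = table.as_integer()
    n = [int(v) for v in t.n]
    R = int(t.R)
    us, ws = [], []
    for a0 in range(min(n[0], R) + 1):
        for a1 in range(min(n[1], R - a0) + 1):
            a2 = R - a0 - a1
            if not 0 <= a2 <= n[2]:
                continue
            r = (a0, a1, a2)
            s = (n[0] - a0, n[1] - a1, n[2] - a2)
            u = 0.0
            for i, j in itertools.combinations(range(3), 2):
                u += s[i] * r[j] + 0.5 * (r[i] * r[j] + s[i] * s[j])
            us.append(u)
            ws.append(math.comb(n[0], a0) * math.comb(n[1], a1) * math.comb(n[2], a2))
    us, ws = np.array(us), np.array(ws, dtype=float)
    ws /= ws.sum()
    mean = float(ws @ us)
    var = float(ws @ (us - mean) ** 2)
    return mean, var


def all_tables_up_to(n_max: int):
    """Every integer 2x3 table with 3 <= N <= n_max on which the JT null
    moments are defined (both rows and at least two columns non-empty)."""
    for N in range(3, n_max + 1):
        for r0 in range(N + 1):
            for r1 in range(N + 1 - r0):
                for r2 in range(N + 1 - r0 - r1):
                    rest = N - r0 - r1 - r2
                    for s0 in range(rest + 1):
                        for s1 in range(rest + 1 - s0):
                            s2 = rest - s0 - s1
                            r, s = (r0, r1, r2), (s0, s1, s2)
                            if sum(r) == 0 or sum(s) == 0:
                                continue
                            n = [ri + si for ri, si in zip(r, s)]
                            if sum(v > 0 for v in n) < 2:
                                continue
                            yield GenotypeTable(r, s)
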