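# Methods

## Problem and data model

A diallelic marker with major allele `a` and minor allele `A` defines three
genotypes ordered by minor-allele count: `G0 = aa`, `G1 = Aa`, `G2 = AA`.
A case-control study yields a 2×3 table of case counts `r = (r0, r1, r2)`
and control counts `s = (s0, s1, s2)`; margins `n_i`, `R`, `S`, `N` are
always derived from the cells, never stored, so they cannot drift out of
sync. Sampling model: `r ~ trinomial(R, τ)` and `s ~ trinomial(S, υ)`
independently, where `τ` and `υ` are the genotype distributions within
cases and controls. The null of no association is `τ = υ`; the trend
alternative orders the within-genotype case probabilities
`π_0 ≤ π_1 ≤ π_2` (or reversed) with at least one strict inequality.

Two conventions are enforced rather than silently repaired: genotype
columns must be in ascending minor-allele-count order (the reader
validates and `minor_allele_frequency` warns when the pooled frequency of
`A` exceeds 0.5), and fractional cell values are a first-class mode —
the theoretical comparison below evaluates both statistics on expected
(non-integer) tables, so every formula in the package is written over
real-valued counts.

## The two trend statistics

**Cochran-Armitage.** Scores `(x0, x1, x2)` with `x0 ≤ x1 ≤ x2`,
`x0 < x2` encode the assumed genetic model: additive `(0, 0.5, 1)` is the
default, with dominant `(0, 1, 1)` and recessive `(0, 0, 1)` presets.
The statistic is invariant under positive affine rescaling of the scores
(verified as a property test), so `(0, 1, 2)` is equivalent to the
default. Degenerate inputs raise rather than return NaN: a missing
case or control row, or all observations on one score value (zero score
variance).

**Jonckheere-Terpstra.** The Mann-Whitney aggregate `U` counts, over all
pairs of subjects from ordered genotype groups `i < i'`, whether the
later group's phenotype exceeds the earlier's (ties score ½). Because the
phenotype is binary, `U` collapses to a closed form over the six cell
counts — `O(1)` instead of the `O(N²)` subject-level triple sum; the test
suite proves the two equal by brute-force enumeration. The null moments
use the tie-corrected variance with components `A`, `B`, `C` accounting
for ties of sizes `n_i` in the grouping variable and `R`, `S` in the
phenotype. The grouping of the variance expression is
`A/72 + B/[36N(N−1)(N−2)] + C/[8N(N−1)]`; an exhaustive permutation
oracle (exact mean and variance of `U` over all case-label assignments,
weighted multivariate-hypergeometrically) confirms this resolution for
every admissible table with `N ≤ 10`.

Both squared statistics are referred to the upper tail of χ²(1); no
one-sided versions and no continuity corrections are offered. The χ²(1)
reference for `T_JT` is asymptotic and degrades when a genotype group is
very small; no hard cutoff is enforced, but the minimum group size is
recorded in the result's notes so downstream code can filter.

## Numerical choices

- All moment arithmetic is float64. `A`, `B`, `C` grow like `N⁶` and
  overflow 64-bit integers already for `N` in the few-thousand range,
  while float64 carries them at ~1e-15 relative error; the worked
  example (`N = 4863`) agrees with exact rational arithmetic to 13
  significant digits.
- A table is treated as integer-valued when every cell is within 1e-9 of
  an integer; the exact HWE test refuses fractional input outright.
- Two-sided exact HWE p-values use the "sum of configurations no more
  probable than observed" convention, computed in log space with a 1e-12
  relative slack on the probability comparison to absorb round-off in
  ties.

## Supporting tests

The exact Hardy-Weinberg test conditions on the observed allele counts
and enumerates every heterozygote count of matching parity; it is run
separately within cases and within controls as a genotyping-error screen.
The allelic test collapses the genotype table to a 2×2 allele-count table
and applies Pearson's χ² without continuity correction — consistent with
the trend tests' asymptotic framework, and valid only under HWE.

## Genetic-model parameterization

Effects are parameterized on a polar arc: `λ1 = 1 + λ cos θ`,
`λ2 = 1 + λ sin θ`, with `λ ≥ 0` the distance from the null `(1, 1)` and
`θ ∈ [π/4, π/2]` the mode of inheritance with respect to the minor
allele — dominant (`λ1 = λ2`) at `π/4`, additive (`λ1 = (1+λ2)/2`) at
`arctan 2`, recessive (`λ1 = 1`) at `π/2`. The normalized angle
`θ' = θ/π ∈ [0.25, 0.5]` is accepted everywhere radians are. Population
genotype frequencies assume Hardy-Weinberg proportions
`((1−q)², 2q(1−q), q²)`; the expected-table grid is only reproducible
under this assumption, which is therefore stated rather than optional.
Penetrances follow from prevalence by the law of total probability
(`Σ P(G_i) f_i = K` pins `f0`), and feasibility requires `f2 < 1` —
violations raise with the offending parameter set named. `λ = 0`
collapses `τ = υ` exactly, so the null is reachable from any angle.

## Monte-Carlo power engine

Default study conditions mirror the comparison the package exists for:
prevalence `K = 0.1`, `λ = 1`, balanced design `R = S = N/2`
(`R = floor(N/2)` for odd `N`), `α = 0.05`, 10,000 replicates; the
θ'-grid runs 0.25 to 0.5. Examples and CI-scale checks use 2,000
replicates, which resolves power differences of ~0.03 at 2 MC standard
errors; the acceptance checks state the replicate counts they use.
All replicates of a setting are drawn as one trinomial block and the
statistics evaluated through vectorized closed forms (elementwise in the
counts), so a 10,000-replicate setting costs milliseconds; the vectorized
and scalar paths are cross-checked in the tests.

Replicates where a test degenerates (e.g. the recessive-score contrast
when the `AA` column is empty at small `N·q`) count as **non-rejections**
and are tallied in a diagnostics counter — discarding them would bias
power upward exactly in the regime where the comparison is most delicate.
Rejection is decided by comparing the statistic to the χ²(1) critical
value, which is equivalent to `p ≤ α` and avoids 10,000 tail evaluations.

Seed policy: a master `SeedSequence` spawns one independent substream per
grid point, so a power curve is bit-reproducible for a fixed seed and any
single point can be recomputed in isolation.

### What the generator does and does not emulate

The trinomial sampler reproduces the study design the tests target:
fixed case/control totals, independent genotype draws from the
penetrance-implied distributions, HWE in the source population. It does
not model genotyping error, missingness, covariates or stratification,
linkage disequilibrium between markers, or departures from HWE —
so passing power and calibration checks here demonstrate correctness of
the statistics under the stated model, not robustness of either test to
those real-data complications (the HWE screen exists precisely because
the allelic test is not robust to such departures).

## Theoretical comparison on expected tables

For each setting, the fractional table `E(r_i) = τ_i N/2`,
`E(s_i) = υ_i N/2` is built and both statistics evaluated on it directly;
their percent difference `ΔT = (T_JT − T_CA)/T_CA × 100` is a
deterministic proxy for relative power. `ΔT` is undefined at the null,
where both statistics vanish. Across the default grid
(`N ∈ {200, 500, 1000}`, `q ∈ {0.05, 0.1, 0.2, 0.3}`), `ΔT > 0` under
dominance, `|ΔT| < 2%` under additivity, `ΔT < 0` under recessivity, and
`ΔT(θ')` crosses zero exactly once on a 0.01 grid for `q ≥ 0.1`. Note the
known caveat: at low MAF and small `N` the theoretical `ΔT` is negative
under the recessive model while empirical power can favour the rank test
— the asymptotics behind the score test are the suspect there, and the
package reports both quantities without attempting to reconcile them.

## Known limitations

- Only 2×3 single-marker tables: no covariates, stratification,
  multi-allelic markers, or per-individual data formats (VCF/PLINK).
- No exact or MAX-type robust trend tests; p-values are asymptotic
  χ²(1) only.
- The binomial-per-genotype sampling formulation (equivalent in
  distribution to the trinomial one under the null margins) is not
  offered as a separate mode.
- Power curves are emitted as tidy TSV; plotting is left to the user.
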