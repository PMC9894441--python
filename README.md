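# jttrend

Trend tests for case-control genetic association at a diallelic marker:
the **Cochran-Armitage (CA) trend test** with arbitrary genotype scores and
the **Jonckheere-Terpstra (JT) rank test** with tie-corrected variance,
together with a penetrance-model simulation framework for comparing their
power across the dominant–additive–recessive spectrum.

## Who this is for

Statistical geneticists and epidemiologists analysing 2×3 genotype count
tables (cases × {aa, Aa, AA}, with `A` the minor allele). The standard
practice is the CA trend test under additive scores, which loses power when
the true mode of inheritance is not additive. The JT test is a rank-based
nonparametric alternative that makes no genetic-model assumption. This
package implements both, plus the machinery to quantify when each wins.

## The statistics

For a table with case counts `r_i`, control counts `s_i`, margins
`n_i = r_i + s_i`, `R`, `S`, `N`, and scores `x = (x0, x1, x2)` with
`x0 ≤ x1 ≤ x2`, `x0 < x2`:

```
T_CA = N (N Σ r_i x_i − R Σ n_i x_i)² / ( R S [N Σ n_i x_i² − (Σ x_i n_i)²] )
```

The JT test aggregates Mann-Whitney pairwise comparisons of the binary
phenotype (control = 0 < case = 1) across ordered genotype groups. In
closed form over the counts, each group pair `(i, i')` with `i < i'`
contributes `s_i r_i' + ½(r_i r_i' + s_i s_i')` to `U`, and

```
T_JT = [U − E(U)]² / Var(U),     E(U) = (N² − Σ n_i²)/4,
Var(U) = A/72 + B/[36 N(N−1)(N−2)] + C/[8 N(N−1)]
```

with the standard tie-correction components `A`, `B`, `C` for ties of sizes
`n_i` (genotype groups) and `R`, `S` (phenotype groups). Both squared
statistics are referred to χ²(1).

The simulation framework parameterizes the genotype relative risks on a
polar arc around the null: `λ1 = 1 + λ cos θ`, `λ2 = 1 + λ sin θ` with
`θ ∈ [π/4, π/2]` sweeping dominant (π/4) → additive (arctan 2) → recessive
(π/2). Given prevalence `K` and MAF `q` under Hardy-Weinberg proportions,
penetrances follow from `f0 = K/[(1−q)² + 2λ1 q(1−q) + λ2 q²]`, `f_i = λ_i f0`,
and the case/control genotype distributions are `τ_i = P(G_i) f_i / K`,
`υ_i = P(G_i)(1−f_i)/(1−K)`. See `docs/methods.md` for details.

## Worked example

The bundled fixture `rs2398162` is a hypertension-associated variant from
the Wellcome Trust Case Control Consortium study: 1940 cases
(1205, 624, 111) and 2923 controls (1608, 1121, 194), with a suggested
dominant effect of the minor allele.

```sh
$ jttrend test --fixture rs2398162 --method jt
jonckheere-terpstra: statistic = 22.82, df = 1, p-value = 1.7785e-06

$ jttrend test --fixture rs2398162 --method ca --preset additive
cochran-armitage: statistic = 19.97, df = 1, p-value = 7.8479e-06
```

The JT statistic (22.82) exceeds the additive-score CA statistic (19.97)
— exactly the regime where the rank test wins, since the underlying
effect is dominant rather than additive. The same comparison in
simulation, at N = 1000, MAF 0.3, prevalence 0.1, effect distance λ = 1:

```sh
$ jttrend simulate-power -q 0.3 -N 1000 --model dominant --reps 2000 --seed 42
jt: power = 0.996 (MC SE 0.001411, reps 2000, degenerate 0)
ca_additive: power = 0.987 (MC SE 0.002533, reps 2000, degenerate 0)

$ jttrend simulate-power -q 0.3 -N 1000 --model recessive --reps 2000 --seed 42
jt: power = 0.704 (MC SE 0.01021, reps 2000, degenerate 0)
ca_additive: power = 0.829 (MC SE 0.008419, reps 2000, degenerate 0)
```

Under the dominant model the JT test is more powerful (0.996 vs 0.987);
under the recessive model the ordering flips (0.704 vs 0.829).

A deterministic proxy for the same comparison evaluates both statistics
on the table of *expected* cell counts `E(r_i) = τ_i N/2`,
`E(s_i) = υ_i N/2` and reports the percent difference
ΔT = (T_JT − T_CA)/T_CA × 100:

```sh
$ jttrend compare-theoretical
     N   MAF   Dominant   Additive  Recessive
   200  0.05      2.15%     -1.39%    -69.47%
   200   0.1      4.97%     -1.68%    -62.83%
   ...
  1000   0.3     12.03%      0.54%    -27.42%
```

ΔT > 0 everywhere under dominance, |ΔT| < 2% under additivity, ΔT < 0
under recessivity.

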