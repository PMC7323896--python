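# hwtest — Hardy-Weinberg equilibrium testing for genotype count data

`hwtest` evaluates the hypothesis of Hardy-Weinberg (HW) proportions at an
autosomal locus from genotype **counts** alone — no sequence files, no
per-individual genotypes. It is aimed at population geneticists and at
laboratory quality control, where departure from HW proportions is a routine
screen for genotyping error, and is simple enough to double as a teaching
tool.

## The model

For a biallelic locus with observed genotype counts D = n(AA), H = n(Aa),
R = n(aa) and N = D + H + R, the allele frequencies are p = (2D + H)/2N and
q = 1 − p, and the null hypothesis is that genotypes occur in the proportions
p², 2pq, q² (generalizing to pᵢ², 2pᵢpⱼ for k alleles). The package provides:

- **Asymptotic tests** — Pearson χ² and the G (log-likelihood ratio) test,
  each with and without continuity correction; the Hogben/Levene χ² against
  the exact conditional expectations E[H] = n_A n_a/(2N−1); and the
  Cannings & Edwards step-corrected χ². For k alleles, the χ² test with
  df = k(k−1)/2 (no correction — it is appropriate only for two alleles).
- **Conditional exact tests** — Fisher (probability ordering) and Haldane
  (deviation ordering) via full enumeration of the conditional distribution
  of the heterozygote count given the allele counts, whose point mass is

  P = N!/(2N)! · (2D+H)! (H+2R)! 2^H / (D! H! R!).

- **Monte-Carlo exact test** (any k) — a parametric bootstrap: t = 1000
  samples of size N are simulated under HW at the observed allele
  frequencies, each sample's own conditional probability Pᵢ is compared with
  the observed P₀, and P = T/t where T counts replicates with Pᵢ ≤ P₀.
- **95% confidence intervals** for every observed and expected genotype-class
  frequency: Gaussian (Wald) f ± 1.96√(f(1−f)/N) and percentile bootstrap.
- **de Finetti diagrams** — an isosceles ternary plot (x = q, y = heterozygote
  frequency, so neither is distorted) with the HW parabola y = 2x(1−x), the
  95% χ² confidence bands at F = ±√(3.841/N), two 1000-point simulated
  population clouds and the observed sample point, rendered to SVG or PNG.

## Worked example

The sample D = 119, H = 42, R = 39 (N = 200) gives p = 0.7 and a strong
heterozygote deficit (84 expected, 42 observed; fixation index F = 0.5):

```sh
hwtest two --counts 119,42,39 --tests all --seed 1 --plot definetti.svg
```

prints (abridged):

```
Allele counts and frequencies:
  A: n = 280  freq = 0.7
  a: n = 120  freq = 0.3
  fixation index F = 0.5

Genotype counts (observed / HW expected):
  AA: 119 / 98
  Aa: 42 / 84
  aa: 39 / 18

Tests:
  Chi-squared:  statistic = 50  df = 1  P = 1.53746e-12
  Chi-squared with continuity correction:  statistic = 48.1385  df = 1  P = 3.97159e-12
  G-test:  statistic = 48.2936  df = 1  P = 3.66952e-12
  Hogben/Levene chi-squared:  statistic = 50.5999  df = 1  P = 1.13249e-12
  Cannings & Edwards chi-squared:  statistic = 47.6474  df = 1  P = 5.10201e-12
  Fisher's exact test:  P = 4.17398e-12
  Haldane's exact test:  P = 4.17398e-12
  Bootstrap exact test:  P = 0/1000 = 0

95% confidence intervals for genotype frequencies:
  class    obs       Wald obs              boot obs      ...
  Aa       0.21      [0.15355, 0.26645]    [0.155, 0.27] ...
```

Every test rejects HW decisively (note χ² = N·F² = 200 · 0.25 = 50), and
each result carries the advisory that p-values below 10⁻⁶ may reflect
genotyping error rather than biology. The bootstrap P = 0/1000 means none of
the 1000 HW-simulated samples was as improbable as the observed one. The
figure shows the observed point at (q, h) = (0.3, 0.21), far below the HW
parabola and outside the 95% band.

For k alleles, supply a lower-triangular count table:

```
alleles,A,B,C,D
A,18
B,22,12
C,14,13,8
D,10,9,8,6
```

```sh
hwtest multi --counts-file counts.csv --seed 1
```

runs the k-allele χ² (here df = 6) and the bootstrap exact test.

The same operations are available as library functions
(`hwtest.chi_square_test`, `hwtest.bootstrap_exact`,
`hwtest.bootstrap_intervals`, `hwtest.build_figure`, ...).

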