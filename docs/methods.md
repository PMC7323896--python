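# Methods

## Scope and data model

All computation starts from genotype counts. `TwoAlleleCounts(D, H, R)`
holds a biallelic sample; `MultiAlleleCounts` holds a lower-triangular k×k
table c_ij (diagonal = homozygotes, off-diagonal = unordered heterozygote
cells). Allele copy counts follow as n_i = 2c_ii + Σ_{j≠i} c_ij, allele
frequencies as p_i = n_i/2N, and HW expected counts as e_ii = Np_i²,
e_ij = 2Np_ip_j.

Validation is advisory by design: rule violations are returned in a
`ValidationReport` rather than raised, so the CLI can refuse bad input
(exit 2) while library callers choose their own strictness. Fatal rules for
two alleles: N < 5, or two of the three genotype classes empty (with two
empty classes every test is degenerate). N ≤ 20 — and N ≤ 10k for k
alleles — only warns: at such sizes the null is essentially never
rejectable, and a rejection more plausibly reflects genotyping error.
Complete heterozygote absence with both homozygote classes present is
accepted; it is the scientifically interesting disequilibrium case, not a
data defect.

## The conditional sample probability

Every exact test rests on the probability of the genotype table given its
own allele counts under random union of gametes:

    P = N!/(2N)! · Π_a n_a! · 2^h / Π_g c_g!

(h = total heterozygotes; for two alleles P = N!/(2N)! (2D+H)!(H+2R)!2^H /
D!H!R!). The k-allele form is the direct product generalization of the
two-allele formula. All probabilities are computed in log space with
`scipy.special.gammaln`: factorials overflow double precision near N ≈ 90,
while log-gamma is accurate to rounding at any N. Comparisons between
log-probabilities treat values within a relative tolerance of 1e-12 as tied,
and ties count into the rejection tail ("smaller than or equal to"). The
test suite verifies the log-space values against exact big-integer rational
arithmetic to 1e-9 relative error.

For two alleles the conditional distribution of the heterozygote count h is
enumerated exactly: fixed allele counts force h to share the parity of n_A
and step by 2 over 0..min(n_A, n_a). The full multiallelic conditional
support is never enumerated (it is combinatorially explosive); multiallelic
exactness comes from Monte-Carlo only.

## Tests

**Pearson χ²** — Σ(o−e)²/e over classes with e > 0, df = k(k−1)/2 (k−1
allele frequencies are estimated from the data). The two-allele statistic
satisfies χ² = N·F̂² with F̂ = 1 − (H/N)/(2pq), which the suite checks as an
identity. The continuity correction (two alleles only) is Yates': each
|o−e| reduced by 0.5, floored at 0.

**G test** — G = 2Σ o·ln(o/e), df = 1. The corrected variant exploits the
constraint that, with allele frequencies estimated from the same data, the
three deviations are locked together (D−e_D = R−e_R = −(H−e_H)/2): the
counts are moved half a lattice step toward expectation along that line
(heterozygotes by min(1, |x|), each homozygote by half that, never crossing).
This preserves N and the allele counts, and because G is twice a
KL-divergence it decreases monotonically along the line — so the corrected G
never exceeds the uncorrected one. A naive per-cell 0.5 shift does not
preserve N and can *increase* G near equilibrium, which is why it was
rejected.

**Hogben/Levene χ²** — the same quadratic form against the exact conditional
expectations E[H] = n_A n_a/(2N−1), E[D] = n_A(n_A−1)/(2(2N−1)),
E[R] = n_a(n_a−1)/(2(2N−1)) (they sum to N identically), df = 1.

**Cannings & Edwards χ²** — the step-aware continuity correction: since h
moves in steps of 2, its deviation is reduced by 1 (half a step) and each
homozygote deviation by 0.5, floored at 0, squared against the unconditional
expectations. It can never exceed the uncorrected χ².

**Fisher / Haldane exact tests** — both sum conditional probabilities over a
tail containing the observed h, differing in the ordering: Fisher uses
probability ordering (all h' with P(h') ≤ P(h_obs)), Haldane deviation
ordering around the conditional mean E[h] = n_A n_a/(2N−1) (all h' with
|h'−E[h]| ≥ |h_obs−E[h]|). Which name goes with which ordering in older
software is not settled; the assignment here (probability → Fisher,
deviation → Haldane) is a documented package convention, and both orderings
are always available. They coincide whenever the two orderings induce the
same tail (e.g. at the conditional mode).

**Bootstrap exact test** — a *parametric* bootstrap: t replicates (default
1000) of size N are drawn from HW proportions at the observed allele
frequencies; each replicate's P_i is computed with that replicate's **own**
allele counts; P = T/t with T = #{P_i ≤ P_0}. Re-estimating the allele
frequencies inside each replicate is deliberate and distinguishes this test
from conditional permutation schemes (Guo–Thompson) that hold allele counts
fixed. P is always a multiple of 1/t; P = 0/t means "less than 1/t", not
literally zero.

Each simulated individual is classified by one uniform draw against the
cumulative genotype probabilities, with draws equal to a boundary assigned
to the earlier class. A single root seed feeds deterministic, named
substreams (bootstrap test, each CI flavor, each plot cloud), so any piece
of output is reproducible in isolation.

No multiple-testing adjustment is applied across the battery: the tests are
reported independently, and the report notes that they are not independent.
p-values below 10⁻⁶ carry a caution that such extremes can arise purely from
genotyping error.

## Confidence intervals

95% fixed (z = 1.96). Wald: f ± 1.96√(f(1−f)/N), clipped to [0,1]; a class
frequency of 0 or 1 has zero Wald variance. Bootstrap: percentile method
(2.5/97.5 empirical quantiles, linear interpolation) over t ≥ 100
replicates. Observed-frequency intervals resample at the observed class
frequencies; expected-frequency intervals resample under HW and recompute
each replicate's expected frequencies from its own allele counts, mirroring
the bootstrap test's resampling philosophy (holding them fixed was the
alternative; the resampling choice is isolated in one function).

## de Finetti geometry

The triple (d, h, r) maps to x = r + h/2, y = h on an isosceles triangle
with unit base and height. x is *exactly* the allele frequency q and y the
heterozygote frequency — the "no distortion" property that motivates this
convention over the equilateral one, and which the suite asserts bitwise.
HW populations lie on y = 2x(1−x). The 95% band is the image of
{p² + pqF, 2pq(1−F), q² + pqF} at F = ±√(3.841/N), i.e. y = 2x(1−x)(1∓F);
3.841 is kept as the conventional rounded χ²₀.₉₅,₁ so curves match published
diagrams (the unrounded quantile is available via `exact_quantile=True`).
Grid points whose genotype coordinates leave [0,1] are dropped, not
projected. A sample point lies between the bands iff its uncorrected χ² ≤
3.841, so under a true null ≈95% of simulated populations fall inside.
Curves use a 401-point q grid; figures are 800×700 px; SVG output suppresses
timestamps and fixes the hash salt so identical inputs give identical bytes.

## Simulation sizes and numerical choices

Default replicate counts follow the tool's conventions: t = 1000 for the
bootstrap test, the CIs and each plot cloud. The test suite verifies
Monte-Carlo correctness at t = 100,000 against exhaustive multinomial
enumeration for N ≤ 8 (the enumeration is exact rational arithmetic), and
calibration with 500 HW-true datasets of N = 200 at p = 0.5: the bootstrap
p-value's ECDF is compared to uniform by a KS test at α = 0.001 and CI
coverage is required to sit in 93–97%. These sizes make the whole suite run
in well under a minute while keeping binomial standard errors small relative
to the asserted tolerances.

## What the simulations do and do not show

The generator draws i.i.d. multinomial genotypes — exactly the sampling
model under which every test here is derived. Passing calibration therefore
shows internal correctness, not robustness to features of real data:
population structure, null alleles, allelic dropout and genotyping error all
violate the i.i.d. multinomial assumption and typically masquerade as
heterozygote deficit (positive F̂). That is precisely why the tool is useful
for quality control, and why a rejection is a flag for follow-up rather than
a verdict on the locus.

## Known limitations

- Exact enumeration is two-allele only; k-allele exactness is Monte-Carlo
  with resolution 1/t.
- The Wald intervals are the textbook Gaussian approximation; no Wilson or
  Clopper–Pearson variants, and no intervals for allele frequencies or F̂.
- The de Finetti plot is defined for two alleles only.
- Continuity-correction formulas for the G and Cannings–Edwards variants are
  literature-standard reconstructions, isolated each behind a single
  function for easy replacement.
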