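# Methods

## Scope and model

`caseinpop` analyses one biallelic, codominant autosomal locus scored on
diploid individuals grouped into populations (breeds) and optionally regions.
Everything reduces to per-group genotype tallies (n₁₁, n₁₂, n₂₂); individuals
with a missing call are dropped before tallying so N always counts genotyped
animals. The estimators assume independent individuals within a group and
treat allele frequencies as estimated by gene counting,
p = (2n₁₁ + n₁₂)/2N, which is the maximum-likelihood estimator under
multinomial sampling of genotypes.

## Hardy–Weinberg test

The test is the classical three-class goodness-of-fit chi-square against
(p²N, 2pqN, q²N) with df = 3 − 1 − 1 = 1 (one frequency estimated from the
data) and **no continuity correction**; the p-value is the upper tail of
χ²(1). For a monomorphic group two expected classes are empty and the result
is flagged invalid rather than computed. When any expected class count falls
below 5, the result carries a `low_expected` flag and the pipeline logs a
warning — the statistic is still reported, because the asymptotic
approximation degrades gradually rather than failing outright, but users
should treat such p-values with caution. No exact (mid-p / Wigginton-style)
test is provided: the survey setting this package reproduces used the
chi-square form, and at the sample sizes involved (N ≥ 86) the two agree.

## Diversity panel

Per group: Na = number of alleles with frequency > 0 (≤ 2 here);
Ne = 1/Σpᵢ²; Shannon I = −Σpᵢ ln pᵢ in **nats** (natural log, following the
GenAlEx convention); Ho = n₁₂/N; He = 1 − Σpᵢ² = 2pq;
uHe = He·2N/(2N−1) (Nei's small-sample correction); F = 1 − Ho/He, undefined
(reported NA) when He = 0. Pooled or regional rows are computed by summing
genotype tallies first and evaluating the indices once on the pooled counts —
not by averaging per-group indices, which would miss the between-group
component of gene diversity (for the bundled survey, pooled Ne is 1.781
versus a 1.713 mean of breed values).

## Differentiation

Pairwise Fst uses Nei's Gst decomposition with the **unweighted** mean of the
two populations' allele frequencies: p̄ = (p_a + p_b)/2, Ht = 2p̄(1−p̄),
Hs = (He_a + He_b)/2, Fst = (Ht − Hs)/Ht. The unweighted convention is
deliberate: it treats populations, not individuals, as the units being
compared, and it is the convention under which the bundled survey's printed
matrix reproduces cell-for-cell (a 2N-weighted mean does not reproduce it).
When both populations are fixed for the same allele, Ht = 0 and Fst is
defined as 0.

Nei's unbiased distance is D = −ln(J_xy/√(uJ_x·uJ_y)) with
J_x = Σp²_{a,i}, J_xy = Σp_{a,i}p_{b,i} and uJ = (2N·J − 1)/(2N − 1).
Because only the within-population homozygosities are bias-corrected, the
raw identity can exceed 1 for very similar populations; the distance is then
clamped to 0 (and likewise any negative Fst residue). The correction also
means D approaches its large-N asymptote from below. The degenerate case of
a group consisting of a single heterozygote gives uJ = 0; the identity
diverges upward and the clamped distance is 0.

An overall among-population differentiation summary is exposed under three
explicitly tagged conventions — `unweighted` (k-population Gst with plain
means), `size_weighted` (pooled-frequency Ht, 2N-weighted Hs), and
`mean_pairwise` (mean of all C(k,2) pairwise Fst). No single "overall"
number is privileged because the three conventions legitimately differ
(0.034, 0.030 and 0.024 respectively on the bundled survey); callers must
pick one and the tag travels with the value.

## Synthetic cohorts

The generator draws each population's genotype tallies from a single
multinomial with class probabilities from the inbreeding decomposition
(p² + fpq, 2pq(1−f), q² + fpq), where f ∈ [max(−p/q, −q/p), 1] keeps all
probabilities non-negative. Sampling at the genotype level (rather than
per-allele Bernoulli) makes f enter exactly, so F = 1 − Ho/He is a
consistent estimator of f and the generator doubles as a calibration rig:
the test suite checks that the chi-square test's type-I error is ≈ 0.05
under f = 0 (2,000 replicates of N = 1,000 at p = 0.3) and that p and f are
recovered at N = 100,000 within 0.005 and 0.02. The default simulated
conditions used in tests mirror the bundled survey (population sizes 86–701,
A1 frequencies 0.145–0.372). The generator is single-snapshot only: no
drift, pedigree, mutation, or linkage, so passing tests say nothing about
temporal dynamics in real herds; they validate the estimators under the
sampling model the estimators themselves assume. All randomness flows
through one `numpy.random.Generator` seeded from the cohort spec — no global
RNG state — so datasets are bit-for-bit reproducible.

## Numerical and reporting conventions

All statistics are computed in double precision from raw integer counts;
nothing is ever computed from a rounded frequency. Rounding happens only at
the rendering boundary, with **half-up** decimal rounding (`0.3575 → 0.358`),
not banker's rounding — this is what published tables in this field use.
Reports default to 3 decimal places (2 for genotype-frequency displays);
the JSON payload written by the pipeline carries full-precision doubles so
downstream comparisons never depend on display rounding. Undefined values
(F of a monomorphic group, the p-value of an invalid HWE test) render as
`NA`.

The bundled survey tallies reproduce the published summary tables at these
precisions with three known exceptions, all attributable to rounded
intermediates in the original spreadsheet workflow rather than to a
different estimator: one breed's printed Ne (1.877 vs 1.876 at full
precision), one breed's printed uHe (equal to its He instead of the
corrected value), and Nei-distance cells that drift by up to 0.002. The test
suite checks those cells at correspondingly loosened tolerances and
everything else at the printed precision.

## Design choices and limitations

- Genotype tokens are normalized case-insensitively and the heterozygote is
  unordered (`a2a1` → `A1A2`). Unknown tokens are hard errors naming the row;
  a configurable sentinel (default `NA`/empty) marks missing calls. How the
  original survey handled failed genotype calls is unknown; dropping them
  per-tally is this package's own policy.
- Region is free text, not an enum; delimiter auto-detection is restricted
  to comma and tab.
- The count-table reader always recomputes N from the three class counts and
  tolerates thousands separators in quoted fields.
- Single locus only: no multi-locus averaging, rarefaction, AMOVA variance
  components, or permutation significance for Fst.
- The CLI is a thin layer over the library; identical input and
  configuration produce byte-identical reports, and all computation precedes
  any file write so validation failures leave no partial outputs.
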