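# Methods

This note records the statistical models the package implements, the design
choices made where the underlying methods are underspecified in common
usage, and what the synthetic-data generators do and do not emulate.

## Exact two-library test

The screen handles the hardest feature of the design — one library per
condition, no replicates — by conditioning. Each gene's count is Poisson;
given `x` reads in library 1 (size N1), the count `y` in library 2 (size
N2) under equal per-molecule expression follows

p(y|x) = r^y (x+y)! / (x! y! (1+r)^(x+y+1)),  r = N2/N1,

which is a negative binomial NB(size = x+1, p = N1/(N1+N2)) in y. We
compute the pmf in log space with log-gamma and the tail probabilities
exactly through scipy's regularized-incomplete-beta nbinom cdf/sf — no
truncated summation, no factorial overflow. Tests pin both against an
exact-rational (fractions.Fraction) oracle.

Two notes on this construction:

* **Sidedness.** The equal-expression hypothesis is two-sided; we double the
  smaller tail (both tails include the observed y) and cap at 1. At
  `x = y`, N1 = N2 this gives p ≈ 1, as it should.
* **Asymmetry.** Conditioning on `x` is directional: swapping
  (x, y, N1, N2) → (y, x, N2, N1) multiplies the pmf by exactly N2/N1 and
  changes tail p-values by a comparable factor. This is a property of the
  conditional construction itself, not an implementation artifact; the
  package conditions on the susceptible library throughout. The pmf is
  exactly symmetric in x ↔ y when N1 = N2.

The fold change is log2 of the RPKM ratio (gene length cancels; only the
depth normalisation matters). Zero-count policy: one zero side gives a
±inf log2 ratio and stays eligible for calling (|log2| ≥ 1 holds
trivially); a both-zero gene cannot be tested — it is reported with NaN
p/FDR, excluded from the BH pool and never called. No pseudocounts: they
would manufacture fold changes for genes the data say nothing about.

Multiplicity: Benjamini–Hochberg step-up ("FDR" here always means the
BH-adjusted p), delegated to statsmodels and verified against a literal
brute-force transcription of the step-up definition. Default thresholds:
FDR ≤ 0.001 and |log2 ratio| ≥ 1, both inclusive.

## Enrichment

Over-representation only: p = P(X ≥ m) for X hypergeometric with
population N (the annotated expressed universe), successes M (term
members), draws n (the DE set). The universe is an explicit caller input —
it is never inferred from the annotation map, because silently shrinking N
to "genes with any annotation row" changes every p-value. Two reporting
conventions are implemented because both are standard: Bonferroni-corrected
p ≤ α (term-enrichment reports) and raw p ≤ α (pathway tables); the
`correction` flag selects one. No GO-graph ancestor propagation: terms are
treated as flat labels.

## Protein quantification

Reporter-ion ratios are positive and multiplicative, so a protein's N
spectrum ratios are aggregated on the log scale: the protein ratio is the
geometric mean, and its uncertainty is the usual multiplicative confidence
interval exp(t·s/√N) — the "error factor" formulation. The differential
test is therefore a two-sided one-sample t-test of log-ratios against 0
with N−1 df. Degenerate cases: N = 1 → p undefined (NaN), reported but
never called; zero spread with non-zero mean → p reported at the smallest
positive float rather than 0 so that p ∈ (0, 1] holds. Calls at
mean ratio ≥ 1.2 or ≤ 0.8 with p ≤ 0.05, all inclusive.

## Integration

Alignment filters: E-value strictly below 1e-15 (a threshold stated as
"less than"), mismatch ≤ 6% and length ≥ 30 aa inclusive. Best hit per
protein: lowest E-value, then longest alignment, then lexicographic
transcript id — fully deterministic. Fold changes are correlated on the
log2 scale on both layers (symmetric treatment of up and down); pairs with
non-finite fold changes (a zero-count side) are excluded from the
correlation. Transcript-side significance for the overlap table uses the
exact-test p < 0.05 — the looser matching criterion appropriate for asking
whether a transcript moves in the same direction — not the screen's FDR
threshold; protein-side significance is the 1.2/0.8-fold +
p ≤ 0.05 call. Concordance = both significant and same sign.

## qPCR

The composite reference is realised as the arithmetic mean of the
reference-gene Ct values, equivalent to a geometric mean of their linear
quantities — the standard way a multi-gene internal reference enters the
ΔΔCt scale. Fold = 2^−ΔΔCt; per-replicate folds are combined as the
geometric mean (arithmetic mean of ΔΔCt), and biological replicates are
paired across strains in replicate order for the paired t-test. No
amplification-efficiency correction: the 2^x model assumes perfect
doubling per cycle.

## Enzyme statistics

GST activity is the least-squares slope of the OD340 trace per mg protein;
PNOD activity inverts a least-squares linear standard curve (flat curves,
detected at relative tolerance 1e-12, are rejected). Strain comparison is
one-way ANOVA with protected Fisher LSD: pairwise t comparisons with the
pooled MSE are consulted only when the ANOVA is itself significant at α,
otherwise all strains share one letter. Letters are assigned from maximal
runs of mutually non-different groups in descending-mean order, which is
exact for the balanced designs this layout uses. Ratios versus the
susceptible strain are reported half-up at 3 decimal places (percentages
half-up at 2), with full precision carried internally — rounding lives
only at the report layer.

## Synthetic data

All generators are pure functions of (config, seed); substreams are
derived per generator from the single seed, so changing e.g. the protein
settings never perturbs the count draws.

* **Counts.** Relative gene abundances are log-uniform over a 100× dynamic
  range (configurable), normalised and scaled by the library depth; counts
  are Poisson, matching the test's sampling model exactly so that the
  type-I error property is checkable. Truly differential genes multiply
  the resistant-library concentration by 2^(±effect) with alternating
  signs; the resistant library is deliberately not renormalised, so null
  genes differ between libraries only through depth. A gamma-mixing
  over-dispersion knob exists for robustness experiments but defaults off.
  Defaults: 2000 genes, 10⁶ reads per library, 5% differential at
  |log2| = 2. The power analyses use depth 2.5×10⁶, which places the
  minimum expected count near 58 — the adequate-coverage regime in which
  ≥ 90% sensitivity at ≤ 5% false calls is the predicted behaviour.
* **Spectra.** Log-normal ratios around the true protein ratio with the
  configured CV (σ² = log(1+CV²)). With CV = 0.1 and 8 spectra the
  geometric mean has log-scale SE 0.035, so ~84% of proteins land within
  5% of truth — the recovery-rate tests assert this analytically derived
  figure, not a rounder aspiration.
* **Matched omics.** Bivariate normal log2 fold changes with population
  correlation exactly ρ (default 0.66; mRNA sd 1.5, protein sd 0.5 —
  protein fold changes are empirically compressed relative to mRNA).
  Alignment rows qualify by default; disjoint configurable fractions are
  forced to violate each of the three matching rules to exercise the
  filter.
* **Ct plates.** Reference genes at fixed base Cts (20, 22), target at 24,
  treated-sample target shifted by −log2(true fold), Gaussian well noise
  (default sd 0.1 cycles), 3 replicates. Recovery tests average 10
  independent plates so the Monte-Carlo error (~3%) is well inside the
  ±15% recovery band being checked.
* **Assays.** Normal replicates at given strain means with sd = SE·√n.

What the generators do **not** emulate: real count over-dispersion beyond
Poisson (biological replicates do not exist in this design), mapping
ambiguity and positional biases, spectrum-level interference and missing
proteins, qPCR efficiency differences, or any annotation structure (terms
are arbitrary labels). Passing tests therefore certify the statistics
under each method's own sampling assumptions — they do not certify
robustness to violations of those assumptions in real libraries.

## Problem sizes

The test suite and the acceptance script run the simulations at 2000–5000
genes, 200–400 proteins and 10 qPCR plates. These sizes put every binomial
/ correlation standard error several-fold below the tolerance being
asserted, which is the criterion by which they were chosen; the whole
battery completes in seconds.
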