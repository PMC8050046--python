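# Methods

This note documents the models, conventions and numerical policies behind
each module, the design choices made where the design was genuinely open,
and what the synthetic-data generators do and do not emulate.

## Codon algebra

A degenerate codon is three IUPAC nucleotide ambiguity codes; its expansion
is the Cartesian product of the per-symbol base sets (sizes 1, 2, 3 or 4, so
the expansion size is their product, at most 64).  Translation uses the
standard nuclear genetic code (translation table 1) only — the designs are
expressed in *E. coli* from mouse V genes, where the standard code applies —
via biopython's codon table rather than a hand-rolled map.  The stop token is
`*` internally and is never counted as an amino acid; RNA `U` and lowercase
input are normalized on construction.  `NNS` (any, any, C/G) expands to 32
codons covering all 20 amino acids plus exactly one stop (TAG); `NNK` is its
complement-symmetric mirror with the same residue profile.

## Library design

**Representation.**  A library is an ordered list of positions — fixed
residue, substitution menu, or one (NNS)\_n insertion block — plus concrete
5′/3′ flanks.  Primer windows are addressed 0-based and half-open in
nucleotides; framework labels are 1-based.  An insertion block carries the
label of the position it follows.  Primer strings are stored exactly as
synthesized (5′→3′, sense-frame codons); a reverse-complement export is
provided instead of guessing orientation, because the cloning architecture
of the downstream amplicon is not modeled.

**Inverse codon design** searches all 15³ = 3,375 degenerate codons.  Every
candidate must cover the full target set (NNN always does, so the search
cannot fail); among covers the objective is lexicographic: fewest off-target
residues, then fewest stop codons, then fewest concrete codons, then
alphabetical symbols.  The result reports whether an exact, stop-free cover
exists — e.g. {E,I,K,L,Q,V} has one (VWA), {D,E,H} does not (best covers
carry one extra residue).

**Diversity accounting.**  Protein diversity multiplies per-position counts
of *distinct stop-free residues* (an NNS block of length n contributes 20ⁿ);
this deliberately ignores stop-containing DNA variants, which are quantified
separately: the stop fraction is 1 − ∏ᵢ(stop-free codons / total codons)ᵢ,
exact because positions are independent — for n NNS codons, 1 − (31/32)ⁿ.
DNA diversity multiplies expansion sizes.  Pooled sublibraries add counts;
their pooled stop fraction is the DNA-count-weighted mean (each DNA variant
of the pool counted once).  Enumeration yields variants in lexicographic
order and refuses above a configurable cap (default 10⁶) to guard against
materializing 10⁷-scale insertion libraries.

## Screening statistics

Colony picking is modeled as i.i.d. multinomial draws from the variant
abundance distribution.  This neglects clonal growth bias and plate-to-plate
imbalance — a documented limitation, not an estimate of them.  Two abundance
models are built in: uniform, and codon-weighted, where a variant's weight is
proportional to the number of concrete codons encoding it.  With stop codons
present the stop-free multiplicities sum to less than the DNA diversity, so
codon weights are normalized over the stop-free DNA count (identical to
dividing by DNA diversity whenever the design is stop-free).  Pools combine
sublibraries equimolarly: equal total weight per sublibrary, codon-weighted
within.

* **Expected missing** after n draws is the exact closed form Σᵢ(1−wᵢ)ⁿ.
* **P(full coverage)** is exact inclusion–exclusion for k ≤ 25 (the 2^k
  subset sums are enumerated; beyond that the alternating sum is both
  expensive and numerically cancellous) and otherwise the Poissonized
  independence approximation ∏ᵢ(1−(1−wᵢ)ⁿ), computed in log space.  It is
  pinned to exactly 0 for n < k.  The report names the method used, and a
  seeded Monte-Carlo verifier (`simulate_coverage`, default seed 20210415)
  provides an independent cross-check.
* **Draws for coverage** inverts the monotone p\_full(n) by exponential
  search plus integer bisection, returning the minimal n.

Hit selection uses *strict* inequality at the threshold (a "> 100,000 RLU"
rule), descending-signal order, ties broken by well index.

## Kabat framework analytics

Framework segments are consumed pre-delimited at the fixed Kabat heavy-chain
lengths 30/14/32/11 (87 positions); full Kabat numbering of raw sequences
(insertion codes such as 52a) is a separate concern and out of scope, as are
alternative delimitations (Chothia, IMGT).  Percent identity always uses the
87-position denominator, with gaps — including gap-aligned-to-gap — counted
as mismatches; the exact fraction is kept internally and display rounds to
one decimal (83/87 → 95.4).  Subgroup assignment is the arg-max of identity
with alphabetical tie-break (ties flagged) and a full ranking returned.
Frequency tables normalize per column by non-gap observations; an all-gap
column yields an empty distribution and is flagged rather than raised.

## Binding characterization

**4PL fitting.**  The model is the Hill form in dose,
B/B₀(%) = bottom + (top−bottom)/(1+(dose/IC₅₀)^slope), fitted on
log-transformed dose for conditioning (the two are the same curve).  Raw
responses are normalized to B/B₀ % against the mean of the zero-dose wells
after subtracting a configurable background (default 0); data already in %
are accepted as-is.  Top and bottom are free parameters — real assays retain
a background below ~5% of B₀, so forcing bottom = 0 would bias the midpoint.
The fit is Levenberg–Marquardt damped least squares with at most
500·(p+1) function evaluations and relative tolerances 1e−10, initialized
from the data (top = max, bottom = min, midpoint = dose nearest the
half-response, slope = 1); it is deterministic given the data, and
non-convergence is flagged on the result, never silent.  A negative fitted
slope is re-expressed as the equivalent positive-slope curve with top and
bottom swapped, keeping the competitive orientation convention.

**LOD** is the dose at which the fitted curve crosses the zero-dose mean
minus twice its standard deviation (sample SD, n−1).  As the B0 variance
approaches zero the rule degenerates to the dose where the curve first drops
below B₀ — i.e. 0, which is returned with a note; a threshold below the
fitted bottom is flagged undefined instead of extrapolated.  The LOD is
monotone increasing in the B0 dispersion.

**Cross-reactivity** is 100 × IC₅₀(analyte)/IC₅₀(analog).

**Unit conversions** keep two volume bases deliberately, because both are
meaningful readings of "X pg/assay": the in-well concentration divides by
the 150 µL final incubation volume (10.0 pg/assay → 66.7 pg/mL → 184 pmol/L
at 362.46 g/mol), while the serum-equivalent concentration divides by the
50 µL standard aliquot and multiplies by the specimen dilution factor
(default 10), expressing what a specimen must have contained.

**Scatchard analysis** assumes single-site mass action without
tracer-depletion corrections (none are identifiable from a bound/free
table): B/F = K\_a(R\_t − B), estimated by ordinary least squares of B/F on
B; K\_a = −slope, R\_t = x-intercept.  A non-negative slope means no
displacement signal and is flagged invalid rather than raised.  Fold
improvements divide mutant by reference and display as the nearest integer,
rounding half away from zero (1.1×10¹⁰/3.6×10⁸ = 30.6 → "31-fold";
706/29.4 = 24.0 → "24-fold"; 706/29.9 = 23.6 is also computable — display
convention follows the 29.4 reading).

## Synthetic-data generators

All generators are pure functions of (config, seed) using numpy's PCG64
`default_rng`; with zero noise they are deterministic and seed-independent.

* **Plates**: 94 colony wells + 2 background wells per 96-well plate.
  Background RLU is normal truncated at zero by resampling — reported plate
  backgrounds have SD of the same order as the mean (e.g. 2758 ± 1909, the
  default), so an untruncated normal would produce negative luminescence.
  The truncation is a modeling choice, not a measured distribution.
  Positives are planted additively at a configured signal (default 500,000
  RLU, far above the 100,000 hit threshold).
* **Dose–response**: a configured 4PL curve sampled at log-spaced doses
  (default 8 doses, 4 replicates) with multiplicative Gaussian noise at a
  configured CV, plus 10 zero-dose wells at the top level anchoring B/B₀
  normalization.
* **Scatchard**: bound/free from single-site mass action at a configured
  K\_a and site concentration, free-tracer levels log-spaced around 1/K\_a
  (default 1.5 decades, 6 points), multiplicative noise on bound.

What passing tests on these generators shows: the estimators invert their
own generating models correctly (noise-free recovery to < 0.1%, unbiased
recovery under moderate noise, exact hit recovery at the default
separation).  What they do not show: robustness to real-assay features the
generators omit — heteroscedastic counting noise, plate edge effects,
drift between plates, tracer depletion, or non-4PL curve shapes.

## Problem sizes and determinism

The test suite and the acceptance script run everything at the native scale
of the designs (1,536- to 8,420-member enumerations, 3,375-codon searches)
and use 10⁴ Monte-Carlo replicates for coverage cross-checks; the whole
suite completes in seconds on one CPU.  Every stochastic routine takes an
explicit seed; library defaults (20210415) make reruns byte-identical.
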