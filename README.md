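# maturelib

Toolkit for *designed* degenerate-codon mutagenesis of antibody fragments and
for the quantitative evaluation of the resulting screening campaigns.  It was
built around a concrete use case — affinity maturation of an anti-cortisol
single-chain Fv (scFv) by targeted randomization of the heavy-chain framework
region 1 (V\_H-FR1, Kabat positions 1–30) — but every component is generic:

* **Codon algebra** — exact expansion of IUPAC-degenerate codons (`NNS`,
  `VWA`, …) through the standard genetic code into residue profiles, and
  equality tests against target residue sets.
* **Library design** — parse degenerate primers into per-position residue
  menus, solve the inverse problem (the minimal degenerate codon covering a
  residue set, searched over all 15³ = 3,375 candidates), compute exact
  protein/DNA diversities and stop fractions for substitution and
  (NNS)\_n-insertion libraries, enumerate variants, and reassemble primers.
* **Screening statistics** — coupon-collector coverage of a k-member library
  by n random colony picks: the closed form E[missing] = Σᵢ(1−wᵢ)ⁿ, the
  probability of full coverage (exact inclusion–exclusion for small k,
  Poissonized product otherwise), its inverse (picks needed for a target
  confidence), and luminescence-threshold hit bookkeeping.
* **Kabat framework analytics** — percent identity over the 87 framework
  positions (FR1–4: 30+14+32+11), subgroup assignment by maximum identity,
  and per-position residue-frequency tables with most-common-amino-acid
  extraction.
* **Binding characterization** — four-parameter-logistic (4PL) fitting of
  competitive-ELISA dose–response curves, `B/B₀(%) = bottom +
  (top−bottom)/(1+(dose/IC₅₀)^slope)`, limit of detection by the
  mean−2·SD-of-zero-dose rule, cross-reactivity (IC₅₀ ratio), assay unit
  conversions, Scatchard estimation of the association constant
  (B/F = K\_a(R\_t − B), K\_a = −slope), and fold-improvement display.
* **Synthetic generators** — seeded simulators for plate readouts, 4PL
  dose–response tables and single-site Scatchard data, so every analytic
  path is testable without instrument files.

## Worked example

The built-in `library-A` design is a 91-mer degenerate oligo whose ten-codon
window substitutes framework positions 1–3, 5–7, 9 and 10 (wild type
`QVQLQQPGAE`) with small residue menus:

```text
$ maturelib diversity library-A
protein_diversity=1536 nucleotide_diversity=1536 stop_fraction=0
```

1,536 is the product of the per-position residue-set sizes
2·2·2·1·6·2·2·1·4·2; because each menu uses one codon per residue, the DNA
and protein counts coincide and no variant carries a stop codon.  The most
degenerate position is position 5:

```text
$ maturelib expand VWA
codons (6): AAA ATA CAA CTA GAA GTA
residue profile: E:1 I:1 K:1 L:1 Q:1 V:1
$ maturelib design-codon EIKLQV
VWA	6 codons	exact stop-free cover
```

The pooled one-, two- and three-residue `NNS` insertion sublibraries count
20 + 400 + 8,000 = 8,420 protein variants (the DNA level is larger, and
~9% of DNA variants carry the TAG stop of NNS):

```text
$ maturelib diversity library-B:1 library-B:2 library-B:3
protein_diversity=8420 nucleotide_diversity=33824 stop_fraction=0.0899066
```

Picking 4,700 random colonies from the 1,536-member library misses ~72
members in expectation (95.3% coverage) — full coverage at 95% confidence
would need ~15,800 picks:

```text
$ maturelib coverage --k 1536 --n-draws 4700
expected_distinct=1464.04 expected_missing=71.96 p_full=9.876e-33 (poissonized)
```

Assay arithmetic — a 10.0 pg/assay dose in the 150 µL incubation, and the
fold gain of a matured K\_a of 1.1×10¹⁰ M⁻¹ over the parental 3.6×10⁸ M⁻¹:

```text
$ maturelib convert 10.0
10 pg/assay = 66.7 pg/mL = 184 pmol/L; serum-equivalent 2.00 ng/mL
$ maturelib fold 1.1e10 3.6e8
30.6 (31-fold)
```

Fitting a generated noise-free dose–response curve recovers its midpoint:

```text
$ maturelib generate-doseresponse --midpoint 706 > curve.csv
$ maturelib fit4pl curve.csv
midpoint=706.0 pg/assay top=100.0 bottom=-0.0 slope=1.000 rms=1.59e-10
```

All commands are thin wrappers over the `maturelib` Python API
(`maturelib.diversity`, `maturelib.fit_4pl`, …), which is the recommended
interface for scripted analyses.

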