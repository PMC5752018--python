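# Methods

This note documents the statistical model, the conventions the package
commits to where several were defensible, and what the simulations do and do
not establish.

## Study design assumed

A library of substitution lines shares the genetic background of one
recurrent parent (the running example is rice cv. HJX74); each line carries a
single contiguous, homozygous donor segment delimited by SSR markers on a cM
genetic map. The trait is days to heading scored on 20 plants per line per
trial year. Because the substitution is homozygous, a QTL of additive effect
*a* (in days) on the segment shifts the line mean by 2*a* relative to the
recurrent parent; dominance is not estimable from this design and is not
modelled.

## Segment notation and segment length

Segments are written in the field's hyphen notation: inner markers (on donor
DNA) joined by single hyphens, flanking markers (recipient DNA) attached with
double hyphens/em-dashes, e.g. `RM596—RM271-RM269-RM258-RM304—PSM167`.
`Short arm`/`Long arm` tokens at the start are chromosome-end anchors and are
accepted after either separator style (published tables use both); anchors
are modelled as a flank pinned at 0 cM. A two-part string whose parts are
both single markers (`B—C`) is read as *flank—inner*; a right-flank-only
segment with a single inner marker is therefore not representable and the
writer's output always re-parses to the same segment for every other shape
(property-tested).

The true donor/recipient breakpoint lies between the outermost inner marker
and its flank. The default **segment-length convention** is the expectation
under a uniform breakpoint position: inner span plus **half** of each
inner-to-flank gap. The conservative flank-to-flank span is available via
`convention="flank_to_flank"`. `segment_to_interval` uses the same midpoint
convention, so interval length always equals the length estimate. A missing
flank with no terminal anchor contributes a zero gap.

## Dunnett many-to-one screen

One-way equal-variance layout per trial year (years are independent
plantings and are analysed as separate families). With control size n₀ and
treatment sizes nᵢ, the pooled-variance t statistics have the joint
correlation structure ρᵢⱼ = λᵢλⱼ with λᵢ = √(nᵢ/(nᵢ+n₀)), which handles
unbalanced panels. Two-sided adjusted p-values are tails of max|T| under the
joint central multivariate t.

They are computed by **Rao-Blackwellized Monte Carlo**: conditioning on the
shared control variate Z₀ and the pooled-variance scale W makes the
treatment statistics independent, so

P(max|Tᵢ| < c) = E_{Z₀,W} [ ∏ᵢ ( Φ(uᵢ) − Φ(lᵢ) ) ]

with the inner product evaluated exactly and only the outer expectation
sampled (default 10⁵ seeded draws). This is unbiased, reduces seed-to-seed
p-value differences to ~10⁻⁴ at the default draw count, and reduces exactly
to the pooled two-sample t test at k = 1. Constant data with equal means
yields p = 1; constant data with unequal means is an error (zero pooled
variance). Missing plants are dropped with a logged warning, never imputed.
Presence calls use p ≤ α with α = 0.01 by default; the threshold is
inclusive.

## Substitution mapping

The candidate region is the intersection of all positive lines' segment
intervals; every negative line's interval is then subtracted (a
non-overlapping negative is a no-op). Intervals are closed; subtraction
keeps the shared endpoint, matching the convention that a QTL "mapped to
[6, 10]" includes the delimiting marker position. Disjoint remainders are
reported as separate QTLs named with ascending positional suffixes
(`qHD-6-1`, `qHD-6-2`). An empty intersection of positives, or negatives
covering the whole candidate, raises an explicit inconsistency error rather
than returning silently empty — in real data that pattern means a mis-called
line or a multi-QTL segment. Mapped intervals are rendered back into hyphen
notation using the markers inside the interval and the nearest outside
markers as flanks; an interval containing no marker gets no notation.

## Effects, contributions, and report rounding

additive effect = (line mean − recipient mean)/2; contribution =
effect / recipient mean × 100, always against the same-year recipient mean.
Computation keeps full precision; rounding happens only when a report is
rendered. Report rounding is **half-up after snapping the value to 15
significant digits**: differencing two 2-decimal means in binary floating
point can land a hair below an exact decimal tie (123.20 − 106.65 halved is
8.274999…97 for the true 8.275), and the snap restores the intended decimal
before the tie-break. This is the rule under which the package's effect
tables agree cell-for-cell with the published values it ships in
`sssltools.reported`.

## Epistasis classification

Given lines carrying QTL A, QTL B, both (AB), and the recurrent parent,
Welch two-sample contrasts at a configurable α (default 0.01) decide:
`a_over_b` when AB phenocopies A (fail to reject) while differing from B
(reject); `b_over_a` symmetrically; `additive` when AB differs from both
single-QTL lines and the interaction contrast AB − A − B + recipient is not
rejected (Welch–Satterthwaite df); `undetermined` otherwise. The test choice
is this package's own — the underlying inference pattern (a double-carrier
line heading like the major-QTL line) is standard, but no particular test is
canonical for it.

## Allele CDS comparison

Global pairwise alignment with affine gaps via Biopython's
`PairwiseAligner`; default scores match +2, mismatch −3, gap open −8, gap
extend −1 (a length-L gap costs −8 − (L−1)). Ties take the aligner's first
reported optimum, and indels are then **left-normalized** (VCF-style) so
coordinates are reproducible in repeat contexts. Adjacent gap columns merge
into one indel record; adjacent mismatch columns stay separate SNPs (two
neighbouring substitutions are conventionally counted as two SNPs).
Coordinates are 1-based inclusive externally ("deletion of positions
103–331" has length 229), half-open internally.

Translation uses the standard genetic code from position 1, stops at the
first stop codon (excluded from the length), truncates a trailing partial
codon with a warning, and warns when no stop is present (partial CDS). A
frameshift is called when the net indel length upstream of the reference
stop is not ≡ 0 (mod 3); a premature stop when the alt protein ends before
the reference protein; substitutions are counted over the shared-length
prefix of the two proteins.

Protein profiles follow the ProtParam conventions: molecular weight from
average residue masses, GRAVY and windowed hydropathy on the Kyte–Doolittle
scale (default window 9), and theoretical pI as the root of the
Henderson–Hasselbalch net-charge function with the Bjellqvist pKa set
(Biopython's charge model), bracketed by bisection/Brent to 10⁻⁶ pH so the
net charge at the reported pI is ~0. Secondary-structure prediction is out
of scope (it requires a trained model, not a formula).

Primer QC: length 18–25 nt, GC 50% ± 10 points, Tm 55 ± 3 °C by the Wallace
rule 2(A+T) + 4(G+C) (nearest-neighbor Tm available), and a hairpin flag
when a self-complementary run of ≥ 6 nt exists with a ≥ 3-nt loop. All
windows are configurable.

## Synthetic data: what it emulates, what it does not

`SimConfig` defaults are the study conditions: 20 plants/line, recipient
mean 105.18 days, residual SD 3 days (per-plant SD implied by published
standard errors at n = 20 is roughly 2–4 days). Marker positions are sorted
uniforms; each line gets one contiguous inner-marker run with the
neighbouring markers as flanks. Phenotypes are Gaussian around
recipient mean + Σ 2a over carried QTLs, with a masked QTL contributing
nothing when its masking QTL is co-carried. All generators are pure
functions of (config, seed).

Allele-pair generation plants SNPs and contiguous indels at exact 1-based
coordinates and pins the single base on each side of every indel so it
cannot shift under left-normalization (pin replacements prefer C, which can
never create a stop codon in any frame). Planted-variant recovery is
coordinate-exact provided neighbouring variants are separated by roughly a
dozen matching bases at the default penalties; closer opposite-sign indel
pairs admit equally- or better-scoring merged representations, which is an
alignment-theoretic fact, not an implementation artifact. One published
fixture hits this for real: in the DTH3 comparison where a GTG→CAA change
abuts the allele's end, equally scoring alignments trade the three terminal
SNPs against a 3-nt-shifted deletion, so only the invariant totals (612 nt
deleted, 81 nt retained) are asserted for it.

What the simulations do **not** emulate: field spatial structure,
genotype-by-year interaction beyond separate analyses, residual donor
contamination (multi-segment lines), genotyping error, and real sequence
composition (allele stand-ins are random DNA with the published variant
geometry). Passing tests therefore establish correctness of the method under
its own model, not robustness to those violations.

## Problem sizes used in checks

The statistical checks run at the study's own scale: 1,000 null replicates
for the familywise error rate (binomial SE ≈ 0.003 at α = 0.01), 1,000
random mapping scenarios against a 0.01-cM grid brute force, and 200 seeds
for effect recovery (planted a = 8 days; the mean estimate is required to be
within twice its standard error) and epistasis classification (> 90%
recovery required). Dunnett Monte Carlo uses 2×10⁴ draws inside the large
replicate loops and 10⁵–2×10⁵ elsewhere.

## Known limitations

- Published segment lengths and mapped-interval lengths (e.g. the 4.15-cM
  overlap) cannot be recomputed because the source prints no marker cM
  positions; the midpoint convention is a principled reconstruction, and
  only its internal properties are verified.
- A handful of published 2015 effect/contribution cells are internally
  inconsistent with the stated formulas at printed precision; the package
  reports the formula's value and `sssltools.reported` documents each
  exclusion.
- The Dunnett adjustment assumes equal variances across lines (pooled
  error); strong heteroscedasticity would require a different procedure.
- `classify_epistasis` distinguishes full masking from additivity; partial
  epistasis lands in `undetermined` by design.
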