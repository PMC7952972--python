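# Methods

This note documents the models, parameter choices and numerical
conventions behind `pgtcnv`, and what the simulation-based tests do and do
not demonstrate about real data.

## Reference frame and cytobands

All coordinates are 0-based, half-open base pairs, matching the BED-like
bin-count files. The bundled cytoband table
(`src/pgtcnv/data/cytobands_synthetic_hg19.tsv`) is a **synthetic
stand-in**: chromosome lengths are real hg19 values, band names follow
ISCN, and band boundaries are approximate — near-real values are used for
the chromosomes exercised by the bundled cases (2, 8, 11, 21, 22, X;
e.g. 21q22.3 = 42.6–48.13 Mb), evenly spaced interpolations elsewhere.
Bands per chromosome tile `[0, length)` exactly and include `p10`/`q10`
centromeric bands, whose shared boundary defines the centromere position.
Any band-level breakpoint is placed at the **band midpoint**, because
referral karyotypes carry band-level precision only; a named sub-band
missing from the table falls back to its parent band. A reduced synthetic
genome (3 × 50 Mb autosomes + 30 Mb X + 10 Mb Y, 190 bins) is a
first-class grid for desk-scale work.

## Meiotic segregation model

A reciprocal-translocation carrier's quadrivalent has four elements — the
two normal homologues A, B and the derivatives der(A) = A-centric +
B-translocated and der(B) = B-centric + A-translocated, where each
chromosome is cut at its breakpoint band midpoint. Gamete classes are the
element subsets: 6 two:two products (alternate ×2, adjacent-1 ×2,
adjacent-2 ×2), 8 three:one products (4 trios + 4 singletons), and the two
4:0 poles — 16 distinct compositions, of which exactly 2 (the alternate
pair) are balanced.

Two weight conventions are exposed:

- `counseling` (default): the "18 gamete types, 2 balanced" count used in
  reproductive counseling. Its published decomposition is not algebraic;
  we realize the 18 slots by giving each 4:0 pole two slots, so uniform
  slot weights put the balanced mass at 2/18 = **1/9** per carrier and a
  double-carrier couple at exactly **1/81** (all weights are
  `fractions.Fraction`, so these are exact rationals, not floats).
- `distinct`: uniform over the 16 compositions, balanced mass 1/8.

The two conventions differ only in weights; segment bookkeeping is
identical. They are deliberately not reconciled — the choice is a genuine
ambiguity in how segregation outcomes are counted.

Robertsonian trivalents give 8 classes (balanced: {der} and {A, B}; the
2:1 and 3:0 malsegregations produce disomic/nullisomic gametes for either
chromosome, modelled on the acrocentric q-arms — the satellite p-arms
carry no unique dosage signal). Inversion carriers give 4 classes: two
balanced non-recombinants and two recombinants; pericentric recombinants
carry a duplicated flank plus a deleted flank, paracentric recombinants
are acentric/dicentric and flagged nonviable (excluded from zygote
formation by default). The default inversion recombination probability is
1/2 (uniform over the four classes). Deletion/duplication carriers
transmit the carried imbalance with probability 1/2. Per-mode weights are
configurable (e.g. 4:0 down-weighted to 0) and renormalized.

Zygote dosage is additive: expected copy = 2 + Σ parental deltas; a
region below copy 0 is rejected. Nullisomy (copy 0) is valid.

## Count simulator

The generator emulates the study regime: 3,000,000 reads per cell on the
full genome (scaled to grid size for reduced genomes, preserving per-bin
depth ≈ 965 reads/Mb), 55 bp single-end (metadata), 1 Mb bins. Expected
count per bin ∝ (local copy / 2) × GC bias, with GC bias multiplicative
log-quadratic in (gc − 0.40), default coefficients (0.8, −6.0) giving a
±5–8% smooth distortion. Counts are negative-binomial via gamma–Poisson
mixing (var = μ + αμ², default α = 0.02, i.e. per-bin CV ≈ 15%, MAPD
≈ 0.14), with per-bin dropout probability 0.01. Whole-sample
amplification failure (probability 0.057) is emulated **in-band** as
extreme dispersion (α = 3) plus 40% dropout rather than a missing file,
so the QC logic is exercised; with the default QC thresholds such samples
are reliably non-informative. A `noiseless` mode returns the rounded
expectation for threshold-boundary scans.

Embryo composition: one gamete per parent drawn by segregation weights;
de novo whole-chromosome meiotic events Poisson(0.7) per embryo with
per-chromosome propensities peaked at chromosomes 22, 19, 21 and 16
(weights 3 / 2.5 / 2 / 2 vs 1 elsewhere), sign ±1 equiprobable; one
mitotic event with probability 0.2 carrying a mosaic fraction drawn
uniformly from (0.2, 0.8). Sex is 50/50. Each sample's ground-truth
category is assigned by the same classification rules applied to the true
event list, so truth labels are recomputable from the truth table.

What the simulator does **not** model: read-level artifacts (mapping,
duplicates), locus-specific MALBAC bias beyond the smooth GC curve,
segmental de novo events, chaotic/multipolar cleavage genomes, or
contamination. Passing tests therefore demonstrate correctness of the
analysis under a realistic dose-plus-noise model, not performance on any
particular wet-lab dataset.

## CNV calling

**QC.** A sample is informative iff total reads ≥ 100 × n_bins and the
MAPD of adjacent raw bin ratios (within chromosomes) ≤ 0.35. The exact
QC criteria behind a given study's no-result rate are never published at
this granularity; these are declared defaults that cleanly separate the
simulated failure mode (MAPD > 1) from intact samples (MAPD ≈ 0.14).

**Reference panel.** Per-bin factor = median across ≥3 normal samples of
(count / autosomal baseline); X factors from the female subset (or male
×2), Y factors from the male subset ×2, so factors everywhere express
two-copy depth. Factors < 0.1 are masked; > 20% masked bins aborts
normalization.

**Baseline.** The two-copy baseline is the mean of per-chromosome medians
lying within 15% of their overall median. On the reduced genome a plain
pooled median (or a plain median of 3 chromosome medians) is biased by
~1.4% whenever a whole chromosome is aneuploid, because the middle order
statistic lands on the extreme normal chromosome; the trimmed mean
removes this while staying robust to single aneuploid chromosomes.

**Normalization.** ratio = (count / baseline) / factor, then a residual
GC correction divides each bin by the median of its 2%-wide GC stratum
computed on *chromosome-centered* residuals (so whole-chromosome
aneuploidies do not leak into stratum factors), then a final rescale to
autosomal baseline 1. Zero-count bins are masked as MALBAC dropout — at
0.04× even a one-copy loss retains ~500 reads/Mb, so a zero is an
artifact; the cost is that true single-bin nullisomy is indistinguishable
from dropout (documented limitation). Sex is inferred from X/Y median
ratios (X < 0.75 or Y > 0.25 ⇒ XY); Y signal in XX samples is never an
event.

**Segmentation.** Recursive binary splitting per chromosome: the split
point maximizes the two-sided mean-shift statistic
√(k(n−k)/n)·|mean_L − mean_R|; a split is accepted when the maximum
exceeds 3.5 × σ̂, where σ̂ = MAPD/(√2·0.6745) floored at 0.01. The 3.5σ
threshold balances false splits (the genome-wide noise maximum is ≈3σ)
against missing ~5-bin half-dose events whose boundary contrast is ~7σ
but can be degraded by an adjacent outlier bin. Adjacent segments whose
means differ by < 0.15 are re-merged (all real dose contrasts are
≥ 0.2, and re-merging makes the noiseless oracle equivalence exact:
any spurious split separates equal-mean pieces). The noise scale is
estimated from adjacent-bin differences, which presumes changes are
sparse; instances with segments < 3 bins apart can inflate σ̂ (the
oracle property is therefore stated for ≥3-bin segments, plus isolated
full-amplitude single bins).

**Calling.** c = 2 × mean ratio; expected copy is 2 on autosomes and
sex-dependent on X/Y. |c − expected| ≥ 0.8 ⇒ full integer call
(round(c)); 0.4 < |c − expected| < 0.8 ⇒ mosaic with fraction
f = |c − expected|; ≤ 0.4 ⇒ no call. The 0.4 floor is the clinical
"> 40% mosaic ⇒ not fit for transfer" rule; 0.8 is its symmetric
complement separating mosaic from full dose. The deviation is resolved
to 1% (two decimals) before threshold comparison — mosaic fractions are
reported at integer-percent resolution, and this guard keeps an exactly
40% noiseless signal, which count quantization can render as 0.4004,
on the transferable side of the strict inequality. Minimum reported
segment is 3 bins, or 1 bin at amplitude ≥ 0.8 (1 Mb resolution is a
configurable limit, not a default); a segment covering ≥ 90% of its
chromosome is flagged whole-chromosome. f is capped at 1.0.

## Classification and transfer policy

The expected-imbalance catalogue is the union over both parents of the
zygote-level profiles of every unbalanced viable gamete class,
deduplicated; a carried del/dup enters via the carrier gamete class, so an
inherited microdeletion is "related". A called event is **related** iff a
catalogue entry on the same chromosome has the same sign, reciprocal
overlap ≥ 0.5, and every interior breakpoint of the entry (those > 3 Mb
from chromosome ends and centromere) lies within 5 Mb of a call
breakpoint; otherwise **de novo**. Both knobs are configurable; the rule
is monotone in the tolerance. Band-level breakpoints justify the 5 Mb
default (a band is several Mb wide).

Categories: V if no events; IV (MAC) if events touch ≥ 3 distinct
chromosomes (threshold configurable — the category is never defined
numerically in clinical reports, so 3 is a declared convention), taking
precedence over I–III; otherwise I/II/III by whether the related and de
novo lists are exclusively or jointly populated. Mosaic events above the
40% floor keep their I–IV identity by event origin and additionally block
transfer; mosaic events at or below 40% are below the reporting threshold
and ignored. Transferable ⇔ category V with no blocking mosaic.

## Cohort statistics

Rates are formatted `x.y(n/d)` with one decimal; the informative count is
the denominator for category rates (QC failures are excluded, matching
clinical reporting). Chi-square is Pearson without continuity correction
(scipy, `correction=False`); Fisher's exact is two-sided by hypergeometric
enumeration (scipy); `auto_test` switches to Fisher when any expected 2×2
cell is < 5, mirroring common practice. No multiple-testing adjustment is
applied — comparisons are reported per-contrast. Outcome rates follow the
per-cycle definitions: implantation = gestational sacs per embryo
transferred; clinical pregnancy, live birth and early miscarriage per
transfer cycle.

## Problem sizes used by tests and the acceptance script

Dose-linearity checks run 20 seeded replicates on the reduced genome;
segmental-detection checks run 10 seeded full-genome blastomeres; the
mosaic-policy scan covers 101 noiseless fractions; the end-to-end
category-recovery property uses 200 embryos per group (four groups) on
the full genome at minimal dispersion, with ≥ 95% agreement between
pipeline and truth categories. These sizes were chosen to bound the
Monte-Carlo error of each check well inside its assertion band.

## Known limitations

- Depth-only inference: haploidy, triploidy and other uniform-ploidy
  genomes are invisible to bin-count ratios (no allele-frequency signal).
- Single-bin nullisomy is masked as dropout (see above).
- Whole-arm Robertsonian imbalances are modelled on q-arms; acrocentric
  p-arm dosage is not simulated or called.
- The meiotic model draws gamete classes independently per rearrangement
  and ignores crossover position within translocated segments, chiasma
  interference, and any interchromosomal effect mechanism.
- Clinical outcome rates (pregnancy, live birth) are patient-population
  quantities; the package only tabulates supplied records and cannot
  regenerate them from sequence-level simulation.
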