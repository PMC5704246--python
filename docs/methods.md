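# Methods

## Read assignment

Reads are collapsed to distinct sequences (RNA U normalized to DNA T,
optional exact-prefix 3′-adapter trimming with a configurable minimum
overlap, default 6 nt; reads containing other characters are dropped with a
logged tally). Each distinct sequence is assigned by trying edit tiers in
increasing order and, within a tier, reference categories in the fixed
priority order rRNA, hairpin, tRNA, miscRNA, ncRNA, transposon, transcript,
intron, pseudogene, intergenic. The first category with at least one
sense-strand hit claims the sequence; all hits within the claiming category
are recorded as (gene, start, end), 1-based closed.

Tier semantics are deliberately asymmetric: tier 0 is an exact substring
match; tier 1 allows edit distance ≤ 1 (substitution, insertion or deletion,
found with edlib's infix alignment); tiers 2 and 3 allow Hamming distance
≤ 2 and ≤ 3 (substitutions only, found by sliding-window comparison). The
default analysis path is tier 0 only — the fragment-level analyses are
restricted to perfectly matching reads — with tiers 1–3 opt-in.

Reverse-complement scanning is off by default: the references are
sense-strand transcript sequences. A read hitting several tRNA genes
(isodecoders often share sequence) contributes its full count to each gene's
profile under the default `multi_gene="each"` policy, but only once to
category totals and RPM denominators; `"fractional"` splits the count evenly
instead. The synthetic references are screened so that no two genes share a
15-mer, making the two policies coincide there.

## RPM and the denominator

Species abundance is RPM = count × 10⁶ / (category-assigned reads of the
library). Assignment runs before any length windowing, so tRNA halves and
background reads stay in the denominator and the denominator is independent
of the tRF length window; it is recorded in every output header. The
alternative (raw-read denominator) is available by passing the raw total
instead.

## Regions and tRNA classes

Each CCA-appended tRNA of length L ≥ 52 is partitioned into 5′ = [1, 26],
3′ = [L−25, L] and middle = [27, L−26] (empty at L = 52; shorter genes are
rejected by name). A fragment is assigned to the region covering at least
2/3 of its nucleotides — the comparison is exact rational arithmetic, and
the bound is inclusive — otherwise SPANNING. Disjoint regions cannot both
reach 2/3, which the code asserts.

A tRNA's class is decided in fixed order: NONE without fragments; LOW_RPM
when total fragment rpm is below the threshold (default 50 rpm); RANDOM when
SPANNING mass reaches the random-mass share (default 0.5 — "randomly
fragmented" has no canonical quantitative definition, so it is
operationalized as majority boundary-crossing mass and exposed as a
parameter); otherwise the set of regions each holding at least the minor
share (default 0.2) of total mass yields the label, COMBINATION when two or
more qualify, with an argmax fallback when none does. The rule is invariant
to species order and to joint rescaling of rpm and threshold.

## Cloverleaf coordinates

Dot-bracket structures are parsed into base-pair helices; a canonical
cloverleaf must contain exactly four helices with the acceptor stem
enclosing the D, anticodon and T stems in 5′→3′ order. Fifteen contiguous
segments follow: (1) acceptor 5′ strand, (2) linker, (3) D-stem 5′ strand,
(4) D loop, (5) D-stem 3′ strand, (6) linker, (7) anticodon-stem 5′ strand,
(8) anticodon loop, (9) anticodon-stem 3′ strand, (10) variable loop, (11)
T-stem 5′ strand, (12) T loop, (13) T-stem 3′ strand, (14) acceptor 3′
strand, (15) discriminator + CCA. The map position → (segment, offset) is a
bijection, rendered `offset;segment`. Structures that do not parse (e.g.
degenerate mitochondrial folds missing the D arm) exclude the gene from
structural cleavage mapping only — it remains in all region-based analyses —
so the pipeline reports both the number of genes tested and the number
foldable.

The fragment "cleavage site" is its last aligned nucleotide (5′ of the
scissile bond). Cleavage profiles default to FIVE-region fragments, the
family whose 3′ processing site is at issue; a flag widens them to all
fragments. Both rpm-weighted (default) and count-weighted profiles can be
emitted, since the weighting convention of such plots is ambiguous in
general.

## Differential analysis

Fold changes are max(a, b)/min(a, b) on rpm + pseudocount (default 1 rpm)
with the direction recorded — symmetric by construction, scale-invariant at
pseudocount 0. No significance testing is attempted: the emulated design
pools replicates before sequencing, so replicate variance does not exist and
fabricating p-values would be misleading. Fraction distributions report
per-feature and aggregate rpm shares across mRNP/60S/monosome/polysome.
Ratio concordance computes per-feature stage log2-ratios (same pseudocount)
for Total and each fraction, restricted to features reaching an rpm floor
(default 50, reusing the low-expression cutoff) in Total for at least one
stage, and summarizes agreement as Spearman's ρ against Total; the null
behaviour is established by permutation in the test suite rather than by a
parametric model. When no sequenced Total library exists, a Total column is
derived by pooling each stage's fraction libraries on the count scale
(counts and denominators summed).

## Synthetic study design

The generator emulates the fractionated-embryo study structure at desk
scale; defaults are fixed once and shared by tests and the acceptance
script.

* **Genes.** 111 tRNA genes with canonical cloverleaf geometry: 7-bp
  acceptor stem, 3-bp D stem with 8-nt D loop, 5-bp anticodon stem with 7-nt
  loop (anticodon at positions 32–34), 4–5-nt variable loop, 5-bp T stem
  with 7-nt loop, discriminator, CCA appended (73–74 nt total). The fixed
  5′-side geometry keeps linear 3′-end positions aligned with structural
  addresses across genes (position 26 ↦ `2;7`). Eight non-designated genes
  receive D-arm-less structures, so 103 of 111 genes fold — exercising the
  exclusion path. Stems are complementary by construction; genes share no
  15-mer with each other or with the background references.
* **Classes.** 50 FIVE, 7 MID, 14 THREE, 16 COMBINATION, 20 LOW_RPM, 2
  RANDOM, 2 NONE. Every expressing gene spreads its tRF mass over fragment
  lengths 15–29 with weights 0.251/0.183/0.176 at 28/27/26 nt and the
  remainder uniform — so the expected pooled length distribution equals the
  configured weights regardless of class mix. FIVE genes anchor fragments at
  position 1; MID at 27; THREE at the 3′ end; COMBINATION mixes 5′/3′ parts
  60/40; RANDOM places 70% of mass on boundary-crossing (SPANNING)
  placements found by scanning; LOW_RPM genes get weights yielding ~20
  expected rpm. Gene expression weights are lognormal (σ = 0.8) within the
  FIVE and COMBINATION blocks, fixed small constants elsewhere.
* **Libraries.** Two stages (0–1 h, 7–8 h) × four fractions, 50,000 reads
  each. Per-library block shares are fixed: tRFs 48/9/1.8/1.2% of reads in
  mRNP/60S/monosome/polysome (i.e. an 80/15/3/2 rpm skew), tRNA halves
  (3′ ends 33–40 nt, modal 35) skewed the same way, unmappable reads 4%
  everywhere, background (rRNA/hairpin/transcript/intergenic fragments of
  18–28 nt) filling the rest. Fixed block shares make expected rpm, fraction
  shares and folds exact rather than approximate.
* **Stage effects.** Three designated genes carry expected rpm folds: a
  Pro-AGG gene up 3.7× early, a Gly-GCC gene up 4.6× and a mitochondrial
  Ser gene up 18.9× late. Because RPM is compositional, multiplying one
  species' mass by φ does not produce an rpm fold of φ; a fixed-point
  calibration adjusts the multipliers so the expected rpm fold equals the
  configured value exactly (verified to 10⁻⁶ in the tests). Observed folds
  then deviate only by multinomial sampling noise — a few percent for the
  abundant species at these depths, more (~10%) for the rare mitochondrial
  one.
* **Presets.** `default_scenario` is the headline design above;
  `window_scenario` places exactly 95% of expected tRF mass inside [1, 28]
  (all-FIVE genes, one 50k library with a 50% tRF share) for the 5′-window
  measurement; `small_scenario` (12 genes, 5k reads) keeps unit tests and
  examples fast. A sequencing-error knob (off by default, since the default
  path is exact matching) exists to exercise the edit tiers, and
  `collision_decoys` plants a tRF sequence inside an rRNA record to test
  priority.

What the generator does **not** emulate: sequence-dependent ligation and RT
bias, nucleotide modifications, true isodecoder sequence sharing, gradient
physics, or read quality. Passing recovery tests therefore demonstrates the
correctness of the accounting — assignment, normalization, classification,
coordinate mapping, differential arithmetic — not robustness to those
real-data artifacts.

## Numerical and scale choices

Region comparisons use exact fractions; RPM sums are float with conservation
asserted to float tolerance. Ties in modal-position and argmax reports
resolve to the lower index via pandas `idxmax`. Degenerate inputs are
explicit: empty libraries yield empty tables, zero total mass makes the
5′-window fraction an error, genes under 52 nt are rejected by name, and a
metadata table lacking a stage or fraction skips the differential stage with
a logged reason instead of failing the run. Problem sizes (50,000 reads per
library, 10,000 oracle triples, 2,000-triple unit checks) were chosen so the
full suite runs in well under a minute while keeping 3-standard-error
recovery bands a fraction of a percentage point.

One count discrepancy is reported rather than reconciled: the number of
genes *tested* (all annotated genes) and the number *foldable* (those whose
structure parses as a cloverleaf) are both emitted, since region-based and
structure-based analyses legitimately cover different gene sets.
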