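# Methods

This package re-implements, as a tested pipeline over synthetic inputs, the
computational characterization of the diverged duplicate subfamilies of
bacterial elongation factor G (EFG): differential-conservation typing,
indel-region detection, diagnostic-motif classification, genome-context
clustering, and duplicate-fate analysis.  This note documents the models,
the defaults and why they were chosen, what the synthetic data emulate, and
the numerical decisions a maintainer would want written down.

## Conservation model

A column's conservation is its sequence-logo information content,

    info_bits = log2(20) − H,   H = −Σ p_a log2 p_a,

with frequencies `p_a` over countable residues only: gaps and the ambiguity
codes X/B/Z are excluded from the denominator.  Columns whose gap fraction
exceeds 0.5 are flagged not-callable and never count as conserved.  No
small-sample entropy correction is applied by default (a flag exists): at
the alignment depths this pipeline targets (~114–140 sequences) the bias
term `19/(2 ln2 · n)` ≈ 0.12 bits is far inside the 3-bit margin, and an
uncorrected logo keeps the threshold arithmetic exact.

A position is *conserved* when `info_bits ≥ 3.0` (inclusive).  Between two
subfamily profiles of the same position:

* **type I** — both conserved, both top residues at ≥ 80 %, top residues
  different;
* **type II** — the second subfamily conserved with ≥ 80 %, and its top
  conservation exceeds the first subfamily's by ≥ 25 percentage points
  (checked after type I; precedence type I > type II > shared);
* **shared** — both conserved with the same top residue; otherwise **none**.

All three thresholds are inclusive, and the percentage comparisons are made
on **half-up integer-rounded** values.  Both choices are forced by the
reference percentages the package curates: a position whose top residue
sits at exactly 80 % (e.g. 91/114 = 79.82 %, printing as 80) must pass, and
a difference printing as exactly 25 must pass, while a 76 % position must
fail.  Exact-count embedding plus full-precision comparison would misplace
two boundary positions (79.82 < 80; 24.66 < 25); integer rounding mirrors
the precision at which such conservation tables are reported and reproduces
the expected 5 type I / 7 type II calls.  Full-precision frequencies remain
available on every `ColumnProfile`.

The Kyte–Doolittle hydropathy scale is taken from biopython
(`Bio.SeqUtils.ProtParamData.kd`).  Domain-level conservation is the
percentage of conserved positions inside user-supplied, non-overlapping
1-based intervals; the shipped five-domain layout is illustrative
configuration, as is the piecewise offset map for the alternative residue
numbering (interpolated between curated anchor positions).

## Indel regions

Per-sequence maximal gap runs are clustered into connected components of
column-overlapping runs; a component is an *indel region* when it is
supported by at least 5 sequences (inclusive, configurable).  Support
counts sequences with overlapping — not necessarily identical — gap runs;
identical endpoints upgrade the region to `conserved-length`.  Terminal gap
runs are excluded by default as likely fragment artifacts.  Polarity is
assigned against a reference frame: gaps over reference-mapped columns are
deletions, gaps over unmapped columns insertions; a region straddling the
boundary is split, each part keeping the member blocks that overlap it (a
part may thereby drop below the support threshold; it is reported anyway,
since its parent region passed).  The diagnostic-insertion scanner looks
for inserted runs anchored inside a reference window (switch I by default)
matching a short consensus (KDG) within a mismatch budget (default 1).

## Motif grammar and subfamily rules

Consensus strings use three tiers over all rows (gaps count in the
denominator, so gappy columns read as weak): capitals strictly above 70 %,
lowercase in (60, 70], dash at or below 60.  The band edges are assigned
this way because the capital tier is explicitly strict at 70.

Pattern slots are required (uppercase), required alternatives (`A/B`), weak
(lowercase — scored at half weight, never blocking), or wildcards (`x`).
A window matches when all required slots are satisfied; the score is the
satisfied fraction with wildcards always satisfied.  Because distinct
patterns can both fully match a window (`RAISI` satisfies both `RxxSI` and
`RxxT/SI`), ranked assignment breaks equal scores by *specificity* — the
sum over slots of 1/|choices| (wildcards 1/20, weak slots halved) — so the
more constrained pattern wins; residual exact ties are flagged, never
silently broken.

Subfamily calls apply rules in fixed order: contradiction check (KDG +
str-operon → unresolved with a note), single copy → EFG I, KDG insertion →
spdEFG1, str-operon residence → EFG I, relaxed G2 (matches `xxxSx`, fails
`RGITI`) → EFG II, otherwise unresolved.  Unknown evidence fields skip
their rule.  Phylogenetic placement can override externally; the classifier
only reports the fired rules.

## Genome context

A gene's neighborhood is the set of ortholog-group labels of up to five
genes each side on the same contig (fewer at contig ends), order discarded,
own group excluded.  Orthology labels are inputs.  The distance

    d(A, B) = 1 − |A ∩ B| / max(|A|, |B|)

is a declared design choice: the shared-neighbor count fixes the numerator
but not the normalization, and max-normalization keeps d in [0, 1] while
penalizing truncated contexts symmetrically.  It is a semimetric (symmetric,
zero exactly for equal sets of equal size).  Clustering uses Saitou–Nei
neighbor joining via scikit-bio (negative branch lengths clamped to zero);
the tests check NJ against an exhaustive OLS minimum-evolution search over
all unrooted topologies at n ≤ 6 and against generating topologies of
additive matrices.  str-operon membership requires ≥ 2 of the marker groups
(rpsL, rpsG, tuf) among the neighbors, tolerating local rearrangement.

## Duplicate fate

dN/dS uses Nei–Gojobori (1986) counting: per-codon synonymous site
fractions by exhaustive single-mutation trial, averaged over the two
sequences; pathway-averaged difference counts for multi-hit codons; and
Jukes–Cantor correction `d = −3/4 ln(1 − 4p/3)` of both proportions
(infinite, flagged saturated, at p ≥ 3/4).  Conventions: mutations *to*
stop codons count as non-synonymous in site tallies; mutational pathways
*through* stop codons are excluded from the average (all retained, stop
steps non-synonymous, in the degenerate case where every path hits a stop).
A counting estimator was chosen over ML codon models deliberately: it is
self-contained and exhaustively testable against a brute-force enumeration
oracle, and everything downstream consumes only (dN, dS).

Pairs with dS strictly above 3 are discarded as saturated (dS = 3 exactly
is kept — the rule is a strict inequality).  ω is binned with a neutral
band of (0.8, 1.2), a configurable interpretation of "ω ≪ 1" vs "ω ∼ 1".
Retention models: neutral line dN = dS; sub-functionalization line
dN = θ₁·dS with θ₁ ∈ (0, 1] (default 0.3, illustrative); and a
neo-functionalization mean curve with 5 %/95 % quantile envelope whose
functional form and parameters are **user configuration** — they are not
published values, and the module degrades to the two analytic lines when
absent.  A power-law convenience constructor is provided.  Survival over a
dS-like time proxy is Weibull, `S(t) = exp(−(t/scale)^shape)` (scipy).

Loss accounting takes a rooted species tree (dendropy), a duplication node
and deletion branches below it, validates the leaf presence table against
the deletion set, and reports the percentage of genomes under the
duplication lacking the copy.  Scenario topologies behind any particular
published loss percentage are not bundled; the generators construct
scenarios with a chosen loss fraction instead.

## Synthetic data: what it does and does not emulate

The generators produce exactly the statistical features each stage
consumes, and nothing else:

* **Profile alignments** embed per-column target percentages by largest-
  remainder apportionment (deterministic tie-break), so recovered integer
  percentages equal the targets.  Residual mass tops up listed minor
  residues in order, capped one point below the top residue (so the top
  never flips — naively piling residual on the first minor would overtake a
  42 % top residue with 15 % residual), overflow going to one unlisted
  residue.  Background columns spread mass over five residues with a 30 %
  maximum, safely below both the 40 % cap and the 3-bit line.
* **Indel alignments** place requested gap blocks with chosen support and
  endpoint variability; **neighborhood tables** realize pairwise shared-
  neighbor counts either through a global core (uniform designs) or
  pair-private groups (dict designs; unrealizable requests are rejected);
  **codon pairs** contain exactly the requested single-position synonymous
  (four-fold third positions) and non-synonymous (stop-free first
  positions) changes; **loss scenarios** are random ladder trees with leaf
  deletions hitting a chosen fraction.

None of this is phylogenetically realistic sequence evolution: columns are
i.i.d., rows carry no tree structure, and indels are placed, not evolved.
Passing tests therefore validate the *algorithms and their thresholds*, not
the pipeline's behavior on real alignments with correlated columns,
alignment errors, or rate variation.

## Problem sizes

Default test and analysis runs use the full 114 + 140 × 610 alignment
embedding (sub-second), codon pairs of 5–60 codons, trees of 4–15 leaves,
and exhaustive topology searches at n ≤ 6 (105 topologies) — sizes chosen
so every oracle comparison is exact and the whole suite runs in seconds.

## Known limitations

* Conservation percentages are compared at integer precision by design;
  callers needing full precision should read `ColumnProfile.freqs`.
* Region splitting at polarity boundaries can emit parts below the support
  threshold (documented above).
* The pairwise neighborhood-overlap generator cannot realize designs with
  overlapping shared pools across genome triples; use the uniform-core mode
  for clique designs.
* `ng86_dnds` follows the classic counting conventions; it will differ from
  implementations that keep stop-codon pathways (only) on pairs whose codon
  paths pass through stops.
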