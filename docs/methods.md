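# Methods

## Sequence model and coordinate conventions

All coordinates are 0-based half-open internally; files are read and
written 1-based inclusive (GFF convention).  Upstream regions are reported
on the gene's coding strand with offsets relative to the translation start
(negative = upstream), so sites, TSSs and promoter elements from different
species are directly comparable, and minus-strand genes need no special
cases downstream of extraction.

Upstream windows span up to 300 bp and by default stop at the nearest
upstream coding interval (on either strand).  Scanning inside ORFs would
inflate the false-positive rate of a threshold-at-minimum scan and real
operator sites are intergenic; a flag (`stop_at_coding=False`) disables the
truncation for users who want the fixed window.  Operons are approximated
by a same-strand gap rule (adjacent same-strand genes with intergenic gap
< 100 bp form one unit); only the first-in-operon gene's upstream region is
scanned.  `N` bases are accepted in input and score as background (weight
0) in every PWM context.

## Motif discovery

### Model

ZOOPS (zero-or-one occurrence per sequence): region *r* contains a site
with prior probability γ (initialized 0.8), located uniformly over valid
positions and both strands.  ZOOPS fits the biology — training sets are
assembled from genome context, and some candidate regions genuinely lack a
site.  The background is a 0-order model estimated from the training
regions with complementary bases averaged (q(A)=q(T), q(C)=q(G)); a
strand-asymmetric background would make the likelihood depend on which
strand a region happens to be reported on.

### Geometry grid

Bacterial operators are bound by dimers, so the motif is constrained to one
of three internal symmetries:

| mode | parameters | defaults | modeled columns |
|---|---|---|---|
| palindrome | width *w* | 20–24 bp | all *w* |
| direct repeat | unit *u*, start-to-start period *P* | *u* 7–11, *P* ∈ {21, 32} | two *u*-blocks |
| spaced inverted repeat | unit *u*, spacer *s* | *s* 20–30 | two *u*-blocks |

Periodicity is interpreted start-to-start (two or three DNA helical
turns), so the unmodeled linker is *P − u* bp.  Spacer/linker columns carry
no probability model — they are background, matching the convention of
writing such motifs as `GGGAC-(27)-GTCCC`.

### EM with symmetry projection

The E-step computes per-(position, strand) responsibilities from the
probability ratio of the window under the PWM versus background.  The
M-step re-estimates the PWM from expected counts and projects it onto the
symmetry manifold: palindrome column *i* is tied to the reverse complement
of column *w*−1−*i*, direct-repeat units are tied identical, inverted units
tied as reverse complements.  Averaging tied columns is the constrained
maximum-likelihood estimate (column totals are equal under ZOOPS), so the
EM monotonicity guarantee survives the projection; each tied pair is
normalized by a single shared scalar so the symmetry relation holds
bitwise, not merely to rounding.  No pseudocount is used inside EM (a
Dirichlet prior would trade the exact monotonicity guarantee for
regularization the seeded starts don't need); zero-probability columns are
handled in log space and produce no NaNs.

Convergence: relative log-likelihood change < 1e-6 or 500 iterations.

### Starting points

EM on planted-site data has a narrow basin of attraction; a PWM seeded
from one uniformly random data window frequently converges to a noise
optimum.  Discovery therefore ranks **all** windows by an internal-symmetry
score — the number of tied base pairs that match within the window itself
(self-reverse-complement pairs for palindromes and inverted repeats, unit
identity for tandem repeats).  True sites are internally symmetric up to
the mutation rate while background pairs match at chance, and the score is
strand-neutral.  The top `4 × restarts` windows, plus `2 × restarts` random
windows for diversity, are each advanced one EM step; the `restarts` best
one-step states run to convergence and the best final log-likelihood wins.
This is deterministic given the seed (all randomness flows from one
`SeedSequence`).

### Model selection and the no-motif flag

Each geometry's best run is scored by the mean per-column information
content (bits) of its modeled columns; the argmax geometry is returned,
ties breaking toward the smaller span.  Mean IC rather than raw
log-likelihood makes geometries of different spans comparable and rewards
conserved half-sites rather than long weakly-constrained windows.

A discovered motif is flagged low-confidence when its mean IC falls below
`DEFAULT_MIN_INFORMATION` (0.81 bits/column).  This value is the 95th
percentile of the best motif's mean IC over 200 null training sets
(20 regions × 300 bp of i.i.d. GC-0.35 background, palindrome grid,
5 restarts), computed by `calibrate_null_threshold`; users fitting very
different problem sizes should recalibrate with that function, since EM
extracts more apparent information from fewer regions.

## PWM scoring and regulon assembly

Site weights are log₂ odds with a background-distributed pseudocount
(α = 1, Laplace-style — the standard choice in the regulon-reconstruction
literature): `w(b,i) = log₂((n(b,i)+α·q(b)) / ((N+α)·q(b)))`.  Scores are
in bits; the threshold θ is the minimum training-site score, which makes
training recall exactly 100% and is asserted, not assumed.  For palindromic
motifs the tied columns give both strands the same score at every position,
so only the canonical plus-strand hit is reported (no double counting).
All above-threshold positions are kept; regulon summaries report the best
hit per operon.

The consistency filter retains an operon iff hits occur upstream of its
orthologs in at least `max(quorum_min=2, ceil(quorum_fraction=0.5 ×
n_eligible))` species, where eligible species carry both the TF ortholog
and the operon ortholog.  The quorum is configurable; the default is
conservative (an absolute floor of two genomes plus a majority rule).
With a single scanned genome no cross-genome evidence exists, so all hits
are returned and the regulon flagged `unverified`.

## Promoters and mechanism calls

σ^A promoter geometry: −10 (TATAAT) ending 4–9 bp upstream of the TSS,
−35 (TTGACA) separated by a 15–19 bp spacer.  The best call minimizes
total mismatches, ties breaking toward the canonical geometry (−10 ending
7 bp before the TSS, 17 bp spacer).  Candidates need ≤ 2 mismatches per
hexamer and ≤ 4 total: on random sequence the best candidate at these
geometries almost always reaches 5+ total mismatches, so ≤ 4 separates
real promoters from background (null-simulation calibration, 95th
percentile rule).

Mechanism classification is a pure function of intervals: repressor if the
site overlaps the 5′UTR `[tss, 0)` or either promoter hexamer; activator
if the site lies entirely upstream of the −35 element (or of TSS−35 bp
when no promoter was located); ambiguous otherwise; unknown without a TSS.
Dual-mode regulators are real (the same TF can repress one operon and
activate another), so calls are reported per-target; the pipeline's
per-TF aggregate is the unanimous call or `ambiguous`.

The footprint report right-aligns each species' upstream region at the
translation start (anchor alignment, no gapped MSA) and marks sites,
promoter hexamers and the TSS in a markup line, so conserved sites line up
in a column band.

## Expression overlay

Input is a gene × condition matrix of replicate-averaged log₂ expression
values; fold changes are differences of stored values.  DE uses a strict
inequality (log₂FC > 2.0) and the moderate band is the closed interval
[1.5, 2.0], so a fold change of exactly 2.0 counts as moderate — the two
sets partition the genes at ≥ 1.5.  The cross-tab cell (r, c) counts genes
up on condition r versus c with a parenthetical regulon-member subcount,
and the union of upregulated genes across all pairs is reported.  A
regulon member is concordant when it is DE for at least one (inducing,
non-inducing) pair.  No count modeling or significance filtering is done
here — the input is expected to be already normalized and averaged.

## Synthetic data generator

The generator emulates the statistical structure of a clade-scale
comparative study, not any particular dataset:

- **Background** i.i.d. with GC = 0.35 (thermophile-like AT-rich
  intergenic sequence).
- **Divergence** between species is independent per-base resampling from
  the background at rate 0.3, with **no indels**, so site offsets stay
  comparable across species and the anchor-aligned footprint display is
  exact.  Planted sites mutate at the lower rate 0.1/base (substitutions
  to a different base), giving the conservation contrast footprinting
  exploits.
- **Design**: 8 species, 10 target operons (one planted site each —
  ZOOPS-consistent), 200 orthologous decoy genes with unconserved
  background upstream regions, 300-bp regions.
- **Toy genomes** concatenate [upstream region][placeholder ORF] units on
  alternating strands with separators sized so extraction recovers every
  region exactly; round-trips through the FASTA/TSV readers are tested
  coordinate-for-coordinate.
- **TSSs** are drawn log-normally with median UTR 50 bp (clipped to
  15–250), and each target is assigned a repressor geometry (site inside
  the 5′UTR) or an activator geometry (site wholly upstream of a planted
  canonical promoter) in configurable proportions.
- **Expression**: baseline log₂ values ~ Normal(8, 1) per gene; regulon
  members gain effect 3.0 on their inducing substrate (round-robin over
  cellulose, cellobiose, glucose, xylan, xylose); Normal(0, 0.3) noise per
  cell.  With these values P(member fold change > 2) ≈ 0.99 per pair.

What passing tests on this generator do **not** show: robustness to
indels and alignment error, to operon-prediction mistakes, to non-i.i.d.
genomic background (repeats, skew), or to motifs that violate the assumed
dimer symmetry.  The generator is the study-design model, not a genome
simulator.

## Problem sizes

The shipped benchmarks run discovery on 15–20 regions × 300 bp with
10–20 restarts per geometry, the recovery benchmark uses 50 training sets,
and the end-to-end benchmark uses the full generator defaults (8 species ×
210 ortholog groups).  These sizes keep the whole suite and the benchmark
script in the minutes range on a single CPU while leaving every measured
quantity comfortably away from its acceptance margin.

## Known limitations

- No Gibbs sampling alternative to EM; a pathological multi-modal
  posterior could in principle trap all restarts, though the
  symmetry-ranked seeding makes this rare in practice.
- Model selection by mean IC is a pragmatic stand-in for a principled
  complexity-penalized criterion (BIC across geometries with different
  free-parameter counts).
- The consistency quorum treats species as independent; phylogenetic
  correlation between close sister genomes is not modeled.
- No genome-wide FDR for scan hits; the threshold-at-minimum rule is
  deliberately recall-oriented and relies on the consistency filter for
  precision.
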