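# Methods

`multisv` implements a multi-platform somatic structural-variant (SV)
integration pipeline of the kind used to build consensus call sets for
tumor/normal reference samples, together with a Hi-C contact-matrix
rearrangement detector and the synthetic data needed to exercise both at desk
scale.  This note records the models, the parameters that matter, the
numerical choices, and what the synthetic experiments do and do not show.

## Windowed merging and reciprocal-size clustering

Calls are split by size class — 50–100 bp, 101–500 bp, 501 bp–1 kb,
1–30 kb, and >30 kb together with all translocations — and merged per class
with class-specific breakpoint windows of 50, 100, 500, 1000, and 10 000 bp
(upper-inclusive boundaries: a 100 bp call belongs to the first class).  Two
calls are linkable when they share a type, their two breakends lie on the
same chromosomes, and both breakend offsets are within the window; insertions
compare by insertion-point distance plus ≥50 % size similarity because their
END coordinate is degenerate.  Merged groups are the connected components of
this relation, mirroring the behaviour of window-based merging tools: two
members of one group may individually violate the pairwise rule through a
chain of intermediates, which is deliberate and tested.

Somatic subtraction is per (platform, tool, replicate) pair: a tumor cluster
is dropped when a cluster from the matched normal is linkable to its
representative at the same window.  After cross-tool merging, clusters of the
same type are further clustered when their reciprocal size similarity
min(s₁,s₂)/max(s₁,s₂) exceeds 0.5 (strict) and their breakends are within the
window of the smaller member's size class (translocations: 10 kb, no size
test).  The representative of a cluster is the member linkable to the most
other members, ties broken by position then identifier; outputs are always
position-sorted so every stage is order-invariant and deterministic.

A known limitation of per-pair subtraction is germline leakage: a germline
variant detected in a tumor call set whose matched normal missed it survives
subtraction, and with many replicates such leaks recur often enough to pass
the replication filters.  This is the dominant false-positive mode in the
synthetic study (high-confidence precision ≈ 0.5 at the default
sensitivities) and is a property of the study design being modelled, not of
the implementation; recall of true somatic events is the quantity the
selection rules are designed to protect.

## Frequencies, consensus score, and call-set selection

The replicate census records how many replicate call sets each
(platform, tool) contributed; the same caller run on two platforms counts as
two tools.  For a merged SV, the per-tool frequency is the number of distinct
replicates of that tool containing the SV divided by the tool's replicate
count; the per-platform frequency divides supporting (tool, replicate) call
sets by the platform total (e.g. 44 for a four-tool, eleven-replicate
short-read platform); the consensus score is the sum of per-tool frequencies.
Denominators always come from the census, never from constants, so any
synthetic design works unchanged.

Selection is a monotone chain.  The initial set requires support in at least
two replicate call sets, removes blacklist overlaps, and keeps primary
chromosomes only.  The high-confidence set additionally requires at least two
platforms and at least two tools, and removes calls in configured
normal-LOH regions.  Before scoring, linked-read deletions below 20 kb are
excluded as a platform-specific reliability rule.  Whether two replicates of
a *single* tool suffice for the initial set is ambiguous in the underlying
design; this implementation says yes (the rule is replicate-based).

## Hi-C quadrant statistic

Read pairs with both MAPQ strictly above 20 are binned at width
w₀ = 50 kb into a symmetric count matrix N. For a bin pair (i, j), N⁺ sums
the north-east and south-west quadrants up to a range R and N⁻ the
north-west and south-east quadrants; each sum includes the center cell in
both of its two terms, exactly as the defining formulas read (the double
count cancels in the numerator).  The two z-scores are

    Z⁺ = (N⁺ − N⁻)/√N⁻        Z⁻ = (N⁻ − N⁺)/√N⁺

with zero denominators floored at 1 to keep the scores finite and monotone.
R is not prescribed anywhere; the default R = 10 bins spans 500 kb at w₀ and
sits comfortably inside the ±2 Mb refinement window.

Candidates are bin pairs where S = max(Z⁺, Z⁻) exceeds a threshold and is a
local maximum within 3 bins (tied plateaus yield one representative).  Three
calibration guards, motivated by systematic biases of the raw-sum statistic
at desk-scale depths, are applied:

* **Per-block evaluation.** Quadrant fields are computed within each
  chromosome-pair block.  On a concatenated genome-wide matrix, windows that
  cross a chromosome boundary absorb the neighbouring chromosome's
  near-diagonal mass and produce deterministic false contrasts.
* **Diagonal band.** Intra-chromosomal pairs within 3R bins of the diagonal
  are suppressed (not the naive R).  The NW/SE quadrants extend 2R bins
  along the distance axis, and the convexity of the contact decay
  λ(d) = depth/(1 + d/w) inflates the expected Z⁻ deterministically — to
  ≈8–10 at offsets of 11–16 bins and below 1 only beyond ≈3R.  The practical
  consequence is that intra-chromosomal events below ≈1.5 Mb (at w₀) are
  invisible to this detector, consistent with proximity ligation only
  resolving megabase-scale rearrangements.
* **Corner skip.** Positions where *both* quadrant axes truncate at block
  edges are skipped: the N⁺/N⁻ areas become asymmetric there (e.g. 122
  versus 22 cells at a corner) and the raw-sum contrast is biased by
  construction.  Single-edge truncation is area-balanced and kept.

The deterministic candidate filter replaces an upstream learned classifier
for which no architecture or weights are available.  It keeps candidates
with S ≥ 6, supporting mass max(N⁺, N⁻) ≥ 50 read pairs, and a balanced
two-sample contrast |N⁺ − N⁻|/√(N⁺ + N⁻) ≥ 6.  The balanced term matters:
when the two quadrant means are comparable, Z⁺ > 6 corresponds to only
≈4.2 Gaussian standard deviations (the denominator uses N⁻ alone), and a
toy genome already carries ~10⁴ effectively independent tests.  With these
defaults the detector reports a median of zero candidates on pure-background
matrices at depth 5 while localizing ≥90 % of implanted translocations to
within one bin.

**Breakpoint refinement** cross-correlates the contact submatrix within
±2 Mb of a candidate with two kernels decaying as exp(−(|dx|+|dy|)/decay),
one supported on the NE/SW quadrants and one on NW/SE; the larger of the two
correlation maxima gives the refined breakpoint at the bin resolution of the
matrix used (ties break toward the NE/SW kernel, then smallest coordinates).
The kernel decay defaults to 5 bins' worth of base pairs.  Refinement may be
run on a finer-binned matrix than detection; this is how sub-bin accuracy is
obtained in the synthetic experiments (50 kb detection, 10 kb refinement).
The kernels assume a two-sided (reciprocal-type) junction; on a strictly
one-sided signal the argmax drifts toward the block interior, so one-sided
junctions refine less sharply.

**Event classification** measures mean counts in the four R-bin quadrant
windows around the refined breakpoint pair, excluding the breakpoint
row/column itself (junction templates fill their quadrant up to the corner,
and boundary cells would leak into neighbouring windows).  The background is
the median cell count in a 2R-wide frame around the windows, falling back to
the frame mean when the median is zero (sparse regimes); for
intra-chromosomal junctions each quadrant is compared against frame cells
from its own diagonal-offset band, because contact decay makes a single
global background biased.  A quadrant is elevated when its mean exceeds
θ = 2.5 times its background — the geometric midpoint between background
(1×) and the canonical elevation (6× at the default signal factor), which
equalizes the miss and false-call margins on the log scale.  The decision
table is a documented reconstruction: inter-chromosomal junctions with one
elevated quadrant are non-reciprocal translocations, with two diagonally
opposite quadrants reciprocal translocations; intra-chromosomal junctions
with only the away-from-diagonal quadrant elevated are deletions, with the
two on-diagonal ("butterfly") quadrants inversions; all four elevated is a
segmental duplication; anything else is reported as unclassified.

## Orthogonal-validation matching

Matching against an independent technology (optical mapping) uses its
published clustering criteria: sized types require both calls above the
500 bp resolution floor, >50 % reciprocal size similarity, and both
breakends within 10 kb; translocations only require breakends within 50 kb,
orientation ignored.  Assignment is greedy one-to-one by ascending breakend
distance (the maximum of the two breakend offsets), which is symmetric in
expectation and deterministic given input order.  Replicate consensus keeps
calls reproduced in ≥2 of the replicate call sets (clusters under the same
predicate) and drops clusters matching any normal-sample call.  For
evaluation against simulated truth the same rules are reused with the size
floor lowered to the 50 bp SV definition, since the 500 bp floor reflects
the validation platform, not the variants.

## Synthetic data

The toy genome is three 20 Mb chromosomes with 2 % of the sequence
blacklisted in 100 kb tiles.  The truth set places non-overlapping events
outside the blacklist with log-uniform sizes per type (deletions and
inversions 50 bp–100 kb, duplications 500 bp–200 kb, insertions
50 bp–10 kb); default composition is 152 somatic events (60 DEL, 20 DUP,
45 INS, 12 INV, 12 TRA, 3 complex breakend records) and roughly twice as
many germline events, echoing the type mix of published tumor consensus
sets at about 1/10 scale.  Translocations are reciprocal with probability
0.5.

Caller emulation draws each (platform, tool, replicate, sample) call set
independently: a truth SV is detected with the platform's type- and
size-dependent sensitivity, breakpoints receive Gaussian jitter (15 bp for
short reads up to 25 kb for proximity ligation), sizes multiplicative noise
(5 %), and false positives arrive as a Poisson process per megabase.  The
default profiles encode qualitative platform behaviour — long reads most
sensitive overall and to insertions, short reads strong on sub-30 kb
deletions but nearly blind to insertions, linked reads reliable only for
large deletions, proximity ligation only above 1 Mb — as configurable
simulation parameters, not measured values.  Emitted records carry their
truth identifier in a reserved INFO key so evaluation can compute exact
recall; the pipeline itself never reads it.  What passing tests show is that
the integration logic is correct under these statistical assumptions; they
say nothing about real caller error modes (alignment artefacts, systematic
breakpoint shifts, coverage waviness), which the generator does not model.

Hi-C backgrounds are Poisson with intra-chromosomal intensity
λ(d) = depth/(1 + d/w) at bin distance d and a constant
0.1 × depth between chromosomes; the default depth of 5 expected pairs per
near-diagonal bin pair keeps a full scan under a second.  Each junction adds
its canonical quadrant pattern (deletion: the away quadrant; inversion: the
butterfly pair; duplication: all four; translocations: one or two opposite
quadrants) at signal_factor × local background over a 10-bin extent, and
matrices are exactly symmetric and bit-reproducible from the seed.

The purity titration models a somatic SV's supporting-read count as Poisson
with mean depth × purity × het_fraction × capture_eff and calls it detected
at ≥ min_support reads; germline events use purity 1.  Defaults
(het_fraction 0.5, capture_eff 0.3, min_support 3, depth grid
10–300×) put the full-purity mean at 15 supporting reads at 100×, which
places the detection cliff below 20 % purity — at 100× the mean crosses the
support threshold between 20 % and 5 % purity, so recall collapses there
while barely moving between 100 % and 50 %.  One latent uniform per SV is
shared across the whole purity × depth grid and converted to a count by the
Poisson inverse CDF: marginally every draw is exactly Poisson, and the
coupling mirrors a real titration series (the same library diluted), making
per-seed recall exactly monotone in the detection mean rather than
monotone only in expectation.

## Problem sizes and determinism

The shipped experiments use the 3×20 Mb genome, ~450 truth events, 42
emulated call sets, 1200-bin contact matrices (20 seeds for detection and
refinement, 50 for the null), and a 10-seed purity grid; the full test suite
runs in about a minute and the end-to-end demo in well under one.  Every
generator and every pipeline stage is deterministic given (inputs, config,
seed); outputs contain no timestamps, so reruns are byte-identical — which
is itself an acceptance test.

## Known limitations

* Insertions are compared by position and length only; no sequence-resolved
  comparison or micro-homology analysis.
* The merge step is transitive, so clusters can span more than one window
  width in dense regions.
* The Hi-C detector uses raw counts with the calibration guards above;
  explicit distance normalization of intra-chromosomal counts is a plausible
  alternative that was not adopted.
* Per-pair somatic subtraction leaks recurrently-missed germline variants
  (see above); a panel-of-normals stage would be the standard remedy and is
  out of scope.
* The CNN-based candidate classifier of the original detector is replaced by
  the deterministic score/mass/balance filter; no attempt is made to learn
  from labelled junctions.
* Manual curation of the final call set is not modelled.
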