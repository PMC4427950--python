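# Methods

`omscaffold` re-implements, as an open toolkit, the optical-mapping (OM)
super-scaffolding workflow used to lift a short-read bird genome assembly
to chromosome scale: evaluate restriction enzymes against the draft,
collect (here: simulate) single-molecule restriction maps, iteratively
extend in silico scaffold maps by map-to-map alignment, join scaffolds
into super-scaffolds, and anchor super-scaffolds to chromosomes with FISH
markers. This note records the models, the parameters that matter, and
the design decisions taken where the workflow's published description
leaves the mechanism open.

## Restriction maps and in silico digestion

A restriction map (Rmap) is an ordered list of fragment lengths in kb.
Maps are digested from sequence by exact recognition-site matching
(ambiguity codes unsupported; a site containing N never matches;
non-palindromic sites are scanned on both strands). Cut coordinates are
`site_start + cut_offset`; coordinates are held in exact base counts
internally and converted to kb for map objects. N runs contribute their
nominal length to the enclosing fragment: assembly gap sizes are length
estimates and real molecules span the actual sequence, so a gap is not a
cut point. Scaffold termini bound the terminal fragments; a map with *k*
cuts has *k* + 1 fragments.

Enzyme evaluation pools all scaffolds' fragments and reports the
usable-fragment percentages (5–20, 6–12, 6–15 kb windows), the count of
fragments > 100 kb, the average fragment size (total length / fragment
count) and the maximum. "Usable %" is computed by fragment count; a
by-mass variant (`by="mass"`) is provided as a sensitivity check because
the two can diverge when small fragments dominate the count.

## Molecule simulation

The simulator draws molecule lengths from a lognormal distribution
(strictly positive and right-skewed, matching the long upper tail of
real mapping runs), truncated below at the instrument's minimum reported
size. Defaults: mean 286.96 kb, sd 120 kb, minimum 150 kb, retention
filter 250 kb, coverage target 500× (total retained molecule length /
genome length). With these defaults the retained (≥ 250 kb) subset has a
mean of ≈ 368 kb, matching the behaviour of production OM runs. The
source map is chosen proportional to length, the start uniformly, the
strand uniformly; the true sub-map is extracted with terminal fragments
truncated at the molecule ends.

The observation model applies, in order: missed cuts (each true cut kept
with probability `p_digest`, default 0.8), false cuts (Poisson along the
molecule, default 0.005/kb), multiplicative Gaussian sizing error per
fragment (CV default 0.05, floored at 0.1 kb), and a desorption limit
(fragments below 1.2 kb merge into the following fragment, the last
merging leftward). Total length changes only through sizing error.
Chimeric molecules are not simulated. Every simulated molecule carries
its origin, start and strand for truth-tracked evaluation; the seed is
mandatory.

## Synthetic genomes

A uniform random sequence fixes the expected site spacing at 4^6 ≈ 4.1 kb
for a 6-cutter — denser than an avian genome digested with a well-chosen
enzyme (~10 kb average). The generator therefore builds site-free
sequence and implants recognition sites at exponentially distributed
spacings (Poisson process, mean 10 kb by default), then repairs any
accidental sites created at junctions. A chromosome can be split into
scaffolds separated by 5–50 kb of dropped sequence (what a short-read
assembly fails to reconstruct), each scaffold independently
reverse-complemented with probability 0.5 and dotted with short N runs.
The truth (order, orientations, gap sizes) is recorded.

What this emulates — and what it does not: fragment-size statistics,
coverage, and the four OM noise channels are modelled; fluorescence-level
artifacts, chimeric molecules, heterozygosity and repeat-induced
ambiguity are not. Passing the truth-tracked tests therefore shows the
algorithmic chain is correct and robust to the modelled noise, not that
a real optical-mapping instrument run would behave identically.

## Overlap alignment of maps

Two maps of one region differ by missed cuts, false cuts and sizing
error. An alignment is a chain of blocks; a block matching *t* fragments
(summed length *x*) against *s* fragments (summed length *y*) scores

    c_match − (x − y)² / (v_size · (x + y)) − c_cut · ((t − 1) + (s − 1))

with defaults c_match = 1, v_size = 0.25 kb, c_cut = 1, at most delta = 4
fragments per side per block. The sizing term is χ²-like because optical
fragment-length variance grows roughly linearly with fragment size.

Alignment is overlap (semi-global): one terminal fragment on each end
truncates freely (molecules start and end mid-fragment), and chain ends
beyond that pay a soft end-gap cost (`c_end_skip`, default 0.5 per
fragment, counted on the map with the smaller leftover — the other map's
leftover is legitimate overhang). Soft ends were chosen over hard
end-reaching because consensus extensions have ragged, low-confidence
tips; a hard rule makes every chain through a long extension pay for tip
junk in full, while the soft cost keeps overlap semantics (skipping a
whole unrelated map costs far more than the significance threshold).
Both orientations of the second map are tried. Score ties prefer the
longest consumed chain, then fewer blocks, then the smaller start — the
maximal-overlap decomposition is the canonical one.

Significance is a fixed threshold: score ≥ 8 and ≥ 5 consumed reference
fragments. An optional fragment-permutation null (1000 shuffles,
empirical rank) is provided for calibrating these numbers. The DP is
exact under the block bound (validated against exhaustive enumeration)
and runs in a compiled kernel; the chain table stores the best chain
ending in a block separately from the restart potential so that an
all-negative best chain is still recovered.

## Iterative seed extension

Molecules aligned significantly to a seed map and overhanging one of its
ends carry site information beyond the scaffold boundary. Per side:

1. **Projection.** Overhang cuts are projected into seed coordinates.
   The projection shift is a median over the outermost matched pairs at
   *real* map cuts — the map termini are mid-fragment, and the DP's
   forced end-matches there would bias every projection. Each projected
   cut carries a positional uncertainty: the sizing CV times the
   root-sum-square of the molecule fragments between anchor and cut.
2. **Clustering.** Uncertainty-aware single linkage (link tolerance
   `max(1.5 kb, quadrature sum of the two sds)`), then density-valley
   splitting with per-point bandwidths: sites a few kb apart chain-merge
   under plain single linkage, and an adaptive kernel density profile
   separates the modes. A cluster holding more projections than spanning
   molecules must contain several true cuts and is bisected at its
   weakest interior density point. Consensus positions are
   inverse-variance weighted means; support is the cluster size.
3. **Trimming.** Scanning outward, a cut is kept if its support reaches
   both `min_cov` (3 molecules) and 35% of the local spanning depth (a
   real site is seen by most spanning molecules at 80% digestion
   efficiency; scatter satellites and co-located false cuts are not).
   The scan stops where spanning depth itself falls below `min_cov` —
   the discarded low-coverage fringe — or at the per-iteration cap.
4. **Polish.** Every 1:1-matched pair of adjacent map cuts in any
   significant alignment measures that consensus fragment directly.
   Each round, extension fragment lengths are replaced by the mean of
   their measurements and positions rebuilt cumulatively outward from
   the exact in silico core cuts. Without this step, projection drift
   compounds across iterations into multi-kb positional error that
   destroys downstream map-to-map alignment scores; with it, positional
   error stays near the per-fragment sizing noise.

The per-iteration extension cap is 60 kb per side: single-anchor
projection scatter (≈ CV·√(mean_frag·distance)) crosses the 1.5 kb
cluster tolerance near that distance, and growth compounds across the
four iterations anyway since each round re-anchors at the new end.
Larger caps were measured to *reduce* end-to-end adjacency recovery
(junk-dominated far fields). Four iterations are the default; molecules
are re-recruited from scratch each round, only retained (≥ 250 kb)
molecules participate, and a molecule whose alignment is confined to the
exact core is dropped from later rounds (the map only grows outward).
The core's cut pattern is never modified.

## Joining and conflict resolution

Extended maps are overlap-aligned pairwise; a significant alignment that
involves at least one extension fragment is a join candidate, recording
which ends meet, the relative orientation, and the signed gap between
the two seed cores in the shared frame (negative when the cores
overlap). Conflicts are resolved greedily by descending score (ties:
smaller |gap|, then lexicographic) under end-exclusivity and acyclicity,
yielding simple paths; the greedy result equals an exhaustive
subset-search oracle on small instances. Paths are read from the
lexicographically smaller terminus; a member is '+' when the path enters
its left end.

Sequence emission inserts either a constant 600 N spacer (default — map
gap estimates carry enough uncertainty that a recognizable constant
simplifies downstream analysis) or the estimated gap rounded to bases
and floored at 100 N; negative gaps are floored too, never trimming
sequence, because map evidence cannot adjudicate bases. AGP v2.1 is
written alongside (component W lines; N gap lines with gap type
`scaffold`, linkage `yes`, evidence `map`) and reconstructs the FASTA
exactly.

## FISH anchoring

Markers lift from scaffold to super-scaffold coordinates through the AGP
layout. Super-scaffolds are ordered by the median rank of their markers
(robust to one mislocalized probe) and oriented by the sign of the
rank-versus-position trend; single-marker or tied cases default to '+'
and are flagged low-confidence rather than dropped. Markers violating
the final monotone order (complement of a longest increasing
subsequence over rank, taken along the final coordinate) are reported as
conflicts, never silently removed. Unanchored super-scaffolds are kept
as "unplaced". The pseudo-chromosome concatenates oriented
super-scaffolds with the constant 600 N gap; member sequence is never
altered.

## Numerical and degenerate-input choices

Nx statistics sort descending with input-order tie-breaking and take the
length where the cumulative sum first reaches the threshold; the
count-to-90% statistic uses the same order and counts the boundary
scaffold. Cuts landing exactly on a sequence end are dropped so all
fragments are positive. Rmap files round fragments to 3 decimals (1 bp);
in-memory objects are exact. All randomness flows through explicitly
seeded NumPy generators; identical seeds give byte-identical outputs.

## Problem sizes used in the tests

The truth-tracked end-to-end evaluation uses a 10 Mb chromosome split
into 20 scaffolds, 50× retained molecule coverage and the default noise
model; unit and property suites use 1.5–2 Mb genomes and reduced
coverage. The alignment DP is checked against exhaustive enumeration on
500 random pairs with ≤ 6 fragments.

## Known limitations

* Recruitment uses a fixed score threshold (8). In locally
  fragment-sparse regions (mean fragment ≳ 20 kb) a single molecule
  cannot reach it — with ~n cuts in the overlap the expected score is
  ≈ 0.36 n under default noise — so extension stalls on such a flank and
  joins whose evidence lies in a sparse patch can stay below threshold.
  On the standard end-to-end workload this costs roughly one to two of
  twenty adjacencies; the remainder are recovered with zero false
  joins. A length-calibrated or permutation-calibrated threshold is the
  natural extension point.
* Gap estimates inherit consensus positional error (±1–2 kb).
* No chimera handling, no assembly-error breaking of input scaffolds,
  and no hybrid evidence; these are explicit non-goals.
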