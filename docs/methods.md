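# Methods

This note documents the models and procedures ragscan implements, the
parameters that matter, the generative model behind the synthetic data, and
the numerical conventions chosen where a convention had to be fixed.

## Coordinates and file dialects

All internal coordinates are 0-based with half-open intervals. BED and
bedGraph files follow their standards (0-based half-open); the project
junction-table TSV stores 1-based positions and is converted on read/write.
Germline (unjoined bait-side) reads carry no coordinates and are stored as a
count only: every downstream rule uses their total, never their identity.
Parsers reject malformed input with the offending line number rather than
repairing it.

## Cryptic-RSS analysis

**Scoring.** A recombination signal sequence is modelled as heptamer
`CACAGTG` + 12- or 23-bp spacer + nonamer `ACAAAAACC`. A window is scored
only if its first three bases are exactly `CAC` (the minimal cleavage
signal); the mismatch count is the Hamming distance of heptamer positions 4–7
to `AGTG` plus the nonamer to `ACAAAAACC` — 13 compared positions. Both
spacer lengths are always evaluated and the smaller count kept, ties broken
toward 12 (no tie convention is standard; one had to be fixed).

**Cleavage coordinate.** RAG cleaves between coding flank and heptamer, so
the cleavage coordinate is defined as the first base of the heptamer read in
site orientation (the base adjacent to the coding flank). For a site on the
minus strand this is the *rightmost* base of the heptamer footprint in
forward coordinates.

**Elimination of unannotated strong RSSs.** Off-target junction sets are
skewed by unannotated near-consensus sites that behave as bona fide RSSs.
Sites with ≤ 4 mismatches (default, configurable) found by the genome scanner
but absent from the annotated catalog are used to *remove* junctions before
cryptic analysis. Removal happens at junction level before collapsing (the
conservative reading; removing whole collapsed peaks afterwards is equivalent
for all planted-truth tests and can be obtained by filtering peaks on
position).

**On-target assignment.** A junction is on-target when it lies within a
tolerance (default 50 bp) of an annotated RSS cleavage site with matching
prey orientation. The tolerance absorbs coding-end resection; the upstream
alignment pipeline's exact rule is not part of this package, so it is a
parameter.

**Collapsing.** Coding ends are processed and junctions spread several bases
from the cleavage site, so cryptic junctions within 15 bp (default) of a CAC
cleavage site of matching orientation are collapsed onto that site; nearest
site wins, exact ties go to the leftmost coordinate, and junctions matching
no site remain as unassigned singletons. Counts are conserved by
construction.

**Orientation.** Deletional = prey convergent (opposite strand) with the
bait RSS; inversional = same orientation. The rule is binary on orientation:
divergent prey (facing away) classify as deletional with the convergent
ones. Per-region percentages are computed per repeat and summarised as
mean ± s.e.m. (sample sd / √n; 0 for one repeat); a region with no junctions
is flagged empty rather than reported as 0/0.

## Usage quantification

Down-sampling treats junction records and germline pseudo-reads as one urn
sampled uniformly without replacement to the target total (default 500,000),
so the retained junction count is hypergeometric and relative usage is
unbiased. Libraries smaller than the target are an error unless explicitly
passed through. Relative usage divides each segment's count by the total
on-target count after exclusion of unassigned junctions (the default; the
alternative ordering is a caller choice since both totals are returned).

Pearson r uses the direct product-moment formula with a two-sided p from
*t* = r·√((n−2)/(1−r²)) on n−2 degrees of freedom (the parametric form, no
permutation); exact identity/negation of the centred vectors short-circuits
to r = ±1 to avoid float rounding at the boundary. Welch's test uses the
unpaired unequal-variance statistic with Welch–Satterthwaite degrees of
freedom (scipy's implementation; an independent direct-formula oracle checks
it in the tests). Binned profiles divide the region into n equal half-open
bins (the last absorbs the remainder) and take the per-repeat **maximum**
per bin, summarised as mean ± s.e.m. across repeats.

## 3C peak calling

3C junction signal is discrete at restriction sites, so the caller works on
per-site counts:

1. each junction goes to its nearest CATG site if ≤ 10 bp away (ties to the
   leftmost site), otherwise it is discarded;
2. junctions in the bait self-ligation exclusion interval are removed (they
   measure circularization, not interaction), the analysis region is applied,
   and every library in the comparison set is down-sampled without
   replacement to the smallest library's retained total, making the set
   directly comparable;
3. only signal-bearing sites (count ≥ 1) are tested; λ at each tested site is
   the moving median of counts over a 101-site window (one centre, 50 per
   side, truncated at the edges). The median of signal-bearing counts is ≥ 1
   and deliberately *over*-estimates the local background, which is what
   makes the Poisson test conservative;
4. raw p = P(X ≥ k) for X ~ Poisson(λ) (upper tail, ≥ not >, the standard
   enrichment convention); Bonferroni m = number of tested sites in the
   region of that library (junctions are region-restricted first, so
   per-region correction is the coherent scope);
5. summits at adjusted p < 0.05 are extended outward over tested sites to the
   first site that is a raw-p local maximum (strictly greater than both
   tested-site neighbours; at the array boundary only the inner neighbour)
   with raw p ≥ 0.05. Stop sites are included in the span; a walk reaching
   the array end stops at the last tested site, so the output is always
   bounded. Overlapping regions merge, keeping the lowest-raw-p summit;
6. regions across 2–5 repeats merge by overlap; support = number of distinct
   repeats contributing; kept iff support is a strict majority (≥ 2 of 2–3,
   ≥ 3 of 4–5), reporting the best summit over contributing repeats.

Numerical conventions: the median over an even number of sites (possible
only in truncated edge windows) takes the lower-middle value, keeping λ
integral and conservative; peak spans are `[leftmost stop site, rightmost
stop site + 1)`.

Calibration, computed by the test suite and the acceptance script on
homogeneous Poisson(20) backgrounds over 5,000 sites: ≤ 10 % of replicates
produce any summit (measured ≈ 6–9 % across seeds — Bonferroni controls the
family-wise rate at 5 % and Poisson discreteness adds slack in both
directions), and planted 8× anchors are recovered at their exact site in
essentially all replicates with ≪ 1 spurious peak per replicate.

## Peak annotation

Each robust peak ± 1 kb (clipped at chromosome ends) is annotated:

* **C** — ≥ 1 reliable CTCF-binding element: a PWM hit with log-odds score
  above threshold that overlaps a ChIP peak in ≥ 2 repeats. The scanner
  scores `Σ log2(((c+ε)/(T+4ε))/0.25)` per column with pseudocount
  ε = 0.01·T. The default threshold 13 is carried over from the FIMO scale
  historically used with the JASPAR CTCF matrix; the generic scanner is not
  guaranteed score-identical to FIMO, so the threshold is configurable.
  Orientations are reported as rightward (+) / leftward (−) — the feature
  that matters for loop-extrusion impediments.
* **E** — maximum E2A signal in the window ≥ 0.5.
* **T** — transcription: a GRO repeat supports the call if its max ≥ 40 *or*
  its mean ≥ 10 over the window (mean over the whole window with uncovered
  bases as 0); T requires ≥ 2 supporting repeats.
* **U** — none of the above.

Labels are a pure function of window summaries, so peak order never affects
the outcome.

## Synthetic data: what it emulates, and what it does not

`make_synthetic_locus` builds a uniform-random sequence (default 200 kb; 120
kb in most tests — large enough for hundreds of restriction sites and a
realistic segment layout while keeping the suite fast) with:

* 24 V-like segments (consensus 12-RSS, minus orientation) spread over the
  first ~70 % of the locus, strengths log-uniform on [0.5, 5] unless given,
  domain-labelled proximal/middle/distal by position tercile, plus a bait
  23-RSS at 88 % of the locus (strength 0: it is the bait, never a prey);
* cryptic CAC sites planted as close +/− pairs (20 bp apart) so any window
  around the recombination centre contains exactly balanced orientations —
  this makes the diffusion-mode 50/50 expectation exact, not approximate.
  The auto-layout keeps an 80-bp margin from planted RSSs so a jittered
  cryptic junction can never fall inside the on-target tolerance;
* CATG sites at a configurable mean spacing (≈ 250 bp) in addition to natural
  occurrences; the restriction map is scanned from the final sequence so it
  is exact by construction;
* optional CBE (consensus motif sequence), E2A and transcription feature
  positions for the annotation closure tests.

A rejection-rewrite pass then scans the draft sequence and mutates one
currently-consensus-matching base of any accidental ≤ 4-mismatch RSS
(preferring its CAC gate), iterating to a fixed point, so the planted catalog
is *exactly* the set of filter-passing sites — the property that turns
scanner tests into exact set-equality tests.

`simulate_vdj_library` draws on-target junctions multinomially over segment
strengths and cryptic junctions under one of two modes: **scanning** (only
CACs convergent with the bait, between the recombination centre and a planted
impediment at 30 % of the locus by default, intensity decaying exponentially
with distance at scale = half the scanned span) or **diffusion** (both
orientations within a 60-kb default radius, uniform). Junction positions get
a resection jitter uniform on [0, 15) bp on the coding-flank side —
deliberately exercising the 15-bp collapsing radius exactly at its boundary.
Remaining reads are germline. The scanning-intensity decay and the diffusion
radius are simulation knobs, not biological estimates.

`simulate_3c_library` gives site weights A·(1+d)^(−decay) in distance d from
the bait (power-law contact decay, exponent 1 by default), times planted
anchor enrichments, plus a self-ligation spike inside the bait exclusion
interval carrying 15 % of reads by default; the requested total is allocated
multinomially, so totals are exact and the per-site marginals are as close to
independent Poissons as a fixed total allows. `simulate_site_count_track`
provides the caller's minimal input — i.i.d. Poisson counts over evenly
spaced sites with optional anchors — for calibration experiments.

What the generator does **not** emulate: mappability and alignment artefacts,
PCR duplication structure, sequence-composition bias of restriction-fragment
ligation, polymer physics of loop extrusion, or RSS-quality variation beyond
a scalar strength. Passing tests therefore demonstrate that the analysis
recovers its own generative truth under the stated statistical models — not
that the thresholds are optimal for any particular real dataset.

## Known limitations

* The PWM score scale is the package's own log-odds definition; the ">13"
  CBE threshold is inherited from an external scale and should be
  recalibrated if a different motif matrix or scanner is used.
* Bonferroni correction is per-library over tested sites in the region;
  genome-wide correction would be stricter.
* The peak caller's λ is purely local-median: it does not model the distance
  decay of 3C backgrounds, which is why the bait-proximal region can retain a
  broad significant peak after self-ligation removal.
* Welch's test and Pearson's p assume approximate normality of the inputs;
  with 2–5 repeats these are the field's conventional summaries rather than
  exact inference.
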