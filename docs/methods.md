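# Methods

## Scope and data model

`flowaudit` audits the transformations that 454 amplicon denoising
pipelines apply to reads.  It does not denoise: clustering outputs
(read→cluster maps plus representative sequences) are inputs, produced
by whatever denoiser is under audit.  The package's own computations
are flowgram filtering and base calling, demultiplexing, read
reconstitution, stage-to-stage change quantification, and
single-linkage preclustering diagnostics.

A flowgram is the vector of light intensities, one per nucleotide
flow, with the Titanium T-A-C-G dispensation cycle; the signal of a
flow approximates the length of the homopolymer incorporated.  Flow
values are handled at the two-decimal precision of the `sffinfo` text
dialect; "ends in .50" tests are made on that fixed-precision
representation, never on binary floating point.  Flow indices are
0-based internally and 1-based in reports, matching the dialect.  The
scan domain of every flowgram operation is `n_usable_flows`, the
highest flow index referenced by the record's Flow Indexes line (the
last flow the instrument base-called); the documented fallback when
that line is absent — synthetic data — is all flows.

## Filtering

Three families, sharing one `FilterParams` threshold set
(no-signal < 0.50, noisy interval 0.50–0.70, large-flow ceiling 6.49
with 9.49 as a known alternate, minimum 360 flows, ceiling 720; the
mothur-style variant uses 450/450):

* **framed** — whole frames of four flows are tested; truncation
  points are multiples of 4.  Criterion 3 is the strict interval
  (0.50, 0.70).  The scan inspects only one frame phase, so a
  low-signal run straddling a frame boundary is invisible; this
  blindness is deliberate and tested, because it explains missed
  ambiguous bases in frame-based filters.
* **flowwise** — the same criteria flow by flow, truncating
  immediately before the offending flow.  Criterion 1 requires the two
  *following* flows to be ≤ 0.50 (the printed asymmetry of < then ≤ is
  implemented as printed); criterion 3 is the half-open [0.50, 0.70),
  so a flow of exactly 0.50 triggers here but not in the framed
  family.  The no-truncate variant applies only the minimum-flow test.
* **quality window** — truncate at the start of the first window whose
  mean quality drops below the threshold (defaults 50 bp / Q25), then
  apply length bounds (150–550); `discard_truncated` eliminates any
  read that had a bad window.

Bookkeeping: a read's elimination reason is always the post-truncation
length test; the criterion that caused the truncation is recorded
separately, and report tables attribute eliminated reads to that
criterion.  This makes "truncated" and "eliminated" disjoint per-read
outcomes, which is how filter summary tables are conventionally read.
The 360-flow minimum interacts with frame truncation so that
357–359-flow survivors cannot occur in the framed family; both bounds
are configuration, not constants.

## Base calling

Each flow contributes `round(value)` copies of its nucleotide.  Two
half-rounding conventions are provided because pipelines genuinely
disagreed on them: `half_down` (instrument-majority behaviour) and
`half_up` (several pipeline scripts).  They differ only at flows whose
two-decimal value ends in .50.

N rules: `three_low` emits one N per maximal run of ≥ 3 consecutive
flows below 0.50; `four_low_framed` requires the run to span a whole
dispensation cycle (four flows, any phase).  One N is emitted per run
regardless of run length, since the true number of missing bases is
unknowable from the flowgram.  Two boundary cases emit nothing: a
*leading* low run (before the first incorporation, up to three dark
flows simply mean the first base sits later in the cycle) and a
*trailing* low run (no evidence any base follows the last
incorporation).  An N maps to the first flow of its run in the
per-base flow map, which is what the flow-evidence view
(`flows_for_positions`) reports when judging whether a denoiser's
change is supported by the raw signal.

A structural consequence, verified by property test: after flowwise
truncation the retained prefix contains no triggering triple, so
`three_low` calling emits no N at all.

## Demultiplexing

Reads are matched by their instrument base call against
mid-tag + primer patterns.  Exact mode is literal comparison with
IUPAC degeneracy in the primer free of charge (the degenerate M in one
standard primer must match A or C at no cost); longer mid tags are
tried first.  Tolerant mode budgets substitutions (and, when enabled,
single-base indels) as an edit distance, computed with edlib in
start-anchored prefix mode with IUPAC equality pairs.  Ties at the
minimal distance across keys leave the read unassigned as "ambiguous"
— auditability beats recovery, so no arbitrary tie-break.  When a key
table shares each sample's mid tag across several primers, bins are
(sample × primer) pairs.

## Change quantification

Phase 1 (end-tolerant) measures the 3′ gap: a global affine-gap
alignment in which the 3′ end is free — trailing gap runs cost nothing
and are excluded from the traced path — while the 5′ end is anchored.
The anchor matters: reads compared across stages share their 5′ start,
and with both ends free a periodic sequence leaves the overhang
placement ambiguous (an ACGT-repeat prefix pair can report −3 instead
of −311).  A leading gap run that survives the anchor is reported
separately as a 5′ overhang (`gap5`) and flagged; it indicates a
prefix-handling problem upstream and is never folded into the 3′ gap.
Overhang ties are broken toward the smaller overhang, then toward the
lexicographically greater sequence, which keeps gap3 exactly
antisymmetric under argument swap.

The overhanging 3′ bases are removed from the longer sequence and
phase 2 (strict) aligns the trimmed pair globally with a prohibitive
gap-opening penalty, so gaps appear only where the lengths force them.
Columns are classified as match, substitution, insertion (query-only
base) or deletion (reference-only base); maximal gap runs are counted
once as events, and base-pair counts are summed run lengths.

Scoring defaults: match +5, mismatch −4; gap open −100, extend −1 in
*both* phases.  The end phase's tolerance comes entirely from the free
3′ end, not from cheap internal gaps: with a cheap internal opening a
luckily-matching ±1 shift of a divergent tail can outscore the true
pairing and bias the overhang by a base (observed on synthetic
accordion cohorts before the default was fixed).  The implementation
requires `gap_open ≤ gap_extend ≤ 0`; under that convexity a gap never
profitably re-opens out of another gap in the same row, which the
vectorised Gotoh recurrence exploits and which keeps the optimum
unique under the fixed traceback priority (diagonal > vertical >
horizontal).  Gap cost convention: the first gap column of a run costs
`gap_open`, each further column `gap_extend`.

`iupac_tolerant` treats a column pairing a degenerate code with one of
its member bases (in either direction, N included) as a match.  It
defaults to off: in stage comparisons an N converted to a regular base
is a genuine change and must count as a substitution, so the flag
should be enabled only for comparisons where reads still carry a
degenerate primer base.

Aggregation: stage tables are exact column sums of the per-read
records (conservation is property-tested); reads present only in the
reference are "eliminated at this stage" and excluded from totals,
because only surviving reads are comparable.  The accordion report
compares, per category, the sum of two step totals with the net
first-to-last total and flags net > sum; the positional profile
histograms changes by 1-based query coordinate (deletion events at the
position before which the missing bases would sit).

## Event distance and preclustering

The single-linkage event distance is
(mismatches + indel events) / (matches + mismatches + indel events) on
an optimal *global* alignment whose terminal gap runs are excluded
from the count afterwards.  Global-then-strip matters: a fully free
overlap alignment would let two unrelated reads meet on a handful of
bases at distance 0, whereas the global alignment forces a full
comparison and still gives distance 0 to two reads identical over the
shorter read's length — the property that lets width-0 single linkage
chain two divergent long reads through a shared short read, which is
precisely the failure mode the audit must reproduce.  The generalised
numerator (mismatches + events together) extrapolates the documented
single-event worked example; the distance is made exactly symmetric by
aligning each pair in canonical (lexicographic) order, since traceback
tie-breaks are orientation-dependent.

`slp_cluster` processes reads in decreasing abundance (ties by id).  A
read joins the first cluster, in creation order, that admits it —
any-member mode within the width of *any* member (true single
linkage), center-only mode within the width of the seed — and
otherwise seeds a new cluster.  Join provenance (admitting member and
chain depth) is retained; `chaining_depth` reports the longest
admission chain and the maximum member-to-seed distance.  Center-only
bounds that radius by the width by construction; any-member can exceed
it at depth ≥ 2, the chaining diagnostic.

## The synthetic generators

The flowgram simulator emulates exactly the phenomena the filters
react to.  Ideal flow values equal homopolymer lengths; per-flow
Gaussian noise (SD 0.05, truncated at zero) is small enough that noise
alone never crosses the 0.50 or 6.49 thresholds, so every
filter-triggering flow in a synthetic cohort is an *injected* one.
Injected phenomena — one noisy flow in [0.50, 0.70), one large flow in
(6.49, 10), or one zeroed three-flow run — are drawn per read as
mutually exclusive events (the rates are per-read probabilities,
summing to ≤ 1) and placed downstream of the mid + primer prefix
flows.  Those two choices make the ground truth exactly recoverable:
each read's filtering outcome attributes to exactly one cause, and
demultiplexing is never corrupted by an injected error.  Real data is
messier in both respects — real reads carry multiple interacting
errors, errors inside the barcode/primer region, and signal drift
along the read that the flat noise model omits — so passing
truth-table tests demonstrates correctness of the bookkeeping, not
field performance of any filter.

Sequence-level generators build stage pairs and triples with known
edits.  Edits are separated by ≥ 60 bases and kept clear of the read
ends; this is not cosmetic: a strict aligner scores two nearby
opposing gaps as a substitution run (a property of optimal alignment,
not of this implementation), so only well-separated edits have a
unique decomposition for truth comparison.  The accordion cohort
truncates by 20–60 bases and re-extends with tails mutated at 30% of
positions — divergent enough to make the effect visible, not so
divergent that tail pairing itself becomes unstable.

## Problem sizes and determinism

Everything is deterministic: simulators take explicit seeds, the
aligner has a fixed tie-break order, clustering order is total, and
report bundles are byte-identical across reruns (verified in tests).
Default test and acceptance runs use cohorts of 50–1,000 reads of
~400 bases and alignment oracles on 1,000 pairs of ≤ 30 bases — sizes
chosen so the full suite runs in well under a minute per module while
still exercising every code path at realistic read lengths.  The
aligner is O(nm) time and memory per pair (numpy row recurrences with
a prefix-max trick for the horizontal gap state), which handles
full-scale cohorts of tens of thousands of 400–800 bp reads in
minutes to hours on one core; the preclustering audit is O(n²)
distance evaluations and is intended for per-sample bins, not whole
runs (no k-mer prefilter is provided, by design).

## Known limitations

* Binary SFF files are out of scope; convert with `sffinfo` first.
* The base caller does not model CAFIE/signal-droop corrections; it
  reproduces interpretation conventions, not the proprietary signal
  processing.
* The aligner's change decompositions are optimal-alignment
  decompositions; where a denoiser's own aligner preferred a different
  optimum, per-category counts can differ slightly even when the
  total edit content agrees.
* The event-distance denominator when mismatches and indel events
  co-occur follows the generalised form above; tools differed here,
  and the choice is logged when both kinds co-occur in one pair.
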