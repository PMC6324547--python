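# Methods

## Model and assumptions

`tilegap` closes scaffold gaps by anchoring long reads through tiling paths
of fixed-length tags rather than whole-read alignment. The approach assumes
that (i) a read's tags, although individually error-bearing, are long
enough (default 300 bp) to align to the correct locus most of the time;
(ii) consistent orientation and collinear order of several tags from one
read is strong evidence that the read is placed correctly; and (iii) the
sequence a correctly placed read holds over a gap is a better estimate of
the missing bases than leaving `N`, even uncorrected. Fills are copied
verbatim from reads — there is deliberately no consensus calling or local
reassembly — so fill base quality equals read base quality. With raw reads
at ~10% error the filled sequence carries ~10% error; with error-corrected
or HiFi-like reads it approaches the truth. This trade is intrinsic to the
method, not an implementation shortcut.

All internal coordinates are 0-based, half-open. SAM input is converted at
the parser boundary. Reverse-orientation reads are canonicalized by reverse
complement with tag offsets mapped as `p' = L − p − tag_len`, so all
extension, pairing, and fill arithmetic runs in a forward frame.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `tag_len` | 300 bp | tag size; the coverage denominator, so all tags share it and the sub-tag read remainder is dropped |
| `min_coverage` | 0.80 | retention threshold on (match + inserted bases)/tag_len, inclusive; unclamped above 1 |
| `min_tag_count` | 5 | minimum anchored tags per read per gap boundary, inclusive |
| `max_deviation` (c) | 0.2 | half-width of the open interval 1 ± c for the read/scaffold distance ratio, reused for multi-mapper rescue |
| `boundary_window` | 5,000 bp | how far from a gap edge an anchor still counts as boundary support |
| `min_gap_len` | 1 | smallest N run reported as a gap; terminal N runs are kept (closable one-sided only) |
| `iterations` | 3 | closure rounds; the loop stops early when a round fills nothing |

The boundary window deserves a note: boundary support counts anchors whose
alignments end (left side) or start (right side) within the window of the
gap edge. Five non-overlapping 300-bp tags occupy ≥ 1,500 bp, so any window
much below ~2 kb can never admit the default tag count; 5 kb gives room for
several tags to drop out under noise while still requiring the support to
sit near the gap. The window must be ≥ `tag_len` and should scale with it.

Thresholds quoted as "over X" are implemented inclusively (≥ 0.80,
≥ 5 tags); the pair-ratio interval `1 − c < r < 1 + c` is strict on both
ends. Coverage and ratio comparisons use exact rational arithmetic so
boundary cases cannot drift with floating-point rounding.

## Numerical and tie-breaking choices

- Median reference for the order filter: lower median on even group sizes,
  so the reference is always a real tag. The consistency check is relative
  to the reference only, exactly as the rule is stated; it does not force
  full pairwise monotonicity, and a second application can in contrived
  configurations remove further tags. On collinear-up-to-outliers groups —
  the case the filter exists for — one pass is stable.
- Orientation tie (equal tag counts per strand): the whole (read, scaffold)
  group is discarded as unreliable.
- Spanning-read tie (equal pair counts): longer read, then lexicographically
  smaller id. Boundary-support tie (equal gap proportion): more tags, then
  smaller id. All ties are deterministic.
- Multi-mapper rescue uses only type-1 anchors as neighbours (a rescued tag
  cannot vouch for another), requires both neighbours to agree on scaffold
  and orientation, and demands a unique surviving candidate; ties rescue
  nothing.
- Type-1 fills exclude the anchor tags themselves: the fill starts at the
  left anchor's end and stops at the right anchor's start, and the replaced
  scaffold interval runs between the corresponding alignment end/start.
  The anchors are the trusted correspondence points; the small flank slack
  between an anchor and the gap edge is rewritten from the read, which is
  why closed loci can differ slightly in length from L(C).
- Type-2 joins keep the printed padding formula with boundary-entry
  positions (the read base that lands on the gap edge), which makes the
  spacer exactly `L(C) − (ext_left + ext_right)`; interval length is then
  conserved and coordinates do not shift for unmet joins. Jointly
  over-spanning reads are joined around a 100-N sentinel, marking a
  junction a later iteration may confirm as type 1.
- Type-3 over-extension is truncated to leave the same 100-N sentinel — a
  one-sided extension never silently fabricates a verified junction. Zero
  extension emits no edit. A gap shorter than the 100-N sentinel that is
  over-spanned in type 2 would grow; such gaps simply persist across
  iterations (the default simulated gaps are ≥ 200 bp).
- Edits are applied right-to-left per scaffold; intervals must be pairwise
  disjoint. When two gaps' replacement intervals collide in one round, the
  leftmost is applied and the other deferred to the next iteration.
- A precomputed-SAM aligner supports exactly one iteration, because its
  coordinates refer to the input assembly; iterative runs need a re-running
  aligner (external command or built-in).
- `--threads` is accepted for interface compatibility but execution is
  serial; at the problem sizes the simulations use (≤ a few hundred kb,
  seconds per run) scheduling would cost more than it saves, and output is
  trivially independent of thread count.

## What the simulator emulates — and what it does not

`make_genome` draws an i.i.d. uniform background and can plant exact copies
of one repeat unit (default separation ≥ 100 bp; the repeat-gap study uses
3,000 bp so each gap keeps a uniquely mappable flank long enough for five
tags). `introduce_gaps` replaces either random intervals (lengths uniform
in 200–2,000 bp, at least one real base between gaps) or every planted
repeat ≥ 200 bp with an equal-length N run, recording the removed truth.
`simulate_long_reads` draws log-normal lengths (mean 10 kb, σ = 0.55,
clamped to ≥ 1 kb), uniform start positions, equiprobable strands, and
applies independent per-base substitution/insertion/deletion errors.

Real long reads are not i.i.d.: errors cluster in homopolymers, read
lengths and coverage are non-uniform, and real genomes carry nested and
diverged repeat families rather than exact copies. Passing the simulated
conditions therefore demonstrates the correctness of the anchoring and
arithmetic — not field performance on any particular instrument. The
built-in exact aligner only finds perfect full-length tag matches and is
used with error-free reads; noisy conditions go through BWA-MEM via the
external-command contract.

Evaluation re-locates each gap in the closed assembly by approximate infix
alignment of its 300-bp truth flanks (robust to small boundary rewrites)
and scores the recovered locus against the removed truth by global pairwise
alignment; identity is `1 − edits/max(len)` in percent. Contigs are maximal
N-free runs; N50 is the classic half-total threshold. This is a lightweight
truth-based stand-in for reference-comparison tools, not a misassembly
caller.

## Study-condition sizes

The shipped test suite and acceptance script use a 200 kb genome with 20
random gaps at 20× coverage for the error-free and noisy conditions, and a
100 kb genome with ten 500-bp repeat copies for the repeat-derived
condition — large enough that each run exercises hundreds of reads and
thousands of tags through every filter, small enough that the whole suite
runs in well under a minute per condition.

## Known limitations

- Fill identity is bounded by read identity (no polishing); at 10% raw
  error, closed loci measure ~90% identity against truth.
- Gaps whose N-run length misstates the true gap size (fixed-size
  placeholders from some scaffolders) use the N-run length as L(C); the
  padding arithmetic for types 2 and 3 is then approximate, though type-1
  closures are unaffected (they replace the interval outright).
- Scaffolds are never merged, split, or joined; terminal gaps can only be
  extended one-sided.
- The orientation vote is per (read, scaffold); a read chimeric within one
  scaffold defeats it only when the halves tie exactly.
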